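"""Matrisome annotation, differential ANOVA, OH-Lys statistics, clustering."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from ecmprofiler.config import ProteomicsSpec, default_config
from ecmprofiler.matrisome import (
    PeptideTable,
    ProteinQuantTable,
    annotate_matrisome,
    cluster_heatmap,
    collagen_ratio,
    differential_ecm,
    ohlys_statistic,
)
from ecmprofiler.synthetic import generate_matrisome_db, generate_proteomics_tables


@pytest.fixture(scope="module")
def study(cfg):
    table, peptides = generate_proteomics_tables(cfg)
    table, counts = annotate_matrisome(table, generate_matrisome_db())
    return table, peptides, counts


def _tiny_table(values: dict, conditions=("healthy", "crc"), patients=(1, 2)):
    names = [f"{c}_p{p}_r1" for c in conditions for p in patients]
    intens = pd.DataFrame(
        {n: list(values.values()) for n in names}, index=list(values)
    ).astype(float)
    genes = pd.Series(list(values), index=list(values))
    samples = pd.DataFrame(
        [(c, p, 1) for c in conditions for p in patients],
        columns=["condition", "patient", "replicate"],
        index=names,
    )
    return ProteinQuantTable(intensities=intens, genes=genes, samples=samples)


class TestAnnotation:
    def test_study_counts_match_design(self, study):
        _table, _peps, counts = study
        assert counts["matrisome"] == 128
        assert counts["division"]["core matrisome"] == 76
        assert counts["division"]["matrix-associated"] == 52
        assert counts["category"]["collagen"] == 18
        assert counts["category"]["proteoglycan"] == 12

    def test_counts_partition_the_table(self, study):
        table, _peps, counts = study
        div = counts["division"]
        assert sum(div.values()) == counts["total"] == len(table.intensities)

    def test_unmatched_gene_is_non_matrisome(self):
        db = generate_matrisome_db()
        table = _tiny_table({"NOTAGENE": 10.0, "col1a1": 20.0})
        table, counts = annotate_matrisome(table, db)
        assert table.annotation.loc["NOTAGENE", "division"] == "non-matrisome"
        # matching is case-insensitive
        assert table.annotation.loc["col1a1", "category"] == "collagen"

    def test_empty_table_all_counts_zero(self):
        table = _tiny_table({})
        table, counts = annotate_matrisome(table, generate_matrisome_db())
        assert counts["matrisome"] == 0 and counts["total"] == 0

    def test_conflicting_db_categories_raise(self):
        db = pd.DataFrame(
            {
                "gene": ["FN1", "FN1"],
                "division": ["core matrisome", "matrix-associated"],
                "category": ["ECM glycoprotein", "ECM regulator"],
            }
        )
        with pytest.raises(ValueError, match="FN1"):
            annotate_matrisome(_tiny_table({"FN1": 1.0}), db)


class TestDifferentialEcm:
    def test_recovers_configured_crc_effects(self, study):
        table, _peps, _counts = study
        result = differential_ecm(table)
        found = set(result.index[result["significant"]])
        truth = set(table.truth["dysregulated"])
        recall = len(found & truth) / len(truth)
        assert recall >= 0.95
        # no false positives among the other matrisome proteins
        assert len(found - truth) <= int(0.01 * len(result)) + 2

    def test_null_type_one_error_near_alpha(self):
        # no effects, 1000 proteins: the significant fraction must sit
        # within the binomial band around alpha = 0.01
        config = default_config(19)
        spec = replace(
            config.proteomics, n_proteins=1000, crc_effects={}, ohlys_overrides={}
        )
        config = replace(config, proteomics=spec)
        table, _peps = generate_proteomics_tables(config)
        table, _ = annotate_matrisome(table, generate_matrisome_db())
        # test over all proteins for a meaningful m
        table.annotation["division"] = "core matrisome"
        result = differential_ecm(table, alpha=0.01)
        m = len(result)
        frac = result["significant"].mean()
        band = 2 * np.sqrt(0.01 * 0.99 / m)
        assert abs(frac - 0.01) <= band

    def test_copied_samples_never_significant(self):
        table = _tiny_table({"FN1": 100.0, "DCN": 7.0})
        table, _ = annotate_matrisome(table, generate_matrisome_db())
        result = differential_ecm(table)
        assert not result["significant"].any()
        assert result["flagged"].all()


class TestOhlysStatistic:
    def test_generator_crc_elevation_limited_to_col1a1(self, study):
        table, peptides, _ = study
        global_frac, per_protein = ohlys_statistic(peptides, table)
        cond = table.samples["condition"]
        g = global_frac.groupby(cond).mean()
        assert g["crc"] > g["healthy"]
        col1 = per_protein.loc["COL1A1"].groupby(cond).mean()
        assert col1["crc"] == pytest.approx(0.20, rel=0.05)
        assert col1["healthy"] == pytest.approx(0.05, rel=0.05)
        # a background collagen is unchanged across conditions
        other = per_protein.drop(["COL1A1", "COL11A1"]).dropna(how="all")
        spread = other.T.groupby(cond).mean().T
        assert np.allclose(spread["crc"], spread["healthy"], rtol=0.05)

    def test_global_equals_intensity_weighted_per_protein_average(self, study):
        table, peptides, _ = study
        global_frac, per_protein = ohlys_statistic(peptides, table)
        sample = table.intensities.columns[0]
        matrisome = table.matrisome_ids
        intens = table.intensities.loc[matrisome, sample]
        fracs = per_protein[sample].reindex(matrisome).fillna(0.0)
        weighted = (intens * fracs).sum() / intens.sum()
        assert global_frac[sample] == pytest.approx(weighted, rel=1e-9)

    def test_no_ohlys_peptides_gives_zero(self, study):
        table, peptides, _ = study
        plain = peptides.peptides[~peptides.ohlys_mask].reset_index(drop=True)
        stripped = PeptideTable(peptides=plain, sample_names=peptides.sample_names)
        global_frac, per_protein = ohlys_statistic(stripped, table)
        assert (global_frac == 0).all()
        assert per_protein.empty

    def test_unknown_parent_protein_raises(self, study):
        table, peptides, _ = study
        bad = peptides.peptides.copy()
        bad.loc[0, "Proteins"] = "UNKNOWN9"
        with pytest.raises(ValueError, match="UNKNOWN9"):
            ohlys_statistic(
                PeptideTable(peptides=bad, sample_names=peptides.sample_names), table
            )


class TestCollagenRatio:
    def test_equal_intensities_fold_one(self):
        table = _tiny_table({"COL12A1": 50.0, "COL6A3": 20.0, "COL6A3-4": 30.0})
        per_sample, folds = collagen_ratio(table)
        assert np.allclose(per_sample, 1.0)
        assert folds["crc"] == pytest.approx(1.0)

    def test_generator_crc_shift_in_printed_range(self, study):
        table, _peps, _ = study
        _per_sample, folds = collagen_ratio(table)
        assert 50.0 <= folds["crc"] <= 200.0
        assert folds["perilesional"] == pytest.approx(1.0, rel=0.6)

    def test_missing_collagen_raises(self):
        table = _tiny_table({"COL12A1": 1.0})
        with pytest.raises(ValueError, match="COL6A3"):
            collagen_ratio(table)


class TestClusterHeatmap:
    def test_crc_samples_form_their_own_cluster(self, study):
        table, _peps, _ = study
        result = differential_ecm(table)
        cl = cluster_heatmap(table, result.index[result["significant"]])
        cut = cl.cut_samples(2)
        conds = table.samples.loc[cut.index, "condition"]
        crc_labels = set(cut[conds == "crc"])
        other_labels = set(cut[conds != "crc"])
        assert len(crc_labels) == 1
        assert crc_labels.isdisjoint(other_labels)

    def test_row_permutation_invariance(self, study):
        table, _peps, _ = study
        result = differential_ecm(table)
        sig = list(result.index[result["significant"]])
        cl1 = cluster_heatmap(table, sig)
        cl2 = cluster_heatmap(table, sig[::-1])
        assert np.array_equal(cl1.protein_linkage, cl2.protein_linkage)
        assert cl1.protein_order == cl2.protein_order

    def test_all_equal_rows_excluded(self):
        table = _tiny_table({"A": 5.0, "B": 5.0, "FN1": 1.0, "DCN": 2.0})
        # make FN1/DCN vary so two variable rows remain
        table.intensities.loc["FN1"] = [1.0, 2.0, 3.0, 4.0]
        table.intensities.loc["DCN"] = [4.0, 3.0, 2.0, 1.0]
        cl = cluster_heatmap(table, ["A", "B", "FN1", "DCN"])
        assert set(cl.excluded) == {"A", "B"}
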