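"""Matrisome-level statistics on label-free proteomics tables.

The matrisome is the curated gene set of ECM and ECM-associated proteins,
split into a core division (collagens, proteoglycans, ECM glycoproteins)
and a matrix-associated division (ECM-affiliated proteins, ECM regulators,
secreted factors).  This module annotates MaxQuant-style protein tables
against a matrisome category table, tests differential ECM composition by
per-protein one-way ANOVA, computes hydroxylysine intensity statistics from
the peptide table, the collagen XII : collagen VI balance, and hierarchical
clustering for the report heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage

__all__ = [
    "ProteinQuantTable",
    "PeptideTable",
    "OHLYS_TOKEN",
    "annotate_matrisome",
    "differential_ecm",
    "ohlys_statistic",
    "collagen_ratio",
    "cluster_heatmap",
    "ClusterResult",
]

#: modification token marking a hydroxylated (oxidized) lysine in the
#: "Modified sequence" column
OHLYS_TOKEN = "K(ox)"

CORE_DIVISION = "core matrisome"
ASSOCIATED_DIVISION = "matrix-associated"
NON_MATRISOME = "non-matrisome"


def sample_name(condition: str, patient: int, replicate: int) -> str:
    return f"{condition}_p{patient}_r{replicate}"


def parse_sample_name(name: str) -> tuple[str, int, int]:
    cond, pat, rep = name.rsplit("_", 2)
    return cond, int(pat.lstrip("p")), int(rep.lstrip("r"))


@dataclass
class ProteinQuantTable:
    """Protein-level LFQ intensities plus sample and matrisome annotation.

    ``intensities`` is proteins x samples (index: protein id); ``genes``
    maps protein id to gene symbol; ``samples`` (index: sample name) has
    columns condition / patient / replicate; ``annotation`` (set by
    :func:`annotate_matrisome`) has columns division / category.
    """

    intensities: pd.DataFrame
    genes: pd.Series
    samples: pd.DataFrame
    annotation: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.intensities.values < 0).any():
            raise ValueError("LFQ intensities must be >= 0")
        if not self.genes.index.equals(self.intensities.index):
            raise ValueError("genes must be indexed by the same protein ids")

    @property
    def matrisome_ids(self) -> pd.Index:
        if self.annotation is None:
            raise ValueError("table is not annotated; run annotate_matrisome first")
        return self.annotation.index[self.annotation["division"] != NON_MATRISOME]

    def patient_means(self, ids=None) -> pd.DataFrame:
        """Replicate-averaged intensities, columns (condition, patient)."""
        sub = self.intensities if ids is None else self.intensities.loc[ids]
        cols = pd.MultiIndex.from_frame(self.samples[["condition", "patient"]])
        grouped = sub.T.groupby(cols).mean().T
        grouped.columns = pd.MultiIndex.from_tuples(
            grouped.columns, names=["condition", "patient"]
        )
        return grouped

    def to_maxquant_tsv(self, path) -> None:
        out = pd.DataFrame({"Protein IDs": self.intensities.index,
                            "Gene names": self.genes.values})
        for col in self.intensities.columns:
            out[f"LFQ intensity {col}"] = self.intensities[col].values
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_maxquant_tsv(cls, path) -> "ProteinQuantTable":
        df = pd.read_csv(path, sep="\t")
        lfq = [c for c in df.columns if c.startswith("LFQ intensity ")]
        names = [c[len("LFQ intensity "):] for c in lfq]
        intens = df[lfq].copy()
        intens.columns = names
        intens.index = df["Protein IDs"].values
        genes = pd.Series(df["Gene names"].values, index=intens.index)
        samples = pd.DataFrame(
            [parse_sample_name(n) for n in names],
            columns=["condition", "patient", "replicate"],
            index=names,
        )
        return cls(intensities=intens, genes=genes, samples=samples)


@dataclass
class PeptideTable:
    """Peptide-level intensities with hydroxylysine flags.

    ``peptides`` has columns Sequence / Modified sequence / Proteins (the
    parent protein id) plus per-sample intensity columns matching the
    protein table's sample names.
    """

    peptides: pd.DataFrame
    sample_names: tuple[str, ...]

    def __post_init__(self) -> None:
        for col in ("Sequence", "Modified sequence", "Proteins"):
            if col not in self.peptides.columns:
                raise ValueError(f"peptide table lacks column {col!r}")

    @property
    def ohlys_mask(self) -> pd.Series:
        return self.peptides["Modified sequence"].str.contains(
            OHLYS_TOKEN, regex=False
        )

    def to_tsv(self, path) -> None:
        self.peptides.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PeptideTable":
        df = pd.read_csv(path, sep="\t")
        meta = {"Sequence", "Modified sequence", "Proteins", "Gene names"}
        names = tuple(c for c in df.columns if c not in meta)
        return cls(peptides=df, sample_names=names)


def annotate_matrisome(
    table: ProteinQuantTable, db: pd.DataFrame
) -> tuple[ProteinQuantTable, dict]:
    """Case-insensitive gene-symbol join against a matrisome table.

    ``db`` needs columns gene / division / category.  Unmatched proteins
    become non-matrisome.  Duplicate genes in the database with conflicting
    categories raise, listing the offenders.  Returns the annotated table
    (annotation set in place) and counts per division and category.
    """
    for col in ("gene", "division", "category"):
        if col not in db.columns:
            raise ValueError(f"matrisome table lacks column {col!r}")
    keyed = db.assign(_key=db["gene"].str.upper())
    conflict = (
        keyed.groupby("_key")[["division", "category"]].nunique().max(axis=1) > 1
    )
    if conflict.any():
        offenders = sorted(conflict.index[conflict])
        raise ValueError(f"conflicting matrisome categories for genes: {offenders}")
    lookup = keyed.drop_duplicates("_key").set_index("_key")[["division", "category"]]

    keys = table.genes.astype(str).str.upper()
    ann = lookup.reindex(keys.values)
    ann.index = table.intensities.index
    ann["division"] = ann["division"].fillna(NON_MATRISOME)
    ann["category"] = ann["category"].fillna(NON_MATRISOME)
    table.annotation = ann

    counts = {
        "total": int(len(ann)),
        "matrisome": int((ann["division"] != NON_MATRISOME).sum()),
        "division": ann["division"].value_counts().to_dict(),
        "category": ann[ann["division"] != NON_MATRISOME]["category"]
        .value_counts()
        .to_dict(),
    }
    return table, counts


def differential_ecm(
    table: ProteinQuantTable,
    alpha: float = 0.01,
    use_log: bool = True,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-protein one-way ANOVA across conditions on matrisome proteins.

    Replicates are averaged within each (condition, patient) so patients
    are the experimental unit.  By default intensities are log10
    transformed (zeros floored at the table's minimum positive value) and
    no multiplicity correction is applied — significance is the raw
    p < alpha; an optional Benjamini-Hochberg mode is available.  Proteins
    with zero within-group variance get a variance-floored p and a flag.
    Returns a frame indexed by protein id with columns p, significant,
    flagged.
    """
    ids = table.matrisome_ids
    data = table.patient_means(ids)
    values = data.values.astype(float)
    if use_log:
        positive = values[values > 0]
        floor = positive.min() if positive.size else 1.0
        values = np.log10(np.clip(values, floor, None))
    conditions = np.array([c for c, _p in data.columns])
    groups = [values[:, conditions == c] for c in pd.unique(conditions)]
    if len(groups) < 2 or min(g.shape[1] for g in groups) < 2:
        raise ValueError("need >= 2 conditions with >= 2 patients each")

    pvals = np.ones(len(ids))
    flagged = np.zeros(len(ids), dtype=bool)
    scale = max(float(np.abs(values).mean()), 1.0)
    for i in range(len(ids)):
        rows = [g[i] for g in groups]
        within = sum(float(np.var(r)) for r in rows)
        if within < (1e-9 * scale) ** 2:
            flagged[i] = True
            grand = np.concatenate(rows)
            # variance floor: identical groups are never significant
            pvals[i] = 0.0 if np.var([r.mean() for r in rows]) > (1e-9 * scale) ** 2 else 1.0
            if np.ptp(grand) < 1e-12 * scale:
                pvals[i] = 1.0
            continue
        pvals[i] = stats.f_oneway(*rows).pvalue

    result = pd.DataFrame({"p": pvals, "flagged": flagged}, index=ids)
    if bh_correction:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        ranked = pvals[order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        result["p_adjusted"] = np.clip(adj, 0, 1)
        result["significant"] = result["p_adjusted"] < alpha
    else:
        result["significant"] = result["p"] < alpha
    return result


def ohlys_statistic(
    peptides: PeptideTable, proteins: ProteinQuantTable
) -> tuple[pd.Series, pd.DataFrame]:
    """Hydroxylysine intensity fractions.

    Global, per sample: summed intensity of OH-Lys-bearing peptides divided
    by the summed matrisome protein intensity.  Per protein, per sample:
    the same numerator restricted to the protein's peptides, divided by
    that protein's intensity.  Zero denominators yield NaN.
    """
    names = list(peptides.sample_names)
    missing = [n for n in names if n not in proteins.intensities.columns]
    if missing:
        raise ValueError(f"peptide samples absent from protein table: {missing}")
    unknown_parents = set(peptides.peptides["Proteins"]) - set(proteins.intensities.index)
    if unknown_parents:
        raise ValueError(f"peptides reference unknown proteins: {sorted(unknown_parents)}")

    mask = peptides.ohlys_mask.values
    pep_int = peptides.peptides[names].values.astype(float)
    parents = peptides.peptides["Proteins"].values

    matrisome_total = proteins.intensities.loc[proteins.matrisome_ids, names].sum(axis=0)
    oh_total = pd.Series(pep_int[mask].sum(axis=0), index=names)
    with np.errstate(divide="ignore", invalid="ignore"):
        global_frac = oh_total / matrisome_total.replace(0, np.nan)

    oh_by_protein = (
        pd.DataFrame(pep_int[mask], columns=names)
        .assign(_parent=parents[mask])
        .groupby("_parent")
        .sum()
    )
    prot_int = proteins.intensities.loc[oh_by_protein.index, names]
    with np.errstate(divide="ignore", invalid="ignore"):
        per_protein = oh_by_protein / prot_int.replace(0, np.nan)
    return global_frac, per_protein


def collagen_ratio(
    table: ProteinQuantTable,
    col12: str = "COL12A1",
    col6_forms: tuple[str, ...] = ("COL6A3", "COL6A3-4"),
    reference: str = "healthy",
) -> tuple[pd.Series, dict[str, float]]:
    """Collagen XII over the summed collagen VI forms, and folds vs healthy.

    Returns the per-sample ratio and, per condition, the median across
    patients of the per-patient (replicate-averaged) fold vs the matched
    healthy sample.
    """
    required = (col12, *col6_forms)
    missing = [p for p in required if p not in table.intensities.index]
    if missing:
        raise ValueError(f"collagen entries missing from table: {missing}")
    num = table.intensities.loc[col12]
    den = table.intensities.loc[list(col6_forms)].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_sample = num / den.replace(0, np.nan)

    means = table.patient_means(list(required))
    num_m = means.loc[col12]
    den_m = means.loc[list(col6_forms)].sum(axis=0)
    ratio_m = num_m / den_m.replace(0, np.nan)  # index (condition, patient)
    ref = ratio_m.loc[reference]
    folds: dict[str, list[float]] = {}
    for (cond, pat), value in ratio_m.items():
        if pat in ref.index and np.isfinite(ref[pat]) and ref[pat] > 0:
            folds.setdefault(cond, []).append(value / ref[pat])
    fold_medians = {c: float(np.median(v)) for c, v in folds.items()}
    return per_sample, fold_medians


@dataclass
class ClusterResult:
    protein_linkage: np.ndarray
    sample_linkage: np.ndarray
    matrix: pd.DataFrame  #: log10, median-centred, leaf-ordered
    protein_order: list
    sample_order: list
    sample_index: list  #: sample order the linkage was built on
    excluded: list  #: all-equal rows dropped before clustering

    def cut_samples(self, k: int) -> pd.Series:
        labels = fcluster(self.sample_linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_index)


def cluster_heatmap(table: ProteinQuantTable, significant_ids) -> ClusterResult:
    """Average-linkage hierarchical clustering of significant proteins.

    Intensities are log10 transformed (zeros floored at the minimum
    positive value) and median-centred per protein; proteins and samples
    are clustered on Euclidean distance with deterministic leaf ordering
    (rows are sorted by protein id before linkage, so the result is
    invariant to input row order).  All-equal rows are excluded with
    notice.
    """
    ids = sorted(significant_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 significant proteins to cluster")
    data = table.intensities.loc[ids].astype(float)
    positive = data.values[data.values > 0]
    floor = positive.min() if positive.size else 1.0
    logged = np.log10(data.clip(lower=floor))
    centred = logged.sub(logged.median(axis=1), axis=0)
    keep = centred.std(axis=1) > 0
    excluded = list(centred.index[~keep])
    centred = centred.loc[keep]
    if len(centred) < 2:
        raise ValueError("fewer than 2 variable proteins left to cluster")

    prot_link = linkage(centred.values, method="average", metric="euclidean")
    samp_link = linkage(centred.values.T, method="average", metric="euclidean")
    prot_order = [
        centred.index[i]
        for i in dendrogram(prot_link, no_plot=True)["leaves"]
    ]
    samp_order = [
        centred.columns[i]
        for i in dendrogram(samp_link, no_plot=True)["leaves"]
    ]
    ordered = centred.loc[prot_order, samp_order]
    return ClusterResult(
        protein_linkage=prot_link,
        sample_linkage=samp_link,
        matrix=ordered,
        protein_order=prot_order,
        sample_order=samp_order,
        sample_index=list(centred.columns),
        excluded=excluded,
    )
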