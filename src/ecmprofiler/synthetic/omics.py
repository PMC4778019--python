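"""Synthetic matrisome database and MaxQuant-like LFQ tables.

The matrisome table is a synthetic stand-in for the curated human matrisome
gene list (1065 genes across six categories); it carries the real gene
symbols the analysis keys on (collagens I/VI/XI/XII, fibronectin, tenascin,
matrilin-2, nidogen-1, laminin beta-2, decorin, mimecan, dermatopontin,
fibulin-1, galectin-3, MFAP2, LOX) padded with synthetic symbols to the
database's category sizes.

The protein table mirrors a post-search proteinGroups file: 1139 proteins
of which 128 are matrisome (76 core: 12 proteoglycans + 18 collagens + 46
glycoproteins; 52 associated: 16 affiliated + 24 regulators + 12 secreted),
with lognormal biological (patient) and technical (replicate) noise and
carcinoma-only effects on a configured protein set.  The peptide table
carries hydroxylysine-flagged peptides whose intensity share of the parent
protein is condition dependent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import CONDITIONS, SimConfig
from ..matrisome import (
    OHLYS_TOKEN,
    PeptideTable,
    ProteinQuantTable,
    sample_name,
)
from ._seeds import STREAM_OMICS, child_rng

__all__ = ["generate_matrisome_db", "generate_proteomics_tables", "MATRISOME_DB_SIZE"]

#: category sizes of the matrisome table (gene counts)
_DB_CATEGORY_SIZES = {
    ("core matrisome", "proteoglycan"): 36,
    ("core matrisome", "collagen"): 45,
    ("core matrisome", "ECM glycoprotein"): 200,
    ("matrix-associated", "ECM-affiliated"): 176,
    ("matrix-associated", "ECM regulator"): 254,
    ("matrix-associated", "secreted factor"): 354,
}
MATRISOME_DB_SIZE = sum(_DB_CATEGORY_SIZES.values())  # 1065

#: real gene symbols per category, used before synthetic padding
_REAL_GENES = {
    ("core matrisome", "proteoglycan"): ["DCN", "OGN"],
    ("core matrisome", "collagen"): ["COL1A1", "COL6A3", "COL11A1", "COL12A1"],
    ("core matrisome", "ECM glycoprotein"): [
        "FN1", "TNC", "FBLN1", "MFAP2", "MATN2", "NID1", "LAMB2", "DPT",
    ],
    ("matrix-associated", "ECM-affiliated"): ["LGALS3"],
    ("matrix-associated", "ECM regulator"): ["LOX"],
    ("matrix-associated", "secreted factor"): [],
}

_CATEGORY_PREFIX = {
    "proteoglycan": "SPG",
    "collagen": "SCOL",
    "ECM glycoprotein": "SGP",
    "ECM-affiliated": "SAF",
    "ECM regulator": "SRG",
    "secreted factor": "SSF",
}

#: how many proteins of each category the synthetic study detects
_DETECTED_SIZES = {
    ("core matrisome", "proteoglycan"): 12,
    ("core matrisome", "collagen"): 18,  # rows; COL6A3 contributes two forms
    ("core matrisome", "ECM glycoprotein"): 46,
    ("matrix-associated", "ECM-affiliated"): 16,
    ("matrix-associated", "ECM regulator"): 24,
    ("matrix-associated", "secreted factor"): 12,
}


def _category_genes(division: str, category: str) -> list[str]:
    real = _REAL_GENES[(division, category)]
    total = _DB_CATEGORY_SIZES[(division, category)]
    prefix = _CATEGORY_PREFIX[category]
    fillers = [f"{prefix}{i:04d}" for i in range(1, total - len(real) + 1)]
    return real + fillers


def generate_matrisome_db() -> pd.DataFrame:
    """Synthetic matrisome category table (columns gene, division, category)."""
    rows = []
    for (division, category), _n in _DB_CATEGORY_SIZES.items():
        for gene in _category_genes(division, category):
            rows.append((gene, division, category))
    return pd.DataFrame(rows, columns=["gene", "division", "category"])


def _detected_proteins() -> pd.DataFrame:
    """Protein rows of the quant table: id, gene, division, category."""
    rows = []
    for (division, category), n in _DETECTED_SIZES.items():
        genes = _category_genes(division, category)
        if category == "collagen":
            # COL6A3 appears as two protein forms sharing the gene symbol
            picked = [g for g in genes if g != "COL6A3"][: n - 2]
            rows.append(("COL6A3", "COL6A3", division, category))
            rows.append(("COL6A3-4", "COL6A3", division, category))
            rows.extend((g, g, division, category) for g in picked)
        else:
            rows.extend((g, g, division, category) for g in genes[:n])
    return pd.DataFrame(rows, columns=["protein", "gene", "division", "category"])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    alphabet = np.array(list("ACDEFGHILMNPQSTVWY"))  # no K/R inside
    return "".join(rng.choice(alphabet, length))


def generate_proteomics_tables(
    config: SimConfig,
) -> tuple[ProteinQuantTable, PeptideTable]:
    """Simulate the protein and peptide tables of the configured study.

    Carcinoma-only multiplicative effects are applied to
    ``config.proteomics.crc_effects`` (raising if an effect targets a
    protein absent from the table); hydroxylysine peptide fractions default
    to ``ohlys_base_fraction`` on collagens and can be overridden per
    (condition, protein).  The returned protein table's ``truth`` records
    the dysregulated set and the per-condition OH-Lys fractions.
    """
    spec = config.proteomics
    rng = child_rng(config.seed, STREAM_OMICS)

    detected = _detected_proteins()
    n_matrisome = len(detected)
    if spec.n_proteins < n_matrisome:
        raise ValueError(
            f"n_proteins must be >= {n_matrisome} (the matrisome rows)"
        )
    n_other = spec.n_proteins - n_matrisome
    others = pd.DataFrame(
        {
            "protein": [f"NMX{i:04d}" for i in range(1, n_other + 1)],
            "gene": [f"NMX{i:04d}" for i in range(1, n_other + 1)],
            "division": "none",
            "category": "none",
        }
    )
    proteins = pd.concat([detected, others], ignore_index=True)
    ids = proteins["protein"].tolist()

    unknown = set(spec.crc_effects) - set(ids)
    if unknown:
        raise ValueError(f"effects requested for proteins absent from the table: {sorted(unknown)}")

    conditions = [c for c in config.conditions if c in CONDITIONS]
    names = [
        sample_name(c, p, r)
        for c in conditions
        for p in range(1, spec.n_patients + 1)
        for r in range(1, spec.n_replicates + 1)
    ]
    samples = pd.DataFrame(
        [(c, p, r)
         for c in conditions
         for p in range(1, spec.n_patients + 1)
         for r in range(1, spec.n_replicates + 1)],
        columns=["condition", "patient", "replicate"],
        index=names,
    )

    lo, hi = spec.base_log10_range
    base = rng.uniform(lo, hi, len(ids))
    # COL11A1 is essentially carcinoma-specific: low baseline expression
    base[ids.index("COL11A1")] = lo - 1.0
    # collagen I dominates ECM protein mass; its abundance is what lets a
    # COL1A1-specific hydroxylation shift move the global OH-Lys statistic
    base[ids.index("COL1A1")] = hi + 1.0

    effect_log10 = np.zeros(len(ids))
    for pid, fold in spec.crc_effects.items():
        effect_log10[ids.index(pid)] = np.log10(fold)

    # biological noise is shared within a (condition, patient) pair;
    # technical noise is per replicate column
    log_int = np.empty((len(ids), len(names)))
    bio = rng.normal(
        0.0, spec.sigma_patient_log10,
        (len(ids), len(conditions), spec.n_patients),
    )
    tech = rng.normal(0.0, spec.sigma_replicate_log10, (len(ids), len(names)))
    for j, (cond, pat, _rep) in enumerate(samples.itertuples(index=False)):
        ci = conditions.index(cond)
        log_int[:, j] = base + bio[:, ci, pat - 1] + tech[:, j]
        if cond == "crc":
            log_int[:, j] += effect_log10

    intensities = pd.DataFrame(10.0**log_int, index=ids, columns=names)
    genes = pd.Series(proteins["gene"].values, index=ids)

    # hydroxylysine fractions per (condition, protein)
    is_collagen = dict(zip(ids, proteins["category"] == "collagen"))
    def oh_fraction(cond: str, pid: str) -> float:
        if (cond, pid) in spec.ohlys_overrides:
            return spec.ohlys_overrides[(cond, pid)]
        return spec.ohlys_base_fraction if is_collagen[pid] else 0.0

    pep_rows = []
    matrisome_ids = detected["protein"].tolist()
    for pid in matrisome_ids:
        seqs = [_random_sequence(rng, int(rng.integers(8, 15))) + "K" for _ in range(3)]
        fracs = {c: oh_fraction(c, pid) for c in conditions}
        has_mod = any(f > 0 for f in fracs.values())
        prot = intensities.loc[pid]
        # two unmodified peptides split the unmodified share 60/40
        for share_idx, seq in enumerate(seqs[:2]):
            split = 0.6 if share_idx == 0 else 0.4
            row = {
                "Sequence": seq,
                "Modified sequence": f"_{seq}_",
                "Proteins": pid,
                "Gene names": genes[pid],
            }
            for name_ in names:
                cond = samples.loc[name_, "condition"]
                row[name_] = prot[name_] * (1.0 - fracs[cond]) * split
            pep_rows.append(row)
        if has_mod:
            seq = seqs[2]
            row = {
                "Sequence": seq,
                "Modified sequence": "_" + seq[:-1] + OHLYS_TOKEN + "_",
                "Proteins": pid,
                "Gene names": genes[pid],
            }
            for name_ in names:
                cond = samples.loc[name_, "condition"]
                row[name_] = prot[name_] * fracs[cond]
            pep_rows.append(row)

    peptides = PeptideTable(
        peptides=pd.DataFrame(pep_rows), sample_names=tuple(names)
    )
    truth = {
        "dysregulated": sorted(spec.crc_effects),
        "effects": dict(spec.crc_effects),
        "ohlys_fractions": {
            f"{c}:{pid}": oh_fraction(c, pid)
            for c in conditions
            for pid in matrisome_ids
            if oh_fraction(c, pid) > 0
        },
    }
    table = ProteinQuantTable(
        intensities=intensities, genes=genes, samples=samples, truth=truth
    )
    return table, peptides
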