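"""Collagen and pyridinoline-crosslink calculators.

Collagen content is estimated from hydroxyproline, which makes up 13.5% of
the collagen amino-acid composition; crosslink panels carry
hydroxylysyl-pyridinoline (HP) and lysyl-pyridinoline (LP), the two mature
trivalent crosslinks formed downstream of lysyl oxidase.  Summaries report
per-condition totals (HP + LP), the HP/LP ratio, and fold changes vs the
matched healthy sample of each patient, aggregated by the median across
patients.  Units are kit-relative; every reported quantity is a ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HYDROXYPROLINE_FRACTION",
    "CrosslinkSummary",
    "collagen_from_hydroxyproline",
    "crosslink_summary",
]

#: hydroxyproline share of the collagen amino-acid composition
HYDROXYPROLINE_FRACTION = 0.135

PANEL_COLUMNS = ("condition", "patient", "HP", "LP", "hydroxyproline")


def collagen_from_hydroxyproline(hydroxyproline: float) -> float:
    """Collagen mass implied by a hydroxyproline amount (same units)."""
    hyp = np.asarray(hydroxyproline, dtype=float)
    if np.any(hyp < 0):
        raise ValueError("hydroxyproline amount must be >= 0")
    result = hyp / HYDROXYPROLINE_FRACTION
    return float(result) if result.ndim == 0 else result


@dataclass(frozen=True)
class CrosslinkSummary:
    totals: dict[str, float]  #: median HP + LP per condition
    ratios: dict[str, float]  #: median HP/LP per condition
    total_folds: dict[str, float]  #: median per-patient total fold vs healthy
    ratio_folds: dict[str, float]  #: median per-patient ratio fold vs healthy
    collagen: dict[str, float]  #: median collagen estimate per condition
    flagged_samples: tuple[tuple[str, object], ...]  #: LP == 0 entries

    def as_dict(self) -> dict:
        return {
            "totals": self.totals,
            "ratios": self.ratios,
            "total_folds": self.total_folds,
            "ratio_folds": self.ratio_folds,
            "collagen": self.collagen,
            "flagged_samples": [list(x) for x in self.flagged_samples],
        }


def crosslink_summary(panel: pd.DataFrame, reference: str = "healthy") -> CrosslinkSummary:
    """Condition-level crosslink totals, HP/LP ratios and folds vs healthy.

    ``panel`` must have columns condition, patient, HP, LP, hydroxyproline
    with one row per (condition, patient).  Folds are computed within each
    patient against that patient's healthy sample, then medianed across
    patients.  Samples with LP == 0 have an undefined ratio and are flagged.
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing columns {missing}")
    if (panel[["HP", "LP", "hydroxyproline"]] < 0).any().any():
        raise ValueError("crosslink amounts must be >= 0")
    if reference not in set(panel["condition"]):
        raise ValueError(f"reference condition {reference!r} absent from panel")

    df = panel.copy()
    df["total"] = df["HP"] + df["LP"]
    flagged = []
    with np.errstate(divide="ignore", invalid="ignore"):
        df["ratio"] = np.where(df["LP"] > 0, df["HP"] / df["LP"], np.nan)
    for _, row in df[df["LP"] == 0].iterrows():
        flagged.append((str(row["condition"]), row["patient"]))
    df["collagen"] = df["hydroxyproline"] / HYDROXYPROLINE_FRACTION

    totals = df.groupby("condition")["total"].median().to_dict()
    ratios = df.groupby("condition")["ratio"].median().to_dict()
    collagen = df.groupby("condition")["collagen"].median().to_dict()

    ref = df[df["condition"] == reference].set_index("patient")
    total_folds: dict[str, list[float]] = {}
    ratio_folds: dict[str, list[float]] = {}
    for _, row in df.iterrows():
        pat = row["patient"]
        if pat not in ref.index:
            continue
        cond = str(row["condition"])
        r = ref.loc[pat]
        if r["total"] > 0:
            total_folds.setdefault(cond, []).append(row["total"] / r["total"])
        if np.isfinite(row["ratio"]) and np.isfinite(r["ratio"]) and r["ratio"] > 0:
            ratio_folds.setdefault(cond, []).append(row["ratio"] / r["ratio"])

    return CrosslinkSummary(
        totals={k: float(v) for k, v in totals.items()},
        ratios={k: float(v) for k, v in ratios.items()},
        total_folds={k: float(np.median(v)) for k, v in total_folds.items()},
        ratio_folds={k: float(np.median(v)) for k, v in ratio_folds.items()},
        collagen={k: float(v) for k, v in collagen.items()},
        flagged_samples=tuple(flagged),
    )
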