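"""Synthetic crosslink / hydroxyproline panels.

One row per (condition, patient) with HP, LP and hydroxyproline levels.
Patient variability and assay error enter as multiplicative lognormal
noise with a configurable coefficient of variation; at zero noise the
configured fold structure (total pyridinoline x1.5 perilesional, x2
carcinoma; HP/LP ratio doubled in carcinoma only) is exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import SimConfig
from ._seeds import STREAM_PANEL, child_rng

__all__ = ["generate_crosslink_panel"]


def generate_crosslink_panel(
    config: SimConfig, noise_cv: float | None = None
) -> pd.DataFrame:
    """Panel with columns condition, patient, HP, LP, hydroxyproline."""
    if noise_cv is None:
        noise_cv = config.study.crosslink_noise_cv
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = child_rng(config.seed, STREAM_PANEL)
    sigma = np.sqrt(np.log1p(noise_cv**2))  # lognormal with unit mean
    rows = []
    for patient in range(1, config.study.n_patients_panel + 1):
        for condition, spec in config.crosslinks.items():
            if noise_cv > 0:
                factors = np.exp(rng.normal(-0.5 * sigma**2, sigma, 3))
            else:
                factors = np.ones(3)
            rows.append(
                {
                    "condition": condition,
                    "patient": patient,
                    "HP": spec.hp * factors[0],
                    "LP": spec.lp * factors[1],
                    "hydroxyproline": spec.hydroxyproline * factors[2],
                }
            )
    return pd.DataFrame(rows)
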