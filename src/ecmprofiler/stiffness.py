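"""Mode decomposition and weighted-median summaries of stiffness data.

Distributions of Young's modulus measured on decellularized ECM are broad
and multi-modal: in log10 space they form an envelope of nearly Gaussian
modes, each attributable to micro-scale structural domains resolved by the
colloidal probe.  This module

* fits a Gaussian mixture to log10(E) with the model order chosen by BIC,
* summarizes each mode by the median of the corresponding lognormal,
  ``E_med = 10^mu``, with the asymptotic standard deviation of a sample
  median, ``sigma_med = E_med * ln(10) * sqrt(pi/2) * s / sqrt(N)``
  (delta-method transfer of the log-space median SD to Pa), and
* aggregates modes into a single effective rigidity: the weighted average
  of mode medians with weights ``f = N / N_tot`` (fraction of curves
  hard-assigned to the mode) and total error obtained by summing in
  quadrature the propagated median errors and an instrumental relative
  error ``eps_rel``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = [
    "LogMode",
    "StiffnessSummary",
    "decompose_modes",
    "mode_median",
    "weighted_summary",
    "summarize_moduli",
    "stiffness_fold",
]

#: sqrt(pi/2): asymptotic efficiency factor of a sample median vs the mean
MEDIAN_FACTOR = math.sqrt(math.pi / 2.0)

#: floor on the log10 spread of a degenerate (all-identical) sample
S_LOG10_FLOOR = 1e-3


@dataclass(frozen=True)
class LogMode:
    """One lognormal mode of a Young's-modulus distribution."""

    mu_log10: float  #: peak position in log10(Pa)
    s_log10: float  #: geometric spread (log10 units)
    n: int  #: curves hard-assigned to this mode
    f: float  #: weight n / n_total
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.s_log10 <= 0:
            raise ValueError("s_log10 must be > 0")
        if not 0 < self.f <= 1:
            raise ValueError("mode weight f must lie in (0, 1]")


@dataclass(frozen=True)
class StiffnessSummary:
    modes: tuple[LogMode, ...]
    medians_pa: tuple[float, ...]  #: E_med per mode
    sigma_medians_pa: tuple[float, ...]  #: sigma_med per mode
    weighted_median_pa: float  #: effective rigidity E
    sigma_pa: float  #: total error sigma_E
    eps_rel: float

    def as_dict(self) -> dict:
        return {
            "weighted_median_pa": self.weighted_median_pa,
            "sigma_pa": self.sigma_pa,
            "eps_rel": self.eps_rel,
            "modes": [
                {
                    "mu_log10": m.mu_log10,
                    "s_log10": m.s_log10,
                    "n": m.n,
                    "f": m.f,
                    "median_pa": e,
                    "sigma_median_pa": s,
                }
                for m, e, s in zip(self.modes, self.medians_pa, self.sigma_medians_pa)
            ],
        }


def decompose_modes(
    e_values: np.ndarray,
    max_modes: int = 5,
    random_state: int = 0,
    n_init: int = 10,
) -> list[LogMode]:
    """Fit a Gaussian mixture to log10(E); model order by BIC.

    Requires at least 100 positive values.  Mode membership is by maximum
    posterior (hard assignment), which defines the per-mode curve counts
    ``N`` and weights ``f``.  A degenerate sample (all values identical)
    yields a single mode with the spread floored at a small constant and
    flagged.
    """
    e = np.asarray(e_values, dtype=float)
    e = e[np.isfinite(e)]
    if e.size < 100:
        raise ValueError(f"need >= 100 modulus values, got {e.size}")
    if np.any(e <= 0):
        raise ValueError("all modulus values must be positive")
    log_e = np.log10(e)

    if np.ptp(log_e) < 1e-9:
        return [
            LogMode(float(log_e[0]), S_LOG10_FLOOR, int(e.size), 1.0, degenerate=True)
        ]

    x = log_e[:, None]
    best_gmm, best_bic = None, np.inf
    for k in range(1, max_modes + 1):
        gmm = GaussianMixture(
            n_components=k,
            n_init=n_init,
            random_state=random_state,
            reg_covar=1e-6,
        ).fit(x)
        bic = gmm.bic(x)
        if bic < best_bic - 1e-9:  # ties resolved toward fewer modes
            best_gmm, best_bic = gmm, bic

    labels = best_gmm.predict(x)
    modes: list[LogMode] = []
    order = np.argsort(best_gmm.means_.ravel())
    n_tot = e.size
    for comp in order:
        n = int(np.sum(labels == comp))
        if n == 0:
            continue  # empty component under hard assignment
        mu = float(best_gmm.means_.ravel()[comp])
        s = float(np.sqrt(best_gmm.covariances_.ravel()[comp]))
        modes.append(LogMode(mu, max(s, S_LOG10_FLOOR), n, n / n_tot))
    # renormalize weights after dropping empty components
    total_f = sum(m.f for m in modes)
    if abs(total_f - 1.0) > 1e-12:
        modes = [
            LogMode(m.mu_log10, m.s_log10, m.n, m.f / total_f, m.degenerate)
            for m in modes
        ]
    return modes


def mode_median(mode: LogMode) -> tuple[float, float]:
    """Median of the mode's lognormal and the SD of the sample median (Pa).

    ``E_med = 10^mu``; in log10 space the asymptotic SD of the median of N
    Gaussian draws is ``sqrt(pi/2) * s / sqrt(N)``, which the delta method
    maps to the linear scale as ``E_med * ln(10)`` times that quantity.
    """
    if mode.n <= 0:
        raise ValueError("mode has no assigned curves")
    e_med = 10.0 ** mode.mu_log10
    sigma_log10 = MEDIAN_FACTOR * mode.s_log10 / math.sqrt(mode.n)
    sigma_med = e_med * math.log(10.0) * sigma_log10
    return e_med, sigma_med


def weighted_summary(modes: list[LogMode], eps_rel: float = 0.05) -> StiffnessSummary:
    """Effective rigidity: weighted average of mode medians with total error.

    ``E = sum_i f_i E_med,i``;
    ``sigma_E = sqrt( sum_i (f_i sigma_med,i)^2 + (eps_rel * E)^2 )``.
    """
    if not modes:
        raise ValueError("empty mode list")
    total_f = sum(m.f for m in modes)
    if abs(total_f - 1.0) > 1e-6:
        raise ValueError(f"mode weights sum to {total_f}, not 1")
    if eps_rel < 0:
        raise ValueError("eps_rel must be >= 0")
    med_sig = [mode_median(m) for m in modes]
    medians = tuple(e for e, _ in med_sig)
    sigmas = tuple(s for _, s in med_sig)
    e_weighted = float(sum(m.f * e for m, e in zip(modes, medians)))
    var = sum((m.f * s) ** 2 for m, s in zip(modes, sigmas))
    sigma_e = math.sqrt(var + (eps_rel * e_weighted) ** 2)
    return StiffnessSummary(
        modes=tuple(modes),
        medians_pa=medians,
        sigma_medians_pa=sigmas,
        weighted_median_pa=e_weighted,
        sigma_pa=sigma_e,
        eps_rel=eps_rel,
    )


def summarize_moduli(
    e_values: np.ndarray,
    max_modes: int = 5,
    eps_rel: float = 0.05,
    random_state: int = 0,
) -> StiffnessSummary:
    """Convenience chain: decompose, then summarize."""
    return weighted_summary(
        decompose_modes(e_values, max_modes=max_modes, random_state=random_state),
        eps_rel=eps_rel,
    )


def stiffness_fold(sample: StiffnessSummary, healthy_ref: StiffnessSummary) -> float:
    """Fold difference of effective rigidity vs the healthy reference."""
    if healthy_ref.weighted_median_pa <= 0:
        raise ValueError("reference weighted median must be positive")
    return sample.weighted_median_pa / healthy_ref.weighted_median_pa
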