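"""Hertzian analysis of AFM force-distance curves.

Converts raw z-piezo / cantilever-deflection records into per-curve Young's
moduli for a spherical (colloidal) probe:

* linear baseline subtraction over the pre-contact region,
* contact-point estimation by piecewise model selection (flat baseline plus
  a Hertz branch, with continuous refinement of the contact position),
* least-squares fit of ``F = (4/3) (E / (1 - nu^2)) sqrt(R) delta^(3/2)``
  over the stiff part of the indentation, excluding a soft superficial
  region (default: the first 35% of total indentation) that would otherwise
  contaminate the modulus with loosely bound surface layers.

Only the approach branch of a curve is modelled; retract data never enters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ForceCurve",
    "ForceVolume",
    "ContactPoint",
    "HertzFit",
    "QCReport",
    "hertz_force",
    "hertz_modulus",
    "deflection_to_force",
    "estimate_contact_point",
    "fit_hertz_sphere",
    "analyze_curve",
    "process_force_volume",
]


def hertz_force(delta: np.ndarray, modulus: float, radius: float, poisson: float) -> np.ndarray:
    """Spherical-indenter Hertz force at indentation ``delta`` (m), in N."""
    delta = np.asarray(delta, dtype=float)
    prefactor = (4.0 / 3.0) * modulus / (1.0 - poisson**2) * np.sqrt(radius)
    return prefactor * np.clip(delta, 0.0, None) ** 1.5


def hertz_modulus(force: float, delta: float, radius: float, poisson: float) -> float:
    """Closed-form Young's modulus from a single (force, indentation) point."""
    return 3.0 * force * (1.0 - poisson**2) / (4.0 * np.sqrt(radius) * delta**1.5)


@dataclass
class ForceCurve:
    """One calibrated approach curve.

    ``z_piezo`` increases toward the sample; ``deflection`` is the
    calibrated cantilever deflection.  Both in metres.
    """

    z_piezo: np.ndarray
    deflection: np.ndarray
    spring_constant: float
    probe_radius: float
    poisson_ratio: float = 0.5
    ramp_frequency: float = 1.1

    def __post_init__(self) -> None:
        self.z_piezo = np.asarray(self.z_piezo, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.z_piezo.shape != self.deflection.shape or self.z_piezo.ndim != 1:
            raise ValueError("z_piezo and deflection must be equal-length 1-D arrays")
        if self.z_piezo.size < 2:
            raise ValueError("a force curve needs at least 2 samples")
        if self.spring_constant <= 0 or self.probe_radius <= 0:
            raise ValueError("spring constant and probe radius must be positive")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")


@dataclass
class ForceVolume:
    """A grid of force curves sharing one z ramp and probe calibration."""

    z_piezo: np.ndarray  #: shared ramp, shape (points,)
    deflection: np.ndarray  #: shape (n_y, n_x, points)
    spring_constant: float
    probe_radius: float
    poisson_ratio: float = 0.5
    scan_size: float = 70e-6
    condition: str | None = None
    truth: dict | None = None  #: generator ground truth, if synthetic

    def __post_init__(self) -> None:
        self.z_piezo = np.asarray(self.z_piezo, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.deflection.ndim != 3 or self.deflection.shape[2] != self.z_piezo.size:
            raise ValueError("deflection must have shape (n_y, n_x, points)")

    @property
    def n_x(self) -> int:
        return self.deflection.shape[1]

    @property
    def n_y(self) -> int:
        return self.deflection.shape[0]

    def curve(self, ix: int, iy: int) -> ForceCurve:
        return ForceCurve(
            self.z_piezo,
            self.deflection[iy, ix],
            self.spring_constant,
            self.probe_radius,
            self.poisson_ratio,
        )

    def __iter__(self) -> Iterator[tuple[int, int, ForceCurve]]:
        for iy in range(self.n_y):
            for ix in range(self.n_x):
                yield ix, iy, self.curve(ix, iy)


@dataclass
class ContactPoint:
    z_c: float
    d_c: float
    index: int
    status: str  #: "ok" | "rejected"
    baseline: tuple[float, float] = (0.0, 0.0)  #: (intercept, slope) vs z


@dataclass
class HertzFit:
    E: float  #: Pa; nan when rejected
    contact_point: tuple[float, float]
    fitted_range: tuple[float, float]  #: indentation interval, m
    residual_rms: float  #: N
    status: str  #: "ok" | "rejected"
    n_points: int = 0


@dataclass
class QCReport:
    n_curves: int
    n_rejected: int
    warning: str | None = None

    @property
    def rejected_fraction(self) -> float:
        return self.n_rejected / self.n_curves if self.n_curves else 0.0


def _linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares line y = a + b x; returns (a, b)."""
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    denom = np.dot(dx, dx)
    b = np.dot(dx, y - ym) / denom if denom > 0 else 0.0
    return ym - b * xm, b


def deflection_to_force(curve: ForceCurve) -> np.ndarray:
    """Hooke's-law force after linear baseline subtraction, in N.

    The baseline is fitted over the leading 50% of the detected pre-contact
    region; with no detectable contact the whole curve is treated as
    baseline (forces near zero).
    """
    cp = estimate_contact_point(curve)
    a, b = cp.baseline
    rel = curve.deflection - (a + b * curve.z_piezo)
    return curve.spring_constant * rel


def _piecewise_sse(z: np.ndarray, d: np.ndarray, i: int) -> float:
    """SSE of a flat-baseline + Hertz-branch model split at sample ``i``."""
    zl, dl = z[:i], d[:i]
    a, b = _linear_fit(zl, dl)
    sse = float(np.sum((dl - (a + b * zl)) ** 2))
    zr = z[i:]
    dr = d[i:] - (a + b * zr)  # baseline-relative deflection on the branch
    delta = (zr - z[i]) - dr
    x = np.clip(delta, 0.0, None) ** 1.5
    xx = float(np.dot(x, x))
    amp = max(float(np.dot(dr, x)) / xx, 0.0) if xx > 0 else 0.0
    sse += float(np.sum((dr - amp * x) ** 2))
    return sse


def _sse_at_zc(z: np.ndarray, d: np.ndarray, z_c: float) -> float:
    i = int(np.searchsorted(z, z_c))
    i = min(max(i, 4), z.size - 4)
    zl, dl = z[:i], d[:i]
    a, b = _linear_fit(zl, dl)
    sse = float(np.sum((dl - (a + b * zl)) ** 2))
    zr = z[i:]
    dr = d[i:] - (a + b * zr)
    d_c = 0.0  # baseline-relative deflection at contact is zero by construction
    delta = (zr - z_c) - (dr - d_c)
    x = np.clip(delta, 0.0, None) ** 1.5
    xx = float(np.dot(x, x))
    amp = max(float(np.dot(dr, x)) / xx, 0.0) if xx > 0 else 0.0
    sse += float(np.sum((dr - amp * x) ** 2))
    return sse


def estimate_contact_point(curve: ForceCurve) -> ContactPoint:
    """Locate tip-sample contact by piecewise model selection.

    A grid of candidate split points is scored by the total SSE of a linear
    baseline (left) plus a Hertz ``delta^(3/2)`` branch (right); the best
    split is refined continuously.  Curves with no resolvable baseline or no
    deflection signal above the noise are flagged ``rejected``.
    """
    z = curve.z_piezo
    d = curve.deflection
    n = z.size

    # hierarchical scan: coarse grid on a decimated copy, then every
    # decimated index around the optimum, then full resolution
    step = max(1, n // 512)
    zs, ds = z[::step], d[::step]
    m = zs.size
    lo, hi = 4, max(5, int(0.97 * m))
    cand = np.unique(np.linspace(lo, hi - 1, min(128, hi - lo)).astype(int))
    spacing = max(1, int(np.ceil((hi - lo) / 128)))
    sses = [_piecewise_sse(zs, ds, i) for i in cand]
    best = cand[int(np.argmin(sses))]

    cand = np.arange(max(lo, best - spacing), min(hi, best + spacing + 1))
    sses = [_piecewise_sse(zs, ds, i) for i in cand]
    best = cand[int(np.argmin(sses))]

    centre = best * step
    fine = np.arange(max(4, centre - step), min(n - 4, centre + step + 1))
    if fine.size == 0:
        fine = np.array([min(max(centre, 4), n - 5)])
    sses = [_piecewise_sse(z, d, i) for i in fine]
    j = int(fine[int(np.argmin(sses))])

    # continuous refinement of z_c between neighbouring samples
    zlo, zhi = z[max(j - 2, 1)], z[min(j + 2, n - 1)]
    res = minimize_scalar(
        lambda zc: _sse_at_zc(z, d, zc),
        bounds=(zlo, zhi),
        method="bounded",
        options={"xatol": (z[1] - z[0]) * 1e-4},
    )
    z_c = float(res.x)
    j = int(np.clip(np.searchsorted(z, z_c), 4, n - 4))

    # final baseline over the leading 50% of pre-contact points
    nb = max(4, j // 2)
    a, b = _linear_fit(z[:nb], d[:nb])
    rel = d - (a + b * z)
    d_c = 0.0  # contact deflection equals the extrapolated baseline

    # noise level from first differences of the pre-contact region
    diffs = np.diff(rel[:j])
    sigma = float(np.median(np.abs(diffs)) / 0.6745 / np.sqrt(2)) if diffs.size else 0.0

    status = "ok"
    if j <= max(4, int(0.01 * n)) or j >= int(0.97 * n):
        status = "rejected"  # no baseline, or contact never reached
    elif float(np.max(rel[j:], initial=0.0)) < max(10 * sigma, 1e-13):
        status = "rejected"  # no deflection signal above noise
    elif abs(b) > 0.01:
        # optical-interference baseline tilt is < ~1e-3 deflection per unit
        # travel; a steeper "baseline" is contact signal, i.e. the curve
        # has no true pre-contact region
        status = "rejected"

    return ContactPoint(z_c=z_c, d_c=d_c, index=j, status=status, baseline=(a, b))


def fit_hertz_sphere(
    force: np.ndarray,
    indentation: np.ndarray,
    radius: float,
    poisson: float = 0.5,
    exclusion_fraction: float = 0.35,
    min_points: int = 20,
) -> HertzFit:
    """Least-squares Hertz fit over the deep part of the indentation.

    The fitted window is ``[exclusion_fraction * delta_max, delta_max]``;
    the soft superficial response below it is excluded.  The modulus enters
    the model linearly, so the fit is closed-form and E > 0 whenever the
    mean force on the window is positive.
    """
    if not 0 <= exclusion_fraction < 1:
        raise ValueError("exclusion_fraction must lie in [0, 1)")
    force = np.asarray(force, dtype=float)
    delta = np.asarray(indentation, dtype=float)
    if force.shape != delta.shape:
        raise ValueError("force and indentation must have the same shape")

    d_max = float(delta.max(initial=0.0))
    if d_max <= 0:
        return HertzFit(np.nan, (np.nan, np.nan), (0.0, 0.0), np.nan, "rejected")
    window = (delta >= exclusion_fraction * d_max) & (delta <= d_max)
    f, x = force[window], delta[window] ** 1.5
    if f.size < min_points:
        return HertzFit(
            np.nan, (np.nan, np.nan), (exclusion_fraction * d_max, d_max),
            np.nan, "rejected", n_points=int(f.size),
        )
    amp = float(np.dot(f, x) / np.dot(x, x))
    resid = f - amp * x
    rms = float(np.sqrt(np.mean(resid**2)))
    status = "ok"
    f_max = float(np.abs(force).max())
    if amp <= 0 or rms > 0.1 * f_max:
        status = "rejected"
    modulus = 0.75 * amp * (1.0 - poisson**2) / np.sqrt(radius)
    return HertzFit(
        E=modulus if status == "ok" else np.nan,
        contact_point=(np.nan, np.nan),
        fitted_range=(exclusion_fraction * d_max, d_max),
        residual_rms=rms,
        status=status,
        n_points=int(f.size),
    )


def analyze_curve(curve: ForceCurve, exclusion_fraction: float = 0.35) -> HertzFit:
    """Full per-curve chain: contact point, baseline, force, Hertz fit."""
    cp = estimate_contact_point(curve)
    if cp.status != "ok":
        return HertzFit(np.nan, (cp.z_c, cp.d_c), (0.0, 0.0), np.nan, "rejected")
    a, b = cp.baseline
    rel = curve.deflection - (a + b * curve.z_piezo)
    z = curve.z_piezo
    post = z >= cp.z_c
    delta = (z[post] - cp.z_c) - (rel[post] - cp.d_c)
    force = curve.spring_constant * (rel[post] - cp.d_c)
    fit = fit_hertz_sphere(
        force, delta, curve.probe_radius, curve.poisson_ratio, exclusion_fraction
    )
    fit.contact_point = (cp.z_c, cp.d_c)
    return fit


def process_force_volume(
    fv: ForceVolume,
    exclusion_fraction: float = 0.35,
    max_rejected_fraction: float = 0.2,
) -> tuple[list[HertzFit], QCReport]:
    """Fit every curve of a force volume; grid order (row-major) preserved."""
    fits: list[HertzFit] = []
    for _ix, _iy, curve in fv:
        fits.append(analyze_curve(curve, exclusion_fraction))
    n_rej = sum(1 for f in fits if f.status != "ok")
    warning = None
    if fits and n_rej / len(fits) > max_rejected_fraction:
        warning = (
            f"{n_rej}/{len(fits)} curves rejected "
            f"(> {max_rejected_fraction:.0%} threshold)"
        )
        warnings.warn(warning, stacklevel=2)
    return fits, QCReport(n_curves=len(fits), n_rejected=n_rej, warning=warning)
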