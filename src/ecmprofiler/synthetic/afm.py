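"""Forward simulation of colloidal-probe force volumes.

Each pixel of a force volume draws a true Young's modulus from the
condition's lognormal mixture and produces an approach curve through the
spherical-indenter Hertz model: for piezo positions beyond the contact
point the measured deflection ``d`` satisfies

    k * d = (4/3) (E / (1 - nu^2)) sqrt(R) * delta^(3/2),
    delta = (z - z_c) - d,

which is inverted by dense parametric sampling in ``delta``.  The contact
point is placed so the ramp ends at the target maximum force (60-70 nN,
drawn uniformly) while keeping a pre-contact baseline of at least 15% of
the ramp.  Additive Gaussian deflection noise and an optional linear
baseline tilt emulate instrument imperfections.  The per-pixel true
modulus is recorded as ground truth.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from ..afm import ForceVolume, hertz_force
from ..config import SimConfig
from ._seeds import STREAM_AFM, child_rng

__all__ = ["generate_force_curve", "generate_force_volume"]

#: minimum pre-contact fraction of the ramp
MIN_BASELINE_FRACTION = 0.15
#: oversampling factor of the parametric delta grid vs ramp points
DELTA_OVERSAMPLE = 4


def _contact_geometry(
    modulus: float, f_max: float, probe, ramp
) -> tuple[float, float]:
    """(z_c, delta_end) placing the ramp end at ``f_max`` when possible.

    Very soft pixels would need more travel than the ramp provides; they
    contact at the minimum baseline fraction instead and end below the
    target force.
    """
    prefactor = (4.0 / 3.0) * modulus / (1.0 - probe.poisson_ratio**2) * np.sqrt(
        probe.radius
    )
    delta_target = (f_max / prefactor) ** (2.0 / 3.0)
    travel = delta_target + f_max / probe.spring_constant
    max_travel = (1.0 - MIN_BASELINE_FRACTION) * ramp.length
    if travel <= max_travel:
        return ramp.length - travel, delta_target
    # solve delta + F(delta)/k = max_travel
    g = lambda d: d + prefactor * d**1.5 / probe.spring_constant - max_travel
    delta_end = brentq(g, 0.0, max_travel)
    return MIN_BASELINE_FRACTION * ramp.length, delta_end


def generate_force_curve(
    rng: np.random.Generator,
    modulus: float,
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """One synthetic approach curve; returns (z, deflection, truth)."""
    if modulus <= 0:
        raise ValueError("modulus must be positive")
    probe, ramp, noise = config.probe, config.ramp, config.noise
    f_max = rng.uniform(*ramp.max_force_range)
    z_c, delta_end = _contact_geometry(modulus, f_max, probe, ramp)

    z = np.linspace(0.0, ramp.length, ramp.points)
    # quadratic spacing concentrates samples near contact, where the
    # delta^(3/2) branch has unbounded curvature
    u = np.linspace(0.0, 1.0, DELTA_OVERSAMPLE * ramp.points)
    delta_grid = delta_end * u**2
    d_grid = hertz_force(delta_grid, modulus, probe.radius, probe.poisson_ratio) / (
        probe.spring_constant
    )
    travel_grid = delta_grid + d_grid  # z - z_c as a function of delta
    deflection = np.interp(z - z_c, travel_grid, d_grid, left=0.0)

    truth = {
        "modulus_pa": float(modulus),
        "z_contact_m": float(z_c),
        "delta_max_m": float(delta_end),
        "f_max_n": float(probe.spring_constant * d_grid[-1]),
    }
    if noise.baseline_tilt > 0:
        slope = rng.normal(0.0, noise.baseline_tilt)
        deflection = deflection + slope * (z - z[0])
        truth["baseline_slope"] = float(slope)
    if noise.deflection_rms > 0:
        deflection = deflection + rng.normal(0.0, noise.deflection_rms, z.size)
    return z, deflection, truth


def generate_force_volume(
    config: SimConfig, condition: str, volume_index: int = 0, patient: int = 0
) -> ForceVolume:
    """Simulate one force volume for a condition of the configured study.

    True moduli are drawn per pixel from the condition's lognormal mixture
    (a draw is positive by construction).  The returned volume carries the
    shared z ramp, the deflection grid, and a ``truth`` dict with per-pixel
    moduli and the mixture's true weighted median.
    """
    modes = config.stiffness_modes(condition)  # raises for unknown condition
    cond_idx = config.conditions.index(condition)
    rng = child_rng(config.seed, STREAM_AFM, cond_idx, patient, volume_index)

    grid = config.grid
    n = grid.n_y * grid.n_x
    weights = np.array([m.weight for m in modes])
    choice = rng.choice(len(modes), size=n, p=weights / weights.sum())
    mus = np.array([m.mu_log10 for m in modes])[choice]
    sds = np.array([m.s_log10 for m in modes])[choice]
    true_e = 10.0 ** rng.normal(mus, sds)

    deflection = np.empty((grid.n_y, grid.n_x, config.ramp.points))
    z = None
    curve_truth = []
    for i, e in enumerate(true_e):
        z, d, t = generate_force_curve(rng, e, config)
        deflection[i // grid.n_x, i % grid.n_x] = d
        curve_truth.append(t)

    truth = {
        "condition": condition,
        "moduli_pa": true_e.reshape(grid.n_y, grid.n_x),
        "weighted_median_pa": config.true_weighted_median(condition),
        "curves": curve_truth,
    }
    return ForceVolume(
        z_piezo=z,
        deflection=deflection,
        spring_constant=config.probe.spring_constant,
        probe_radius=config.probe.radius,
        poisson_ratio=config.probe.poisson_ratio,
        scan_size=grid.scan_size,
        condition=condition,
        truth=truth,
    )
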