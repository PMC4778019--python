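"""Synthetic SEM-like textures: oriented fibril fields and capillary masks.

Fibril fields are sums of Gaussian ridge profiles along straight segments.
Orientations follow an axial von Mises model: the doubled angle ``2 theta``
is von Mises distributed with concentration ``kappa``, so the expected
nematic order parameter is ``I1(kappa) / I0(kappa)``.  Angles are drawn by
randomized stratified (inverse-CDF) sampling, which keeps the realized
order of a finite fibril population tight around the target — a field
configured for order 0.1 actually has order ~0.1 instead of being inflated
by sqrt(1/n) sampling noise.

Capillary masks are binary fields of non-overlapping elliptical lumens,
Poisson in number, placed by rejection sampling with a minimum separation
so neighbouring lumens never merge into one connected component.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats
from scipy.optimize import brentq
from skimage.draw import ellipse as draw_ellipse

from ..config import SimConfig
from ..micrographs import Micrograph
from ._seeds import STREAM_CAPILLARY, STREAM_FIBRIL, child_rng

__all__ = [
    "kappa_for_order",
    "generate_fibril_micrograph",
    "generate_capillary_mask",
]

#: FWHM of a Gaussian in units of its sigma
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: kappa above which fibrils are rendered exactly parallel
KAPPA_PARALLEL = 500.0


def kappa_for_order(order: float) -> float:
    """Von Mises concentration giving a target nematic order I1/I0 = order."""
    if not 0 <= order <= 1:
        raise ValueError("order must lie in [0, 1]")
    if order == 0:
        return 0.0
    if order >= special.i1(KAPPA_PARALLEL) / special.i0(KAPPA_PARALLEL):
        return KAPPA_PARALLEL
    return brentq(
        lambda k: special.i1(k) / special.i0(k) - order, 1e-9, KAPPA_PARALLEL
    )


def _axial_angles(rng: np.random.Generator, n: int, kappa: float, theta0: float) -> np.ndarray:
    """Randomized-stratified axial von Mises sample on [0, pi)."""
    if n == 0:
        return np.empty(0)
    u = (np.arange(n) + rng.uniform(0.0, 1.0, n)) / n
    if kappa >= KAPPA_PARALLEL:
        doubled = np.zeros(n)
    elif kappa == 0.0:
        doubled = (2.0 * u - 1.0) * np.pi
    else:
        doubled = stats.vonmises.ppf(u, kappa)
    theta = theta0 + 0.5 * doubled
    return rng.permutation(theta) % np.pi


def generate_fibril_micrograph(
    config: SimConfig, condition: str, index: int = 0, patient: int = 0
) -> Micrograph:
    """Render one oriented-ridge field for a condition.

    Ridges have Gaussian cross-sections whose FWHM is drawn from the
    condition's width distribution (truncated at one pixel) and common
    unit amplitude; the shared mean orientation is random per field.
    Ground truth records the drawn widths, the target order and the
    realized order parameter of the drawn orientations.
    """
    try:
        spec = config.fibrils[condition]
    except KeyError:
        raise KeyError(f"no fibril spec for condition {condition!r}") from None
    cond_idx = config.conditions.index(condition)
    rng = child_rng(config.seed, STREAM_FIBRIL, cond_idx, patient, index)

    size = spec.image_size
    kappa = kappa_for_order(spec.order)
    theta0 = rng.uniform(0.0, np.pi)
    thetas = _axial_angles(rng, spec.n_fibrils, kappa, theta0)

    lo = max(1.0 * spec.pixel_size_nm, 0.25 * spec.width_nm_mean)
    if spec.width_nm_sd > 0:
        a = (lo - spec.width_nm_mean) / spec.width_nm_sd
        widths_nm = stats.truncnorm.rvs(
            a, np.inf, loc=spec.width_nm_mean, scale=spec.width_nm_sd,
            size=spec.n_fibrils, random_state=rng,
        )
    else:
        widths_nm = np.full(spec.n_fibrils, spec.width_nm_mean)

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    image = np.zeros((size, size))
    centres = rng.uniform(0.0, size, (spec.n_fibrils, 2))
    lengths = rng.uniform(1.6, 2.4, spec.n_fibrils) * size
    sigma_ref = spec.width_nm_mean / FWHM_FACTOR / spec.pixel_size_nm
    for theta, w_nm, (cy, cx), length in zip(thetas, widths_nm, centres, lengths):
        sigma = w_nm / FWHM_FACTOR / spec.pixel_size_nm
        # fibrils span the field; amplitude ~ sqrt(sigma) equalizes each
        # fibril's gradient power so the image nematic tensor reads the
        # orientation sample without per-fibril weight noise
        amp = np.sqrt(sigma / sigma_ref)
        ux, uy = np.cos(theta), np.sin(theta)
        dx, dy = xx - cx, yy - cy
        along = dx * ux + dy * uy
        across = -dx * uy + dy * ux
        # soft ends keep gradients finite at segment tips
        overhang = np.clip(np.abs(along) - 0.5 * length, 0.0, None)
        image += amp * np.exp(
            -(across**2) / (2.0 * sigma**2) - overhang**2 / (2.0 * (3.0 * sigma) ** 2)
        )

    peak = image.max()
    if peak > 0:
        image /= peak
    if spec.noise > 0:
        image = image + rng.normal(0.0, spec.noise, image.shape)

    realized = float(np.abs(np.mean(np.exp(2j * thetas)))) if thetas.size else 0.0
    return Micrograph(
        intensity=image,
        pixel_size=spec.pixel_size_nm,
        modality="sem-fibril",
        truth={
            "condition": condition,
            "target_order": spec.order,
            "realized_order": realized,
            "mean_orientation": float(theta0 % np.pi),
            "widths_nm": widths_nm,
        },
    )


def generate_capillary_mask(
    config: SimConfig, condition: str, index: int = 0, patient: int = 0
) -> Micrograph:
    """Binary mask of non-overlapping elliptical capillary lumens.

    The lumen count is Poisson with mean density x field area; minor-axis
    widths follow the condition's truncated-normal width distribution and
    the major axis is the minor axis times a jittered elongation.  Lumens
    keep a minimum 2 px boundary gap (and clear the field border) so the
    connected-component count equals the true count.  Raises when the
    requested density cannot be placed without overlap.
    """
    try:
        spec = config.capillaries[condition]
    except KeyError:
        raise KeyError(f"no capillary spec for condition {condition!r}") from None
    cond_idx = config.conditions.index(condition)
    rng = child_rng(config.seed, STREAM_CAPILLARY, cond_idx, patient, index)

    px = spec.pixel_size_um
    size = int(round(spec.field_size_um / px))
    mask = np.zeros((size, size), dtype=bool)
    count = int(rng.poisson(spec.density_per_mm2 * spec.field_area_mm2))
    if count == 0:
        return Micrograph(
            mask, px, "capillary-mask",
            truth={"condition": condition, "count": 0, "widths_um": np.empty(0)},
        )

    if spec.width_um_sd > 0:
        a = (2.0 * px - spec.width_um_mean) / spec.width_um_sd
        minors = stats.truncnorm.rvs(
            a, np.inf, loc=spec.width_um_mean, scale=spec.width_um_sd,
            size=count, random_state=rng,
        )
    else:
        minors = np.full(count, spec.width_um_mean)
    majors = minors * rng.uniform(1.0, 2.0 * spec.elongation - 1.0, count)
    orientations = rng.uniform(0.0, np.pi, count)

    placed: list[tuple[float, float, float]] = []  # (cy, cx, clearance radius px)
    gap_px = 2.0
    for i in range(count):
        radius_px = 0.5 * majors[i] / px
        margin = radius_px + gap_px
        if 2 * margin >= size:
            raise ValueError("lumen larger than the field; density unachievable")
        for _attempt in range(2000):
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            ok = all(
                (cy - py) ** 2 + (cx - px_) ** 2 >= (margin + pr) ** 2
                for py, px_, pr in placed
            )
            if ok:
                placed.append((cy, cx, radius_px))
                rr, cc = draw_ellipse(
                    cy, cx, 0.5 * minors[i] / px, radius_px,
                    shape=mask.shape, rotation=orientations[i],
                )
                mask[rr, cc] = True
                break
        else:
            raise ValueError(
                f"could not place lumen {i + 1}/{count} without overlap; "
                "requested density is unachievable at this field size"
            )

    return Micrograph(
        intensity=mask,
        pixel_size=px,
        modality="capillary-mask",
        truth={
            "condition": condition,
            "count": count,
            "widths_um": minors,
            "density_per_mm2": count / spec.field_area_mm2,
        },
    )
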