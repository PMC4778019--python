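"""Study configuration.

A :class:`SimConfig` bundles every tunable of the synthetic study — probe
calibration, ramp geometry, per-condition stiffness mixtures, fibril and
capillary texture parameters, proteomics effect structure and the crosslink
panel — together with a single integer seed from which every stream of
randomness is derived.  The defaults encode the acquisition geometry of a
colloidal-probe AFM study on decellularized colon ECM (16 x 16 force volumes
on a 70 um x 70 um area, 4096 points per 10 um ramp, 60-70 nN peak force)
and a healthy -> perilesional -> carcinoma gradient in stiffness (x2.5 /
x9.4 on the weighted median), anisotropy, crosslinking (x1.5 / x2) and
vascularization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

#: canonical condition labels, in gradient order
CONDITIONS = ("healthy", "perilesional", "crc")

#: fold gradient of the weighted-median stiffness vs healthy
STIFFNESS_FOLDS = {"healthy": 1.0, "perilesional": 2.5, "crc": 9.4}


def _require_positive(name: str, *values: float) -> None:
    for v in values:
        if not v > 0:
            raise ValueError(f"{name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class StiffnessMode:
    """One lognormal component of a condition's Young's-modulus mixture."""

    mu_log10: float  #: peak position, log10(Pa)
    s_log10: float  #: geometric spread in log10 units
    weight: float  #: mixture weight, in (0, 1]

    def __post_init__(self) -> None:
        _require_positive("s_log10", self.s_log10)
        if not 0 < self.weight <= 1:
            raise ValueError(f"mode weight must be in (0, 1], got {self.weight}")

    @property
    def median_pa(self) -> float:
        return 10.0 ** self.mu_log10


@dataclass(frozen=True)
class ProbeSpec:
    """Colloidal-probe calibration (midpoints of the instrument ranges)."""

    spring_constant: float = 0.25  #: N/m
    radius: float = 9e-6  #: m
    poisson_ratio: float = 0.5  #: incompressible soft tissue

    def __post_init__(self) -> None:
        _require_positive("spring_constant", self.spring_constant)
        _require_positive("radius", self.radius)
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")


@dataclass(frozen=True)
class RampSpec:
    points: int = 4096  #: samples per force curve
    length: float = 10e-6  #: piezo travel, m
    max_force_range: tuple[float, float] = (60e-9, 70e-9)  #: N, drawn uniform
    frequency: float = 1.1  #: Hz, metadata only

    def __post_init__(self) -> None:
        if self.points < 16:
            raise ValueError("a force curve needs at least 16 points")
        _require_positive("ramp length", self.length)
        lo, hi = self.max_force_range
        _require_positive("max force", lo, hi)
        if hi < lo:
            raise ValueError("max_force_range must be (low, high)")


@dataclass(frozen=True)
class GridSpec:
    n_x: int = 16
    n_y: int = 16
    scan_size: float = 70e-6  #: m

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid dimensions must be >= 1")
        _require_positive("scan_size", self.scan_size)


@dataclass(frozen=True)
class NoiseSpec:
    deflection_rms: float = 1e-9  #: m, additive Gaussian on the deflection
    baseline_tilt: float = 5e-5  #: dimensionless slope scale of the baseline

    def __post_init__(self) -> None:
        if self.deflection_rms < 0 or self.baseline_tilt < 0:
            raise ValueError("noise amplitudes must be >= 0")


@dataclass(frozen=True)
class FibrilSpec:
    """Oriented-ridge texture emulating an SEM field of ECM fibrils."""

    width_nm_mean: float  #: mean fibril width (full width at half maximum)
    width_nm_sd: float
    order: float  #: target nematic order parameter in [0, 1)
    pixel_size_nm: float = 10.0
    image_size: int = 512  #: pixels per side
    n_fibrils: int = 25
    noise: float = 0.02  #: pixel noise SD relative to unit ridge amplitude

    def __post_init__(self) -> None:
        _require_positive("width_nm_mean", self.width_nm_mean)
        _require_positive("pixel_size_nm", self.pixel_size_nm)
        if self.width_nm_sd < 0 or self.noise < 0:
            raise ValueError("spreads must be >= 0")
        if not 0 <= self.order <= 1:
            raise ValueError("order must lie in [0, 1]")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32 px")
        if self.n_fibrils < 0:
            raise ValueError("n_fibrils must be >= 0")


@dataclass(frozen=True)
class CapillarySpec:
    """Elliptical lumen field emulating capillary holes in the lamina propria."""

    density_per_mm2: float
    width_um_mean: float  #: lumen minor axis
    width_um_sd: float
    elongation: float = 1.6  #: major/minor axis ratio (mean)
    pixel_size_um: float = 0.25
    field_size_um: float = 500.0  #: square field side

    def __post_init__(self) -> None:
        if self.density_per_mm2 < 0:
            raise ValueError("density must be >= 0")
        _require_positive("width_um_mean", self.width_um_mean)
        _require_positive("pixel_size_um", self.pixel_size_um)
        _require_positive("field_size_um", self.field_size_um)
        if self.width_um_sd < 0:
            raise ValueError("width_um_sd must be >= 0")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")

    @property
    def field_area_mm2(self) -> float:
        return (self.field_size_um / 1000.0) ** 2


@dataclass(frozen=True)
class CrosslinkSpec:
    """Per-condition pyridinoline crosslink and hydroxyproline levels.

    Units are kit-relative amounts; every downstream quantity is a ratio, so
    the absolute scale is inert.
    """

    hp: float
    lp: float
    hydroxyproline: float

    def __post_init__(self) -> None:
        if self.hp < 0 or self.lp < 0 or self.hydroxyproline < 0:
            raise ValueError("crosslink panel levels must be >= 0")


@dataclass(frozen=True)
class ProteomicsSpec:
    """Shape and effect structure of the LFQ tables.

    ``crc_effects`` maps protein ids to multiplicative intensity effects
    applied in the carcinoma condition only; ``ohlys_fractions`` maps
    (condition, protein id) to the fraction of that protein's intensity
    carried by hydroxylysine-bearing peptides.
    """

    n_proteins: int = 1139
    n_patients: int = 5
    n_replicates: int = 3
    base_log10_range: tuple[float, float] = (6.5, 8.5)
    sigma_patient_log10: float = 0.1  #: biological spread between patients
    sigma_replicate_log10: float = 0.02  #: technical spread between replicates
    crc_effects: dict[str, float] = field(default_factory=dict)
    ohlys_base_fraction: float = 0.05  #: OH-Lys fraction on collagens
    ohlys_overrides: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_patients < 2 or self.n_replicates < 1:
            raise ValueError("proteomics table shape is degenerate")
        for v in self.crc_effects.values():
            _require_positive("crc effect", v)


@dataclass(frozen=True)
class StudySpec:
    """Sampling depth of a simulated study."""

    n_patients_afm: int = 3
    volumes_per_condition: int = 5
    micrographs_per_condition: int = 3
    n_patients_panel: int = 5
    crosslink_noise_cv: float = 0.05  #: lognormal CV on panel levels


# default CRC-only effects: down-modulated basal membrane / interstitial
# proteins, up-modulated invasion-associated proteins, and a strong shift of
# the collagen XII : collagen VI balance (20x up vs 0.2x down -> ratio x100)
_DEFAULT_CRC_EFFECTS = {
    "LAMB2": 0.2,
    "NID1": 0.2,
    "MATN2": 0.2,
    "COL6A3": 0.2,
    "COL6A3-4": 0.2,
    "OGN": 0.2,
    "DCN": 0.2,
    "DPT": 0.2,
    "FN1": 5.0,
    "COL12A1": 20.0,
    "FBLN1": 5.0,
    "MFAP2": 5.0,
    "TNC": 5.0,
    "LGALS3": 5.0,
    "COL11A1": 30.0,
}

# COL1A1 lysine hydroxylation rises in carcinoma; COL11A1 carries a high
# OH-Lys load wherever it is expressed (it is essentially CRC-only)
_DEFAULT_OHLYS_OVERRIDES = {
    ("crc", "COL1A1"): 0.20,
    ("healthy", "COL11A1"): 0.30,
    ("perilesional", "COL11A1"): 0.30,
    ("crc", "COL11A1"): 0.30,
}

# three well-resolved lognormal modes (0.6 dex apart, 4 sigma at s = 0.15)
# with a ~3 kPa weighted median, consistent with 60-70 nN reaching 2-3 um
# indentation under the default probe geometry
_HEALTHY_MODES = (
    StiffnessMode(2.8, 0.15, 0.5),
    StiffnessMode(3.4, 0.15, 0.3),
    StiffnessMode(4.0, 0.15, 0.2),
)


def _shifted_modes(modes: Sequence[StiffnessMode], fold: float) -> tuple[StiffnessMode, ...]:
    """Shift every mode by log10(fold): scales the weighted median exactly."""
    shift = math.log10(fold)
    return tuple(
        StiffnessMode(m.mu_log10 + shift, m.s_log10, m.weight) for m in modes
    )


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    conditions: tuple[str, ...] = CONDITIONS
    stiffness: dict[str, tuple[StiffnessMode, ...]] = field(default_factory=dict)
    probe: ProbeSpec = field(default_factory=ProbeSpec)
    ramp: RampSpec = field(default_factory=RampSpec)
    grid: GridSpec = field(default_factory=GridSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    fibrils: dict[str, FibrilSpec] = field(default_factory=dict)
    capillaries: dict[str, CapillarySpec] = field(default_factory=dict)
    crosslinks: dict[str, CrosslinkSpec] = field(default_factory=dict)
    proteomics: ProteomicsSpec = field(default_factory=ProteomicsSpec)
    study: StudySpec = field(default_factory=StudySpec)

    def __post_init__(self) -> None:
        for cond, modes in self.stiffness.items():
            total = sum(m.weight for m in modes)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"stiffness mode weights for {cond!r} sum to {total}, not 1"
                )

    def stiffness_modes(self, condition: str) -> tuple[StiffnessMode, ...]:
        try:
            return self.stiffness[condition]
        except KeyError:
            raise KeyError(f"unknown condition {condition!r}") from None

    def true_weighted_median(self, condition: str) -> float:
        """Generator ground truth of the weighted-median stiffness, Pa."""
        return sum(m.weight * m.median_pa for m in self.stiffness_modes(condition))


def default_config(seed: int = 0) -> SimConfig:
    """The default study conditions.

    Stiffness mixtures for perilesional and carcinoma tissue are the healthy
    mixture rigidly shifted in log space, so the true weighted-median folds
    are exactly 2.5x and 9.4x.  Fibril textures carry a 0.1 / 0.2 / 0.4
    nematic-order gradient with 90 +/- 26 nm fibrils in healthy and
    perilesional submucosa thinning to 40 +/- 8 nm in carcinoma.  Capillary
    lumen fields go from 146 per mm^2 at 2.9 um to 262 per mm^2 at 5.3 um
    (healthy -> perilesional; carcinoma vessels are ectatic and not modelled
    as discrete lumens).  The crosslink panel realizes total-pyridinoline
    folds of 1.5x / 2x with an HP/LP ratio doubled only in carcinoma, at
    constant hydroxyproline (collagen content does not change).
    """
    stiffness = {
        cond: _shifted_modes(_HEALTHY_MODES, STIFFNESS_FOLDS[cond])
        for cond in CONDITIONS
    }
    fibrils = {
        "healthy": FibrilSpec(width_nm_mean=90.0, width_nm_sd=26.0, order=0.1),
        "perilesional": FibrilSpec(width_nm_mean=90.0, width_nm_sd=26.0, order=0.2),
        "crc": FibrilSpec(width_nm_mean=40.0, width_nm_sd=8.0, order=0.4),
    }
    capillaries = {
        "healthy": CapillarySpec(density_per_mm2=146.0, width_um_mean=2.9, width_um_sd=0.4),
        "perilesional": CapillarySpec(density_per_mm2=262.0, width_um_mean=5.3, width_um_sd=0.8),
    }
    crosslinks = {
        "healthy": CrosslinkSpec(hp=0.5, lp=0.5, hydroxyproline=13.5),
        "perilesional": CrosslinkSpec(hp=0.75, lp=0.75, hydroxyproline=13.5),
        "crc": CrosslinkSpec(hp=4.0 / 3.0, lp=2.0 / 3.0, hydroxyproline=13.5),
    }
    proteomics = ProteomicsSpec(
        crc_effects=dict(_DEFAULT_CRC_EFFECTS),
        ohlys_overrides=dict(_DEFAULT_OHLYS_OVERRIDES),
    )
    return SimConfig(
        seed=seed,
        stiffness=stiffness,
        fibrils=fibrils,
        capillaries=capillaries,
        crosslinks=crosslinks,
        proteomics=proteomics,
    )


def config_to_yaml(config: SimConfig, path) -> None:
    """Dump the resolved configuration (for run provenance)."""
    payload = asdict(config)
    # tuple-keyed dicts are not YAML-representable; flatten them
    ov = payload["proteomics"].get("ohlys_overrides", {})
    payload["proteomics"]["ohlys_overrides"] = {
        f"{cond}:{pid}": v for (cond, pid), v in ov.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
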