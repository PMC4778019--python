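"""Shared fixtures: study configurations at several simulation scales."""

from dataclasses import replace

import pytest

from ecmprofiler import default_config
from ecmprofiler.config import GridSpec, NoiseSpec, RampSpec, StudySpec


@pytest.fixture(scope="session")
def cfg():
    """Default study conditions, fixed seed."""
    return default_config(seed=7)


@pytest.fixture(scope="session")
def noiseless_cfg(cfg):
    """Default conditions with instrument noise switched off."""
    return replace(cfg, noise=NoiseSpec(deflection_rms=0.0, baseline_tilt=0.0))


@pytest.fixture(scope="session")
def tiny_cfg(cfg):
    """Small grids and short ramps for end-to-end pipeline tests."""
    return replace(
        cfg,
        # shorter ramp keeps stiff contacts well sampled at 512 points
        grid=GridSpec(n_x=12, n_y=12, scan_size=70e-6),
        ramp=RampSpec(points=512, length=4e-6),
        study=StudySpec(
            n_patients_afm=1,
            volumes_per_condition=3,
            micrographs_per_condition=2,
            n_patients_panel=3,
        ),
    )
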