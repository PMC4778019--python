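"""Hertz fitting: closed-form inversion, contact-point recovery, QC."""

import numpy as np
import pytest

from ecmprofiler.afm import (
    ForceCurve,
    analyze_curve,
    deflection_to_force,
    estimate_contact_point,
    fit_hertz_sphere,
    hertz_force,
    hertz_modulus,
    process_force_volume,
)
from ecmprofiler.synthetic import generate_force_curve, generate_force_volume
from ecmprofiler.synthetic._seeds import child_rng

R = 9e-6
NU = 0.5


class TestFitHertzSphere:
    def test_exact_inversion_of_noiseless_power_law(self):
        delta = np.linspace(0, 2.5e-6, 500)
        force = hertz_force(delta, 1000.0, R, NU)
        fit = fit_hertz_sphere(force, delta, R, NU)
        assert fit.status == "ok"
        assert fit.E == pytest.approx(1000.0, rel=1e-6)

    def test_single_point_closed_form_matches_65nN_at_2p5um(self):
        # E = 3 F (1 - nu^2) / (4 sqrt(R) delta^(3/2)) at 65 nN, 2.5 um
        e = hertz_modulus(65e-9, 2.5e-6, R, NU)
        assert e == pytest.approx(3083.5, rel=1e-3)
        delta = np.linspace(0, 2.5e-6, 500)
        force = hertz_force(delta, e, R, NU)
        fit = fit_hertz_sphere(force, delta, R, NU)
        assert fit.E == pytest.approx(e, rel=1e-6)

    @pytest.mark.parametrize("scale", [2.0, 0.5, 10.0])
    def test_scale_equivariance_in_force(self, scale):
        delta = np.linspace(0, 2e-6, 400)
        force = hertz_force(delta, 2000.0, R, NU)
        e1 = fit_hertz_sphere(force, delta, R, NU).E
        e2 = fit_hertz_sphere(scale * force, delta, R, NU).E
        assert e2 == pytest.approx(scale * e1, rel=1e-9)

    def test_fitted_range_starts_at_exclusion_fraction(self):
        delta = np.linspace(0, 2e-6, 400)
        force = hertz_force(delta, 2000.0, R, NU)
        fit = fit_hertz_sphere(force, delta, R, NU, exclusion_fraction=0.35)
        lo, hi = fit.fitted_range
        assert lo == pytest.approx(0.35 * delta.max())
        assert hi == pytest.approx(delta.max())

    def test_too_few_points_rejected(self):
        delta = np.linspace(0, 1e-6, 10)
        force = hertz_force(delta, 1000.0, R, NU)
        assert fit_hertz_sphere(force, delta, R, NU).status == "rejected"

    def test_invalid_exclusion_raises(self):
        delta = np.linspace(0, 1e-6, 100)
        with pytest.raises(ValueError):
            fit_hertz_sphere(delta, delta, R, NU, exclusion_fraction=1.0)

    def test_soft_superficial_layer_bias_reduced_by_exclusion(self):
        # a loosely bound soft layer responds with E_soft over the first
        # 30% of indentation before the bulk (E_bulk) takes over
        delta = np.linspace(0, 2.5e-6, 1000)
        d0 = 0.3 * delta.max()
        soft = hertz_force(delta, 300.0, R, NU)
        bulk = hertz_force(np.clip(delta - d0, 0, None), 3000.0, R, NU)
        force = np.where(delta < d0, soft, soft[np.searchsorted(delta, d0)] + bulk)
        e_nox = fit_hertz_sphere(force, delta, R, NU, exclusion_fraction=0.0,
                                 min_points=20).E
        e_excl = fit_hertz_sphere(force, delta, R, NU, exclusion_fraction=0.35).E
        assert abs(e_excl - 3000.0) < abs(e_nox - 3000.0)


class TestContactPoint:
    def test_noiseless_recovery_within_two_samples(self, noiseless_cfg):
        rng = child_rng(0, 90)
        for e_pa in (500.0, 3000.0, 30000.0):
            z, d, truth = generate_force_curve(rng, e_pa, noiseless_cfg)
            curve = ForceCurve(z, d, 0.25, R, NU)
            cp = estimate_contact_point(curve)
            dz = z[1] - z[0]
            assert cp.status == "ok"
            assert abs(cp.z_c - truth["z_contact_m"]) < 2 * dz

    def test_curve_entirely_in_contact_rejected(self):
        z = np.linspace(0, 10e-6, 2048)
        d = hertz_force(z, 2000.0, R, NU) / 0.25  # contact from the start
        cp = estimate_contact_point(ForceCurve(z, d, 0.25, R, NU))
        assert cp.status == "rejected"

    def test_pure_noise_rejected(self):
        rng = np.random.default_rng(3)
        z = np.linspace(0, 10e-6, 2048)
        d = rng.normal(0, 1e-9, z.size)
        cp = estimate_contact_point(ForceCurve(z, d, 0.25, R, NU))
        assert cp.status == "rejected"

    def test_noisy_monte_carlo_bias_and_precision(self, cfg):
        # 1 nm RMS deflection noise: z_c within 20 nm, modulus bias < 5%
        rng = child_rng(0, 91)
        z_errs, e_errs = [], []
        for _ in range(60):
            e_pa = 10 ** rng.uniform(2.8, 4.4)
            z, d, truth = generate_force_curve(rng, e_pa, cfg)
            fit = analyze_curve(ForceCurve(z, d, 0.25, R, NU))
            assert fit.status == "ok"
            z_errs.append(abs(fit.contact_point[0] - truth["z_contact_m"]))
            e_errs.append(fit.E / e_pa - 1.0)
        assert np.median(z_errs) < 20e-9
        assert abs(np.mean(e_errs)) < 0.05


class TestForceConversion:
    def test_zero_deflection_gives_zero_force(self):
        z = np.linspace(0, 10e-6, 1024)
        curve = ForceCurve(z, np.zeros_like(z), 0.25, R, NU)
        assert np.allclose(deflection_to_force(curve), 0.0)

    def test_hookes_law_linearity(self, noiseless_cfg):
        # 200 nm deflection at k = 0.25 N/m is 50 nN
        rng = child_rng(0, 92)
        z, d, _ = generate_force_curve(rng, 3000.0, noiseless_cfg)
        force = deflection_to_force(ForceCurve(z, d, 0.25, R, NU))
        idx = int(np.argmin(np.abs(d - 200e-9)))
        assert force[idx] == pytest.approx(0.25 * d[idx], rel=1e-6)
        assert force[idx] == pytest.approx(50e-9, rel=0.02)


class TestProcessForceVolume:
    def test_noiseless_volume_recovers_truth_per_pixel(self, noiseless_cfg):
        fv = generate_force_volume(noiseless_cfg, "healthy", volume_index=0)
        fits, qc = process_force_volume(fv)
        assert qc.n_curves == fv.n_x * fv.n_y
        assert qc.n_rejected == 0
        true_e = fv.truth["moduli_pa"].ravel()
        fitted = np.array([f.E for f in fits])
        assert np.max(np.abs(fitted / true_e - 1.0)) < 1e-4

    def test_modulus_invariant_to_z_origin_shift(self, noiseless_cfg):
        rng = child_rng(0, 93)
        z, d, _ = generate_force_curve(rng, 3000.0, noiseless_cfg)
        e1 = analyze_curve(ForceCurve(z, d, 0.25, R, NU)).E
        e2 = analyze_curve(ForceCurve(z + 3e-6, d, 0.25, R, NU)).E
        assert e2 == pytest.approx(e1, rel=1e-9)

    def test_simulated_max_force_in_instrument_range(self, cfg):
        fv = generate_force_volume(cfg, "healthy", volume_index=1)
        f_max = [t["f_max_n"] for t in fv.truth["curves"]]
        assert np.all(np.asarray(f_max) <= 70e-9 + 1e-12)
        # stiff enough pixels reach the configured 60-70 nN window
        assert np.median(f_max) > 55e-9

    def test_typical_indentation_reaches_2_to_3_um(self, cfg):
        # at the ~3 kPa weighted-median stiffness the probe indents 2-3 um
        fv = generate_force_volume(cfg, "healthy", volume_index=2)
        delta = np.array([t["delta_max_m"] for t in fv.truth["curves"]])
        med = np.median(delta)
        assert 1.5e-6 < med < 4e-6
        assert delta.max() > 2e-6
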