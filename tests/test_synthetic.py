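"""Generator contracts: determinism, configured truths, noise structure."""

from dataclasses import replace

import numpy as np
import pytest

from ecmprofiler.config import CapillarySpec, GridSpec, RampSpec, default_config
from ecmprofiler.micrographs import capillary_morphometrics, nematic_anisotropy
from ecmprofiler.stiffness import decompose_modes
from ecmprofiler.synthetic import (
    generate_capillary_mask,
    generate_crosslink_panel,
    generate_fibril_micrograph,
    generate_force_volume,
    generate_proteomics_tables,
    kappa_for_order,
)


class TestDeterminism:
    def test_force_volume_bitwise_reproducible(self, tiny_cfg):
        fv1 = generate_force_volume(tiny_cfg, "healthy", volume_index=3)
        fv2 = generate_force_volume(tiny_cfg, "healthy", volume_index=3)
        assert np.array_equal(fv1.deflection, fv2.deflection)
        fv3 = generate_force_volume(tiny_cfg, "healthy", volume_index=4)
        assert not np.array_equal(fv1.deflection, fv3.deflection)

    def test_micrograph_and_tables_reproducible(self, cfg):
        m1 = generate_fibril_micrograph(cfg, "crc", index=1)
        m2 = generate_fibril_micrograph(cfg, "crc", index=1)
        assert np.array_equal(m1.intensity, m2.intensity)
        t1, p1 = generate_proteomics_tables(cfg)
        t2, p2 = generate_proteomics_tables(cfg)
        assert t1.intensities.equals(t2.intensities)
        assert p1.peptides.equals(p2.peptides)
        assert generate_crosslink_panel(cfg).equals(generate_crosslink_panel(cfg))


class TestForceVolumeGenerator:
    def test_paper_acquisition_geometry(self, cfg):
        fv = generate_force_volume(cfg, "healthy")
        assert (fv.n_x, fv.n_y) == (16, 16)
        assert fv.z_piezo.size == 4096
        assert fv.scan_size == pytest.approx(70e-6)

    def test_unknown_condition_raises(self, cfg):
        with pytest.raises(KeyError, match="unknown condition"):
            generate_force_volume(cfg, "metastatic")

    def test_mixture_draw_matches_configured_modes(self, cfg):
        # many cheap curves: the log10-E histogram of the generator truth
        # peaks at the configured mode positions
        config = replace(
            cfg,
            grid=GridSpec(n_x=45, n_y=45, scan_size=70e-6),
            ramp=RampSpec(points=64, length=10e-6),
        )
        fv = generate_force_volume(config, "healthy")
        e = fv.truth["moduli_pa"].ravel()
        modes = decompose_modes(np.asarray(e), random_state=0)
        found = sorted(m.mu_log10 for m in modes)
        expected = sorted(m.mu_log10 for m in cfg.stiffness_modes("healthy"))
        assert len(found) == len(expected)
        assert np.allclose(found, expected, atol=0.05)

    def test_truth_weighted_median_fold_structure(self, cfg):
        h = cfg.true_weighted_median("healthy")
        assert cfg.true_weighted_median("perilesional") / h == pytest.approx(2.5)
        assert cfg.true_weighted_median("crc") / h == pytest.approx(9.4)


class TestFibrilGenerator:
    def test_all_parallel_fibrils_score_high(self, cfg):
        spec = replace(cfg.fibrils["healthy"], order=1.0, image_size=256)
        config = replace(cfg, fibrils={**cfg.fibrils, "healthy": spec})
        m = generate_fibril_micrograph(config, "healthy")
        assert nematic_anisotropy(m).score >= 0.95

    def test_uniform_orientations_score_low(self, cfg):
        # isotropy limit at a large field / fibril population
        spec = replace(
            cfg.fibrils["healthy"], order=0.0, noise=0.0,
            n_fibrils=200, image_size=640,
        )
        config = replace(cfg, fibrils={**cfg.fibrils, "healthy": spec})
        m = generate_fibril_micrograph(config, "healthy")
        assert nematic_anisotropy(m).score <= 0.05

    def test_kappa_inverts_the_order_parameter(self):
        from scipy import special

        for target in (0.1, 0.4, 0.8):
            k = kappa_for_order(target)
            assert special.i1(k) / special.i0(k) == pytest.approx(target, abs=1e-6)
        assert kappa_for_order(0.0) == 0.0

    def test_truth_records_realized_order_near_target(self, cfg):
        m = generate_fibril_micrograph(cfg, "crc", index=5)
        assert m.truth["realized_order"] == pytest.approx(
            m.truth["target_order"], abs=0.03
        )


class TestCapillaryGenerator:
    def test_zero_density_empty_mask(self, cfg):
        spec = CapillarySpec(density_per_mm2=0.0, width_um_mean=2.9, width_um_sd=0.1)
        config = replace(cfg, capillaries={**cfg.capillaries, "healthy": spec})
        m = generate_capillary_mask(config, "healthy")
        assert not m.intensity.any()
        assert m.truth["count"] == 0

    def test_component_count_equals_true_count(self, cfg):
        # minimum-separation placement: no merged lumens, so the density
        # estimator is exact per field and unbiased across Poisson draws
        counts, truths = [], []
        for patient in range(25):
            m = generate_capillary_mask(cfg, "perilesional", patient=patient)
            density, _w = capillary_morphometrics(m)
            area = m.intensity.size * (m.pixel_size / 1000.0) ** 2
            counts.append(density * area)
            truths.append(m.truth["count"])
        assert counts == pytest.approx(truths)
        spec = cfg.capillaries["perilesional"]
        expected = spec.density_per_mm2 * spec.field_area_mm2
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_unachievable_density_raises(self, cfg):
        spec = CapillarySpec(
            density_per_mm2=80000.0, width_um_mean=5.3, width_um_sd=0.1,
            field_size_um=100.0,
        )
        config = replace(cfg, capillaries={**cfg.capillaries, "perilesional": spec})
        with pytest.raises(ValueError, match="density"):
            generate_capillary_mask(config, "perilesional")


class TestProteomicsGenerator:
    def test_replicate_correlation_above_098(self, cfg):
        table, _peps = generate_proteomics_tables(cfg)
        log_int = np.log10(table.intensities)
        cors = []
        groups = table.samples.groupby(["condition", "patient"]).groups
        for _key, names in groups.items():
            sub = log_int[list(names)].values
            for i in range(sub.shape[1]):
                for j in range(i + 1, sub.shape[1]):
                    cors.append(np.corrcoef(sub[:, i], sub[:, j])[0, 1])
        assert np.mean(cors) >= 0.98

    def test_effect_for_unknown_protein_raises(self, cfg):
        spec = replace(cfg.proteomics, crc_effects={"NOSUCH1": 5.0})
        config = replace(cfg, proteomics=spec)
        with pytest.raises(ValueError, match="NOSUCH1"):
            generate_proteomics_tables(config)

    def test_truth_lists_configured_dysregulation(self, cfg):
        table, _peps = generate_proteomics_tables(cfg)
        assert set(table.truth["dysregulated"]) == set(cfg.proteomics.crc_effects)

    def test_peptide_parents_exist_in_protein_table(self, cfg):
        table, peps = generate_proteomics_tables(cfg)
        assert set(peps.peptides["Proteins"]) <= set(table.intensities.index)


class TestCrosslinkGenerator:
    def test_zero_noise_panel_is_exact(self, cfg):
        panel = generate_crosslink_panel(cfg, noise_cv=0.0)
        healthy = panel[panel["condition"] == "healthy"]
        assert (healthy["HP"] == cfg.crosslinks["healthy"].hp).all()

    def test_negative_noise_raises(self, cfg):
        with pytest.raises(ValueError):
            generate_crosslink_panel(cfg, noise_cv=-0.1)
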