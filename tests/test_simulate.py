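"""The leaf-spectra generator: designs, independence structure, isotope math."""

import dataclasses

import numpy as np
import pytest

from isoleaf import (
    AIR_R15,
    check_covariate_independence,
    default_field_config,
    default_greenhouse_config,
    delta_after_label_addition,
    generate_field_dataset,
    generate_greenhouse_dataset,
    simulate_leaf_spectrum,
)
from isoleaf.simulate import _baseline_curve
from isoleaf.spectra import LeafType


class TestSpectrumGeneration:
    def test_deterministic_under_seed(self):
        cfg = default_greenhouse_config(seed=4)
        s1, r1 = generate_greenhouse_dataset(cfg)
        s2, r2 = generate_greenhouse_dataset(cfg)
        np.testing.assert_array_equal(s1.matrix, s2.matrix)
        assert r1 == r2

    def test_noise_free_spectrum_matches_closed_form(self):
        # oracle: independent reimplementation of the generating curve
        cfg = default_greenhouse_config()
        quiet = dataclasses.replace(
            cfg, jump_factor_sd=0.0, noise_sd_vnir=0.0, noise_sd_swir1=0.0,
            noise_sd_swir2=0.0,
        )
        quiet.features = cfg.features
        sp = "H. halimifolium"
        profile = cfg.species[sp]
        traits = {"species": sp, "delta15N": 10.0, "n_content": 1.6, "gwc": 1.2,
                  "sla": profile.sla_mean}
        out = simulate_leaf_spectrum(traits, quiet, np.random.default_rng(0))
        wl = out.wavelengths.astype(float)
        expected = _baseline_curve(wl, profile, profile.sla_mean)
        for f in cfg.features:
            depth = f.depth + f.n_sensitivity * 1.6 + f.water_sensitivity * 1.2
            width = f.width * (
                1.0 + f.iso_sensitivity * profile.iso_band_weight(f.center) * 10.0
            )
            expected = expected * (
                1.0 - max(depth, 0.0) * np.exp(-((wl - f.center) ** 2) / (2 * width**2))
            )
        np.testing.assert_allclose(out.values, np.clip(expected, 1e-6, None), atol=1e-12)

    def test_isotope_effect_localized_at_sensitive_bands(self):
        # oracle: analytic difference of the generating curves
        cfg = default_greenhouse_config()
        quiet = dataclasses.replace(
            cfg, jump_factor_sd=0.0, noise_sd_vnir=0.0, noise_sd_swir1=0.0,
            noise_sd_swir2=0.0,
        )
        quiet.features = cfg.features
        sp = "H. rosa-sinensis"
        base = {"species": sp, "n_content": 2.2, "gwc": 2.4, "sla": 15.0}
        rng = np.random.default_rng(0)
        lo = simulate_leaf_spectrum({**base, "delta15N": 0.0}, quiet, rng)
        hi = simulate_leaf_spectrum({**base, "delta15N": 20.0}, quiet, rng)
        diff = np.abs(hi.values - lo.values)
        centers = quiet.iso_sensitive_centers(sp)
        top = lo.wavelengths[np.argsort(diff)[-30:]]
        # every top-difference band lies within 2.5 widths of a planted center
        assert all(np.min(np.abs(centers - t)) < 2.5 * 16 for t in top)

    def test_iso_switch_off_removes_delta_dependence(self):
        cfg = default_greenhouse_config().without_iso_effect()
        quiet = dataclasses.replace(
            cfg, jump_factor_sd=0.0, noise_sd_vnir=0.0, noise_sd_swir1=0.0,
            noise_sd_swir2=0.0,
        )
        quiet.features = cfg.features
        base = {"species": "A. unedo", "n_content": 1.1, "gwc": 1.0, "sla": 6.0}
        rng = np.random.default_rng(0)
        a = simulate_leaf_spectrum({**base, "delta15N": 0.0}, quiet, rng)
        b = simulate_leaf_spectrum({**base, "delta15N": 20.0}, quiet, rng)
        np.testing.assert_array_equal(a.values, b.values)

    def test_excessive_depth_rejected(self):
        cfg = default_greenhouse_config()
        traits = {"species": "H. rosa-sinensis", "delta15N": 0.0, "n_content": 20.0,
                  "gwc": 1.0, "sla": 15.0}
        with pytest.raises(ValueError, match="depth"):
            simulate_leaf_spectrum(traits, cfg, np.random.default_rng(0))


class TestGreenhouseDesign:
    def test_sample_bookkeeping(self, greenhouse):
        _, sset, records = greenhouse
        assert sset.n_samples == (16 + 12 + 11) * 9  # plants x 3 leaf types x 3
        by_species = {}
        for r in records:
            by_species.setdefault(r.species, []).append(r)
        assert len(by_species["H. halimifolium"]) == 144
        assert len(by_species["H. rosa-sinensis"]) == 108
        assert len(by_species["A. unedo"]) == 99

    def test_au_two_treatments_only(self, greenhouse):
        _, _, records = greenhouse
        au_treatments = {r.treatment for r in records if r.species == "A. unedo"}
        assert au_treatments == {0.0, 20.0}
        other = {r.treatment for r in records if r.species != "A. unedo"}
        assert other == {0.0, 10.0, 20.0}

    def test_covariates_independent_of_isotope_signal(self, greenhouse):
        _, _, records = greenhouse
        table = check_covariate_independence(records)
        assert np.all(np.abs(table["spearman_r"]) < 0.3)

    def test_delta_ranges_match_design(self, greenhouse):
        # labeling spans roughly 16-19 permil within species
        _, _, records = greenhouse
        for sp in ("H. halimifolium", "H. rosa-sinensis", "A. unedo"):
            d = [r.delta15N for r in records if r.species == sp]
            assert 13.0 < max(d) - min(d) < 23.0

    def test_au_mature_labeling_failure(self, greenhouse):
        _, _, records = greenhouse
        mature = [r for r in records if r.species == "A. unedo" and r.leaf_type == LeafType.MATURE]
        d0 = [r.delta15N for r in mature if r.treatment == 0.0]
        d20 = [r.delta15N for r in mature if r.treatment == 20.0]
        # no uptake: treatment groups indistinguishable in mature leaves
        assert abs(np.mean(d20) - np.mean(d0)) < 1.0
        young = [r for r in records if r.species == "A. unedo" and r.leaf_type == LeafType.YOUNG]
        y20 = [r.delta15N for r in young if r.treatment == 20.0]
        assert np.mean(y20) > 10.0


class TestFieldDesign:
    def test_printed_bounds_and_correlation(self):
        rs = []
        for seed in range(5):
            _, records = generate_field_dataset(default_field_config(), seed=seed)
            n = np.array([r.n_content for r in records])
            d = np.array([r.delta15N for r in records])
            assert n.min() >= 0.47 - 1e-9 and n.max() <= 0.96 + 1e-9
            rs.append(np.corrcoef(d, n)[0, 1])
        assert 0.6 <= np.median(rs) <= 0.9

    def test_distance_decay_limit(self):
        cfg = default_field_config()
        cfg.field_design = dataclasses.replace(
            cfg.field_design, delta_noise_sd=0.0, max_distance=400.0, n_samples=50
        )
        _, records = generate_field_dataset(cfg, seed=0)
        far = max(records, key=lambda r: r.distance_to_canopy)
        assert far.delta15N == pytest.approx(cfg.field_design.background_delta, abs=0.1)

    def test_delta_span_matches_gradient(self):
        _, records = generate_field_dataset(default_field_config(), seed=1)
        d = np.array([r.delta15N for r in records])
        assert d.min() < -10.0 and d.max() > -4.5


class TestLabelAdditionBookkeeping:
    def test_identity_mixing(self):
        x_pool = AIR_R15 * 1.01 / (1 + AIR_R15 * 1.01)  # pool at +10 permil
        assert delta_after_label_addition(0.01, 10.0, [(1e-6, x_pool)]) == pytest.approx(
            10.0, abs=1e-9
        )

    def test_fertilizer_recipe_yields_ten_permil(self):
        # oracle: direct atom-count arithmetic, independently recomputed here
        pool_mol, pool_delta = 14.8e-3, 0.0
        additions = [(0.274e-6, 0.98), (2 * 0.145e-6, 0.95)]  # KNO3; (NH4)2SO4 has 2 N
        result = delta_after_label_addition(pool_mol, pool_delta, additions)

        x_air = AIR_R15 / (1 + AIR_R15)
        heavy = pool_mol * x_air + sum(m * x for m, x in additions)
        total = pool_mol + sum(m for m, _ in additions)
        x = heavy / total
        expected = (x / (1 - x) / AIR_R15 - 1) * 1000
        assert result == pytest.approx(expected, abs=1e-9)
        assert result == pytest.approx(10.0, abs=0.35)

    def test_small_perturbation_linearity(self):
        one = delta_after_label_addition(14.8e-3, 0.0, [(0.274e-6, 0.98), (0.29e-6, 0.95)])
        two = delta_after_label_addition(
            14.8e-3, 0.0, [(2 * 0.274e-6, 0.98), (2 * 0.29e-6, 0.95)]
        )
        assert two / one == pytest.approx(2.0, rel=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            delta_after_label_addition(-1.0, 0.0, [])
        with pytest.raises(ValueError):
            delta_after_label_addition(1.0, 0.0, [(-1e-6, 0.98)])
        with pytest.raises(ValueError):
            delta_after_label_addition(1.0, 0.0, [(1e-6, 1.5)])


class TestCovariateCheck:
    def test_shuffled_delta_uncorrelated(self, greenhouse):
        _, _, records = greenhouse
        rng = np.random.default_rng(0)
        deltas = rng.permutation([r.delta15N for r in records])
        shuffled = [dataclasses.replace(r, delta15N=d) for r, d in zip(records, deltas)]
        table = check_covariate_independence(shuffled)
        assert np.all(np.abs(table["spearman_r"]) < 0.25)

    def test_copied_covariate_fully_correlated(self, greenhouse):
        _, _, records = greenhouse
        copied = [dataclasses.replace(r, delta15N=r.n_content) for r in records]
        table = check_covariate_independence(copied)
        n_rows = table[table["covariate"] == "n_content"]
        np.testing.assert_allclose(n_rows["spearman_r"], 1.0)

    def test_constant_covariate_reported_undefined(self):
        from isoleaf import SampleRecord

        records = [
            SampleRecord(f"s{i}", "sp", delta15N=float(i), n_content=1.0, gwc=1.0, sla=5.0)
            for i in range(6)
        ]
        table = check_covariate_independence(records)
        assert table["spearman_r"].isna().all()

    def test_too_few_records_rejected(self):
        from isoleaf import SampleRecord

        records = [SampleRecord("a", "sp", 0.0, 1.0, 1.0, 5.0)]
        with pytest.raises(ValueError, match=">= 5"):
            check_covariate_independence(records)
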