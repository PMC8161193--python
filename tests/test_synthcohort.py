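"""Generator tests: cohort structure, ground-truth models, rendering physics."""

import numpy as np
import pytest
from scipy import stats

import marrowmap as mm
from marrowmap.config import ConfigurationError, GeneratorConfig, tiny_generator_config
from marrowmap.synthcohort import (LABELS, age_group_of, marrow_truth,
                                   sample_cohort, _rician)


class TestSampleCohort:
    def test_balanced_cells(self):
        metas = sample_cohort(10, seed=7)
        assert len(metas) == 100
        from collections import Counter
        cells = Counter((m.sex, m.age_group) for m in metas)
        assert len(cells) == 10 and set(cells.values()) == {10}

    def test_minimal_cohort(self):
        metas = sample_cohort(1, seed=0)
        assert len(metas) == 10
        assert sum(m.sex == "M" for m in metas) == 5

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            sample_cohort(0, seed=1)

    def test_ages_within_bands(self):
        for m in sample_cohort(20, seed=3):
            lo, hi = {"30-39": (30, 39), "40-49": (40, 49), "50-59": (50, 59),
                      "60-69": (60, 69), ">=70": (70, 85)}[m.age_group]
            assert lo <= m.age <= hi

    def test_bmi_truncated_normal_mean(self):
        # Oracle: analytic mean of the truncated normal the cohort draws from.
        cfg = GeneratorConfig()
        a = (cfg.bmi_min - cfg.bmi_mean["M"]) / cfg.bmi_sd["M"]
        expected = stats.truncnorm.mean(a, np.inf, loc=cfg.bmi_mean["M"],
                                        scale=cfg.bmi_sd["M"])
        men = [m.bmi for m in sample_cohort(200, seed=1) if m.sex == "M"]
        assert abs(np.mean(men) - expected) < 0.35  # ~3 SE at n=1000
        assert min(men) >= cfg.bmi_min


class TestAgeGroups:
    @pytest.mark.parametrize("age,band", [(30, "30-39"), (39, "30-39"),
                                          (55, "50-59"), (70, ">=70"),
                                          (85, ">=70")])
    def test_band_assignment(self, age, band):
        assert age_group_of(age) == band

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            age_group_of(29)


class TestMarrowTruth:
    @pytest.mark.parametrize("sex,age,adc", [("M", 30, 450.0), ("F", 30, 503.0)])
    def test_noiseless_adc_model(self, sex, age, adc):
        t = marrow_truth(mm.SubjectMeta("s", sex, age, 24.0))
        assert t.true_adc == pytest.approx(adc)

    def test_noiseless_ff_model(self):
        t = marrow_truth(mm.SubjectMeta("s", "F", 50, 24.0))
        assert t.true_ff == pytest.approx(64.0)

    def test_age_out_of_range(self):
        with pytest.raises(ValueError):
            mm.SubjectMeta("s", "M", 20, 24.0)

    def test_clipping_keeps_refinement_ranges(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = marrow_truth(mm.SubjectMeta("s", "F", 84, 24.0), rng=rng)
            assert 15.0 <= t.true_ff <= 95.0
            assert 100.0 <= t.true_adc <= 1000.0

    def test_age_ff_correlation_matches_direct_simulation(self):
        # Oracle: simulate the stated distributions directly (uniform band
        # ages, Gaussian %FF noise around the linear model) and compare the
        # generator's Spearman r at n=400.
        cfg = GeneratorConfig()
        rng = np.random.default_rng(123)
        ages_mc = np.concatenate([rng.integers(lo, hi + 1, 40000)
                                  for lo, hi in cfg.age_bands])
        ff_mc = cfg.ff_intercept + cfg.ff_age_slope * ages_mc \
            + rng.normal(0, cfg.ff_sd, ages_mc.size)
        r_expected = stats.spearmanr(ages_mc, ff_mc).statistic

        metas = sample_cohort(40, seed=11)           # 400 subjects
        gen_rng = np.random.default_rng(99)
        truths = [marrow_truth(m, cfg, rng=gen_rng) for m in metas]
        r = stats.spearmanr([m.age for m in metas],
                            [t.true_ff for t in truths]).statistic
        assert r > 0
        assert abs(r - r_expected) < 0.1


class TestPhantom:
    def test_all_labels_present_and_disjoint(self, noiseless_tiny_study):
        phantom, _ = noiseless_tiny_study
        lab = np.concatenate([v.data.ravel() for v in phantom.dwi_labels])
        assert set(np.unique(lab)) == set(LABELS.values())

    def test_station_counting(self, tiny_config):
        phantom = mm.build_phantom(mm.SubjectMeta("s", "M", 40, 25.0), tiny_config)
        assert len(phantom.dwi_grids) == tiny_config.n_stations
        total = sum(g.shape[2] for g in phantom.dwi_grids)
        assert total == tiny_config.n_stations * tiny_config.dwi_shape[2]

    def test_too_small_grid_raises(self):
        cfg = tiny_generator_config(dwi_shape=(8, 8, 4), dwi_spacing=(24.0, 24.0, 30.0),
                                    dixon_shape=(12, 12, 17),
                                    dixon_spacing=(16.0, 16.0, 7.0))
        with pytest.raises(ConfigurationError):
            mm.build_phantom(mm.SubjectMeta("s", "M", 40, 25.0), cfg)


class TestRender:
    def test_noiseless_signal_is_analytic(self, noiseless_tiny_study, tiny_config):
        phantom, study = noiseless_tiny_study
        marrow = phantom.tissues["marrow"]
        expected = marrow.s0 * np.exp(-900e-6 * marrow.true_adc)
        for lab_vol, b900 in zip(phantom.dwi_labels, study.stations["b900"]):
            sel = lab_vol.data == LABELS["marrow"]
            if sel.any():
                assert np.allclose(b900.data[sel], expected, rtol=1e-6)

    def test_mono_exponential_decay_arithmetic(self):
        # s0 at b50 = 1000 with ADC 422 um^2/s decays to 698.6 at b900
        assert 1000 * np.exp(-850 * 422e-6) == pytest.approx(698.6, abs=0.05)

    def test_seeded_determinism(self, tiny_config, meta_m30):
        phantom = mm.build_phantom(meta_m30, tiny_config)
        a = mm.render_study(phantom, 10.0, seed=5, config=tiny_config)
        b = mm.render_study(phantom, 10.0, seed=5, config=tiny_config)
        c = mm.render_study(phantom, 10.0, seed=6, config=tiny_config)
        for chan in a.stations:
            for va, vb in zip(a.stations[chan], b.stations[chan]):
                assert np.array_equal(va.data, vb.data)
        assert not np.array_equal(a.stations["b50"][0].data,
                                  c.stations["b50"][0].data)

    def test_negative_noise_rejected(self, noiseless_tiny_study):
        phantom, _ = noiseless_tiny_study
        with pytest.raises(ValueError):
            mm.render_study(phantom, -1.0, seed=0)

    def test_rician_mean_inflation(self):
        # Low-noise expansion: E[|S + n|] ~ S + sigma^2 / (2 S) at SNR >> 1.
        s, sigma = 1000.0, 20.0
        rng = np.random.default_rng(42)
        out = _rician(np.full(400_000, s), sigma, rng)
        assert out.mean() == pytest.approx(s + sigma ** 2 / (2 * s), abs=0.15)


class TestFixtureIO:
    def test_fixture_round_trip(self, tmp_path, tiny_config, meta_m30):
        phantom = mm.build_phantom(meta_m30, tiny_config)
        study = mm.render_study(phantom, 5.0, seed=2, config=tiny_config)
        manifest = mm.write_fixture(study, tmp_path)
        n_img = sum(len(v) for v in manifest["files"].values())
        assert n_img == 6 * tiny_config.n_stations
        back = mm.read_subject(tmp_path)
        assert back.meta.age == meta_m30.age
        assert back.truth["true_ff"] == pytest.approx(study.truth["true_ff"])
        for chan in study.stations:
            for orig, rt in zip(study.stations[chan], back.stations[chan]):
                assert np.array_equal(np.asarray(orig.data, float),
                                      np.asarray(rt.data, float))
                assert np.allclose(orig.geometry.origin, rt.geometry.origin)

    def test_same_seed_identical_fixtures(self, tmp_path, tiny_config, meta_m30):
        s1 = mm.simulate_subject(meta_m30, tiny_config, seed=3)
        s2 = mm.simulate_subject(meta_m30, tiny_config, seed=3)
        for chan in s1.stations:
            for a, b in zip(s1.stations[chan], s2.stations[chan]):
                assert np.array_equal(a.data, b.data)
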