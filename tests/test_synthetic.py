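"""Synthetic generators: determinism, statistical contracts, cohort shape."""

import numpy as np
import pytest

from sleepdyn import (
    DivergenceError,
    EntropyParams,
    GeneratorConfig,
    InvalidLengthError,
    ParameterError,
    binarize_median,
    gen_actigraphy_night,
    gen_cohort,
    gen_fgn,
    gen_gaussian_noise,
    gen_henon,
    gen_pink_noise,
    moving_average,
    null_config,
    sampen,
)


class TestGaussian:
    def test_deterministic(self):
        assert np.array_equal(gen_gaussian_noise(4, 5), gen_gaussian_noise(4, 5))

    def test_moments(self):
        n = 100_000
        x = gen_gaussian_noise(n, 0)
        assert abs(x.mean()) < 3 / np.sqrt(n)
        assert abs(x.var() - 1) < 0.05

    def test_too_short(self):
        with pytest.raises(InvalidLengthError):
            gen_gaussian_noise(1, 0)


class TestFgn:
    def test_h_half_is_white(self):
        x = gen_fgn(0.5, 20_000, 0)
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(lag1) < 3 / np.sqrt(len(x))

    def test_unit_variance_target(self):
        x = gen_fgn(0.7, 50_000, 1)
        assert x.var() == pytest.approx(1.0, abs=0.1)

    def test_persistent_fgn_positive_lag1(self):
        x = gen_fgn(0.9, 20_000, 2)
        # theory: rho(1) = 2^(2H-1) - 1 ~ 0.74 for H=0.9
        assert np.corrcoef(x[:-1], x[1:])[0, 1] == pytest.approx(0.74, abs=0.10)

    def test_invalid_hurst(self):
        for h in (0.0, 1.0, 1.2, -0.3):
            with pytest.raises(ParameterError):
                gen_fgn(h, 100, 0)


class TestPink:
    def test_periodogram_slope_near_minus_one(self):
        x = gen_pink_noise(2 ** 15, 0)
        p = np.abs(np.fft.rfft(x)) ** 2
        f = np.fft.rfftfreq(len(x))
        mask = f > 0
        slope = np.polyfit(np.log10(f[mask]), np.log10(p[mask]), 1)[0]
        assert -1.2 < slope < -0.8

    def test_seeds_differ_slope_stable(self):
        x0, x1 = gen_pink_noise(4096, 0), gen_pink_noise(4096, 1)
        assert not np.array_equal(x0, x1)

        def slope(x):
            p = np.abs(np.fft.rfft(x)) ** 2
            f = np.fft.rfftfreq(len(x))
            return np.polyfit(np.log10(f[1:]), np.log10(p[1:]), 1)[0]

        assert slope(x0) == pytest.approx(slope(x1), abs=0.15)

    def test_too_short(self):
        with pytest.raises(InvalidLengthError):
            gen_pink_noise(8, 0)


class TestHenon:
    def test_bounded_canonical_orbit(self):
        x = gen_henon(5000)
        assert np.all(np.abs(x) <= 1.5)

    def test_degenerate_fixed_point(self):
        x = gen_henon(100, a=0.0, b=0.0)
        assert np.allclose(x, 1.0)

    def test_divergence_detected(self):
        with pytest.raises(DivergenceError):
            gen_henon(1000, a=6.0, b=0.3)


class TestNight:
    def test_nonnegative_and_length(self):
        cfg = GeneratorConfig(series_length=3600, seed=0)
        series, states = gen_actigraphy_night(cfg, "A", seed=1)
        assert len(series) == 3600
        assert np.all(series.values >= 0)
        assert set(np.unique(states)) <= {0, 1}

    def test_unknown_group(self):
        cfg = GeneratorConfig(series_length=600, seed=0)
        with pytest.raises(ParameterError):
            gen_actigraphy_night(cfg, "C", seed=0)

    def test_group_effect_sign_in_high_state(self):
        """With the group CV contrast, the pointwise entropy of the binarized
        series during high-irregularity epochs is lower for group B (paired
        over seeds, at the 100 s scale where the group statistics operate)."""
        from sleepdyn import exp_sampen

        diffs = []
        for seed in range(30):
            vals = {}
            for group in ("A", "B"):
                cfg = GeneratorConfig(series_length=7200,
                                      state_dwell_mean=1800.0, seed=0)
                series, states = gen_actigraphy_night(cfg, group, seed)
                b = binarize_median(series.values).values
                av = moving_average(b, 100)
                ese = exp_sampen(av, EntropyParams(scale=100))
                st = states[ese.time_offset:ese.time_offset + len(ese.values)]
                if st.mean() < 0.05 or st.mean() > 0.95:
                    vals = None
                    break
                vals[group] = ese.values[st == 1].mean()
            if vals:
                diffs.append(vals["A"] - vals["B"])
        assert len(diffs) >= 20
        # systematic deficit for B: positive mean, clearly more wins than losses
        assert np.mean(diffs) > 0
        assert np.mean(np.array(diffs) > 0) > 0.6

    def test_null_configuration_symmetric(self):
        """With equal CVs the group label changes nothing but the label."""
        cfg = null_config(GeneratorConfig(series_length=2000, seed=0))
        a, _ = gen_actigraphy_night(cfg, "A", seed=9)
        b, _ = gen_actigraphy_night(cfg, "B", seed=9)
        assert np.array_equal(a.values, b.values)


class TestCohort:
    def test_paper_sized_cohort_count(self):
        cfg = GeneratorConfig(n_subjects_per_group=17, nights_per_subject=3,
                              series_length=64, seed=0)
        cohort = gen_cohort(cfg)
        assert len(cohort.recordings) == 102

    def test_bit_identical_under_same_config(self):
        cfg = GeneratorConfig(n_subjects_per_group=2, nights_per_subject=2,
                              series_length=500, seed=3)
        c1, c2 = gen_cohort(cfg), gen_cohort(cfg)
        for key in c1.recordings:
            assert np.array_equal(c1.recordings[key].values,
                                  c2.recordings[key].values)

    def test_zero_subjects_rejected(self):
        with pytest.raises(ParameterError):
            GeneratorConfig(n_subjects_per_group=0, seed=0)

    def test_effect_direction_constraint(self):
        with pytest.raises(ParameterError):
            GeneratorConfig(interval_cv_high={"A": 0.3, "B": 1.0}, seed=0)
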