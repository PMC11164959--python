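"""Slope fitting, cycle segmentation, background correction, scaling."""

import numpy as np
import pandas as pd
import pytest

import fishphys as fp
from fishphys.trace import (BackgroundModel, CycleSchedule,
                            RespirometerGeometry, fit_background,
                            fit_slope, segment_cycles,
                            select_scaling_model)


def _make_trace(n_cycles=3, flush_s=300.0, measure_s=600.0, dt=5.0,
                labeled=True):
    rows = []
    for c in range(n_cycles):
        start = c * (flush_s + measure_s)
        for t in np.arange(start, start + flush_s, dt):
            rows.append((t, 6.8, "flush", c))
        for t in np.arange(start + flush_s, start + flush_s + measure_s,
                           dt):
            rows.append((t, 6.8 - 0.02 * (t - start - flush_s) / 60.0,
                         "measure", c))
    df = pd.DataFrame(rows, columns=["time_s", "o2_mg_per_l", "phase",
                                     "cycle_index"])
    if not labeled:
        df = df.drop(columns=["phase", "cycle_index"])
    return df


class TestSegmentCycles:
    def test_three_cycles_of_expected_width(self):
        wins = segment_cycles(_make_trace())
        assert len(wins) == 3
        for w in wins:
            assert w["time_s"].iloc[-1] - w["time_s"].iloc[0] == \
                pytest.approx(595.0)

    def test_no_measure_samples_gives_empty(self):
        df = _make_trace()
        df["phase"] = "flush"
        assert segment_cycles(df) == []

    def test_schedule_matches_labels(self):
        labeled = segment_cycles(_make_trace())
        derived = segment_cycles(
            _make_trace(labeled=False),
            schedule=CycleSchedule(flush_s=300.0, measure_s=600.0))
        assert len(labeled) == len(derived)
        for a, b in zip(labeled, derived):
            np.testing.assert_array_equal(a["time_s"], b["time_s"])
            np.testing.assert_array_equal(a["o2_mg_per_l"],
                                          b["o2_mg_per_l"])

    def test_unordered_times_rejected(self):
        df = _make_trace()
        df.loc[1, "time_s"] = df.loc[0, "time_s"]
        with pytest.raises(ValueError, match="strictly increasing"):
            segment_cycles(df)


class TestFitSlope:
    def test_exact_line(self):
        t = np.arange(0, 600, 5.0)
        o2 = 7.0 - 0.02 * (t / 60.0)
        fit = fit_slope(t, o2)
        assert fit.slope == pytest.approx(-0.02)
        assert fit.intercept == pytest.approx(7.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_trace_is_rateless(self):
        t = np.arange(0, 600, 5.0)
        fit = fit_slope(t, np.full_like(t, 6.8))
        assert fit.slope == pytest.approx(0.0, abs=1e-15)
        assert fit.r2 == pytest.approx(0.0, abs=1e-15)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            fit_slope([0, 1], [7, 6.9])

    def test_noisy_slope_within_three_se(self):
        """OLS sampling property: over 500 seeded windows the estimate
        lands within 3 standard errors of the generating slope."""
        rng = np.random.default_rng(42)
        t = np.arange(0, 600, 5.0)
        t_min = t / 60.0
        true = -0.05
        sigma = 0.02
        se = sigma / np.sqrt(np.sum((t_min - t_min.mean()) ** 2))
        hits = 0
        for _ in range(500):
            o2 = 7.0 + true * t_min + rng.normal(0, sigma, len(t))
            if abs(fit_slope(t, o2).slope - true) < 3 * se:
                hits += 1
        assert hits >= 490   # 3-sigma coverage ~99.7%


class TestFitBackground:
    def _fits(self, slope, n=3):
        t = np.arange(0, 600, 5.0)
        return [fit_slope(t, 7.0 + slope * t / 60.0) for _ in range(n)]

    def test_exponential_midpoint_is_geometric_mean(self):
        span = 24 * 3600.0
        bg = fit_background(self._fits(-0.01), self._fits(-0.06), span)
        assert bg.evaluate(span / 2) == pytest.approx(
            np.sqrt(0.01 * 0.06), rel=1e-9)
        assert bg.evaluate(0.0) == pytest.approx(0.01)
        assert bg.evaluate(span) == pytest.approx(0.06)

    def test_equal_blanks_constant(self):
        bg = fit_background(self._fits(-0.02), self._fits(-0.02), 3600.0)
        assert bg.k == 0.0
        assert bg.evaluate(1800.0) == pytest.approx(0.02)

    def test_zero_blanks_zero_model(self):
        bg = fit_background(self._fits(0.0), self._fits(0.0), 3600.0)
        assert bg.mode == "zero"
        assert bg.evaluate(1234.0) == 0.0

    def test_nonpositive_initial_falls_back_to_linear(self):
        with pytest.warns(UserWarning, match="linear"):
            bg = fit_background(self._fits(0.0), self._fits(-0.06),
                                3600.0)
        assert bg.mode == "linear"
        assert bg.evaluate(1800.0) == pytest.approx(0.03)
        assert bg.evaluate(3600.0) == pytest.approx(0.06)

    def test_too_few_blanks_rejected(self):
        with pytest.raises(ValueError, match="blank cycles"):
            fit_background(self._fits(-0.01, n=2), self._fits(-0.06),
                           3600.0)


class TestComputeMO2:
    GEOM = RespirometerGeometry(v_r_l=0.566, v_f_l=0.005, mass_kg=0.005)

    def test_direct_arithmetic(self):
        t = np.arange(0, 600, 5.0)
        fit = fit_slope(t, 7.0 - 0.5 * t / 60.0)
        s = fp.compute_mo2(fit, self.GEOM)
        assert s.mo2 == pytest.approx(0.5 * 0.561 / 0.005)  # 56.1

    def test_slope_equal_to_background_gives_zero(self):
        t = np.arange(0, 600, 5.0)
        fit = fit_slope(t, 7.0 - 0.02 * t / 60.0)
        bg = BackgroundModel(b0=0.02, k=0.0, t_ref_s=3600.0)
        s = fp.compute_mo2(fit, self.GEOM, bg)
        assert s.mo2 == pytest.approx(0.0, abs=1e-9)
        bg2 = BackgroundModel(b0=0.03, k=0.0, t_ref_s=3600.0)
        over = fp.compute_mo2(fit, self.GEOM, bg2)
        assert over.flagged and over.mo2 == 0.0

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError, match="v_r_l > v_f_l"):
            RespirometerGeometry(v_r_l=0.004, v_f_l=0.005, mass_kg=0.005)

    def test_order_invariance(self, nf_trial, nf_config):
        geom = RespirometerGeometry(nf_config.chamber_volume_l,
                                    nf_config.fish_volume_l,
                                    nf_config.fish_mass_kg)
        wins = segment_cycles(nf_trial.trace)
        fwd = [fp.compute_mo2(fit_slope(w["time_s"], w["o2_mg_per_l"]),
                              geom).mo2 for w in wins]
        rev = [fp.compute_mo2(fit_slope(w["time_s"], w["o2_mg_per_l"]),
                              geom).mo2 for w in reversed(wins)]
        np.testing.assert_array_equal(fwd, rev[::-1])


class TestScaling:
    def _cohort(self, b, n=12, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        m = rng.lognormal(np.log(0.005), 0.5, n)
        whole = 10.0 * m ** b * np.exp(rng.normal(0, noise, n))
        return m, whole / m      # mass-specific

    def test_recovers_universal_exponent(self):
        m, y = self._cohort(0.89, noise=0.01)
        d = select_scaling_model(m, y)
        assert abs(d.free_b - 0.89) < 0.05
        assert "universal" in d.equivalent and "free" in d.equivalent

    def test_recovers_isometry(self):
        m, y = self._cohort(1.0, noise=0.01)
        d = select_scaling_model(m, y)
        assert "isometric" in d.equivalent

    def test_identical_masses_rejected(self):
        with pytest.raises(ValueError, match="identical mass"):
            select_scaling_model([0.005] * 6, [2.0] * 6)

    def test_scale_identity_cases(self):
        assert fp.scale_to_common_mass(10.0, 0.005, b=0.5) == 10.0
        assert fp.scale_to_common_mass(10.0, 0.02, b=1.0) == 10.0

    def test_scale_direct_arithmetic(self):
        assert fp.scale_to_common_mass(10.0, 0.010, b=0.89) == \
            pytest.approx(10.0 * 2 ** 0.11)

    def test_scale_round_trip(self):
        x = 7.31
        y = fp.scale_to_common_mass(x, 0.012, b=0.89)
        back = y * (0.012 / 0.005) ** (0.89 - 1.0)
        assert back == pytest.approx(x, rel=1e-12)
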