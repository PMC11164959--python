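"""Specific dynamic action: masking, baseline, integration, energetics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishphys.sda import (MealSpec, compute_sda, compute_sda_coeff,
                          compute_sda_peak, compute_smr_sda,
                          hourly_minimum_line, mask_handling_window,
                          scope_partition)
from fishphys.simulate import RespSimConfig, SDAParams
from fishphys.pipeline import PipelineConfig, analyze_cohort
from fishphys.simulate import CohortGroup, simulate_cohort


class TestMask:
    def test_filters_first_hours(self):
        out = mask_handling_window([1, 2, 4, 6], [5, 6, 7, 8], mask_h=3.0)
        assert list(out["t_h"]) == [4, 6]

    def test_zero_mask_is_identity(self):
        out = mask_handling_window([1, 2, 4], [5, 6, 7], mask_h=0.0)
        assert len(out) == 3

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            mask_handling_window([1.0, 2.0], [5.0, 6.0], mask_h=3.0)


class TestBaseline:
    def test_lowest_decile(self):
        masked = pd.DataFrame({"t_h": np.arange(20.0),
                               "mo2": np.arange(1.0, 21.0)})
        smr, _ = compute_smr_sda(masked)
        assert smr == pytest.approx(1.5)

    def test_constant_pool(self):
        masked = pd.DataFrame({"t_h": np.arange(12.0),
                               "mo2": np.full(12, 3.0)})
        assert compute_smr_sda(masked)[0] == 3.0


class TestHourlyMinimum:
    def test_node_is_minimum_of_hour(self):
        masked = pd.DataFrame({
            "t_h": [4.1, 4.5, 4.9, 5.2, 5.8],
            "mo2": [5.1, 4.2, 6.0, 3.0, 3.5]})
        line = hourly_minimum_line(masked)
        assert line.iloc[0]["t_h"] == 4.5
        assert line.iloc[0]["mo2"] == 4.2
        assert line.iloc[1]["mo2"] == 3.0

    def test_monotone_series_takes_last_of_each_hour(self):
        t = np.arange(3.0, 9.0, 0.25)
        masked = pd.DataFrame({"t_h": t, "mo2": 10.0 - t})
        line = hourly_minimum_line(masked)
        # strictly decreasing: the hour minimum is its final sample
        assert (line["t_h"] == [3.75, 4.75, 5.75, 6.75, 7.75, 8.75]).all()

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError, match="2 nonempty"):
            hourly_minimum_line(pd.DataFrame({"t_h": [4.1, 4.2],
                                              "mo2": [5.0, 6.0]}))


class TestIntegral:
    def test_triangle_closed_form(self):
        """Rise from baseline to +4 at 10 h, back at 20 h: the area is
        half base x height in minutes = 2400 mg O2 kg-1."""
        smr = 2.0
        line = pd.DataFrame({"t_h": [10.0, 20.0], "mo2": [6.0, 2.0]})
        sda, dur, trunc = compute_sda(None, smr, line=line)
        assert sda == pytest.approx(0.5 * 4.0 * 20.0 * 60.0)
        assert dur == 20.0
        assert not trunc

    def test_flat_curve_zero(self):
        line = pd.DataFrame({"t_h": [4.0, 10.0], "mo2": [2.0, 2.0]})
        sda, dur, _ = compute_sda(None, 2.0, line=line)
        assert sda == 0.0 and dur == 0.0

    def test_truncated_when_never_returning(self):
        line = pd.DataFrame({"t_h": [4.0, 10.0], "mo2": [5.0, 6.0]})
        sda, dur, trunc = compute_sda(None, 2.0, line=line)
        assert trunc and dur == 10.0

    def test_duplicate_nodes_do_not_change_integral(self):
        line = pd.DataFrame({"t_h": [5.0, 5.0, 15.0],
                             "mo2": [6.0, 6.0, 2.0]})
        ref = pd.DataFrame({"t_h": [5.0, 15.0], "mo2": [6.0, 2.0]})
        assert compute_sda(None, 2.0, line=line)[0] == \
            pytest.approx(compute_sda(None, 2.0, line=ref)[0])

    @given(st.lists(st.tuples(st.floats(0.1, 40.0), st.floats(0.0, 8.0)),
                    min_size=2, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_trapezoid_matches_closed_form(self, nodes):
        """Oracle: for piecewise-linear curves that stay above baseline
        until a final return node, trapezoid integration equals the
        sum of per-segment trapezoid areas computed independently."""
        smr = 1.0
        ts = np.unique([t for t, _ in nodes])
        if len(ts) < 2:
            return
        ys = smr + np.array([dict(nodes)[t] for t in ts])
        ys[-1] = smr   # force a return to baseline at the last node
        if not (ys[:-1] > smr).all():
            return     # stays-above precondition
        line = pd.DataFrame({"t_h": ts, "mo2": ys})
        sda, dur, trunc = compute_sda(None, smr, line=line)
        # independent closed form: area of each trapezoid in minutes
        full_t = np.concatenate([[0.0], ts]) * 60.0
        full_y = np.concatenate([[smr], ys]) - smr
        expect = float(sum((full_t[i + 1] - full_t[i])
                           * (full_y[i] + full_y[i + 1]) / 2.0
                           for i in range(len(full_t) - 1)))
        assert sda == pytest.approx(expect, rel=1e-9, abs=1e-9)
        assert dur == ts[-1] and not trunc


class TestPeak:
    def test_tie_breaks_to_earliest(self):
        masked = pd.DataFrame({"t_h": [4.0, 6.0, 8.0, 10.0],
                               "mo2": [5.0, 9.0, 9.0, 7.0]})
        peak, t = compute_sda_peak(masked)
        assert peak == 9.0 and t == 6.0

    def test_monotone_decline_peaks_at_first_sample(self):
        masked = pd.DataFrame({"t_h": [3.5, 5.0, 7.0],
                               "mo2": [8.0, 6.0, 4.0]})
        assert compute_sda_peak(masked) == (8.0, 3.5)


class TestEnergyBudget:
    @pytest.mark.parametrize("sda, expected", [
        (31.23, 0.69), (48.58, 1.07), (0.0, 0.0)])
    def test_meal_energy_coefficient(self, sda, expected):
        """A 2% body-mass scallop ration holds 61.92 kJ of digestible
        energy per kg of fish; the coefficient follows directly."""
        assert compute_sda_coeff(sda, MealSpec(percent_bm=2.0)) == \
            pytest.approx(expected, abs=0.005)

    def test_invalid_meal_rejected(self):
        with pytest.raises(ValueError):
            MealSpec(percent_bm=0.0)

    def test_partition_arithmetic(self):
        p = scope_partition(smr=2.0, mmr=14.0, aas=12.0, sda_peak=8.0)
        assert p.scope_used_pct == pytest.approx(50.0)
        assert p.scope_remaining_pct == pytest.approx(50.0)
        assert p.remaining_scope_abs == pytest.approx(6.0)
        assert p.peak_to_smr == pytest.approx(4.0)

    @pytest.mark.parametrize("sda_peak, used", [(14.0, 100.0),
                                                (2.0, 0.0)])
    def test_partition_boundaries(self, sda_peak, used):
        p = scope_partition(2.0, 14.0, 12.0, sda_peak)
        assert p.scope_used_pct == pytest.approx(used)

    def test_peak_below_smr_flagged(self):
        assert scope_partition(2.0, 14.0, 12.0, 1.5).flagged

    @given(smr=st.floats(0.5, 10), aas=st.floats(0.5, 20),
           peak_frac=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_partition_identity(self, smr, aas, peak_frac):
        p = scope_partition(smr, smr + aas, aas, smr + peak_frac * aas)
        assert p.scope_used_pct + p.scope_remaining_pct == \
            pytest.approx(100.0, abs=1e-9)


class TestSimulatedSDARecovery:
    def _run(self, spike_rate):
        sda = SDAParams(peak_height=3.0, time_to_peak_h=10.0,
                        duration_h=26.0, fed_time_h=20.0)
        groups = [CohortGroup("g", RespSimConfig(
            sda_params=sda, trial_duration_h=62.0, noise_sd=0.01,
            sample_dt_s=2.0, activity_spike_rate=spike_rate,
            activity_spike_mag=3.0, seed=5), n=1)]
        res = analyze_cohort(simulate_cohort(groups, seed=5),
                             PipelineConfig())
        return res["sda"].iloc[0], sda

    def test_mask_reduces_handling_bias(self):
        """With a handling-spike-like early artifact, masking shortens
        the pool and can only shrink the integral."""
        masked = mask_handling_window([1.0, 4.0, 6.0], [9.0, 5.0, 4.0],
                                      mask_h=3.0)
        assert len(masked) == 2

    def test_integral_and_peak_recovered(self):
        row, truth = self._run(spike_rate=0.0)
        assert row["sda_mg_per_kg"] == pytest.approx(
            truth.true_integral_mg_per_kg(), rel=0.10)
        assert row["sda_peak"] == pytest.approx(2.5 + 3.0, rel=0.05)
        # hourly nodes plus baseline bias put the crossing within ~3 h
        assert row["sda_dur_h"] == pytest.approx(26.0, abs=3.0)

    def test_hourly_minimum_is_robust_to_spikes(self):
        """Activity spikes barely move the hourly-minimum SDA."""
        clean, truth = self._run(spike_rate=0.0)
        spiky, _ = self._run(spike_rate=1.0)
        assert spiky["sda_mg_per_kg"] == pytest.approx(
            clean["sda_mg_per_kg"], rel=0.08)
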