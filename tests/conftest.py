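import numpy as np
import pytest

from fishphys.simulate import (CardiacSimConfig, CohortGroup,
                               RespSimConfig, SDAParams, simulate_cohort,
                               simulate_respirometry_trial)


@pytest.fixture
def nf_config():
    """Noise-free overnight trial: no background, no spikes, no meal."""
    return RespSimConfig(smr_true=2.0, mmr_true=14.0, noise_sd=0.0,
                         background_start_frac=0.0,
                         background_end_frac=0.0,
                         activity_spike_rate=0.0,
                         trial_duration_h=19.0, seed=7)


@pytest.fixture
def nf_trial(nf_config):
    return simulate_respirometry_trial(nf_config)


@pytest.fixture(scope="session")
def small_cohort():
    """Two respirometry groups plus two cardiac groups, light noise."""
    groups = [
        CohortGroup("t27", RespSimConfig(
            trial_duration_h=64.0, sda_params=SDAParams(),
            noise_sd=0.02, sample_dt_s=2.0, seed=0), n=3,
            param_cv={"smr_true": 0.08}, mass_cv=0.3),
        CohortGroup("t33", RespSimConfig(
            smr_true=4.0, mmr_true=16.0, temp_c=33.0,
            trial_duration_h=64.0, noise_sd=0.02, sample_dt_s=2.0,
            sda_params=SDAParams(peak_height=5.0, time_to_peak_h=5.0,
                                 duration_h=26.0)), n=3, mass_cv=0.3),
        CohortGroup("c28", CardiacSimConfig(
            peak_bpm=350.0, t_peak_true=35.0, t_arr_true=36.0,
            fh_noise_sd=8.0), n=4),
        CohortGroup("c33", CardiacSimConfig(
            peak_bpm=415.0, t_peak_true=37.0, t_arr_true=38.0,
            fh_noise_sd=8.0), n=4),
    ]
    return simulate_cohort(groups, seed=11)


def brute_force_steepest_window(t, y, min_window_s=120.0, r2_gate=0.9):
    """Independent oracle: try every (start, end) sample pair with
    np.polyfit and pick the steepest decline passing the r2 gate,
    breaking ties to the earliest start then the shortest window."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    best = None
    for i in range(len(t)):
        for j in range(i + 2, len(t)):
            if t[j] - t[i] < min_window_s:
                continue
            tw = t[i:j + 1] / 60.0
            yw = y[i:j + 1]
            slope, _ = np.polyfit(tw, yw, 1)
            if np.std(yw) == 0:
                r2 = 0.0
            else:
                r2 = np.corrcoef(tw, yw)[0, 1] ** 2
            if r2 <= r2_gate:
                continue
            if best is None or slope < best[2] - 1e-12 * max(1, abs(slope)):
                best = (i, j, slope, r2)
    return best
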