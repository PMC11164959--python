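"""The simulator's traces must encode their own ground truth exactly."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import fishphys as fp
from fishphys.simulate import (CardiacSimConfig, CohortGroup,
                               RespSimConfig, SDAParams,
                               simulate_cardiac_assay, simulate_cohort,
                               simulate_respirometry_trial)


class TestRespirometryTrial:
    def test_first_window_slope_implies_mmr(self, nf_config, nf_trial):
        """Noise-free, background-free: the post-chase slope gives MMR
        and late-night slopes give SMR."""
        geom = fp.RespirometerGeometry(nf_config.chamber_volume_l,
                                       nf_config.fish_volume_l,
                                       nf_config.fish_mass_kg)
        series = fp.mo2_series(nf_trial.trace, geom)
        assert series["mo2_mg_kg_min"].iloc[0] == pytest.approx(14.0)
        assert series["mo2_mg_kg_min"].iloc[-1] == pytest.approx(2.0,
                                                                 rel=1e-6)

    def test_slope_implied_mo2_matches_held_truth(self, nf_config,
                                                  nf_trial):
        """Conservation: in noise-free mode every window's slope-implied
        MO2 equals the simulator's held instantaneous MO2 to 1e-9."""
        geom = fp.RespirometerGeometry(nf_config.chamber_volume_l,
                                       nf_config.fish_volume_l,
                                       nf_config.fish_mass_kg)
        series = fp.mo2_series(nf_trial.trace, geom)
        truth = nf_trial.truth.cycles
        np.testing.assert_allclose(series["mo2_mg_kg_min"].to_numpy(),
                                   truth["mo2_held"].to_numpy(),
                                   rtol=1e-9)

    def test_background_fraction_by_construction(self):
        cfg = RespSimConfig(background_start_frac=0.1,
                            background_end_frac=0.6, noise_sd=0.0,
                            activity_spike_rate=0.0)
        end = cfg.trial_duration_h * 3600.0
        assert cfg.background_slope(end) / cfg._smr_slope() == \
            pytest.approx(0.6)
        assert cfg.background_slope(0.0) / cfg._smr_slope() == \
            pytest.approx(0.1)

    def test_same_seed_identical_trace(self, nf_config):
        cfg = dataclasses.replace(nf_config, noise_sd=0.02,
                                  activity_spike_rate=0.5)
        a = simulate_respirometry_trial(cfg)
        b = simulate_respirometry_trial(cfg)
        pd.testing.assert_frame_equal(a.trace, b.trace)
        pd.testing.assert_frame_equal(a.blanks_pre, b.blanks_pre)

    def test_flush_restores_saturation(self, nf_trial, nf_config):
        flush = nf_trial.trace[nf_trial.trace["phase"] == "flush"]
        assert (flush["o2_mg_per_l"] == nf_config.o2_saturation).all()

    def test_postprandial_bump_peak_and_return(self):
        sda = SDAParams(peak_height=3.0, time_to_peak_h=10.0,
                        duration_h=25.0, fed_time_h=20.0)
        cfg = RespSimConfig(sda_params=sda, noise_sd=0.0,
                            activity_spike_rate=0.0,
                            background_start_frac=0.0,
                            background_end_frac=0.0,
                            trial_duration_h=64.0)
        assert sda.bump(10.0) == pytest.approx(3.0)
        assert sda.bump(25.0) == pytest.approx(0.0, abs=1e-12)
        assert sda.bump(30.0) == 0.0
        # fish MO2 at fed + peak time is SMR + bump (recovery done)
        t_peak_s = (20.0 + 10.0) * 3600.0
        assert cfg.mo2_continuous(t_peak_s) == pytest.approx(
            cfg.smr_true + 3.0, rel=1e-6)

    def test_bump_integral_closed_form_matches_quadrature(self):
        sda = SDAParams(peak_height=2.5, time_to_peak_h=13.0,
                        duration_h=28.0)
        tau = np.linspace(0, 28.0, 200001)
        numeric = np.trapezoid(sda.bump(tau), tau) * 60.0
        assert sda.true_integral_mg_per_kg() == pytest.approx(numeric,
                                                              rel=1e-6)

    @pytest.mark.parametrize("bad, msg", [
        (dict(smr_true=-1.0), "smr_true"),
        (dict(mmr_true=1.0), "mmr_true"),
        (dict(background_start_frac=1.5), "background_start_frac"),
        (dict(fish_volume_l=1.0), "fish_volume_l"),
        (dict(flush_s=0.0), "cycle durations"),
    ])
    def test_invalid_config_rejected(self, bad, msg):
        with pytest.raises(ValueError, match=msg):
            RespSimConfig(**bad)


class TestCardiacAssay:
    def test_noise_free_peak_at_t_peak(self):
        cfg = CardiacSimConfig(peak_bpm=400.0, t_peak_true=37.0,
                               t_arr_true=39.0, fh_noise_sd=0.0)
        assay, _ = simulate_cardiac_assay(cfg)
        rhythmic = assay[~assay["arrhythmia_flag"]]
        top = rhythmic.loc[rhythmic["fhmax_bpm"].idxmax()]
        assert top["step_temp_c"] == 37.0

    def test_first_flagged_step_at_t_arr(self):
        cfg = CardiacSimConfig(t_arr_true=38.0, start_temp=28.0,
                               step_size=1.0, fh_noise_sd=0.0)
        assay, _ = simulate_cardiac_assay(cfg)
        flagged = assay[assay["arrhythmia_flag"]]
        assert len(flagged) == 1
        assert flagged["step_temp_c"].iloc[0] == 38.0
        # collapse: at least 50% below the rhythmic running max
        assert flagged["fhmax_bpm"].iloc[0] <= \
            0.5 * assay["fhmax_bpm"].max()

    def test_noisy_seeds_differ_but_flag_near_truth(self):
        """Across 100 seeds the flagged step stays within one 1-degC
        step of the configured arrhythmia temperature."""
        temps = []
        for seed in range(100):
            cfg = CardiacSimConfig(t_arr_true=38.0, fh_noise_sd=10.0,
                                   seed=seed)
            assay, _ = simulate_cardiac_assay(cfg)
            temps.append(
                assay.loc[assay["arrhythmia_flag"], "step_temp_c"].iloc[0])
        assert np.all(np.abs(np.array(temps) - 38.0) <= 1.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="t_arr_true"):
            CardiacSimConfig(t_arr_true=30.0, t_peak_true=37.0)


class TestCohort:
    def test_counts_and_truth_echo(self):
        groups = [
            CohortGroup("a", RespSimConfig(trial_duration_h=2.0,
                                           noise_sd=0.0,
                                           activity_spike_rate=0.0), n=3),
            CohortGroup("b", RespSimConfig(trial_duration_h=2.0,
                                           noise_sd=0.0,
                                           activity_spike_rate=0.0), n=3),
        ]
        data = simulate_cohort(groups, seed=1)
        assert len(data.trials) == 6
        assert len(data.truth) == 6
        assert data.truth["fish_id"].is_unique

    def test_cardiac_cohort_assay_count(self):
        """Four cardiac groups of 7, 8, 10 and 10 fish give 35 assays."""
        groups = [CohortGroup(f"g{i}", CardiacSimConfig(fh_noise_sd=5.0),
                              n=n)
                  for i, n in enumerate([7, 8, 10, 10])]
        data = simulate_cohort(groups, seed=2)
        assert data.cardiac["fish_id"].nunique() == 35

    def test_duplicate_group_names_rejected(self):
        g = CohortGroup("a", CardiacSimConfig(), n=1)
        with pytest.raises(ValueError, match="collide"):
            simulate_cohort([g, g], seed=0)

    def test_same_seed_identical_files(self, tmp_path):
        groups = [CohortGroup("a", RespSimConfig(trial_duration_h=1.0),
                              n=1),
                  CohortGroup("c", CardiacSimConfig(fh_noise_sd=3.0),
                              n=2)]
        simulate_cohort(groups, seed=5, out_dir=tmp_path / "x")
        simulate_cohort(groups, seed=5, out_dir=tmp_path / "y")
        for rel in ["metadata.csv", "truth.csv", "cardiac.csv",
                    "traces/a_01.csv", "blanks/a_01_pre.csv"]:
            assert (tmp_path / "x" / rel).read_bytes() == \
                (tmp_path / "y" / rel).read_bytes(), rel
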