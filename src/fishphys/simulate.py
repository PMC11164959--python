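"""Synthetic respirometry trials and cardiac heating-ramp assays.

Everything downstream of this module (slope fitting, background
correction, SMR/MMR extraction, recovery curves, SDA integration,
cardiac thermal limits) is tested by parameter recovery against the
ground truth that these generators echo back.

The respirometry generator emulates an intermittent-flow trial: a fish
is chased to exhaustion and sealed in a chamber, so its instantaneous
oxygen uptake starts at MMR and decays biexponentially toward SMR;
optionally it is later gavage-fed, producing a postprandial bump that
rises to a peak and relaxes back across ~a day.  Chamber oxygen
concentration falls linearly within each sealed measurement phase and
is restored to air saturation by each flush.  Microbial background
respiration grows as a first-order exponential across the trial, from
a small fraction of the fish-driven signal to a large one.

Ground-truth convention: the fish's oxygen uptake is sampled at the
start of each measurement window and held constant across it, so in
noise-free mode the concentration slope of a window implies the held
MO2 exactly.  The held value (with and without activity-spike
contamination) is echoed per cycle in :class:`TrialTruth`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SDAParams",
    "RespSimConfig",
    "CardiacSimConfig",
    "TrialTruth",
    "RespTrial",
    "CohortGroup",
    "CohortData",
    "simulate_respirometry_trial",
    "simulate_cardiac_assay",
    "simulate_beats",
    "simulate_cohort",
]

# mg O2 per liter at air saturation, ~28 degC seawater
DEFAULT_O2_SATURATION = 6.8


@dataclass(frozen=True)
class SDAParams:
    """Postprandial metabolic bump above SMR.

    The bump rises linearly from zero (at feeding) to ``peak_height``
    at ``time_to_peak_h``, then relaxes exponentially toward a slight
    undershoot chosen so the curve first crosses SMR exactly at
    ``duration_h``; it is clamped at SMR afterwards.  This keeps peak,
    duration and integral analytically known.
    """

    peak_height: float = 2.5          # mg O2 kg-1 min-1 above SMR
    time_to_peak_h: float = 13.0
    duration_h: float = 28.0
    fed_time_h: float = 20.0          # hours after the chase
    undershoot_frac: float = 0.05     # asymptote below SMR, as frac of peak
    meal_percent_bm: float = 2.0      # ration size, % of body mass

    def _decay_constants(self) -> tuple[float, float]:
        a_inf = -self.undershoot_frac * self.peak_height
        lam = math.log((self.peak_height - a_inf) / (-a_inf)) / (
            self.duration_h - self.time_to_peak_h
        )
        return a_inf, lam

    def bump(self, tau_h):
        """Excess MO2 (mg O2 kg-1 min-1) at ``tau_h`` hours post-feeding."""
        tau = np.asarray(tau_h, dtype=float)
        a_inf, lam = self._decay_constants()
        rise = self.peak_height * tau / self.time_to_peak_h
        decay = (self.peak_height - a_inf) * np.exp(
            -lam * (tau - self.time_to_peak_h)
        ) + a_inf
        out = np.where(tau < self.time_to_peak_h, rise, decay)
        out = np.where((tau < 0) | (out < 0), 0.0, out)
        return out if out.ndim else float(out)

    def true_integral_mg_per_kg(self) -> float:
        """Closed-form area of the bump above SMR, in mg O2 kg-1.

        Integral of a per-minute rate over minutes, i.e. the SDA an
        ideal analysis would recover from a densely sampled trial.
        """
        a_inf, lam = self._decay_constants()
        rise = 0.5 * self.peak_height * self.time_to_peak_h
        span = self.duration_h - self.time_to_peak_h
        decay = (self.peak_height - a_inf) * (1 - math.exp(-lam * span)) / lam
        decay += a_inf * span
        return (rise + decay) * 60.0


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class RespSimConfig:
    """Parameters of one simulated intermittent-flow respirometry trial.

    Rates are mass-specific (mg O2 kg-1 min-1); volumes in liters,
    mass in kg, schedule durations in seconds.  Background fractions
    express the blank-chamber concentration slope as a fraction of the
    SMR-driven slope at trial start and end.
    """

    smr_true: float = 2.5
    mmr_true: float = 14.0
    recovery_halflives: tuple[float, float] = (6.0, 45.0)   # min, fast/slow
    fast_fraction: float = 0.6
    sda_params: Optional[SDAParams] = None
    background_start_frac: float = 0.1
    background_end_frac: float = 0.6
    noise_sd: float = 0.01            # mg O2 l-1 on concentration samples
    activity_spike_rate: float = 0.5  # spikes per hour
    activity_spike_mag: float = 2.0   # mg O2 kg-1 min-1
    activity_spike_duration_min: float = 5.0
    flush_s: float = 300.0
    measure_s: float = 600.0
    mmr_measure_s: float = 360.0      # post-chase measurement phase
    chamber_volume_l: float = 0.566
    fish_mass_kg: float = 0.005
    fish_volume_l: float = 0.005      # 1 kg assumed to displace 1 l
    trial_duration_h: float = 20.0
    o2_saturation: float = DEFAULT_O2_SATURATION
    sample_dt_s: float = 1.0
    temp_c: float = 27.0
    chamber_id: str = "ch01"
    seed: int = 0

    def __post_init__(self):
        _require(self.smr_true > 0, "smr_true must be > 0")
        _require(self.mmr_true > self.smr_true, "mmr_true must exceed smr_true")
        _require(all(h > 0 for h in self.recovery_halflives),
                 "recovery_halflives must be > 0")
        _require(0 < self.fast_fraction < 1, "fast_fraction must be in (0, 1)")
        _require(0 <= self.background_start_frac < 1,
                 "background_start_frac must be in [0, 1)")
        _require(0 <= self.background_end_frac < 1,
                 "background_end_frac must be in [0, 1)")
        _require(self.flush_s > 0 and self.measure_s > 0,
                 "cycle durations must be > 0")
        _require(self.mmr_measure_s > 0, "mmr_measure_s must be > 0")
        _require(self.trial_duration_h > 0, "trial_duration_h must be > 0")
        _require(self.fish_volume_l < self.chamber_volume_l,
                 "fish_volume_l must be smaller than chamber_volume_l")
        _require(self.fish_mass_kg > 0, "fish_mass_kg must be > 0")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        if self.sda_params is not None:
            sda = self.sda_params
            _require(sda.duration_h > sda.time_to_peak_h > 0,
                     "sda duration_h must exceed time_to_peak_h > 0")
            _require(sda.peak_height > 0, "sda peak_height must be > 0")

    # -- analytic truth -------------------------------------------------

    @property
    def net_volume_l(self) -> float:
        return self.chamber_volume_l - self.fish_volume_l

    def _smr_slope(self) -> float:
        """Concentration slope (mg l-1 min-1) a fish at SMR would drive."""
        return self.smr_true * self.fish_mass_kg / self.net_volume_l

    def background_slope(self, t_s):
        """Blank-chamber slope magnitude (mg l-1 min-1) at trial time t."""
        b0 = self.background_start_frac * self._smr_slope()
        b1 = self.background_end_frac * self._smr_slope()
        span = self.trial_duration_h * 3600.0
        t = np.asarray(t_s, dtype=float)
        if b0 <= 0 and b1 <= 0:
            out = np.zeros_like(t)
        elif b0 <= 0:
            out = b1 * t / span
        else:
            k = math.log(b1 / b0) / span
            out = b0 * np.exp(k * t)
        return out if out.ndim else float(out)

    def mo2_continuous(self, t_s):
        """Fish-only MO2 (mg O2 kg-1 min-1) at trial time t (seconds)."""
        t_min = np.asarray(t_s, dtype=float) / 60.0
        aas = self.mmr_true - self.smr_true
        k_fast = math.log(2) / self.recovery_halflives[0]
        k_slow = math.log(2) / self.recovery_halflives[1]
        w = self.fast_fraction
        val = self.smr_true + aas * (
            w * np.exp(-k_fast * t_min) + (1 - w) * np.exp(-k_slow * t_min)
        )
        if self.sda_params is not None:
            tau_h = (np.asarray(t_s, dtype=float)
                     - self.sda_params.fed_time_h * 3600.0) / 3600.0
            val = val + self.sda_params.bump(np.maximum(tau_h, 0.0)) * (tau_h > 0)
        return val if val.ndim else float(val)


@dataclass(frozen=True)
class CardiacSimConfig:
    """Parameters of one simulated cardiac heating-ramp assay.

    Maximum heart rate follows a Gaussian-bump thermal performance
    curve peaking at ``t_peak_true``; at the first ramp step at or
    above ``t_arr_true`` the heart goes arrhythmic: the step is
    flagged and the rate collapses to ``collapse_frac`` of the running
    maximum, ending the ramp.
    """

    peak_bpm: float = 415.0
    t_peak_true: float = 37.0
    tpc_width: float = 8.0          # degC, Gaussian sigma of the curve
    t_arr_true: float = 38.0
    start_temp: float = 28.0
    step_size: float = 1.0
    step_duration_min: float = 6.0
    fh_noise_sd: float = 0.0        # bpm
    collapse_frac: float = 0.4
    seed: int = 0

    def __post_init__(self):
        _require(self.t_peak_true > self.start_temp,
                 "t_peak_true must exceed start_temp")
        _require(self.t_arr_true > self.t_peak_true,
                 "t_arr_true must exceed t_peak_true")
        _require(self.step_size > 0, "step_size must be > 0")
        _require(self.peak_bpm > 0, "peak_bpm must be > 0")
        _require(0 < self.collapse_frac < 0.5,
                 "collapse_frac must be in (0, 0.5) to register a collapse")

    def fhmax_curve(self, temp_c):
        """Noise-free f_Hmax (bpm) on the rhythmic portion of the ramp."""
        t = np.asarray(temp_c, dtype=float)
        out = self.peak_bpm * np.exp(-((t - self.t_peak_true) ** 2)
                                     / (2 * self.tpc_width ** 2))
        return out if out.ndim else float(out)


@dataclass
class TrialTruth:
    """Generating parameters echoed back beside the simulated data."""

    fish_id: str
    params: dict
    cycles: Optional[pd.DataFrame] = None  # per-cycle held MO2 etc.


@dataclass
class RespTrial:
    """One simulated respirometry trial: fish trace, blank cycles, truth."""

    trace: pd.DataFrame
    blanks_pre: pd.DataFrame
    blanks_post: pd.DataFrame
    truth: TrialTruth


TRACE_COLUMNS = ["time_s", "o2_mg_per_l", "temp_c", "phase",
                 "cycle_index", "chamber_id"]


def _measure_windows(config: RespSimConfig) -> list[tuple[int, float, float]]:
    """(cycle_index, start_s, end_s) of every measurement window."""
    end = config.trial_duration_h * 3600.0
    windows = [(0, 0.0, min(config.mmr_measure_s, end))]
    t = config.mmr_measure_s
    idx = 1
    while t + config.flush_s < end:
        start = t + config.flush_s
        stop = min(start + config.measure_s, end)
        if stop - start >= 3 * config.sample_dt_s:
            windows.append((idx, start, stop))
        t = start + config.measure_s
        idx += 1
    return windows


def simulate_respirometry_trial(config: RespSimConfig,
                                fish_id: str = "fish01") -> RespTrial:
    """Generate one intermittent-flow trial with known ground truth.

    Deterministic for a fixed config (the seed lives in the config).
    """
    rng = np.random.default_rng(config.seed)
    end_s = config.trial_duration_h * 3600.0
    dt = config.sample_dt_s
    windows = _measure_windows(config)

    # Poisson-timed activity spikes (drawn before noise so that the
    # noise stream is unchanged when spikes are disabled).
    n_spikes = 0
    spike_times = np.empty(0)
    if config.activity_spike_rate > 0:
        n_spikes = rng.poisson(config.activity_spike_rate
                               * config.trial_duration_h)
        spike_times = np.sort(rng.uniform(0.0, end_s, size=n_spikes))
    spike_dur_s = config.activity_spike_duration_min * 60.0

    def spike_excess(t: float) -> float:
        if n_spikes == 0:
            return 0.0
        active = (spike_times <= t) & (t < spike_times + spike_dur_s)
        return config.activity_spike_mag * int(active.sum())

    times = np.arange(0.0, end_s + dt / 2, dt)
    o2 = np.full_like(times, config.o2_saturation)
    phase = np.full(times.shape, "flush", dtype=object)
    cycle = np.full(times.shape, -1, dtype=int)

    truth_rows = []
    for idx, start, stop in windows:
        mask = (times >= start) & (times < stop)
        if idx == 0:
            mask = (times >= start) & (times <= stop)
        # midpoint of the *sampled* window, matching what a slope fit
        # over these samples will report
        t_w = times[mask]
        t_mid = 0.5 * (t_w[0] + t_w[-1])
        mo2_base = config.mo2_continuous(start)
        excess = spike_excess(start)
        mo2_held = mo2_base + excess
        fish_slope = mo2_held * config.fish_mass_kg / config.net_volume_l
        bg = config.background_slope(t_mid)
        total = fish_slope + bg
        o2[mask] = config.o2_saturation - total * (times[mask] - start) / 60.0
        phase[mask] = "measure"
        cycle[mask] = idx
        truth_rows.append({
            "cycle_index": idx, "t_start_s": start, "t_end_s": stop,
            "t_mid_s": t_mid, "mo2_base": mo2_base, "spike_excess": excess,
            "mo2_held": mo2_held, "bg_slope_mid": bg, "total_slope": total,
        })

    if config.noise_sd > 0:
        o2 = o2 + rng.normal(0.0, config.noise_sd, size=o2.shape)
    o2 = np.maximum(o2, 0.0)

    trace = pd.DataFrame({
        "time_s": times, "o2_mg_per_l": o2,
        "temp_c": config.temp_c, "phase": phase,
        "cycle_index": cycle, "chamber_id": config.chamber_id,
    })

    blanks_pre = _blank_trace(config, rng, at_t_s=0.0, t_offset_s=0.0)
    blanks_post = _blank_trace(config, rng, at_t_s=end_s, t_offset_s=end_s)

    params = {
        "fish_id": fish_id,
        "smr_true": config.smr_true,
        "mmr_true": config.mmr_true,
        "mass_kg": config.fish_mass_kg,
        "chamber_volume_l": config.chamber_volume_l,
        "bg_start_frac": config.background_start_frac,
        "bg_end_frac": config.background_end_frac,
    }
    if config.sda_params is not None:
        sda = config.sda_params
        params.update({
            "sda_peak_height": sda.peak_height,
            "sda_time_to_peak_h": sda.time_to_peak_h,
            "sda_duration_h": sda.duration_h,
            "sda_fed_time_h": sda.fed_time_h,
            "sda_integral_true": sda.true_integral_mg_per_kg(),
        })
    truth = TrialTruth(fish_id=fish_id, params=params,
                       cycles=pd.DataFrame(truth_rows))
    return RespTrial(trace=trace, blanks_pre=blanks_pre,
                     blanks_post=blanks_post, truth=truth)


def _blank_trace(config: RespSimConfig, rng: np.random.Generator,
                 at_t_s: float, t_offset_s: float,
                 n_cycles: int = 3) -> pd.DataFrame:
    """Blank-chamber cycles whose slope is the background at ``at_t_s``.

    Blanks bracket the trial, so all pre (post) cycles carry the
    background magnitude at trial start (end) on the trial clock.
    """
    dt = config.sample_dt_s
    bg = config.background_slope(at_t_s)
    rows_t, rows_o2, rows_phase, rows_cycle = [], [], [], []
    t0 = t_offset_s
    for i in range(n_cycles):
        start = t0 + i * (config.flush_s + config.measure_s)
        flush_t = np.arange(start, start + config.flush_s, dt)
        meas_t = np.arange(start + config.flush_s,
                           start + config.flush_s + config.measure_s, dt)
        rows_t.append(flush_t)
        rows_o2.append(np.full_like(flush_t, config.o2_saturation))
        rows_phase.extend(["flush"] * len(flush_t))
        rows_cycle.extend([i] * len(flush_t))
        rows_t.append(meas_t)
        rows_o2.append(config.o2_saturation
                       - bg * (meas_t - meas_t[0]) / 60.0)
        rows_phase.extend(["measure"] * len(meas_t))
        rows_cycle.extend([i] * len(meas_t))
    t = np.concatenate(rows_t)
    o2 = np.concatenate(rows_o2)
    if config.noise_sd > 0:
        o2 = o2 + rng.normal(0.0, config.noise_sd, size=o2.shape)
    return pd.DataFrame({
        "time_s": t, "o2_mg_per_l": np.maximum(o2, 0.0),
        "temp_c": config.temp_c, "phase": rows_phase,
        "cycle_index": rows_cycle, "chamber_id": config.chamber_id,
    })


def simulate_cardiac_assay(config: CardiacSimConfig,
                           fish_id: str = "fish01"
                           ) -> tuple[pd.DataFrame, TrialTruth]:
    """Generate one heating-ramp assay (per-degC-step f_Hmax table)."""
    rng = np.random.default_rng(config.seed)
    temps, fh, flags = [], [], []
    t = config.start_temp
    running_max = 0.0
    while True:
        if t >= config.t_arr_true - 1e-12:
            collapsed = config.collapse_frac * max(running_max, 1.0)
            if config.fh_noise_sd > 0:
                collapsed += rng.normal(0.0, config.fh_noise_sd)
            temps.append(t)
            fh.append(max(collapsed, 1.0))
            flags.append(True)
            break
        val = config.fhmax_curve(t)
        if config.fh_noise_sd > 0:
            val += rng.normal(0.0, config.fh_noise_sd)
        val = max(val, 1.0)
        running_max = max(running_max, val)
        temps.append(t)
        fh.append(val)
        flags.append(False)
        t += config.step_size
    assay = pd.DataFrame({
        "fish_id": fish_id, "step_temp_c": temps,
        "fhmax_bpm": fh, "arrhythmia_flag": flags,
    })
    truth = TrialTruth(fish_id=fish_id, params={
        "fish_id": fish_id,
        "peak_bpm": config.peak_bpm,
        "t_peak_true": config.t_peak_true,
        "t_arr_true": config.t_arr_true,
    })
    return assay, truth


def simulate_beats(rate_bpm: float, duration_s: float = 15.0,
                   jitter_cv: float = 0.05,
                   rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Beat timestamps (s) at a mean rate with gamma-jittered intervals."""
    if rng is None:
        rng = np.random.default_rng(0)
    mean_ibi = 60.0 / rate_bpm
    n = int(duration_s / mean_ibi) + 2
    if jitter_cv > 0:
        shape = 1.0 / jitter_cv ** 2
        ibis = rng.gamma(shape, mean_ibi / shape, size=n)
    else:
        ibis = np.full(n, mean_ibi)
    beats = np.concatenate([[0.0], np.cumsum(ibis)])
    return beats[beats <= duration_s]


# -- cohorts ------------------------------------------------------------


@dataclass(frozen=True)
class CohortGroup:
    """One acclimation group within a simulated cohort.

    ``param_cv`` maps config field names (e.g. ``smr_true``) to a
    lognormal coefficient of variation for among-fish spread.
    ``mass_cv`` spreads body mass, and ``scaling_b`` sets the
    whole-animal allometric exponent used to tie mass-specific rates
    to mass (1.0 = isometric).
    """

    name: str
    config: RespSimConfig | CardiacSimConfig
    n: int
    param_cv: dict = field(default_factory=dict)
    mass_cv: float = 0.0
    scaling_b: float = 1.0

    def __post_init__(self):
        _require(self.n >= 1, "group size n must be >= 1")


@dataclass
class CohortData:
    """In-memory simulated cohort; mirrors the on-disk layout."""

    metadata: pd.DataFrame
    trials: dict            # fish_id -> RespTrial
    cardiac: pd.DataFrame   # possibly empty
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        (out / "traces").mkdir(parents=True, exist_ok=True)
        (out / "blanks").mkdir(exist_ok=True)
        self.metadata.to_csv(out / "metadata.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        for fish_id, trial in self.trials.items():
            trial.trace.to_csv(out / "traces" / f"{fish_id}.csv", index=False)
            trial.blanks_pre.to_csv(out / "blanks" / f"{fish_id}_pre.csv",
                                    index=False)
            trial.blanks_post.to_csv(out / "blanks" / f"{fish_id}_post.csv",
                                     index=False)
        if len(self.cardiac):
            self.cardiac.to_csv(out / "cardiac.csv", index=False)
        return out


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv ** 2))
    return float(rng.lognormal(-0.5 * sigma ** 2, sigma))


def simulate_cohort(groups: list[CohortGroup], seed: int,
                    out_dir: str | Path | None = None) -> CohortData:
    """Simulate a multi-group cohort; optionally write it to disk.

    Fish ids are ``<group>_<i>``; duplicate group names are rejected
    to keep ids collision-free.  Deterministic in (groups, seed).
    """
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise ValueError("duplicate group names would collide fish ids")
    root = np.random.default_rng(seed)
    meta_rows, truth_rows = [], []
    trials: dict[str, RespTrial] = {}
    cardiac_frames = []
    for group in groups:
        for i in range(group.n):
            fish_id = f"{group.name}_{i + 1:02d}"
            fish_seed = int(root.integers(0, 2 ** 31 - 1))
            rng = np.random.default_rng(fish_seed)
            if isinstance(group.config, CardiacSimConfig):
                cfg = replace(group.config, seed=fish_seed)
                for fld, cv in group.param_cv.items():
                    cfg = replace(cfg, **{
                        fld: getattr(cfg, fld) * _lognormal_factor(rng, cv)})
                assay, truth = simulate_cardiac_assay(cfg, fish_id=fish_id)
                assay = assay.assign(group=group.name)
                cardiac_frames.append(assay)
                meta_rows.append({
                    "fish_id": fish_id, "chamber_id": "",
                    "mass_kg": np.nan, "chamber_volume_l": np.nan,
                    "group": group.name, "meal_percent_bm": np.nan,
                    "fed_time_s": np.nan, "kind": "cardiac",
                })
                truth_rows.append(truth.params | {"group": group.name})
            else:
                mass = group.config.fish_mass_kg * _lognormal_factor(
                    rng, group.mass_cv)
                # whole-animal rate ~ m^b  =>  mass-specific ~ m^(b-1)
                rate_fac = (mass / group.config.fish_mass_kg) ** (
                    group.scaling_b - 1.0)
                cfg = replace(
                    group.config, seed=fish_seed, fish_mass_kg=mass,
                    fish_volume_l=mass * 1.0,  # 1 kg displaces 1 l
                    smr_true=group.config.smr_true * rate_fac,
                    mmr_true=group.config.mmr_true * rate_fac,
                    chamber_id=f"ch_{fish_id}",
                )
                for fld, cv in group.param_cv.items():
                    cfg = replace(cfg, **{
                        fld: getattr(cfg, fld) * _lognormal_factor(rng, cv)})
                trial = simulate_respirometry_trial(cfg, fish_id=fish_id)
                trials[fish_id] = trial
                fed = (np.nan if cfg.sda_params is None
                       else cfg.sda_params.fed_time_h * 3600.0)
                meal = (np.nan if cfg.sda_params is None
                        else cfg.sda_params.meal_percent_bm)
                meta_rows.append({
                    "fish_id": fish_id, "chamber_id": cfg.chamber_id,
                    "mass_kg": cfg.fish_mass_kg,
                    "chamber_volume_l": cfg.chamber_volume_l,
                    "group": group.name, "meal_percent_bm": meal,
                    "fed_time_s": fed, "kind": "resp",
                })
                truth_rows.append(trial.truth.params | {"group": group.name})
    cardiac = (pd.concat(cardiac_frames, ignore_index=True)
               if cardiac_frames else pd.DataFrame(
                   columns=["fish_id", "step_temp_c", "fhmax_bpm",
                            "arrhythmia_flag", "group"]))
    data = CohortData(metadata=pd.DataFrame(meta_rows), trials=trials,
                      cardiac=cardiac, truth=pd.DataFrame(truth_rows))
    if out_dir is not None:
        data.write(out_dir)
    return data
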