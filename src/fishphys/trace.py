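"""Raw oxygen traces to background-corrected, mass-aware MO2.

The central relation is the intermittent-flow respirometry equation

    MO2 = |dO2/dt| * (v_R - v_F) / m

with the concentration slope (mg O2 l-1 min-1) taken from an ordinary
least-squares fit over one sealed measurement window, corrected for
microbial background respiration modeled as a first-order exponential
between the mean pre-trial and post-trial blank-chamber slopes.

Whole-animal rates may scale allometrically with body mass; candidate
exponents (free, isometric 1.0, universal 0.89) are compared by BIC
and a chosen exponent standardizes rates to a common body mass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CycleSchedule",
    "RespirometerGeometry",
    "SlopeFit",
    "BackgroundModel",
    "MO2Sample",
    "ScalingDecision",
    "segment_cycles",
    "fit_slope",
    "fit_background",
    "compute_mo2",
    "mo2_series",
    "select_scaling_model",
    "scale_to_common_mass",
]


@dataclass(frozen=True)
class CycleSchedule:
    """Flush/measure cycle timing used to derive windows when phase
    labels are absent.  ``start_s`` is when the first flush begins."""

    flush_s: float
    measure_s: float
    start_s: float = 0.0
    flush_first: bool = True

    def __post_init__(self):
        if self.flush_s <= 0 or self.measure_s <= 0:
            raise ValueError("flush_s and measure_s must be > 0")


@dataclass(frozen=True)
class RespirometerGeometry:
    """Chamber volume, fish volume (1 kg assumed = 1 l) and mass."""

    v_r_l: float
    v_f_l: float
    mass_kg: float

    def __post_init__(self):
        if not (self.v_r_l > self.v_f_l > 0):
            raise ValueError("require v_r_l > v_f_l > 0")
        if self.mass_kg <= 0:
            raise ValueError("mass_kg must be > 0")

    @property
    def net_volume_l(self) -> float:
        return self.v_r_l - self.v_f_l


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of concentration on time over one window.

    Slope is signed (declines negative), in mg O2 l-1 min-1; r2 is the
    squared Pearson correlation, defined as 0 for a flat response.
    """

    slope: float
    intercept: float
    r2: float
    window_start_s: float
    window_end_s: float
    n_points: int

    @property
    def t_mid_s(self) -> float:
        return 0.5 * (self.window_start_s + self.window_end_s)


@dataclass(frozen=True)
class BackgroundModel:
    """Blank-chamber slope magnitude as a function of trial time.

    ``exp`` mode: B(t) = b0 * exp(k t), anchored at the mean initial
    and end blank magnitudes.  ``linear`` is the fallback when the
    initial blank is nonpositive but the end blank is not; ``zero``
    when both are.
    """

    b0: float
    k: float
    t_ref_s: float
    mode: str = "exp"
    b_end: float = 0.0

    def evaluate(self, t_s):
        t = np.asarray(t_s, dtype=float)
        if self.mode == "zero":
            out = np.zeros_like(t)
        elif self.mode == "linear":
            out = self.b_end * np.clip(t / self.t_ref_s, 0.0, None)
        else:
            out = self.b0 * np.exp(self.k * t)
        return out if out.ndim else float(out)

    @classmethod
    def zero(cls) -> "BackgroundModel":
        return cls(b0=0.0, k=0.0, t_ref_s=1.0, mode="zero")


@dataclass(frozen=True)
class MO2Sample:
    """One background-corrected, mass-specific MO2 measurement."""

    t_mid_s: float
    mo2: float                      # mg O2 kg-1 min-1
    r2: float
    cycle_index: int = -1
    context: Optional[str] = None   # exercise-recovery | postprandial
    flagged: bool = False           # correction drove the slope negative

    @property
    def valid_09(self) -> bool:
        return self.r2 > 0.9 and not self.flagged

    @property
    def valid_095(self) -> bool:
        return self.r2 > 0.95 and not self.flagged


@dataclass(frozen=True)
class ScalingDecision:
    """Allometric-exponent model choice for one trait (SMR or MMR)."""

    trait: str
    chosen_b: float
    chosen_model: str
    candidate_bics: dict = field(default_factory=dict)
    free_b: float = float("nan")
    equivalent: tuple = ()          # models within delta-BIC 7 of best
    common_mass_kg: float = 0.005


def segment_cycles(trace: pd.DataFrame,
                   schedule: Optional[CycleSchedule] = None
                   ) -> list[pd.DataFrame]:
    """Split a trace into its measurement windows.

    Uses the ``phase``/``cycle_index`` labels when present; otherwise
    derives windows from ``schedule``.  Returns one DataFrame per
    window, ordered and disjoint; flush samples are dropped.
    """
    trace = trace.sort_values("time_s")
    t = trace["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("trace times must be strictly increasing")
    if "phase" in trace.columns and trace["phase"].notna().all():
        meas = trace[trace["phase"] == "measure"]
        if meas.empty:
            return []
        out = [g.reset_index(drop=True)
               for _, g in meas.groupby("cycle_index", sort=True)]
        return out
    if schedule is None:
        raise ValueError("phase labels absent and no schedule provided")
    period = schedule.flush_s + schedule.measure_s
    rel = t - schedule.start_s
    if schedule.flush_first:
        offset = schedule.flush_s
    else:
        offset = 0.0
    cyc = np.floor(rel / period).astype(int)
    within = rel - cyc * period
    in_measure = (rel >= 0) & (within >= offset) & (
        within < offset + schedule.measure_s)
    labeled = trace.loc[in_measure].copy()
    labeled["cycle_index"] = cyc[in_measure]
    return [g.reset_index(drop=True)
            for _, g in labeled.groupby("cycle_index", sort=True)]


def fit_slope(time_s: Sequence[float], o2: Sequence[float]) -> SlopeFit:
    """OLS of concentration on time (converted to minutes) in one window."""
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(o2, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 samples to fit a slope")
    if np.ptp(t) == 0:
        raise ValueError("zero time variance in window")
    t_min = t / 60.0
    tc = t_min - t_min.mean()
    yc = y - y.mean()
    sxx = float(tc @ tc)
    sxy = float(tc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * t_min.mean())
    # r2 as squared Pearson correlation; a flat trace carries no rate
    # information, so its r2 is defined as 0.
    r2 = 0.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return SlopeFit(slope=slope, intercept=intercept, r2=float(r2),
                    window_start_s=float(t[0]), window_end_s=float(t[-1]),
                    n_points=len(t))


def _mean_magnitude(fits: Sequence[SlopeFit]) -> float:
    # a (nonphysical) positive blank slope is clamped to zero magnitude
    mags = [max(-f.slope, 0.0) for f in fits]
    return float(np.mean(mags)) if mags else 0.0


def fit_background(pre_blanks: Sequence[SlopeFit],
                   post_blanks: Sequence[SlopeFit],
                   trial_span_s: float) -> BackgroundModel:
    """First-order exponential between mean initial and end blank slopes.

    B(0) equals the mean pre-trial blank magnitude and B(trial_span)
    the mean post-trial magnitude.  Falls back to linear growth from
    zero when the initial mean is nonpositive, and to a zero model
    when both are.
    """
    if len(pre_blanks) < 3 or len(post_blanks) < 3:
        raise ValueError("need >= 3 blank cycles before and after the trial")
    if trial_span_s <= 0:
        raise ValueError("trial_span_s must be > 0")
    b0 = _mean_magnitude(pre_blanks)
    b1 = _mean_magnitude(post_blanks)
    if b0 <= 0 and b1 <= 0:
        return BackgroundModel.zero()
    if b0 <= 0:
        warnings.warn("initial blank slope nonpositive; using linear "
                      "background growth from zero", stacklevel=2)
        return BackgroundModel(b0=0.0, k=0.0, t_ref_s=trial_span_s,
                               mode="linear", b_end=b1)
    if b1 <= 0:
        warnings.warn("end blank slope nonpositive; clamping to the "
                      "initial magnitude (constant background)",
                      stacklevel=2)
        b1 = b0
    k = math.log(b1 / b0) / trial_span_s
    return BackgroundModel(b0=b0, k=k, t_ref_s=trial_span_s, b_end=b1)


def compute_mo2(fit: SlopeFit, geom: RespirometerGeometry,
                bg: Optional[BackgroundModel] = None,
                cycle_index: int = -1,
                context: Optional[str] = None) -> MO2Sample:
    """Background-correct one slope and convert it to mass-specific MO2."""
    if bg is None:
        bg = BackgroundModel.zero()
    if fit.slope > 0:
        warnings.warn("positive O2 slope treated as zero uptake",
                      stacklevel=2)
    corrected = max(-fit.slope, 0.0) - bg.evaluate(fit.t_mid_s)
    flagged = corrected < 0
    mo2 = max(corrected, 0.0) * geom.net_volume_l / geom.mass_kg
    return MO2Sample(t_mid_s=fit.t_mid_s, mo2=mo2, r2=fit.r2,
                     cycle_index=cycle_index, context=context,
                     flagged=flagged)


def mo2_series(trace: pd.DataFrame, geom: RespirometerGeometry,
               bg: Optional[BackgroundModel] = None,
               schedule: Optional[CycleSchedule] = None) -> pd.DataFrame:
    """Per-cycle MO2 table for one fish (one row per measurement window)."""
    rows = []
    for win in segment_cycles(trace, schedule=schedule):
        fit = fit_slope(win["time_s"], win["o2_mg_per_l"])
        idx = int(win["cycle_index"].iloc[0]) if "cycle_index" in win else -1
        s = compute_mo2(fit, geom, bg, cycle_index=idx)
        rows.append({
            "cycle_index": s.cycle_index, "t_mid_s": s.t_mid_s,
            "mo2_mg_kg_min": s.mo2, "r2": s.r2, "slope": fit.slope,
            "flagged": s.flagged, "valid_09": s.valid_09,
            "valid_095": s.valid_095,
        })
    return pd.DataFrame(rows)


_CANDIDATES = {"free": None, "isometric": 1.0, "universal": 0.89}


def select_scaling_model(masses_kg: Sequence[float],
                         trait_values: Sequence[float],
                         trait: str = "MMR",
                         candidates: Optional[dict] = None,
                         common_mass_kg: float = 0.005,
                         delta_bic: float = 7.0) -> ScalingDecision:
    """Compare allometric-exponent models for one trait by BIC.

    ``trait_values`` are mass-specific rates (mg O2 kg-1 min-1); the
    regression is log10(whole-animal rate) on log10(mass), with the
    slope either free or fixed at a candidate exponent.  Models within
    ``delta_bic`` of the best are reported as equivalent.
    """
    m = np.asarray(masses_kg, dtype=float)
    y = np.asarray(trait_values, dtype=float)
    if len(m) < 4:
        raise ValueError("need >= 4 fish for scaling model selection")
    if np.any(m <= 0) or np.any(y <= 0):
        raise ValueError("masses and trait values must be positive")
    if np.ptp(m) == 0:
        raise ValueError("all fish have identical mass; exponent "
                         "unidentifiable")
    if candidates is None:
        candidates = _CANDIDATES
    logm = np.log10(m)
    logw = np.log10(y * m)          # whole-animal rate
    n = len(m)
    bics: dict[str, float] = {}
    free_b = float("nan")
    chosen_exponents: dict[str, float] = {}
    for name, b in candidates.items():
        if b is None:
            x = logm - logm.mean()
            slope = float(x @ (logw - logw.mean()) / (x @ x))
            resid = logw - (logw.mean() + slope * x)
            p = 2
            free_b = slope
            chosen_exponents[name] = slope
        else:
            resid = logw - b * logm
            resid = resid - resid.mean()
            p = 1
            chosen_exponents[name] = float(b)
        rss = float(resid @ resid)
        rss = max(rss, 1e-300)
        bics[name] = n * math.log(rss / n) + p * math.log(n)
    best = min(bics, key=bics.get)
    equivalent = tuple(sorted(
        k for k in bics if bics[k] - bics[best] < delta_bic))
    return ScalingDecision(trait=trait, chosen_b=chosen_exponents[best],
                           chosen_model=best, candidate_bics=bics,
                           free_b=free_b, equivalent=equivalent,
                           common_mass_kg=common_mass_kg)


def scale_to_common_mass(mo2: float, mass_kg: float, b: float,
                         common_mass_kg: float = 0.005) -> float:
    """Standardize a mass-specific rate to a common body mass.

    mo2_common = mo2 * (m / m_common)^(1 - b); the identity when
    b = 1 (isometry) or when the fish is already at the common mass.
    """
    if mass_kg <= 0 or common_mass_kg <= 0:
        raise ValueError("masses must be positive")
    return mo2 * (mass_kg / common_mass_kg) ** (1.0 - b)
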