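"""Cardiac upper thermal limits from heating-ramp heart-rate data.

During an acute ramp (1 degC every 6 min under pharmacological
blockade/stimulation), maximum heart rate f_Hmax rises to a peak
(T_PEAK) then falls until the heartbeat turns arrhythmic (T_ARR).
Per-fish metrics are the peak f_Hmax, T_PEAK, T_ARR and the thermal
safety margin TSM = T_ARR - environmental reference temperature.
Group-level thermal performance curves are polynomials of order 1-4
fitted to pooled pre-arrhythmia points, pooled across groups or
group-specific, compared by BIC; a grouped model winning is evidence
that acclimation temperature shapes the curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CardiacMetrics",
    "TPCFit",
    "fhmax_from_beats",
    "detect_t_arr",
    "peak_metrics",
    "fit_tpc",
]

DEFAULT_ENV_TEMPS = (31.0, 33.0)


@dataclass(frozen=True)
class CardiacMetrics:
    """Per-fish thermal-limit summary from one ramp assay."""

    peak_fhmax: float
    t_peak: float
    t_arr: Optional[float]
    tsm: dict = field(default_factory=dict)   # env temp -> degC margin
    flagged: bool = False                     # too few usable steps


def fhmax_from_beats(beat_times_s: Sequence[float]) -> float:
    """Heart rate (bpm) from beat timestamps in a ~15-s window.

    Uses inter-beat intervals: 60 x n_intervals / spanned seconds.
    """
    t = np.sort(np.asarray(beat_times_s, dtype=float))
    if len(t) < 2:
        raise ValueError("need >= 2 beats in the window")
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("beats must span a positive duration")
    return 60.0 * (len(t) - 1) / span


def _validate_assay(assay: pd.DataFrame) -> pd.DataFrame:
    temps = assay["step_temp_c"].to_numpy(dtype=float)
    if len(temps) > 1 and not np.all(np.diff(temps) > 0):
        raise ValueError("step temperatures must be strictly increasing")
    return assay.reset_index(drop=True)


def detect_t_arr(assay: pd.DataFrame,
                 drop_frac: float = 0.3) -> Optional[float]:
    """Arrhythmia-onset temperature for one assay.

    The first step flagged arrhythmic wins; absent a flag, the first
    step whose f_Hmax falls below (1 - drop_frac) of the running
    maximum — a precipitous decline — is used.  Returns None when
    neither occurs (the assay is then unusable for T_ARR summaries).
    """
    assay = _validate_assay(assay)
    flags = assay.get("arrhythmia_flag")
    if flags is not None:
        flagged = assay[flags.astype(bool)]
        if len(flagged):
            return float(flagged["step_temp_c"].iloc[0])
    fh = assay["fhmax_bpm"].to_numpy(dtype=float)
    running = np.maximum.accumulate(fh)
    for i in range(1, len(fh)):
        if fh[i] < (1.0 - drop_frac) * running[i - 1]:
            return float(assay["step_temp_c"].iloc[i])
    return None


def peak_metrics(assay: pd.DataFrame,
                 drop_frac: float = 0.3,
                 env_temps: Sequence[float] = DEFAULT_ENV_TEMPS,
                 min_usable_steps: int = 3) -> CardiacMetrics:
    """Peak f_Hmax, T_PEAK, T_ARR and thermal safety margins.

    The peak is searched at or before T_ARR (ties on f_Hmax break to
    the lowest temperature).  TSM is computed for each environmental
    reference temperature; assays with fewer than ``min_usable_steps``
    rhythmic steps are flagged.
    """
    assay = _validate_assay(assay)
    t_arr = detect_t_arr(assay, drop_frac=drop_frac)
    if t_arr is not None:
        pre = assay[assay["step_temp_c"] <= t_arr]
        rhythmic = pre[pre["step_temp_c"] < t_arr]
    else:
        pre = rhythmic = assay
    fh = rhythmic["fhmax_bpm"].to_numpy(dtype=float)
    temps = rhythmic["step_temp_c"].to_numpy(dtype=float)
    if len(fh) == 0:
        fh = pre["fhmax_bpm"].to_numpy(dtype=float)
        temps = pre["step_temp_c"].to_numpy(dtype=float)
    i = int(np.argmax(fh))          # first occurrence = lowest temperature
    tsm = ({e: t_arr - e for e in env_temps} if t_arr is not None else {})
    return CardiacMetrics(
        peak_fhmax=float(fh[i]), t_peak=float(temps[i]), t_arr=t_arr,
        tsm=tsm, flagged=len(rhythmic) < min_usable_steps)


@dataclass
class TPCFit:
    """Polynomial thermal-performance-curve model selection."""

    chosen_order: int
    chosen_structure: str           # "pooled" | "grouped"
    bic_table: dict                 # (order, structure) -> BIC
    coefficients: dict              # group (or "pooled") -> polyfit coefs
    t_center: float = 0.0           # polynomials are in (T - t_center)

    @property
    def temperature_effect(self) -> bool:
        """True when a group-specific model beats the pooled one."""
        return self.chosen_structure == "grouped"

    def evaluate(self, group: str, temp_c):
        key = group if group in self.coefficients else "pooled"
        t = np.asarray(temp_c, dtype=float) - self.t_center
        return np.polyval(self.coefficients[key], t)


def fit_tpc(points: pd.DataFrame, orders: Sequence[int] = (1, 2, 3, 4),
            group_col: str = "group") -> TPCFit:
    """Fit pooled and group-specific polynomials and choose by BIC.

    ``points`` holds pre-arrhythmia (step_temp_c, fhmax_bpm) samples,
    pooled across fish, with a group label.  For each order a single
    pooled polynomial and per-group polynomials are fitted by least
    squares; BIC (computed on the pooled residuals in both cases)
    selects the model.  Orders that the temperature design cannot
    identify are skipped with a warning.
    """
    temps = points["step_temp_c"].to_numpy(dtype=float)
    fh = points["fhmax_bpm"].to_numpy(dtype=float)
    groups = points[group_col].astype(str).to_numpy()
    uniq = sorted(set(groups))
    n = len(points)
    if n < 5:
        raise ValueError("too few points for a TPC fit")
    bic_table: dict[tuple[int, str], float] = {}
    coefs: dict[tuple[int, str], dict] = {}
    # center temperature for numerical conditioning
    t0 = temps.mean()
    tc = temps - t0
    for order in orders:
        if len(np.unique(temps)) <= order:
            warnings.warn(f"order {order} skipped: too few distinct "
                          "temperatures", stacklevel=2)
            continue
        c_pool = np.polyfit(tc, fh, order)
        rss_pool = float(((fh - np.polyval(c_pool, tc)) ** 2).sum())
        bic_table[(order, "pooled")] = (n * math.log(max(rss_pool, 1e-300)
                                                    / n)
                                        + (order + 2) * math.log(n))
        coefs[(order, "pooled")] = {"pooled": c_pool}
        if len(uniq) > 1:
            rss_g = 0.0
            cg = {}
            ok = True
            for g in uniq:
                sel = groups == g
                if len(np.unique(temps[sel])) <= order:
                    ok = False
                    break
                c = np.polyfit(tc[sel], fh[sel], order)
                rss_g += float(((fh[sel] - np.polyval(c, tc[sel])) ** 2)
                               .sum())
                cg[g] = c
            if ok:
                p = len(uniq) * (order + 1) + 1
                bic_table[(order, "grouped")] = (
                    n * math.log(max(rss_g, 1e-300) / n) + p * math.log(n))
                coefs[(order, "grouped")] = cg
    if not bic_table:
        raise ValueError("no polynomial order could be fitted")
    best = min(bic_table, key=bic_table.get)
    return TPCFit(chosen_order=best[0], chosen_structure=best[1],
                  bic_table=bic_table, coefficients=coefs[best],
                  t_center=t0)
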