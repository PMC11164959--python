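"""SMR, MMR and aerobic scope per fish.

MMR comes from a sliding-window analysis of the first post-chase
measurement phase: every window of at least ``min_window_s`` starting
at 1-s increments is fit by OLS and the steepest decline with
r2 above the gate wins.  SMR is the lowest-decile summary of all
gated MO2 measurements; absolute and factorial aerobic scope follow
as MMR - SMR and MMR / SMR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trace import (BackgroundModel, MO2Sample, RespirometerGeometry,
                    SlopeFit, compute_mo2)

__all__ = [
    "MetabolicTraits",
    "sliding_window_slopes",
    "compute_mmr",
    "compute_smr",
    "compute_scope",
]


@dataclass(frozen=True)
class MetabolicTraits:
    """Per-fish metabolic summary at a common body mass."""

    smr: float
    mmr: float
    aas: float
    fas: float
    smr_n_used: int = 0
    mmr_window: tuple[float, float] = (float("nan"), float("nan"))


def _best_window(t: np.ndarray, y: np.ndarray, min_window_s: float,
                 r2_gate: float) -> Optional[tuple[int, int, float, float]]:
    """Steepest-decline window by exhaustive search with prefix sums.

    Returns (i, j, slope, r2) over samples i..j inclusive, or None if
    no window passes the r2 gate.  Ties on slope (within 1e-12
    relative) break to the earliest start, then the shortest window.
    """
    n = len(t)
    t_min = t / 60.0
    c1 = np.concatenate([[0.0], np.cumsum(t_min)])
    c2 = np.concatenate([[0.0], np.cumsum(t_min * t_min)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    cty = np.concatenate([[0.0], np.cumsum(t_min * y)])
    best = None
    best_slope = np.inf
    for i in range(n):
        j_min = int(np.searchsorted(t, t[i] + min_window_s))
        if j_min >= n:
            break
        j = np.arange(j_min, n)
        m = (j - i + 1).astype(float)
        st = c1[j + 1] - c1[i]
        stt = c2[j + 1] - c2[i]
        sy = cy[j + 1] - cy[i]
        syy = cyy[j + 1] - cyy[i]
        sty = cty[j + 1] - cty[i]
        sxx = stt - st * st / m
        sxy = sty - st * sy / m
        syy_c = syy - sy * sy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = sxy / sxx
            r2 = np.where(syy_c > 0, (sxy * sxy) / (sxx * syy_c), 0.0)
        ok = r2 > r2_gate
        if not ok.any():
            continue
        slopes = np.where(ok, slope, np.inf)
        s_min = float(slopes.min())
        # shortest window among numerically tied slopes at this start
        tol_here = 1e-12 * max(1.0, abs(s_min))
        k = int(np.argmax(slopes <= s_min + tol_here))
        tol = 1e-12 * max(1.0, abs(best_slope if np.isfinite(best_slope)
                                   else s_min))
        if slopes[k] < best_slope - tol:
            best_slope = float(slopes[k])
            best = (i, int(j[k]), float(slopes[k]), float(r2[k]))
    return best


def sliding_window_slopes(time_s: Sequence[float], o2: Sequence[float],
                          min_window_s: float = 120.0,
                          r2_gate: float = 0.9) -> Optional[SlopeFit]:
    """Steepest valid OLS decline over all windows >= ``min_window_s``."""
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(o2, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 samples")
    res = _best_window(t, y, min_window_s, r2_gate)
    if res is None:
        return None
    i, j, slope, r2 = res
    tw = t[i:j + 1] / 60.0
    intercept = float(np.mean(y[i:j + 1]) - slope * np.mean(tw))
    return SlopeFit(slope=slope, intercept=intercept, r2=r2,
                    window_start_s=float(t[i]), window_end_s=float(t[j]),
                    n_points=j - i + 1)


def compute_mmr(post_chase: pd.DataFrame, geom: RespirometerGeometry,
                bg: Optional[BackgroundModel] = None,
                min_window_s: float = 120.0,
                r2_gate: float = 0.9
                ) -> tuple[Optional[MO2Sample], Optional[SlopeFit]]:
    """MMR from the post-chase measurement phase.

    Returns (sample, fit), or (None, None) when no window passes the
    r2 gate — MMR is then undefined for this fish and it is excluded
    from group summaries.
    """
    fit = sliding_window_slopes(post_chase["time_s"],
                                post_chase["o2_mg_per_l"],
                                min_window_s=min_window_s, r2_gate=r2_gate)
    if fit is None:
        return None, None
    sample = compute_mo2(fit, geom, bg, cycle_index=0,
                         context="exercise-recovery")
    return sample, fit


def compute_smr(mo2_values: Sequence[float],
                r2_values: Optional[Sequence[float]] = None,
                r2_gate: float = 0.95, quantile: float = 0.10,
                method: str = "mean_lowest") -> tuple[float, int]:
    """SMR as the lowest-``quantile`` summary of gated MO2 values.

    ``method='mean_lowest'`` (default) averages the lowest decile of
    the gated pool; ``method='quantile'`` returns the quantile value
    itself.  Returns (smr, n_values_in_pool).
    """
    vals = np.asarray(mo2_values, dtype=float)
    if r2_values is not None:
        r2 = np.asarray(r2_values, dtype=float)
        vals = vals[r2 > r2_gate]
    if len(vals) < 10:
        raise ValueError("need >= 10 gated MO2 values for a stable "
                         "low-quantile SMR")
    if method == "quantile":
        return float(np.quantile(vals, quantile)), len(vals)
    if method != "mean_lowest":
        raise ValueError(f"unknown smr method: {method!r}")
    n_low = max(1, int(np.floor(quantile * len(vals) + 1e-9)))
    lowest = np.sort(vals)[:n_low]
    return float(lowest.mean()), len(vals)


def compute_scope(smr: float, mmr: float, smr_n_used: int = 0,
                  mmr_window: tuple[float, float] = (float("nan"),
                                                    float("nan"))
                  ) -> MetabolicTraits:
    """Absolute (MMR - SMR) and factorial (MMR / SMR) aerobic scope."""
    if smr <= 0:
        raise ValueError("smr must be > 0")
    return MetabolicTraits(smr=smr, mmr=mmr, aas=mmr - smr, fas=mmr / smr,
                           smr_n_used=smr_n_used, mmr_window=mmr_window)
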