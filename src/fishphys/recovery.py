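"""Post-exercise recovery trajectories and threshold times.

Recovery of oxygen uptake after an exhaustive chase is summarized
three ways: (1) a biexponential decay MO2(t) = A1 e^(-k1 t) +
A2 e^(-k2 t) + c fitted per group (a monoexponential is fitted
alongside and both BICs reported); (2) time until the instantaneous
factorial scope MMR/MO2(t) reaches 2, on 10-min pooled blocks;
(3) percent of absolute aerobic scope recovered, 100 (MMR - MO2)/AAS,
with a logarithmic growth curve a + b ln(t) fitted to the series and
inverted for threshold-crossing times (75% and 100% AAS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .traits import MetabolicTraits

__all__ = [
    "RecoveryCurve",
    "fit_biexponential",
    "percent_aas_recovered",
    "fit_log_growth",
    "time_to_threshold",
    "cv_percent_aas",
]


@dataclass
class RecoveryCurve:
    """Biexponential recovery fit (k in min-1, fast component first)."""

    a1: float
    k1: float
    a2: float
    k2: float
    asymptote: float
    r2: float
    bic_biexp: float
    bic_monoexp: float
    converged: bool = True

    def evaluate(self, t_min):
        t = np.asarray(t_min, dtype=float)
        out = (self.a1 * np.exp(-self.k1 * t)
               + self.a2 * np.exp(-self.k2 * t) + self.asymptote)
        return out if out.ndim else float(out)

    @property
    def prefers_biexponential(self) -> bool:
        return self.bic_biexp < self.bic_monoexp


def _varpro_rss(logk: np.ndarray, t: np.ndarray, y: np.ndarray
                ) -> tuple[float, np.ndarray]:
    """RSS after solving the linear amplitudes for fixed decay rates."""
    ks = np.exp(logk)
    cols = [np.exp(-k * t) for k in ks] + [np.ones_like(t)]
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), coef


def _bic(rss: float, n: int, n_params: int) -> float:
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + (n_params + 1) * math.log(n)


def fit_biexponential(t_min: Sequence[float], mo2: Sequence[float],
                      min_samples: int = 8,
                      min_span_min: float = 60.0) -> RecoveryCurve:
    """Least-squares biexponential fit with multistart decay rates.

    Decay rates are optimized on a log scale with the amplitudes and
    asymptote profiled out by linear least squares (variable
    projection), which makes the fit robust to starting values.
    """
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(mo2, dtype=float)
    if len(t) < min_samples:
        raise ValueError(f"need >= {min_samples} samples")
    if np.ptp(t) < min_span_min:
        raise ValueError(f"samples must span >= {min_span_min} min")
    if np.ptp(y) == 0:
        raise ValueError("constant series; recovery curve degenerate")

    starts = [(kf, ks) for kf in (0.5, 0.15, 0.05)
              for ks in (0.02, 0.005) if kf > ks]
    best_rss, best_logk, best_coef = np.inf, None, None
    for kf, ks in starts:
        res = minimize(lambda lk: _varpro_rss(lk, t, y)[0],
                       x0=np.log([kf, ks]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": 2000})
        rss, coef = _varpro_rss(res.x, t, y)
        if rss < best_rss:
            best_rss, best_logk, best_coef = rss, res.x, coef
    # monoexponential comparator (single decay rate)
    mono_rss = np.inf
    for k0 in (0.3, 0.05, 0.01):
        res = minimize(lambda lk: _varpro_rss(lk, t, y)[0],
                       x0=np.log([k0]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": 1000})
        rss, _ = _varpro_rss(res.x, t, y)
        mono_rss = min(mono_rss, rss)

    ks = np.exp(best_logk)
    amps = best_coef[:2]
    order = np.argsort(-ks)          # fast component first
    k1, k2 = float(ks[order[0]]), float(ks[order[1]])
    a1, a2 = float(amps[order[0]]), float(amps[order[1]])
    c = float(best_coef[2])
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - best_rss / tss if tss > 0 else 0.0
    n = len(t)
    return RecoveryCurve(a1=a1, k1=k1, a2=a2, k2=k2, asymptote=c, r2=r2,
                         bic_biexp=_bic(best_rss, n, 5),
                         bic_monoexp=_bic(mono_rss, n, 3),
                         converged=bool(np.isfinite(best_rss)))


def percent_aas_recovered(t_min: Sequence[float], mo2: Sequence[float],
                          traits: MetabolicTraits,
                          clip_tol: float = 5.0) -> pd.DataFrame:
    """%AAS recovered, 100 (MMR - MO2)/AAS, per measurement.

    0 at MMR, 100 at SMR; clipped to [0, 100 + clip_tol] so that mild
    undershoot below SMR does not read as >105% recovery.
    """
    if traits.aas <= 0:
        raise ValueError("aas must be > 0")
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(mo2, dtype=float)
    pct = 100.0 * (traits.mmr - y) / traits.aas
    pct = np.clip(pct, 0.0, 100.0 + clip_tol)
    return pd.DataFrame({"t_min": t, "pct_aas": pct})


@dataclass(frozen=True)
class LogGrowthFit:
    a: float
    b: float
    r2: float

    def evaluate(self, t_min):
        return self.a + self.b * np.log(t_min)


def fit_log_growth(t_min: Sequence[float],
                   pct_aas: Sequence[float]) -> LogGrowthFit:
    """Least squares of %AAS(t) = a + b ln(t), t in minutes, t > 0.

    The t = 0 point (MMR itself) is excluded since ln is undefined
    there; the first post-MMR measurement anchors the curve.
    """
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(pct_aas, dtype=float)
    keep = t > 0
    t, y = t[keep], y[keep]
    if len(t) < 6:
        raise ValueError("need >= 6 points with t > 0")
    x = np.log(t)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("all timepoints identical")
    b = float(xc @ (y - y.mean()) / sxx)
    a = float(y.mean() - b * x.mean())
    resid = y - (a + b * x)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    return LogGrowthFit(a=a, b=b, r2=r2)


def time_to_threshold(kind: str, *,
                      t_min: Optional[Sequence[float]] = None,
                      mo2: Optional[Sequence[float]] = None,
                      mmr: Optional[float] = None,
                      loggrowth: Optional[LogGrowthFit] = None,
                      threshold: float = 2.0,
                      block_min: float = 10.0,
                      window_min: float = 180.0) -> Optional[float]:
    """Recovery threshold time in minutes, or None if never reached.

    ``kind='fas2'``: instantaneous available factorial scope
    MMR/MO2(t), pooled into ``block_min`` blocks; the midpoint of the
    first block whose mean reaches the threshold is returned.

    ``kind='pct_aas'``: the fitted logarithmic growth curve is
    inverted, t* = exp((threshold - a)/b); times beyond the
    observation window are reported as not reached.
    """
    if kind == "fas2":
        if t_min is None or mo2 is None or mmr is None:
            raise ValueError("fas2 needs t_min, mo2 and mmr")
        t = np.asarray(t_min, dtype=float)
        y = np.asarray(mo2, dtype=float)
        fas_avail = mmr / y
        order = np.argsort(t)
        t, fas_avail = t[order], fas_avail[order]
        n_blocks = int(np.ceil((t.max() + 1e-9) / block_min))
        for i in range(max(n_blocks, 1)):
            sel = (t >= i * block_min) & (t < (i + 1) * block_min)
            if sel.any() and fas_avail[sel].mean() >= threshold:
                return (i + 0.5) * block_min
        return None
    if kind == "pct_aas":
        if loggrowth is None:
            raise ValueError("pct_aas needs a fitted log-growth curve")
        if loggrowth.b <= 0:
            return None
        t_star = math.exp((threshold - loggrowth.a) / loggrowth.b)
        return t_star if t_star <= window_min else None
    raise ValueError(f"unknown threshold kind: {kind!r}")


def cv_percent_aas(pct_by_fish: pd.DataFrame,
                   time_col: str = "t_min",
                   value_col: str = "pct_aas") -> float:
    """Group CV (%) of %AAS across fish, averaged over timepoints.

    Expects one row per (fish, timepoint); a group of one fish has no
    spread and is rejected.  Per timepoint, CV = 100 sd/mean across
    fish; timepoints with nonpositive mean are skipped.
    """
    if pct_by_fish["fish_id"].nunique() < 2:
        raise ValueError("need >= 2 fish for a group CV")
    cvs = []
    for _, g in pct_by_fish.groupby(time_col):
        if len(g) < 2:
            continue
        mean = g[value_col].mean()
        if mean > 0:
            cvs.append(100.0 * g[value_col].std(ddof=1) / mean)
    if not cvs:
        raise ValueError("no timepoints with positive mean %AAS")
    return float(np.mean(cvs))
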