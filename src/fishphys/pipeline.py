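"""End-to-end orchestration: simulated or on-disk cohort -> trait tables.

Stage functions are plain library calls so that the CLI, the analysis
drivers and the tests all share one code path.  Every stage consumes
and produces DataFrames; `run_pipeline` wires them together for a
cohort directory (metadata.csv, traces/, blanks/, cardiac.csv) and
writes per-fish tables, group summaries (mean +/- SEM) and a
machine-readable run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cardiac import DEFAULT_ENV_TEMPS, fit_tpc, peak_metrics
from .recovery import (cv_percent_aas, fit_biexponential, fit_log_growth,
                       percent_aas_recovered, time_to_threshold)
from .sda import (MealSpec, compute_sda, compute_sda_coeff,
                  compute_sda_peak, compute_smr_sda, hourly_minimum_line,
                  mask_handling_window, scope_partition)
from .trace import (RespirometerGeometry, fit_background, fit_slope,
                    mo2_series, scale_to_common_mass, segment_cycles,
                    select_scaling_model)
from .traits import compute_mmr, compute_scope, compute_smr

__all__ = ["PipelineConfig", "summarize_group", "run_pipeline",
           "analyze_cohort"]


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, in one place."""

    mmr_r2_gate: float = 0.9
    smr_r2_gate: float = 0.95
    smr_quantile: float = 0.10
    smr_method: str = "mean_lowest"
    mask_h: float = 3.0
    min_window_s: float = 120.0
    block_min: float = 10.0
    recovery_window_min: float = 180.0
    pct_aas_threshold: float = 75.0
    drop_frac: float = 0.3
    common_mass_kg: float = 0.005
    smr_scaling_b: float = 1.0      # isometric
    mmr_scaling_b: float = 0.89     # universal fish exponent
    env_temps: tuple = DEFAULT_ENV_TEMPS
    meal_energy_density_kj_g: float = 3.87
    meal_digestibility: float = 0.8
    o2_energy_kj_per_g: float = 13.6
    seed: int = 0

    def __post_init__(self):
        for name, lo, hi in [("mmr_r2_gate", 0, 1), ("smr_r2_gate", 0, 1),
                             ("smr_quantile", 0, 0.5),
                             ("drop_frac", 0, 1),
                             ("meal_digestibility", 0, 1)]:
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.mask_h < 0 or self.min_window_s <= 0 or self.block_min <= 0:
            raise ValueError("durations must be positive (mask_h >= 0)")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["env_temps"] = list(self.env_temps)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        d.update({k: v for k, v in overrides.items() if v is not None})
        if "env_temps" in d:
            d["env_temps"] = tuple(d["env_temps"])
        return cls(**d)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def summarize_group(per_fish: pd.DataFrame, metrics: list[str],
                    group_col: str = "group") -> pd.DataFrame:
    """Group mean, SEM (sample sd / sqrt(n)) and n per metric."""
    rows = []
    for g, sub in per_fish.groupby(group_col):
        for m in metrics:
            vals = sub[m].dropna()
            n = len(vals)
            rows.append({
                "group": g, "metric": m,
                "mean": vals.mean() if n else np.nan,
                "sem": vals.std(ddof=1) / np.sqrt(n) if n >= 2 else np.nan,
                "n": n,
            })
    return pd.DataFrame(rows)


# -- cohort loading -----------------------------------------------------


def _load_cohort(cohort_dir: Path) -> dict:
    meta = pd.read_csv(cohort_dir / "metadata.csv")
    traces, blanks = {}, {}
    for _, row in meta.iterrows():
        if row.get("kind", "resp") != "resp":
            continue
        fid = row["fish_id"]
        path = cohort_dir / "traces" / f"{fid}.csv"
        try:
            traces[fid] = pd.read_csv(path)
            blanks[fid] = (
                pd.read_csv(cohort_dir / "blanks" / f"{fid}_pre.csv"),
                pd.read_csv(cohort_dir / "blanks" / f"{fid}_post.csv"),
            )
        except (OSError, pd.errors.ParserError) as exc:
            raise IOError(f"unreadable input for fish {fid}: {path}") \
                from exc
    cardiac_path = cohort_dir / "cardiac.csv"
    cardiac = (pd.read_csv(cardiac_path) if cardiac_path.exists()
               else pd.DataFrame())
    return {"metadata": meta, "traces": traces, "blanks": blanks,
            "cardiac": cardiac}


# -- respirometry stages ------------------------------------------------


def stage_mo2(trace: pd.DataFrame, blanks_pre: pd.DataFrame,
              blanks_post: pd.DataFrame, geom: RespirometerGeometry,
              fed_time_s: Optional[float], config: PipelineConfig
              ) -> tuple[pd.DataFrame, object]:
    """Background-corrected MO2 series for one fish, with contexts."""
    pre_fits = [fit_slope(w["time_s"], w["o2_mg_per_l"])
                for w in segment_cycles(blanks_pre)]
    post_fits = [fit_slope(w["time_s"], w["o2_mg_per_l"])
                 for w in segment_cycles(blanks_post)]
    span = float(trace["time_s"].max())
    bg = fit_background(pre_fits, post_fits, span)
    series = mo2_series(trace, geom, bg)
    fed = fed_time_s if fed_time_s is not None and np.isfinite(fed_time_s) \
        else np.inf
    series["context"] = np.where(series["t_mid_s"] >= fed,
                                 "postprandial", "exercise-recovery")
    return series, bg


def _fish_traits(trace: pd.DataFrame, series: pd.DataFrame, bg,
                 geom: RespirometerGeometry, fed_time_s: Optional[float],
                 config: PipelineConfig) -> dict:
    """Raw (not mass-standardized) SMR and MMR for one fish."""
    windows = segment_cycles(trace)
    if not windows:
        raise ValueError("trace has no measurement windows")
    mmr_sample, mmr_fit = compute_mmr(
        windows[0], geom, bg, min_window_s=config.min_window_s,
        r2_gate=config.mmr_r2_gate)
    # SMR pool: validated post-exercise samples plus post-feeding
    # samples outside the handling mask; the MMR cycle itself stays out.
    pool = series[series["cycle_index"] > 0].copy()
    fed = fed_time_s if fed_time_s is not None and np.isfinite(fed_time_s) \
        else np.inf
    masked_out = ((pool["t_mid_s"] >= fed)
                  & (pool["t_mid_s"] < fed + config.mask_h * 3600.0))
    pool = pool[~masked_out]
    smr, n_used = compute_smr(pool["mo2_mg_kg_min"], pool["r2"],
                              r2_gate=config.smr_r2_gate,
                              quantile=config.smr_quantile,
                              method=config.smr_method)
    return {
        "smr_raw": smr, "smr_n_used": n_used,
        "mmr_raw": mmr_sample.mo2 if mmr_sample is not None else np.nan,
        "mmr_window_start_s": (mmr_fit.window_start_s
                               if mmr_fit is not None else np.nan),
        "mmr_window_end_s": (mmr_fit.window_end_s
                             if mmr_fit is not None else np.nan),
        "mmr_undefined": mmr_sample is None,
    }


def stage_traits(per_fish: pd.DataFrame,
                 config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Mass-standardize raw traits and derive scope, cohort-wide.

    Scaling exponents for the standardization come from the config
    (isometric SMR, universal 0.89 MMR); the BIC model selection over
    candidate exponents is run when the cohort spans enough masses and
    reported alongside.
    """
    out = per_fish.copy()
    decisions = {}
    for trait, col, b in [("SMR", "smr_raw", config.smr_scaling_b),
                          ("MMR", "mmr_raw", config.mmr_scaling_b)]:
        ok = out[col].notna() & (out[col] > 0)
        try:
            decisions[trait] = select_scaling_model(
                out.loc[ok, "mass_kg"], out.loc[ok, col], trait=trait,
                common_mass_kg=config.common_mass_kg)
        except ValueError as exc:
            decisions[trait] = None
            warnings.warn(f"scaling selection skipped for {trait}: {exc}",
                          stacklevel=2)
        out[trait.lower()] = [
            scale_to_common_mass(v, m, b, config.common_mass_kg)
            if np.isfinite(v) else np.nan
            for v, m in zip(out[col], out["mass_kg"])]
    out["aas"] = out["mmr"] - out["smr"]
    out["fas"] = out["mmr"] / out["smr"]
    return out, decisions


def stage_recovery(series_by_fish: dict[str, pd.DataFrame],
                   traits: pd.DataFrame,
                   config: PipelineConfig) -> pd.DataFrame:
    """Group-level recovery metrics from pooled post-exercise samples."""
    rows = []
    for group, sub in traits.groupby("group"):
        frames, pct_frames = [], []
        for _, fish in sub.iterrows():
            fid = fish["fish_id"]
            if fid not in series_by_fish or not np.isfinite(fish["mmr"]):
                continue
            s = series_by_fish[fid]
            rec = s[(s["context"] == "exercise-recovery")
                    & (s["t_mid_s"] / 60.0 <= config.recovery_window_min)
                    & s["valid_09"]]
            t_min = rec["t_mid_s"].to_numpy() / 60.0
            mo2 = rec["mo2_mg_kg_min"].to_numpy()
            frames.append(pd.DataFrame({"fish_id": fid, "t_min": t_min,
                                        "mo2": mo2}))
            ft = compute_scope(fish["smr"], fish["mmr"])
            pct = percent_aas_recovered(t_min, mo2, ft)
            pct.insert(0, "fish_id", fid)
            pct["t_blk"] = np.round(pct["t_min"])
            pct_frames.append(pct)
        if not frames:
            continue
        pooled = pd.concat(frames, ignore_index=True)
        pcts = pd.concat(pct_frames, ignore_index=True)
        row = {"group": group, "n": pooled["fish_id"].nunique()}
        try:
            curve = fit_biexponential(pooled["t_min"], pooled["mo2"])
            row.update(biexp_a1=curve.a1, biexp_k1=curve.k1,
                       biexp_a2=curve.a2, biexp_k2=curve.k2,
                       biexp_c=curve.asymptote, biexp_r2=curve.r2,
                       bic_biexp=curve.bic_biexp,
                       bic_monoexp=curve.bic_monoexp)
        except ValueError:
            warnings.warn(f"biexponential fit failed for group {group}",
                          stacklevel=2)
        lg = fit_log_growth(pcts["t_min"], pcts["pct_aas"])
        row.update(loggrowth_a=lg.a, loggrowth_b=lg.b, loggrowth_r2=lg.r2)
        mmr_mean = sub["mmr"].mean()
        row["time_to_fas2_min"] = time_to_threshold(
            "fas2", t_min=pooled["t_min"], mo2=pooled["mo2"], mmr=mmr_mean,
            block_min=config.block_min)
        row["time_to_75aas_min"] = time_to_threshold(
            "pct_aas", loggrowth=lg, threshold=config.pct_aas_threshold,
            window_min=config.recovery_window_min)
        row["time_to_100aas_min"] = time_to_threshold(
            "pct_aas", loggrowth=lg, threshold=100.0,
            window_min=config.recovery_window_min)
        try:
            row["cv_pct_aas"] = cv_percent_aas(
                pcts.rename(columns={"t_blk": "tp"}), time_col="tp")
        except ValueError:
            pass
        rows.append(row)
    return pd.DataFrame(rows)


def stage_sda(series_by_fish: dict[str, pd.DataFrame],
              traits: pd.DataFrame, metadata: pd.DataFrame,
              config: PipelineConfig) -> pd.DataFrame:
    """Per-fish SDA metrics for every fed fish."""
    rows = []
    meta = metadata.set_index("fish_id")
    for _, fish in traits.iterrows():
        fid = fish["fish_id"]
        if fid not in series_by_fish:
            continue
        fed = meta.loc[fid, "fed_time_s"]
        if not np.isfinite(fed):
            continue
        s = series_by_fish[fid]
        post = s[(s["context"] == "postprandial") & s["valid_09"]]
        t_h = (post["t_mid_s"].to_numpy() - fed) / 3600.0
        try:
            masked = mask_handling_window(t_h, post["mo2_mg_kg_min"],
                                          mask_h=config.mask_h)
            smr_sda, _ = compute_smr_sda(masked,
                                         quantile=config.smr_quantile,
                                         method=config.smr_method)
            line = hourly_minimum_line(masked)
            sda, dur, truncated = compute_sda(masked, smr_sda, line=line)
            peak, t_peak = compute_sda_peak(masked)
        except ValueError as exc:
            warnings.warn(f"SDA skipped for fish {fid}: {exc}",
                          stacklevel=2)
            continue
        meal = MealSpec(
            percent_bm=float(meta.loc[fid, "meal_percent_bm"]),
            energy_density_kj_g=config.meal_energy_density_kj_g,
            digestibility=config.meal_digestibility,
            o2_energy_kj_per_g=config.o2_energy_kj_per_g)
        rows.append({
            "fish_id": fid, "group": fish["group"],
            "meal_percent_bm": meal.percent_bm,
            "sda_mg_per_kg": sda, "sda_dur_h": dur,
            "sda_peak": peak, "time_to_peak_h": t_peak,
            "smr_sda": smr_sda,
            "sda_coeff_pct": compute_sda_coeff(sda, meal),
            "truncated": truncated,
        })
    return pd.DataFrame(rows)


def stage_cardiac(cardiac: pd.DataFrame,
                  config: PipelineConfig
                  ) -> tuple[pd.DataFrame, Optional[object]]:
    """Per-fish cardiac limits plus the group TPC model selection."""
    if cardiac.empty:
        return pd.DataFrame(), None
    rows, pre_frames = [], []
    for (fid,), assay in cardiac.groupby(["fish_id"]):
        m = peak_metrics(assay, drop_frac=config.drop_frac,
                         env_temps=config.env_temps)
        row = {"fish_id": fid,
               "group": assay["group"].iloc[0] if "group" in assay else "",
               "peak_fhmax": m.peak_fhmax, "t_peak": m.t_peak,
               "t_arr": m.t_arr, "flagged": m.flagged}
        for e in config.env_temps:
            row[f"tsm_{e:g}"] = m.tsm.get(e, np.nan)
        rows.append(row)
        if m.t_arr is not None:
            pre = assay[assay["step_temp_c"] < m.t_arr]
        else:
            pre = assay
        pre_frames.append(pre)
    metrics = pd.DataFrame(rows)
    points = pd.concat(pre_frames, ignore_index=True)
    tpc = None
    if "group" in points.columns and points["group"].notna().all() \
            and len(points) >= 5:
        try:
            tpc = fit_tpc(points)
        except ValueError as exc:
            warnings.warn(f"TPC fit skipped: {exc}", stacklevel=2)
    return metrics, tpc


# -- the full pipeline --------------------------------------------------


def analyze_cohort(cohort, config: Optional[PipelineConfig] = None) -> dict:
    """Run every stage over a cohort (directory path or CohortData)."""
    config = config or PipelineConfig()
    if isinstance(cohort, (str, Path)):
        data = _load_cohort(Path(cohort))
        metadata = data["metadata"]
        traces = data["traces"]
        blanks = data["blanks"]
        cardiac = data["cardiac"]
    else:  # CohortData
        metadata = cohort.metadata
        traces = {fid: tr.trace for fid, tr in cohort.trials.items()}
        blanks = {fid: (tr.blanks_pre, tr.blanks_post)
                  for fid, tr in cohort.trials.items()}
        cardiac = cohort.cardiac

    series_by_fish: dict[str, pd.DataFrame] = {}
    fish_rows = []
    flagged: list[dict] = []
    for _, row in metadata.iterrows():
        fid = row["fish_id"]
        if fid not in traces:
            continue
        try:
            geom = RespirometerGeometry(
                v_r_l=float(row["chamber_volume_l"]),
                v_f_l=float(row["mass_kg"]) * 1.0,
                mass_kg=float(row["mass_kg"]))
            series, bg = stage_mo2(traces[fid], *blanks[fid], geom,
                                   row.get("fed_time_s"), config)
            series_by_fish[fid] = series
            tr = _fish_traits(traces[fid], series, bg, geom,
                              row.get("fed_time_s"), config)
        except (ValueError, KeyError) as exc:
            flagged.append({"fish_id": fid, "reason": str(exc)})
            continue
        tr.update(fish_id=fid, group=row["group"],
                  mass_kg=float(row["mass_kg"]))
        fish_rows.append(tr)

    results: dict = {"flagged": flagged, "config": config}
    if fish_rows:
        per_fish = pd.DataFrame(fish_rows)
        traits, scaling = stage_traits(per_fish, config)
        results["traits"] = traits
        results["scaling"] = scaling
        results["mo2"] = pd.concat(
            [s.assign(fish_id=f) for f, s in series_by_fish.items()],
            ignore_index=True)
        results["recovery"] = stage_recovery(series_by_fish, traits, config)
        results["sda"] = stage_sda(series_by_fish, traits,
                                   metadata, config)
        results["traits_group"] = summarize_group(
            traits, ["smr", "mmr", "aas", "fas"])
        if len(results["sda"]):
            results["sda_group"] = summarize_group(
                results["sda"],
                ["sda_mg_per_kg", "sda_dur_h", "sda_peak",
                 "time_to_peak_h", "sda_coeff_pct"])
            results["scope_partition"] = _group_scope_partition(
                traits, results["sda"])
    metrics, tpc = stage_cardiac(cardiac, config)
    if len(metrics):
        results["cardiac"] = metrics
        results["cardiac_points"] = cardiac
        results["tpc"] = tpc
        usable = metrics[~metrics["flagged"]]
        tsm_cols = [c for c in metrics.columns if c.startswith("tsm_")]
        results["cardiac_group"] = summarize_group(
            usable, ["peak_fhmax", "t_peak", "t_arr", *tsm_cols])
    return results


def _group_scope_partition(traits: pd.DataFrame,
                           sda: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for group, sub in sda.groupby("group"):
        t = traits[traits["group"] == group]
        if t.empty:
            continue
        part = scope_partition(t["smr"].mean(), t["mmr"].mean(),
                               t["aas"].mean(), sub["sda_peak"].mean())
        rows.append({"group": group,
                     "remaining_scope_abs": part.remaining_scope_abs,
                     "scope_used_pct": part.scope_used_pct,
                     "scope_remaining_pct": part.scope_remaining_pct,
                     "peak_to_smr": part.peak_to_smr, "fas": part.fas,
                     "flagged": part.flagged})
    return pd.DataFrame(rows)


def run_pipeline(cohort_dir: str | Path, out_dir: str | Path,
                 config: Optional[PipelineConfig] = None,
                 figures: bool = False) -> dict:
    """Analyze a cohort directory and write the output bundle."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = analyze_cohort(Path(cohort_dir), config)
    if figures:
        from .plots import make_figures
        make_figures(results, out / "figures",
                     cardiac_points=results.get("cardiac_points"))
    for key in ["traits", "mo2", "recovery", "sda", "traits_group",
                "sda_group", "scope_partition", "cardiac",
                "cardiac_group"]:
        if key in results and isinstance(results[key], pd.DataFrame):
            results[key].to_csv(out / f"{key}.csv", index=False)
    summary = {}
    for key in ["traits_group", "sda_group", "cardiac_group"]:
        if key in results:
            summary[key] = results[key].to_dict(orient="records")
    if results.get("tpc") is not None:
        tpc = results["tpc"]
        summary["tpc"] = {
            "chosen_order": tpc.chosen_order,
            "chosen_structure": tpc.chosen_structure,
            "temperature_effect": tpc.temperature_effect,
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 default=float))
    log = {
        "fishphys_version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": dataclasses.asdict(config) | {
            "env_temps": list(config.env_temps)},
        "n_fish_flagged": len(results["flagged"]),
        "flagged": results["flagged"],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2,
                                                 default=str))
    config.to_yaml(out / "config_used.yaml")
    return results
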