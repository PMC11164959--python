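"""Static summary figures for a pipeline run.

One PNG per theme: metabolic traits by group, group recovery curves,
the scope partition at peak digestion, and cardiac thermal
performance curves. Thin matplotlib wrappers over the result tables;
everything scientific happens upstream.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["make_figures"]


def _traits_figure(traits: pd.DataFrame, path: Path) -> None:
    metrics = ["smr", "mmr", "aas"]
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2), sharex=True)
    groups = sorted(traits["group"].unique())
    xs = np.arange(len(groups))
    for ax, m in zip(axes, metrics):
        for i, g in enumerate(groups):
            vals = traits.loc[traits["group"] == g, m].dropna()
            ax.plot(np.full(len(vals), i), vals, "o", ms=3, alpha=0.5)
            if len(vals):
                ax.errorbar([i], [vals.mean()],
                            yerr=[vals.sem()] if len(vals) > 1 else None,
                            fmt="ks", capsize=3)
        ax.set_title(m.upper())
        ax.set_xticks(xs, groups, rotation=45)
    axes[0].set_ylabel("mg O2 kg$^{-1}$ min$^{-1}$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _recovery_figure(recovery: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    t = np.linspace(1, 180, 200)
    for _, row in recovery.iterrows():
        if not np.isfinite(row.get("loggrowth_a", np.nan)):
            continue
        pct = np.clip(row["loggrowth_a"]
                      + row["loggrowth_b"] * np.log(t), 0, 105)
        ax.plot(t, pct, label=str(row["group"]))
    ax.axhline(75, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("minutes post-exercise")
    ax.set_ylabel("% aerobic scope recovered")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _scope_figure(partition: pd.DataFrame, traits_group: pd.DataFrame,
                  path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    groups = partition["group"].tolist()
    means = traits_group.pivot(index="group", columns="metric",
                               values="mean")
    xs = np.arange(len(groups))
    for i, g in enumerate(groups):
        smr = means.loc[g, "smr"]
        mmr = means.loc[g, "mmr"]
        row = partition[partition["group"] == g].iloc[0]
        peak = smr + (100 - row["scope_remaining_pct"]) / 100.0 \
            * (mmr - smr)
        ax.bar(i, smr, color="0.6")
        ax.bar(i, peak - smr, bottom=smr, color="tab:orange",
               label="digestion" if i == 0 else None)
        ax.bar(i, mmr - peak, bottom=peak, color="white",
               edgecolor="k", label="remaining scope" if i == 0 else None)
    ax.set_xticks(xs, groups, rotation=45)
    ax.set_ylabel("mg O2 kg$^{-1}$ min$^{-1}$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _tpc_figure(cardiac_points: pd.DataFrame, tpc, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for g, sub in cardiac_points.groupby("group"):
        ax.plot(sub["step_temp_c"], sub["fhmax_bpm"], "o", ms=3,
                alpha=0.4)
        if tpc is not None:
            t = np.linspace(sub["step_temp_c"].min(),
                            sub["step_temp_c"].max(), 100)
            ax.plot(t, tpc.evaluate(str(g), t), label=str(g))
    ax.set_xlabel("test temperature (°C)")
    ax.set_ylabel("f$_{Hmax}$ (bpm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def make_figures(results: dict, out_dir: str | Path,
                 cardiac_points: pd.DataFrame | None = None) -> list[Path]:
    """Write the summary figures available from a results bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if "traits" in results:
        p = out / "fig_traits.png"
        _traits_figure(results["traits"], p)
        written.append(p)
    if "recovery" in results and len(results["recovery"]):
        p = out / "fig_recovery.png"
        _recovery_figure(results["recovery"], p)
        written.append(p)
    if "scope_partition" in results and "traits_group" in results:
        p = out / "fig_scope_partition.png"
        _scope_figure(results["scope_partition"],
                      results["traits_group"], p)
        written.append(p)
    if cardiac_points is not None and len(cardiac_points):
        p = out / "fig_tpc.png"
        _tpc_figure(cardiac_points, results.get("tpc"), p)
        written.append(p)
    return written
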