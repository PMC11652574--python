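"""Plain-figure rendering from pipeline artifacts.

Each figure is drawn exclusively from a CSV produced by an upstream stage;
missing stage outputs are skipped with a warning rather than failing the
report.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

log = logging.getLogger("dyadgaze")

#: the three table AOIs drawn in timelock figures (face/none are exported in
#: the CSV but not plotted)
PLOT_AOIS = ("blocks", "build", "model")
_COLORS = {"blocks": "tab:blue", "build": "tab:orange", "model": "tab:green"}


def _plot_timelock(timelock: pd.DataFrame, out: Path) -> Path:
    combos = timelock[["event_type", "source"]].drop_duplicates().to_numpy()
    ncol = 2
    nrow = max(1, (len(combos) + ncol - 1) // ncol)
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(9, 3 * nrow), sharex=True, sharey=True, squeeze=False
    )
    for ax, (event_type, source) in zip(axes.ravel(), combos):
        sub = timelock[
            (timelock["event_type"] == event_type) & (timelock["source"] == source)
        ]
        for aoi in PLOT_AOIS:
            a = sub[sub["aoi"] == aoi]
            ax.plot(a["tau_s"], a["mean"], label=aoi, color=_COLORS[aoi])
            ax.fill_between(
                a["tau_s"], a["ci_lo"], a["ci_hi"], alpha=0.25, color=_COLORS[aoi]
            )
        ax.axvline(0, color="k", lw=0.5)
        ax.set_title(f"{event_type} ({source})")
        ax.set_ylim(0, 1)
    for ax in axes[-1]:
        ax.set_xlabel("time from onset (s)")
    for row in axes:
        row[0].set_ylabel("proportion of looks")
    axes.ravel()[0].legend(frameon=False)
    fig.tight_layout()
    f = out / "timelock.png"
    fig.savefig(f, dpi=120)
    plt.close(fig)
    return f


def _plot_dwell(dwell: pd.DataFrame, summary: pd.DataFrame, out: Path) -> Path:
    sources = summary["source"].unique()
    fig, axes = plt.subplots(1, len(sources), figsize=(4.5 * len(sources), 3.5), squeeze=False)
    for ax, source in zip(axes.ravel(), sources):
        s = summary[summary["source"] == source]
        x = range(len(s))
        ax.bar(x, s["group_mean"], yerr=s["group_se"], color="0.7")
        d = dwell[dwell["source"] == source]
        for i, cat in enumerate(s["category"]):
            vals = d[d["category"] == cat]["mean"].dropna()
            ax.plot([i] * len(vals), vals, "o", color="tab:orange", ms=3, alpha=0.6)
        for i, (m, n) in enumerate(zip(s["group_mean"], s["n_participants"])):
            ax.annotate(str(n), (i, 1.02), ha="center", fontsize=8)
        ax.set_xticks(list(x), s["category"])
        ax.set_ylim(0, 1.1)
        ax.set_title(f"source: {source}")
        ax.set_ylabel("relative dwell")
    fig.tight_layout()
    f = out / "dwell.png"
    fig.savefig(f, dpi=120)
    plt.close(fig)
    return f


def _plot_models(inference: pd.DataFrame, out: Path) -> Path:
    pair = inference.groupby(["model", "dyad_id"])[["model_score", "benchmark_score"]].mean()
    grand = pair.groupby("model").mean()
    se = pair.groupby("model").sem()
    fig, ax = plt.subplots(figsize=(7, 3.5))
    x = range(len(grand))
    ax.bar(x, grand["model_score"], yerr=se["model_score"], color="0.7", label="model")
    ax.plot(
        x, grand["benchmark_score"], "k_", ms=20, label="benchmark"
    )
    ax.set_xticks(list(x), grand.index, rotation=20)
    ax.set_ylabel("proportion correct")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    f = out / "models.png"
    fig.savefig(f, dpi=120)
    plt.close(fig)
    return f


def _plot_shiftfun(shiftfun: pd.DataFrame, out: Path) -> Path:
    comps = shiftfun["comparison"].unique()
    fig, axes = plt.subplots(1, len(comps), figsize=(4.5 * len(comps), 3.5), squeeze=False)
    for ax, comp in zip(axes.ravel(), comps):
        s = shiftfun[shiftfun["comparison"] == comp]
        ax.errorbar(
            s["decile"],
            s["diff"],
            yerr=[s["diff"] - s["ci_lo"], s["ci_hi"] - s["diff"]],
            fmt="o-",
        )
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(comp)
        ax.set_xlabel("decile")
        ax.set_ylabel("decile difference")
    fig.tight_layout()
    f = out / "shiftfun.png"
    fig.savefig(f, dpi=120)
    plt.close(fig)
    return f


def render_report(artifact_dir: str | Path) -> list[Path]:
    """Render figures and a summary document from pipeline CSV outputs."""
    out = Path(artifact_dir)
    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    produced: list[Path] = []

    def load(name):
        f = out / name
        if not f.exists():
            log.warning("missing %s; figure skipped", name)
            return None
        return pd.read_csv(f)

    timelock = load("timelock.csv")
    if timelock is not None:
        produced.append(_plot_timelock(timelock, figdir))
    dwell, dsummary = load("dwell.csv"), load("dwell_summary.csv")
    if dwell is not None and dsummary is not None:
        produced.append(_plot_dwell(dwell, dsummary, figdir))
    inference = load("inference.csv")
    if inference is not None:
        produced.append(_plot_models(inference, figdir))
    shiftfun = load("shiftfun.csv")
    if shiftfun is not None:
        produced.append(_plot_shiftfun(shiftfun, figdir))

    lines = ["# dyadgaze report", ""]
    lines += [f"- figure: {p.name}" for p in produced]
    (out / "report.md").write_text("\n".join(lines) + "\n")
    produced.append(out / "report.md")
    return produced
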