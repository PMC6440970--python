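"""Tabular and graphical group reports.

Produces the summary CSV (group mean/median/n per connectivity class),
significance annotations from Holm-corrected Mann-Whitney tests, boxplots
with individual observations, and the aligned depth-profile plot.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import GroupComparison


def summarize_table(table: pd.DataFrame, value_col: str = "value",
                    class_col: str = "pair_class") -> pd.DataFrame:
    g = table.groupby(class_col)[value_col]
    out = g.agg(["mean", "median", "count"]).rename(columns={"count": "n"})
    return out.reset_index()


def _boxplot(table: pd.DataFrame, value_col: str, class_col: str,
             title: str, path: Path) -> None:
    classes = list(table[class_col].unique())
    data = [table.loc[table[class_col] == c, value_col].to_numpy() for c in classes]
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.boxplot(data, tick_labels=classes, showmeans=True)
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for i, vals in enumerate(data):
        ax.plot(i + 1 + rng.uniform(-0.08, 0.08, vals.size), vals, "o",
                ms=3, alpha=0.6)
    ax.set_ylabel(value_col)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_aligned_profile(profile: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.errorbar(profile["rel_depth"], profile["mean_r"], yerr=profile["sem_r"],
                fmt="o-", capsize=3)
    for _, row in profile.iterrows():
        ax.annotate(str(int(row["n"])), (row["rel_depth"], row["mean_r"]),
                    textcoords="offset points", xytext=(0, -14), fontsize=7,
                    ha="center")
    ax.set_xlabel("depth relative to intermediate GM (voxels)")
    ax.set_ylabel("correlation with dorsal seed")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def build_report(tables: dict[str, pd.DataFrame],
                 comparisons: list[GroupComparison],
                 out_dir: str | Path,
                 aligned_profile: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write summary CSVs, the significance table and plots; return paths.

    ``tables`` maps a modality name (e.g. "fmri", "lfp") to a long-format
    connectivity table with ``pair_class`` and ``value`` columns.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in tables.items():
        if table.empty:
            continue
        summary = summarize_table(table)
        p = out / f"{name}_summary.csv"
        summary.to_csv(p, index=False)
        paths[f"{name}_summary"] = p
        fig_p = out / f"{name}_boxplot.png"
        _boxplot(table, "value", "pair_class", name, fig_p)
        paths[f"{name}_boxplot"] = fig_p
    if comparisons:
        rows = [{
            "group_a": c.name_a, "group_b": c.name_b, "U": c.u_stat,
            "p_raw": c.p_raw, "p_adjusted": c.p_adjusted, "method": c.method,
            "annotation": c.stars,
        } for c in comparisons]
        p = out / "comparisons.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths["comparisons"] = p
    if aligned_profile is not None and not aligned_profile.empty:
        p = out / "aligned_profile.png"
        plot_aligned_profile(aligned_profile, p)
        paths["aligned_profile"] = p
        csv_p = out / "aligned_profile.csv"
        aligned_profile.to_csv(csv_p, index=False)
        paths["aligned_profile_csv"] = csv_p
    return paths
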