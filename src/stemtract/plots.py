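"""Report figures: termination-density box plots and asymmetry bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def ntds_boxplot(ntds: pd.DataFrame, tract: str = "", ax=None):
    """Per-region box plots of NTDS with group means, split by hemisphere.

    Mirrors the standard presentation of termination densities: one box
    per region and hemisphere, a diamond at the mean.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    regions = sorted(ntds.region.unique())
    data, labels = [], []
    for r in regions:
        for h in ("left", "right"):
            vals = ntds[(ntds.region == r)
                        & (ntds.hemisphere == h)].ntds.to_numpy()
            data.append(vals if len(vals) else np.array([0.0]))
            labels.append(f"{r}\n{h[0].upper()}")
    ax.boxplot(data, tick_labels=labels, showmeans=True,
               meanprops=dict(marker="D", markerfacecolor="k",
                              markeredgecolor="k", markersize=4))
    ax.set_ylabel("NTDS")
    if tract:
        ax.set_title(f"{tract} termination densities")
    ax.tick_params(axis="x", labelsize=7)
    return ax


def asymmetry_barplot(asym: pd.DataFrame, tract: str = "", ax=None):
    """Mean asymmetry index per region; significant regions highlighted."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    tested = asym[asym.tested].sort_values("region")
    colors = ["tab:red" if s else "tab:gray" for s in tested.significant]
    ax.bar(tested.region, tested.mean_ai, color=colors)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel("asymmetry index (R−L)/(R+L)")
    if tract:
        ax.set_title(f"{tract} termination asymmetries")
    ax.tick_params(axis="x", rotation=45, labelsize=7)
    return ax


def save_report_figures(ntds: pd.DataFrame, asym: pd.DataFrame,
                        out_dir, tract: str = ""):
    """Write the two report figures for one tract into ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    ax = ntds_boxplot(ntds, tract)
    ax.figure.tight_layout()
    ax.figure.savefig(out / f"ntds_{tract or 'tract'}.png", dpi=120)
    plt.close(ax.figure)
    ax = asymmetry_barplot(asym, tract)
    ax.figure.tight_layout()
    ax.figure.savefig(out / f"asymmetry_{tract or 'tract'}.png", dpi=120)
    plt.close(ax.figure)
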