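"""Basic profile and fit plots (headless-safe; TSV stays canonical)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import dar
from .io_tables import AbundanceTable

__all__ = ["plot_profiles", "plot_pl_fit"]


def plot_profiles(tidy: pd.DataFrame, out_path) -> Path:
    """Bar panels of mean z, D_max and RIP versus grouping, one bar per q.

    ``tidy`` is the pipeline's tidy frame (one row per grouping x level
    x q).  Returns the written path.
    """
    panels = [("mean_z", "z"), ("mean_Dmax", "D_max"), ("mean_RIP", "RIP (%)")]
    tidy = tidy.copy()
    if tidy["taxon_level"].nunique() > 1:
        tidy["grouping"] = tidy["grouping"] + "/" + tidy["taxon_level"]
    qs = sorted(tidy["q"].unique())
    groups = list(dict.fromkeys(tidy["grouping"]))
    fig, axes = plt.subplots(1, 3, figsize=(4 * 3, 3.2))
    width = 0.8 / len(qs)
    x = np.arange(len(groups))
    for ax, (col, label) in zip(axes, panels):
        for k, q in enumerate(qs):
            sub = tidy[tidy["q"] == q].set_index("grouping")
            vals = [sub[col].get(g, np.nan) for g in groups]
            ax.bar(x + k * width, vals, width, label=f"q={q:g}")
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels(groups, rotation=60, fontsize=7)
        ax.set_ylabel(label)
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_pl_fit(
    table: AbundanceTable,
    site: str,
    q: float,
    out_path,
    seed: int | None = None,
) -> Path:
    """Log-log accrual scatter for one site with the fitted power-law line."""
    rng = np.random.default_rng(seed)
    ids = table.samples_at_site(site)
    order = [ids[i] for i in rng.permutation(len(ids))]
    curve = dar.accrual_curve(table, order, q)
    fit = dar.fit_pl(curve)
    fig, ax = plt.subplots(figsize=(4, 3.2))
    ax.plot(np.log(curve.areas), np.log(curve.diversities), "o", ms=3)
    if fit.success:
        xs = np.log(curve.areas)
        ax.plot(xs, fit.ln_c + fit.z * xs, "-", lw=1.2,
                label=f"z={fit.z:.3f}, c={fit.c:.1f}, R={fit.R:.3f}")
        ax.legend(fontsize=7)
    ax.set_xlabel("ln A (accumulated samples)")
    ax.set_ylabel(f"ln D (q={q:g})")
    ax.set_title(site, fontsize=9)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
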