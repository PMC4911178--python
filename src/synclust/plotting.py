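"""Rendering of simulation snapshots and sweep summaries."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .clustering import cluster_nuclei
from .simulate import SimState

__all__ = ["render_snapshot", "plot_sweep"]


def render_snapshot(
    state: SimState,
    path,
    shell_width: float = 0.05,
    x_window: Optional[tuple] = None,
    dpi: int = 150,
) -> None:
    """Draw the syncytium section: membranes plus cluster-coloured nuclei.

    Singleton nuclei are grey; nuclei in clusters (>= 2 connected) share a
    colour per cluster.  ``x_window`` restricts the view, e.g. ``(100, 150)``.
    """
    domain = state.domain
    xs = np.linspace(0.0, domain.length, 2000)
    upper = np.asarray(domain.height_at(xs), dtype=float)
    if upper.ndim == 0:
        upper = np.full_like(xs, float(upper))

    fig, ax = plt.subplots(figsize=(12, 2.2))
    ax.plot(xs, np.zeros_like(xs), color="k", lw=1)
    ax.plot(xs, upper, color="k", lw=1)

    n = state.n_nuclei
    if n:
        assignment = cluster_nuclei(state.positions, shell_width)
        cmap = plt.get_cmap("tab20")
        clustered_ids = [c for c in range(assignment.n_clusters)
                        if assignment.sizes[c] >= 2]
        colour_of = {c: cmap(i % 20) for i, c in enumerate(clustered_ids)}
        for i in range(n):
            c = assignment.labels[i]
            face = colour_of.get(c, (0.7, 0.7, 0.7, 1.0))
            ax.add_patch(
                plt.Circle(state.positions[i], 0.5, facecolor=face,
                           edgecolor="k", lw=0.3)
            )
    if x_window is not None:
        ax.set_xlim(*x_window)
    else:
        ax.set_xlim(0, domain.length)
    ax.set_ylim(-0.6, float(np.max(upper)) + 0.6)
    ax.set_aspect("equal")
    ax.set_xlabel("x (nuclear diameters)")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def plot_sweep(sweep_result, path, metric: str = "mean_cluster_size_weighted") -> None:
    """Aggregated metric vs parameter value with the 95% interval band."""
    agg = sweep_result.aggregate(metric)
    finite = np.isfinite(agg["value"].to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(
        agg.loc[finite, "value"],
        agg.loc[finite, "mean"],
        yerr=[
            agg.loc[finite, "mean"] - agg.loc[finite, "ci_lo"],
            agg.loc[finite, "ci_hi"] - agg.loc[finite, "mean"],
        ],
        marker="o",
        capsize=3,
    )
    ax.set_xlabel(sweep_result.spec.scenario)
    ax.set_ylabel(metric.replace("_", " "))
    if sweep_result.spec.scenario in ("adhesion", "diffusion", "fusion_sites"):
        ax.set_xscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
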