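"""Static figures: rarefaction curves and tanglegrams."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .openness import HeapsFit, RarefactionResult
from .trees import TanglegramResult


def rarefaction_plot(
    result: RarefactionResult,
    fit: Optional[HeapsFit] = None,
    path: Optional[str] = None,
):
    """Core and pan curves (median +/- one SD) with the optional fit."""
    fig, (ax_core, ax_pan) = plt.subplots(1, 2, figsize=(10, 4))
    ns = result.ns
    ax_core.errorbar(ns, result.core_median, yerr=result.core_sd, fmt="o-", ms=3)
    ax_core.set_xlabel("genomes included")
    ax_core.set_ylabel("core genes")
    ax_pan.errorbar(ns, result.pan_median, yerr=result.pan_sd, fmt="o-", ms=3)
    if fit is not None:
        grid = np.linspace(1, ns[-1], 200)
        ax_pan.plot(grid, fit.kappa * grid**fit.gamma, "r--",
                    label=f"{fit.kappa:.0f} n^{fit.gamma:.4f}")
        ax_pan.legend()
    ax_pan.set_xlabel("genomes included")
    ax_pan.set_ylabel("pan-genome size")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def tanglegram_plot(result: TanglegramResult, path: Optional[str] = None):
    """Side-by-side leaf orders with connectors (congruence at a glance)."""
    fig, ax = plt.subplots(figsize=(6, max(3, 0.25 * len(result.order1))))
    pos1 = {lab: i for i, lab in enumerate(result.order1)}
    pos2 = {lab: i for i, lab in enumerate(result.order2)}
    for lab in result.order1:
        ax.plot([0, 1], [pos1[lab], pos2[lab]], "-", color="steelblue", lw=0.8)
        ax.text(-0.02, pos1[lab], lab, ha="right", va="center", fontsize=7)
        ax.text(1.02, pos2[lab], lab, ha="left", va="center", fontsize=7)
    ax.set_xlim(-0.4, 1.4)
    ax.axis("off")
    ax.set_title(
        f"crossings={result.crossings}  entanglement={result.entanglement:.3f}  "
        f"RF={result.rf_distance:.3f}",
        fontsize=9,
    )
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
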