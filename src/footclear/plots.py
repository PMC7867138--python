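"""Minimal diagnostic figures: Bland-Altman and stride trajectory."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import BlandAltman
from .trajectory import Stride


def bland_altman_plot(stats: BlandAltman, path: str | Path) -> None:
    """Scatter of pairwise differences vs means with bias and limits."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(stats.means, stats.diffs, s=12, alpha=0.6)
    for y, style in ((stats.bias, "-"), (stats.loa_lower, "--"),
                     (stats.loa_upper, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("Mean of paired MFC estimates (mm)")
    ax.set_ylabel("Difference (mm)")
    ax.set_title("Inter-rater agreement")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def trajectory_plot(stride: Stride, path: str | Path) -> None:
    """Raw clearance samples with the fitted quintic overlaid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    x = stride.frame_indices
    ax.plot(x, stride.clearances, "-", label="lowest-point clearance")
    if stride.poly is not None:
        xf = np.linspace(x[0], x[-1], 200)
        ax.plot(xf, stride.poly(xf), ":", label="quintic fit")
    ax.set_xlabel("Frame")
    ax.set_ylabel("Clearance (px)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
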