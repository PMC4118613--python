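"""LR-profile plotting: one track per linkage group with the FDR line."""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")  # headless-safe; figures are written, not shown
import matplotlib.pyplot as plt

from .scan import ScanResult

__all__ = ["plot_lr_profile"]

#: marker colors by class count, as in the study's figures
_COLORS = {4: "tab:red", 3: "tab:blue", 2: "tab:green"}


def plot_lr_profile(scan: ScanResult, path: os.PathLike | str) -> None:
    """Render the per-group LR tracks of a scan with its threshold line.

    Markers are colored by the number of genotype classes (red = 4,
    blue = 3, green = 2); the horizontal line is the genome-wide FDR
    threshold (minimum LR among BH-rejected markers), drawn only when at
    least one marker is significant.
    """
    groups = sorted({r.marker.linkage_group for r in scan.rows})
    fig, axes = plt.subplots(
        1, len(groups), figsize=(2.2 * len(groups), 2.8),
        sharey=True, squeeze=False,
    )
    for ax, g in zip(axes[0], groups):
        rows = [r for r in scan.rows if r.marker.linkage_group == g]
        ax.plot(
            [r.marker.position_cm for r in rows],
            [r.lr for r in rows],
            color="0.6", lw=0.8, zorder=1,
        )
        for r in rows:
            ax.scatter(
                r.marker.position_cm, r.lr, s=8, zorder=2,
                color=_COLORS[r.marker.seg_type.n_classes],
            )
        if scan.threshold_lr is not None:
            ax.axhline(scan.threshold_lr, color="k", lw=0.8, ls="--")
        ax.set_title(f"LG{g}", fontsize=9)
        ax.set_xlabel("cM", fontsize=8)
    axes[0][0].set_ylabel("LR")
    fig.suptitle(scan.trait)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
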