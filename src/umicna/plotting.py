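"""Copy-number profile plot: per-region log-ratios, segment means, calls."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

_STATUS_COLORS = {"gain": "#1f62b4", "loss": "#c23b22", "normal": "#555555", "untested": "#999999"}


def plot_profile(profile, calls, path: str | Path, title: str | None = None) -> Path:
    """Plot log-ratios by panel index with segment means and gene boundaries.

    Regions are points ordered by panel index; each segment is a
    horizontal bar at its weighted mean, blue for significant gains and
    red for significant losses; vertical lines mark gene boundaries with
    gene labels along the bottom.
    """
    path = Path(path)
    panel = profile.panel
    P = panel.n_regions
    x = np.arange(P)

    fig, ax = plt.subplots(figsize=(max(8, P / 25), 4.5))
    finite = np.isfinite(profile.l)
    ax.scatter(x[finite], profile.l[finite], s=8, c="#bbbbbb", zorder=1, label="region log-ratio")

    pos = {p: i for i, p in enumerate(x)}
    for call in calls:
        seg = call.segment
        xs = [seg.region_indices[0] - 0.4, seg.region_indices[-1] + 0.4]
        ax.plot(
            xs,
            [seg.mean, seg.mean],
            lw=2.5,
            color=_STATUS_COLORS.get(call.status, "#555555"),
            zorder=3,
        )

    ax.axhline(0.0, color="black", lw=0.6, zorder=2)
    ymin, ymax = ax.get_ylim()
    for block in panel.blocks:
        ax.axvline(block.start - 0.5, color="#dddddd", lw=0.6, zorder=0)
        ax.text(
            (block.start + block.stop - 1) / 2,
            ymin + 0.02 * (ymax - ymin),
            block.label,
            rotation=90,
            ha="center",
            va="bottom",
            fontsize=6,
            color="#333333",
        )
    ax.set_xlabel("targeted region (panel order)")
    ax.set_ylabel("log2 ratio (UMI depth)")
    ax.set_title(title or profile.sample_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
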