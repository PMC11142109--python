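"""Conservation plotting: binned stacked-bar tracks.

The query window's k-mer starts are partitioned into contiguous,
near-equal bins; within each bin the stacked bar shows, per conservation
level, the fraction of k-mer starts conserved at that level.  Following
the usual convention for such tracks, the fully conserved level (present
in every genome) is left as white space above the stack, so deeply
conserved regions read as mostly-white columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .query_engine import ConservationResult

__all__ = ["PlotSpec", "bin_conservation", "render_plot"]


@dataclass(frozen=True)
class PlotSpec:
    out_path: str
    n_bins: int
    title: str = ""
    mode: str = "full"  # or "quantile"

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


def bin_conservation(
    result: ConservationResult, n_bins: int, t: int
) -> list[dict[int, float]]:
    """Per-bin fractions of k-mer starts at each conservation level.

    Starts are split into ``n_bins`` contiguous near-equal bins; each
    returned dict maps conservation level -> fraction of that bin's
    starts, summing to 1 per bin.  ``t`` is the total genome count, the
    highest possible level when the pivot is included.
    """
    counts = np.asarray(result.counts)
    if counts.size == 0:
        raise ValueError("no conservation values to bin")
    if n_bins > counts.size:
        raise ValueError(f"n_bins={n_bins} exceeds number of k-mer starts {counts.size}")
    if counts.max() > t:
        raise ValueError("conservation level exceeds genome count t")
    bins = np.array_split(counts, n_bins)
    out = []
    for chunk in bins:
        levels, freq = np.unique(chunk, return_counts=True)
        out.append({int(l): f / chunk.size for l, f in zip(levels, freq)})
    return out


def render_plot(
    binned: list[dict[int, float]], spec: PlotSpec, t: int
) -> str:
    """Render the stacked-bar conservation plot to ``spec.out_path``.

    Levels below ``t`` are stacked bottom-up from least to most conserved;
    the white area above each stack is the fraction conserved across all
    ``t`` genomes.
    """
    for frac_map in binned:
        vals = np.array(list(frac_map.values()), dtype=float)
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("binned fractions must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("binned fractions must sum to 1 per bin")
    levels = sorted({l for fm in binned for l in fm if l < t})
    n_bins = len(binned)
    x = np.arange(n_bins)
    cmap = plt.get_cmap("viridis")
    fig, ax = plt.subplots(figsize=(max(4, n_bins * 0.08), 3.2))
    bottom = np.zeros(n_bins)
    for idx, level in enumerate(levels):
        heights = np.array([fm.get(level, 0.0) for fm in binned])
        color = cmap(idx / max(1, len(levels) - 1)) if len(levels) > 1 else cmap(0.5)
        ax.bar(x, heights, bottom=bottom, width=1.0, color=color,
               label=str(level), edgecolor="none")
        bottom += heights
    ax.set_xlim(-0.5, n_bins - 0.5)
    ax.set_ylim(0, 1)
    ax.set_xlabel("bin (query window, left to right)")
    ax.set_ylabel("fraction of k-mer starts")
    if spec.title:
        ax.set_title(spec.title)
    if levels:
        ax.legend(title="conservation", fontsize="x-small", ncols=2, loc="upper right")
    fig.tight_layout()
    fig.savefig(spec.out_path, dpi=120)
    plt.close(fig)
    return spec.out_path
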