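"""Genome-wide SV density plots and per-region SV/gene track plots.

Chromosomes are tiled with fixed-size windows and each SV is counted in
exactly one window — the one containing its midpoint — so per-type window
sums always equal the input SV counts.  The genome view draws one ring
(circular) or panel row (linear) per SV type; colors default to blue
deletions, red duplications, green inversions.  Region plots show gene
elements (blue) above deletion (red) and duplication (green) tracks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Rectangle

from .core import DataError, SV_TYPES
from .annotate import GeneElement
from .merge import MergedSV

__all__ = ["WindowCounts", "window_counts", "plot_genome", "plot_region",
           "TYPE_COLORS"]

TYPE_COLORS = {"del": "#1f77cc", "dup": "#cc3333", "inv": "#2ca02c"}

# deterministic SVG output: content-derived element ids, no creation date
matplotlib.rcParams["svg.hashsalt"] = "svmeld"


@dataclass(slots=True)
class WindowCounts:
    chrom: str
    window_start: int  # 1-based inclusive
    window_end: int
    counts: dict[str, int]


def window_counts(
    merged: dict[str, list[MergedSV]],
    chrom_sizes: dict[str, int],
    window: int = 1_000_000,
) -> list[WindowCounts]:
    """Count SVs per tiling window, assigning each SV to the window that
    contains its midpoint.  The last window is truncated at the chromosome
    end.  SVs on chromosomes absent from ``chrom_sizes`` are a hard error.
    """
    if window <= 0:
        raise DataError("window size must be positive")
    unknown = sorted({
        m.chrom for t in merged for m in merged[t] if m.chrom not in chrom_sizes
    })
    if unknown:
        raise DataError(f"SVs on chromosomes missing from sizes: {unknown}")

    windows: list[WindowCounts] = []
    index: dict[tuple[str, int], WindowCounts] = {}
    for chrom, length in chrom_sizes.items():
        n_win = (length + window - 1) // window
        for k in range(n_win):
            wc = WindowCounts(chrom, k * window + 1,
                              min((k + 1) * window, length),
                              {t: 0 for t in SV_TYPES})
            windows.append(wc)
            index[(chrom, k)] = wc

    for sv_type, svs in merged.items():
        for m in svs:
            mid = (m.pos1 + m.pos2) // 2
            mid = min(max(mid, 1), chrom_sizes[m.chrom])
            index[(m.chrom, (mid - 1) // window)].counts[sv_type] += 1
    return windows


def _order_chroms(windows: list[WindowCounts]) -> list[str]:
    seen: list[str] = []
    for w in windows:
        if w.chrom not in seen:
            seen.append(w.chrom)
    return seen


def plot_genome(
    windows: list[WindowCounts],
    style: str = "circular",
    out: str | Path = "genome.svg",
) -> Path:
    """Render windowed SV counts genome-wide; returns the output path."""
    if not windows:
        raise DataError("no windows to plot")
    if style == "circular":
        fig = _plot_genome_circular(windows)
    elif style == "linear":
        fig = _plot_genome_linear(windows)
    else:
        raise DataError(f"unknown genome plot style {style!r}")
    out = Path(out)
    fig.savefig(out, metadata=_metadata(out))
    plt.close(fig)
    return out


def _metadata(out: Path) -> dict | None:
    if out.suffix.lower() == ".svg":
        return {"Date": None}
    return None


def _genome_layout(windows: list[WindowCounts]):
    chroms = _order_chroms(windows)
    sizes = {c: max(w.window_end for w in windows if w.chrom == c)
             for c in chroms}
    gap = 0.02 * sum(sizes.values())
    offsets, cum = {}, 0.0
    for c in chroms:
        offsets[c] = cum
        cum += sizes[c] + gap
    return chroms, sizes, offsets, cum


def _plot_genome_circular(windows: list[WindowCounts]):
    chroms, sizes, offsets, total = _genome_layout(windows)
    fig = plt.figure(figsize=(8, 8))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_axis_off()
    max_count = max((w.counts[t] for w in windows for t in SV_TYPES), default=0)
    scale = 0.16 / max(max_count, 1)
    radii = {"del": 1.0, "dup": 0.78, "inv": 0.56}
    for w in windows:
        theta = 2 * np.pi * (offsets[w.chrom] +
                             (w.window_start + w.window_end) / 2) / total
        width = 2 * np.pi * (w.window_end - w.window_start + 1) / total
        for t in SV_TYPES:
            if w.counts[t]:
                ax.bar(theta, w.counts[t] * scale, width=width,
                       bottom=radii[t], color=TYPE_COLORS[t],
                       edgecolor="none", align="center")
    for c in chroms:
        span = np.linspace(
            2 * np.pi * offsets[c] / total,
            2 * np.pi * (offsets[c] + sizes[c]) / total, 50)
        ax.plot(span, np.full_like(span, 0.52), color="0.3", lw=2)
        mid = 2 * np.pi * (offsets[c] + sizes[c] / 2) / total
        ax.text(mid, 0.42, c, ha="center", va="center", fontsize=8)
    ax.set_rlim(0, 1.2)
    _legend(fig)
    return fig


def _plot_genome_linear(windows: list[WindowCounts]):
    chroms, sizes, _, _ = _genome_layout(windows)
    fig, axes = plt.subplots(len(chroms), 1,
                             figsize=(10, 1.4 * len(chroms) + 1),
                             squeeze=False, sharex=True)
    max_count = max((w.counts[t] for w in windows for t in SV_TYPES), default=1)
    for ax, chrom in zip(axes[:, 0], chroms):
        ws = [w for w in windows if w.chrom == chrom]
        for w in ws:
            x = w.window_start
            width = w.window_end - w.window_start + 1
            for i, t in enumerate(SV_TYPES):
                if w.counts[t]:
                    ax.bar(x + i * width / 3, w.counts[t], width=width / 3,
                           align="edge", color=TYPE_COLORS[t])
        ax.set_ylim(0, max(max_count, 1) * 1.1)
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center", fontsize=8)
        ax.spines[["top", "right"]].set_visible(False)
    axes[-1, 0].set_xlabel("position (bp)")
    _legend(fig)
    fig.tight_layout()
    return fig


def _legend(fig) -> None:
    handles = [Rectangle((0, 0), 1, 1, color=TYPE_COLORS[t]) for t in SV_TYPES]
    labels = ["deletion", "duplication", "inversion"]
    fig.legend(handles, labels, loc="lower center", ncol=3, frameon=False)


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive)."""
    try:
        chrom, rng = region.rsplit(":", 1)
        start_s, end_s = rng.split("-", 1)
        start, end = int(start_s.replace(",", "")), int(end_s.replace(",", ""))
    except ValueError as exc:
        raise DataError(f"malformed region {region!r}; "
                        "expected chrom:start-end") from exc
    if start >= end:
        raise DataError(f"region {region!r}: start must be < end")
    return chrom, start, end


def plot_region(
    merged: dict[str, list[MergedSV]],
    elements: list[GeneElement],
    region: str,
    out: str | Path = "region.svg",
    known_chroms: set[str] | None = None,
) -> Path:
    """Render gene elements and SVs inside a region as stacked tracks.

    Features partially overlapping the region boundary are clipped to it,
    not dropped.
    """
    chrom, start, end = parse_region(region)
    if known_chroms is not None and chrom not in known_chroms:
        raise DataError(f"region chromosome {chrom!r} not in genome")

    fig, ax = plt.subplots(figsize=(10, 3.2))
    tracks = [
        ("genes", "#1f77cc",
         [(e.start, e.end, e.id) for e in elements
          if e.chrom == chrom and e.tag == "gene"
          and e.start <= end and e.end >= start]),
        ("deletions", "#cc3333",
         [(m.pos1, m.pos2, m.methods) for m in merged.get("del", [])
          if m.chrom == chrom and m.pos1 <= end and m.pos2 >= start]),
        ("duplications", "#2ca02c",
         [(m.pos1, m.pos2, m.methods) for m in merged.get("dup", [])
          if m.chrom == chrom and m.pos1 <= end and m.pos2 >= start]),
        ("inversions", "#9467bd",
         [(m.pos1, m.pos2, m.methods) for m in merged.get("inv", [])
          if m.chrom == chrom and m.pos1 <= end and m.pos2 >= start]),
    ]
    for level, (label, color, feats) in enumerate(tracks):
        y = len(tracks) - 1 - level
        for s, e, name in sorted(feats):
            s_c, e_c = max(s, start), min(e, end)  # clip to the region
            ax.add_patch(Rectangle((s_c, y + 0.2), max(e_c - s_c + 1, 1), 0.6,
                                   facecolor=color, edgecolor="black", lw=0.3))
            ax.text((s_c + e_c) / 2, y + 0.85, name, ha="center",
                    fontsize=6, clip_on=True)
        ax.text(start, y + 0.5, label + "  ", ha="right", va="center",
                fontsize=8)
    ax.set_xlim(start, end)
    ax.set_ylim(0, len(tracks) + 0.2)
    ax.set_yticks([])
    ax.set_xlabel(f"{chrom} (bp)")
    ax.spines[["top", "right", "left"]].set_visible(False)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, metadata=_metadata(out))
    plt.close(fig)
    return out
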