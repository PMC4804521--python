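"""Metagene-style binned feature profiles across loops and their flanks.

Each loop is extended by an equal-sized region on both flanks and the
3x-length window is split into 30 contiguous bins, each spanning 10% of the
loop length (bins 1-10 left flank, 11-20 loop body, 21-30 right flank).
Feature counts per bin are normalised into FPKM (features per kilobase per
million features) to cancel bin-size and library-size differences, the
median FPKM across loops is taken per bin, and profiles are optionally
mean-centred on zero so marks with different baseline densities can share a
plot.  Because the per-bin statistic is a median, a bin scores above zero
only when the feature occurs there in at least half the surveyed loops.
Variance is never normalised: amplitude differences between features are
part of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .genomic_core import (
    ChromSizes,
    ExperimentalLoop,
    GenomicInterval,
    build_interval_trees,
)
from .loop_prediction import PredictedLoop

__all__ = [
    "BinGrid",
    "Profile",
    "make_profile_bins",
    "bin_fpkm",
    "feature_profile",
    "loop_body",
]


@dataclass(frozen=True)
class BinGrid:
    """Contiguous bins tiling a loop's [start - L, end + L) window exactly."""

    chrom: str
    bins: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.bins, self.bins[1:]):
            if e1 != s2:
                raise ValueError("bins must be contiguous")


@dataclass
class Profile:
    """Per-bin median FPKM across loops, optionally mean-centred."""

    bin_values: np.ndarray
    n_loops_used: int
    n_loops_rejected: int
    normalized: bool
    feature_label: str = "feature"


def loop_body(
    loop: Union[GenomicInterval, PredictedLoop, ExperimentalLoop]
) -> GenomicInterval:
    """Reduce any loop representation to its body interval (anchor to anchor)."""
    if isinstance(loop, GenomicInterval):
        return loop
    if isinstance(loop, PredictedLoop):
        return GenomicInterval(loop.chrom, loop.start, loop.end)
    if isinstance(loop, ExperimentalLoop):
        return GenomicInterval(loop.chrom, loop.anchor1.start, loop.anchor2.end)
    raise TypeError(f"cannot interpret {type(loop).__name__} as a loop body")


def make_profile_bins(
    loop_interval: GenomicInterval,
    chrom_sizes: ChromSizes,
    n_bins: int = 30,
) -> Optional[BinGrid]:
    """Bin grid over the loop plus equal-size flanks, or ``None`` when the
    extended window would run past a chromosome end (such loops are dropped
    from profiling).

    ``n_bins`` must be divisible by 3 so the flanks and body get equal bin
    counts.  Window lengths not divisible by ``n_bins`` use largest-remainder
    allocation: bin widths differ by at most 1 bp and tile the window
    exactly.
    """
    if n_bins < 3 or n_bins % 3:
        raise ValueError("n_bins must be a positive multiple of 3")
    chrom_length = chrom_sizes[loop_interval.chrom]
    L = loop_interval.length
    window_start = loop_interval.start - L
    window_end = loop_interval.end + L
    if window_start < 0 or window_end > chrom_length:
        return None
    width = window_end - window_start
    base, extra = divmod(width, n_bins)
    bins = []
    pos = window_start
    for i in range(n_bins):
        w = base + (1 if i < extra else 0)
        bins.append((pos, pos + w))
        pos += w
    return BinGrid(loop_interval.chrom, tuple(bins))


def bin_fpkm(feature_count: float, bin_length_bp: int, total_features: int) -> float:
    """Features per kilobase (of bin) per million features (in the track)."""
    if bin_length_bp <= 0:
        raise ValueError("bin_length_bp must be > 0")
    if total_features <= 0:
        raise ValueError("total_features must be > 0")
    return feature_count / (bin_length_bp / 1000.0) / (total_features / 1e6)


def feature_profile(
    loops: Sequence[Union[GenomicInterval, PredictedLoop, ExperimentalLoop]],
    features: Sequence[GenomicInterval],
    chrom_sizes: ChromSizes,
    n_bins: int = 30,
    center: bool = True,
    feature_label: str = "feature",
) -> Profile:
    """Median-FPKM profile of a feature track across loops and flanks.

    A feature counts in every bin it overlaps by >= 1 bp (an interval
    spanning several bins contributes once per bin).  ``features`` may be
    ChIP-seq reads reduced to aligned-span intervals, exons, genes or
    chromatin-state segments; ``total_features`` in the FPKM normalisation
    is the full track size.  Raises when no loop survives the chromosome-end
    filter.
    """
    bodies = [loop_body(l) for l in loops]
    grids = [make_profile_bins(b, chrom_sizes, n_bins) for b in bodies]
    accepted = [g for g in grids if g is not None]
    n_rejected = len(grids) - len(accepted)
    if not accepted:
        raise ValueError("no loops left after chromosome-end filtering")
    total = len(features)
    if total == 0:
        raise ValueError("empty feature track")
    trees = build_interval_trees(features)
    fpkm = np.empty((len(accepted), n_bins))
    for row, grid in enumerate(accepted):
        tree = trees.get(grid.chrom)
        for col, (start, end) in enumerate(grid.bins):
            count = len(tree.overlap(start, end)) if tree is not None else 0
            fpkm[row, col] = bin_fpkm(count, end - start, total)
    values = np.median(fpkm, axis=0)
    if center:
        values = values - values.mean()
    return Profile(values, len(accepted), n_rejected, center, feature_label)
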