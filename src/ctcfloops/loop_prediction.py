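"""Directional loop prediction from oriented CTCF anchors.

The predictor exploits the convergence of CTCF motifs at loop anchors: the
motif at the 5' anchor lies on the + strand and the motif at the 3' anchor
on the - strand, both pointing into the loop body.  A single left-to-right
scan over peak-contained motifs therefore opens candidate loops at + motifs
and closes them at - motifs:

* a + motif while no end anchors are pending joins the current start list;
* a + motif encountered after one or more - motifs first emits every
  (start x end) pair as a predicted loop, then starts a fresh episode seeded
  with itself (both lists are cleared: retaining stale end anchors would
  allow loops that end before they start);
* a - motif joins the current end list;
* the chromosome end flushes the final (start x end) block.

One pass cannot see nested loops, so the scan is repeated while stripping
progressively larger fractions of the weakest ChIP-seq peaks (default: 10%
steps up to 60%).  Stronger peaks are more likely to engage in real
interactions, so removing weak inner anchors lets the scan connect the
stronger outer anchors that enclose them; the union over all thresholds
recovers nested loop hierarchies.  Only the forward scan is performed - the
reverse scan provably yields the same pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .genomic_core import Peak
from .motif_anchors import Anchor, loop_score

__all__ = [
    "PredictedLoop",
    "ThresholdSchedule",
    "scan_chromosome",
    "apply_peak_threshold",
    "predict_loops",
    "select_top_loops",
    "loop_length",
]


@dataclass(frozen=True)
class PredictedLoop:
    """A convergent anchor pair predicted by the scan.

    ``discovery_threshold`` records the smallest peak-removal fraction at
    which the loop first appeared; scores never depend on the threshold
    because anchor scores are fixed.
    """

    start_anchor: Anchor
    end_anchor: Anchor
    score: float
    discovery_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.start_anchor.strand != "+":
            raise ValueError("start anchor motif must be on the + strand")
        if self.end_anchor.strand != "-":
            raise ValueError("end anchor motif must be on the - strand")
        if self.start_anchor.chrom != self.end_anchor.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.start_anchor.position >= self.end_anchor.position:
            raise ValueError("start anchor must precede end anchor")
        if self.score < 0:
            raise ValueError("loop score must be >= 0")

    @property
    def chrom(self) -> str:
        return self.start_anchor.chrom

    @property
    def start(self) -> int:
        """Start of the 5' anchor motif."""
        return self.start_anchor.motif.interval.start

    @property
    def end(self) -> int:
        """End of the 3' anchor motif."""
        return self.end_anchor.motif.interval.end

    def key(self) -> tuple:
        """Deduplication key over motif coordinates + strands (motifs are
        stable across datasets while peaks shrink and merge)."""
        m1, m2 = self.start_anchor.motif.interval, self.end_anchor.motif.interval
        return (m1.chrom, m1.start, m1.end, m1.strand, m2.start, m2.end, m2.strand)


def loop_length(loop: PredictedLoop) -> int:
    """Loop span between the inner motif edges (end motif start minus start
    motif end)."""
    return loop.end_anchor.motif.interval.start - loop.start_anchor.motif.interval.end


@dataclass(frozen=True)
class ThresholdSchedule:
    """Iterative peak-removal schedule.

    ``increment`` and ``final`` are fractions of the total peak count removed
    per pass (proportion mode, the default) or score quantile equivalents
    (score mode); defaults are 10% steps up to a 60% final threshold.
    """

    increment: float = 0.10
    final: float = 0.60
    mode: str = "proportion"

    def __post_init__(self) -> None:
        if not (0 <= self.increment < 1 and 0 <= self.final < 1):
            raise ValueError("increment and final must lie in [0, 1)")
        if self.final and self.increment > self.final:
            raise ValueError("increment cannot exceed a non-zero final threshold")
        if self.mode not in ("proportion", "score"):
            raise ValueError("mode must be 'proportion' or 'score'")

    def thresholds(self) -> list[float]:
        if self.increment == 0:
            return [0.0]
        out = [0.0]
        k = 1
        while self.increment * k <= self.final + 1e-9:
            out.append(round(self.increment * k, 10))
            k += 1
        return out


def scan_chromosome(
    anchors: Sequence[Anchor], discovery_threshold: float = 0.0
) -> list[PredictedLoop]:
    """Single forward scan over position-sorted anchors of one chromosome.

    Raises if the anchors are unsorted or span several chromosomes rather
    than silently fixing the input, so the scan stays auditable.
    """
    if not anchors:
        return []
    chroms = {a.chrom for a in anchors}
    if len(chroms) > 1:
        raise ValueError(f"anchors span multiple chromosomes: {sorted(chroms)}")
    positions = [a.position for a in anchors]
    if positions != sorted(positions):
        raise ValueError("anchors must be sorted by motif start position")

    loops: list[PredictedLoop] = []
    starts: list[Anchor] = []
    ends: list[Anchor] = []

    def flush() -> None:
        for s in starts:
            for e in ends:
                loops.append(
                    PredictedLoop(s, e, loop_score(s, e), discovery_threshold)
                )

    for anchor in anchors:
        if anchor.strand == "+":
            if ends:
                flush()
                starts = [anchor]
                ends = []
            else:
                starts.append(anchor)
        else:
            ends.append(anchor)
    flush()
    return loops


def _peak_key(peak: Peak) -> tuple:
    return (peak.interval.chrom, peak.interval.start, peak.interval.end, peak.score)


def apply_peak_threshold(
    anchors: Sequence[Anchor],
    fraction_removed: float,
    peaks: Optional[Sequence[Peak]] = None,
) -> list[Anchor]:
    """Drop anchors whose peaks fall in the weakest ``fraction_removed``.

    The lowest-scoring ``floor(fraction * n_peaks)`` peaks are removed, ranked
    by score ascending with ties broken by (chrom, start) ascending (the
    lower coordinate is removed first).  ``peaks`` defaults to the distinct
    peaks referenced by the anchors, but the full ChIP-seq peak set (including
    motif-less peaks) may be supplied so the fraction refers to the total
    peak count.
    """
    if not 0 <= fraction_removed < 1:
        raise ValueError("fraction_removed must be in [0, 1)")
    if peaks is None:
        seen: dict[tuple, Peak] = {}
        for a in anchors:
            seen.setdefault(_peak_key(a.peak), a.peak)
        universe = list(seen.values())
    else:
        universe = list(peaks)
    n_remove = math.floor(fraction_removed * len(universe))
    if n_remove == 0:
        return list(anchors)
    ranked = sorted(
        universe, key=lambda p: (p.score, p.interval.chrom, p.interval.start)
    )
    removed = {_peak_key(p) for p in ranked[:n_remove]}
    return [a for a in anchors if _peak_key(a.peak) not in removed]


def _score_cutoffs(peaks: Sequence[Peak], schedule: ThresholdSchedule) -> list[float]:
    """Score-mode equivalents of the proportion thresholds (score quantiles)."""
    ranked = sorted(peaks, key=lambda p: p.score)
    cutoffs = []
    for frac in schedule.thresholds():
        k = math.floor(frac * len(ranked))
        cutoffs.append(-math.inf if k == 0 else ranked[k - 1].score)
    return cutoffs


def predict_loops(
    anchors: Sequence[Anchor],
    schedule: Optional[ThresholdSchedule] = None,
    peaks: Optional[Sequence[Peak]] = None,
) -> list[PredictedLoop]:
    """Run the scan at every threshold of the schedule and merge the results.

    Loops are deduplicated on motif coordinates + strands; each retained loop
    records the smallest peak-removal fraction at which it was produced.
    Output is sorted by (chrom, start motif, end motif).
    """
    schedule = schedule or ThresholdSchedule()
    if not anchors:
        return []
    merged: dict[tuple, PredictedLoop] = {}
    if schedule.mode == "score" and peaks is not None:
        cutoffs = _score_cutoffs(peaks, schedule)
    else:
        cutoffs = None
    for i, frac in enumerate(schedule.thresholds()):
        if cutoffs is None:
            retained = apply_peak_threshold(anchors, frac, peaks)
        else:
            retained = [a for a in anchors if a.peak.score > cutoffs[i]]
        by_chrom: dict[str, list[Anchor]] = {}
        for a in retained:
            by_chrom.setdefault(a.chrom, []).append(a)
        for chrom in by_chrom:
            chrom_anchors = sorted(by_chrom[chrom], key=lambda a: a.position)
            for loop in scan_chromosome(chrom_anchors, discovery_threshold=frac):
                merged.setdefault(loop.key(), loop)
    return sorted(merged.values(), key=lambda l: (l.chrom, l.start, l.end))


def select_top_loops(
    loops: Sequence[PredictedLoop],
    top_fraction: float = 0.05,
    max_length: int = 1_000_000,
) -> list[PredictedLoop]:
    """Stringent high-confidence subset: gate to loops shorter than
    ``max_length`` (inner motif edges), then keep the top ``top_fraction``
    by score (ties broken by chrom, then start, genomically first wins).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    gated = [l for l in loops if loop_length(l) < max_length]
    if not gated:
        return []
    ranked = sorted(gated, key=lambda l: (-l.score, l.chrom, l.start))
    n_keep = math.ceil(top_fraction * len(gated))
    return ranked[:n_keep]


def write_predicted_bedpe(loops: Sequence[PredictedLoop], path) -> None:
    """Write predictions as BEDPE: anchors are the two motif intervals, the
    score column carries the loop score, followed by the motif strands, the
    discovery threshold and the loop length."""
    with open(path, "w") as out:
        for i, l in enumerate(loops, start=1):
            m1, m2 = l.start_anchor.motif.interval, l.end_anchor.motif.interval
            out.write(
                f"{m1.chrom}\t{m1.start}\t{m1.end}\t{m2.chrom}\t{m2.start}\t{m2.end}"
                f"\tpredicted_loop_{i}\t{l.score:.4f}\t{m1.strand}\t{m2.strand}"
                f"\t{l.discovery_threshold:.2f}\t{loop_length(l)}\n"
            )
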