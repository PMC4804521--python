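"""CTCF motif handling: PWM scanning, motif-in-peak anchors and loop scores.

A loop anchor is a CTCF motif fully contained in a ChIP-seq peak.  Because
CTCF binding strength varies between cell types at the same site while the
motif match is static, the anchor strength weights the experimentally
measured peak score tenfold more than the motif score::

    anchor_score = peak_score * (motif_score / 10)

and a candidate loop between two anchors is scored with the geometric mean
of the two anchor scores (less outlier-sensitive than the arithmetic mean).

A simple log-odds PWM scanner is included as plumbing so the toolkit can run
from FASTA + a JASPAR-style matrix without an external motif caller; motif
hits produced by external scanners are equally accepted as BED6 (motif score
in the score column).  Motif scores are treated as caller-supplied and
dimension-free.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio import motifs as bio_motifs

from .genomic_core import (
    BedRecord,
    GenomicInterval,
    Peak,
    build_interval_trees,
)

__all__ = [
    "PWM",
    "MotifHit",
    "Anchor",
    "scan_pwm",
    "assign_motifs_to_peaks",
    "loop_score",
    "motifs_from_bed",
    "motifs_to_bed",
]

_ALPHABET = "ACGT"
_ENCODE = {c: i for i, c in enumerate(_ALPHABET)}


@dataclass(frozen=True)
class PWM:
    """Position weight matrix over {A, C, G, T}.

    ``probs`` holds per-position letter probabilities (shape L x 4, columns
    in ACGT order), already pseudocount-regularised so each row sums to 1.
    ``background`` is the base composition used for log-odds scoring
    (uniform by default, matching a caller-agnostic null).
    """

    probs: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must have shape (L, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        pseudocount: float = 0.01,
        background: Optional[Sequence[float]] = None,
    ) -> "PWM":
        """Build a PWM from a count (or frequency) matrix, shape L x 4."""
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must have shape (L, 4)")
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        reg = counts + pseudocount
        probs = reg / reg.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(probs, bg, pseudocount)

    @classmethod
    def from_jaspar(
        cls,
        source: Union[str, Path],
        pseudocount: float = 0.01,
        background: Optional[Sequence[float]] = None,
    ) -> "PWM":
        """Read a JASPAR pfm file (4 rows of counts, optional '>' header)."""
        text = Path(source).read_text()
        fmt = "jaspar" if text.lstrip().startswith(">") else "pfm"
        motif = bio_motifs.read(io.StringIO(text), fmt)
        counts = np.array([motif.counts[base] for base in _ALPHABET]).T
        return cls.from_counts(counts, pseudocount, background)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """Per-position log2-odds scores against the background (L x 4)."""
        return np.log2(self.probs / self.background)

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.probs.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    def score_distribution(self, granularity: float = 1e-3) -> dict[float, float]:
        """Exact distribution of the log-odds score under the background
        model, by dynamic-programming convolution of the per-position score
        distributions (scores rounded to ``granularity``).
        """
        lo = self.log_odds
        dist: dict[int, float] = {0: 1.0}
        for pos in range(self.length):
            nxt: dict[int, float] = {}
            for key, prob in dist.items():
                for letter in range(4):
                    k = key + round(lo[pos, letter] / granularity)
                    nxt[k] = nxt.get(k, 0.0) + prob * self.background[letter]
            dist = nxt
        return {k * granularity: v for k, v in dist.items()}

    def score_cutoff(self, p_value: float, granularity: float = 1e-3) -> float:
        """Smallest score whose background tail probability is <= ``p_value``.

        Converts a match p-value threshold into a log-odds score cutoff; hits
        scoring >= the returned value occur with probability <= p under the
        background model.
        """
        if not 0 < p_value <= 1:
            raise ValueError("p_value must be in (0, 1]")
        dist = self.score_distribution(granularity)
        tail = 0.0
        cutoff = math.inf
        for score in sorted(dist, reverse=True):
            tail += dist[score]
            if tail > p_value:
                break
            cutoff = score
        return cutoff


@dataclass(frozen=True)
class MotifHit:
    """A stranded, scored motif occurrence (forward-strand coordinates)."""

    interval: GenomicInterval
    motif_score: float
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("motif hits must be stranded (+ or -)")
        if not math.isfinite(self.motif_score):
            raise ValueError("motif_score must be finite")

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class Anchor:
    """A peak-contained motif with the combined anchor strength.

    ``anchor_score`` is computed as ``peak.score * (motif.motif_score / 10)``
    when not given explicitly.
    """

    motif: MotifHit
    peak: Peak
    anchor_score: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.peak.interval.contains(self.motif.interval):
            raise ValueError("anchor motif must be fully contained in its peak")
        if self.anchor_score is None:
            object.__setattr__(
                self, "anchor_score", self.peak.score * (self.motif.motif_score / 10.0)
            )

    @property
    def chrom(self) -> str:
        return self.motif.interval.chrom

    @property
    def strand(self) -> str:
        return self.motif.strand

    @property
    def position(self) -> int:
        return self.motif.interval.start


# ---------------------------------------------------------------------------
# PWM scanning


def _encode(sequence: str) -> np.ndarray:
    seq = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(seq.shape, -1, dtype=np.int8)
    for letter, code in _ENCODE.items():
        out[seq == ord(letter)] = code
    return out


def scan_pwm(
    sequence: str,
    pwm: PWM,
    score_threshold: Optional[float] = None,
    p_threshold: Optional[float] = None,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan a sequence on both strands for PWM matches above a cutoff.

    Exactly one of ``score_threshold`` (minimum log2-odds score) or
    ``p_threshold`` (match p-value, converted to a score cutoff by the exact
    background score distribution) must be given.  Minus-strand hits report
    forward-strand coordinates; windows containing N are skipped.  A sequence
    shorter than the motif yields no hits.
    """
    if (score_threshold is None) == (p_threshold is None):
        raise ValueError("give exactly one of score_threshold or p_threshold")
    if p_threshold is not None:
        score_threshold = pwm.score_cutoff(p_threshold)
    L = pwm.length
    encoded = _encode(sequence)
    if encoded.size < L:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    valid = (windows >= 0).all(axis=1)
    lo_fwd = pwm.log_odds
    # reverse-complement matrix: reverse positions, complement letters
    # (ACGT order makes complementing a column reversal)
    lo_rev = lo_fwd[::-1, ::-1]
    idx = np.arange(L)
    safe = np.where(windows >= 0, windows, 0)
    fwd_scores = lo_fwd[idx, safe].sum(axis=1)
    rev_scores = lo_rev[idx, safe].sum(axis=1)
    hits = []
    for pos in np.nonzero(valid)[0]:
        for strand, score in (("+", fwd_scores[pos]), ("-", rev_scores[pos])):
            if score >= score_threshold:
                hits.append(
                    MotifHit(
                        GenomicInterval(chrom, offset + int(pos), offset + int(pos) + L, strand),
                        round(float(score), 6),
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# anchors


def assign_motifs_to_peaks(
    motifs: Sequence[MotifHit], peaks: Sequence[Peak]
) -> list[Anchor]:
    """Pair peak-contained motifs with their enclosing peaks.

    Containment is full (the whole motif interval inside the peak interval,
    boundary-touching allowed under half-open arithmetic); motifs outside
    every peak are dropped, and a motif inside several overlapping peaks
    yields one anchor per containing peak.  Output follows motif input order.
    """
    trees = build_interval_trees([p.interval for p in peaks], peaks)
    anchors = []
    for motif in motifs:
        tree = trees.get(motif.interval.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(motif.interval.start, motif.interval.end)):
            peak: Peak = hit.data
            if peak.interval.contains(motif.interval):
                anchors.append(Anchor(motif, peak))
    return anchors


def loop_score(anchor_a: Anchor, anchor_b: Anchor) -> float:
    """Geometric mean of the two anchor scores."""
    return math.sqrt(anchor_a.anchor_score * anchor_b.anchor_score)


# ---------------------------------------------------------------------------
# BED interop for motif hits


def motifs_from_bed(records: Iterable[BedRecord]) -> list[MotifHit]:
    """Interpret BED6 records as motif hits (score column = motif score)."""
    return [MotifHit(r.interval, r.score) for r in records]


def motifs_to_bed(hits: Iterable[MotifHit], name: str = "motif") -> list[BedRecord]:
    return [
        BedRecord(h.interval, f"{name}_{i}", h.motif_score)
        for i, h in enumerate(hits, start=1)
    ]
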