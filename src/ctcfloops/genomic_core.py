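"""Genomic interval data model, text-format I/O and loop/peak filtering.

Everything downstream works on 0-based half-open coordinates (the BED
convention).  Readers for the four tab-separated dialects the toolkit touches
(BED6, narrowPeak, BEDPE, UCSC chrom.sizes) preserve coordinates bit-exactly
and report malformed input with the offending line number; "track"/"browser"
header lines and comments are skipped.  "Overlap" throughout the package
means at least one shared base.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, Union

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "BedRecord",
    "Peak",
    "ExperimentalLoop",
    "ChromSizes",
    "ParseError",
    "read_intervals",
    "write_bed6",
    "write_narrowpeak",
    "write_bedpe",
    "write_chrom_sizes",
    "filter_chiapet_loops",
    "merge_peak_sets",
    "build_interval_trees",
]

_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Malformed line in a genomic text file; message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share >= 1 base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True when *other* lies fully within this interval (half-open)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class BedRecord:
    """A BED6 line: a named, scored, optionally stranded interval."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0


@dataclass(frozen=True)
class Peak:
    """A scored ChIP-seq peak (binding-strength value is non-negative)."""

    interval: GenomicInterval
    score: float
    name: str = "."

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"peak score must be >= 0, got {self.score}")


@dataclass(frozen=True)
class ExperimentalLoop:
    """An experimentally determined anchor pair (ChIA-PET or Hi-C style).

    ``ligation_count`` is the number of ligation products supporting the
    interaction for ChIA-PET input, or a generic score for Hi-C loop lists.
    Intra-chromosomal loops are normalised so anchor1 is the left anchor.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    ligation_count: float
    name: str = "."

    def __post_init__(self) -> None:
        if self.ligation_count < 1:
            raise ValueError(
                f"ligation_count must be >= 1, got {self.ligation_count}"
            )
        if self.is_intra and self.anchor2.start < self.anchor1.start:
            a1, a2 = self.anchor1, self.anchor2
            object.__setattr__(self, "anchor1", a2)
            object.__setattr__(self, "anchor2", a1)

    @property
    def is_intra(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp (lengths strictly positive)."""

    def __init__(self, sizes: Mapping[str, int] = ()):  # type: ignore[assignment]
        super().__init__()
        for chrom, length in dict(sizes).items():
            self[chrom] = length

    def __setitem__(self, chrom: str, length: int) -> None:
        if length <= 0:
            raise ValueError(f"chromosome length must be > 0, got {length} for {chrom}")
        super().__setitem__(chrom, int(length))


# ---------------------------------------------------------------------------
# readers


def _data_lines(path: Union[str, Path]) -> Iterator[tuple[int, list[str]]]:
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            yield lineno, line.split("\t")


def _parse_int(value: str, what: str, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"line {lineno}: {what} is not an integer: {value!r}") from None


def _parse_float(value: str, what: str, lineno: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"line {lineno}: {what} is not numeric: {value!r}") from None


def _require(fields: Sequence[str], n: int, lineno: int, dialect: str) -> None:
    if len(fields) < n:
        raise ParseError(
            f"line {lineno}: {dialect} needs >= {n} columns, got {len(fields)}"
        )


def _interval(fields: Sequence[str], lineno: int, strand: str = ".") -> GenomicInterval:
    start = _parse_int(fields[1], "start", lineno)
    end = _parse_int(fields[2], "end", lineno)
    try:
        return GenomicInterval(fields[0], start, end, strand)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None


def _read_bed6(path: Union[str, Path]) -> list[BedRecord]:
    records = []
    for lineno, fields in _data_lines(path):
        _require(fields, 3, lineno, "BED")
        name = fields[3] if len(fields) > 3 else "."
        score = _parse_float(fields[4], "score", lineno) if len(fields) > 4 else 0.0
        strand = fields[5] if len(fields) > 5 else "."
        records.append(BedRecord(_interval(fields, lineno, strand), name, score))
    return records


def _read_narrowpeak(path: Union[str, Path], score_column: int = 7) -> list[Peak]:
    if score_column not in (5, 7):
        raise ValueError("narrowPeak score column must be 5 (score) or 7 (signalValue)")
    peaks = []
    for lineno, fields in _data_lines(path):
        _require(fields, max(6, score_column), lineno, "narrowPeak")
        strand = fields[5] if len(fields) > 5 else "."
        score = _parse_float(fields[score_column - 1], "peak score", lineno)
        try:
            peaks.append(Peak(_interval(fields, lineno, strand), score, fields[3]))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return peaks


def _read_bedpe(path: Union[str, Path]) -> list[ExperimentalLoop]:
    loops = []
    for lineno, fields in _data_lines(path):
        _require(fields, 8, lineno, "BEDPE")
        strand1 = fields[8] if len(fields) > 8 else "."
        strand2 = fields[9] if len(fields) > 9 else "."
        a1 = _interval(fields[0:3], lineno, strand1)
        a2 = _interval(fields[3:6], lineno, strand2)
        count = _parse_float(fields[7], "ligation count/score", lineno)
        try:
            loops.append(ExperimentalLoop(a1, a2, count, fields[6]))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return loops


def _read_chrom_sizes(path: Union[str, Path]) -> ChromSizes:
    sizes = ChromSizes()
    for lineno, fields in _data_lines(path):
        _require(fields, 2, lineno, "chrom.sizes")
        try:
            sizes[fields[0]] = _parse_int(fields[1], "chromosome length", lineno)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return sizes


def _read_chiapet_block(path: Union[str, Path]) -> list[ExperimentalLoop]:
    """Convert the blocked-BED ChIA-PET interaction dialect to loop records.

    Each line is a BED12-style record whose two blocks are the anchors and
    whose score column carries the ligation-product count; BEDPE is the
    canonical internal representation.
    """
    loops = []
    for lineno, fields in _data_lines(path):
        _require(fields, 12, lineno, "blocked ChIA-PET BED")
        chrom = fields[0]
        chrom_start = _parse_int(fields[1], "chromStart", lineno)
        count = _parse_float(fields[4], "score", lineno)
        n_blocks = _parse_int(fields[9], "blockCount", lineno)
        if n_blocks != 2:
            raise ParseError(f"line {lineno}: expected 2 blocks, got {n_blocks}")
        sizes = [_parse_int(x, "blockSize", lineno) for x in fields[10].rstrip(",").split(",")]
        starts = [_parse_int(x, "blockStart", lineno) for x in fields[11].rstrip(",").split(",")]
        if len(sizes) != 2 or len(starts) != 2:
            raise ParseError(f"line {lineno}: block lists must have 2 entries")
        anchors = [
            GenomicInterval(chrom, chrom_start + s, chrom_start + s + w)
            for s, w in zip(starts, sizes)
        ]
        try:
            loops.append(ExperimentalLoop(anchors[0], anchors[1], count, fields[3]))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return loops


_READERS = {
    "bed6": _read_bed6,
    "narrowPeak": _read_narrowpeak,
    "bedpe": _read_bedpe,
    "chrom_sizes": _read_chrom_sizes,
    "chiapet_block": _read_chiapet_block,
}


def read_intervals(path: Union[str, Path], format: str, **kwargs):
    """Read a genomic text file into typed records, in file order.

    Parameters
    ----------
    path:
        Input file path.
    format:
        One of ``bed6`` (-> :class:`BedRecord`), ``narrowPeak`` (->
        :class:`Peak`; keyword ``score_column`` selects column 7/signalValue,
        the default, or column 5), ``bedpe`` (-> :class:`ExperimentalLoop`,
        column 8 = ligation count), ``chrom_sizes`` (-> :class:`ChromSizes`)
        or ``chiapet_block`` (blocked-BED ChIA-PET dialect ->
        :class:`ExperimentalLoop`).
    """
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(
            f"unknown format {format!r}; choose from {sorted(_READERS)}"
        ) from None
    return reader(path, **kwargs)


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)


def write_bed6(records: Iterable[BedRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as out:
        for r in records:
            i = r.interval
            out.write(
                f"{i.chrom}\t{i.start}\t{i.end}\t{r.name}\t{_fmt(r.score)}\t{i.strand}\n"
            )


def write_narrowpeak(peaks: Iterable[Peak], path: Union[str, Path]) -> None:
    """Write peaks as narrowPeak with the score in both column 5 and 7."""
    with open(path, "w") as out:
        for p in peaks:
            i = p.interval
            out.write(
                f"{i.chrom}\t{i.start}\t{i.end}\t{p.name}\t{_fmt(p.score)}\t{i.strand}"
                f"\t{_fmt(p.score)}\t-1\t-1\t-1\n"
            )


def write_bedpe(loops: Iterable[ExperimentalLoop], path: Union[str, Path]) -> None:
    with open(path, "w") as out:
        for l in loops:
            a, b = l.anchor1, l.anchor2
            out.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t{l.name}\t{_fmt(l.ligation_count)}\t{a.strand}\t{b.strand}\n"
            )


def write_chrom_sizes(sizes: ChromSizes, path: Union[str, Path]) -> None:
    with open(path, "w") as out:
        for chrom, length in sizes.items():
            out.write(f"{chrom}\t{length}\n")


def _fmt(x: float) -> str:
    """Render a score without trailing '.0' noise for integral values."""
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# overlap machinery and the filtering/merging rules


def build_interval_trees(
    intervals: Iterable[GenomicInterval], payloads: Iterable = None
) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees; payload defaults to the interval itself."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    items = list(intervals)
    data = list(payloads) if payloads is not None else items
    for iv, payload in zip(items, data):
        trees[iv.chrom].addi(iv.start, iv.end, payload)
    return dict(trees)


def _overlaps_any(trees: Mapping[str, IntervalTree], iv: GenomicInterval) -> bool:
    tree = trees.get(iv.chrom)
    return bool(tree is not None and tree.overlap(iv.start, iv.end))


def filter_chiapet_loops(
    loops: Sequence[ExperimentalLoop],
    peaks: Sequence[Peak],
    min_ligation: float = 3,
) -> list[ExperimentalLoop]:
    """Keep reliable experimental loops: intra-chromosomal anchor pairs that
    overlap a ChIP-seq peak at both anchors and are supported by at least
    ``min_ligation`` ligation products.  Input order is preserved.
    """
    if not peaks:
        warnings.warn(
            "empty peak set: every loop fails the both-anchors-in-peaks filter",
            stacklevel=2,
        )
    trees = build_interval_trees([p.interval for p in peaks])
    return [
        l
        for l in loops
        if l.is_intra
        and l.ligation_count >= min_ligation
        and _overlaps_any(trees, l.anchor1)
        and _overlaps_any(trees, l.anchor2)
    ]


def merge_peak_sets(peak_sets: Sequence[Sequence[Peak]]) -> list[Peak]:
    """Merge replicate/lab peak sets into one non-overlapping set.

    Peaks sharing >= 1 base collapse into the union interval of their overlap
    component, carrying the maximum contributing score.  Output is sorted by
    (chrom, start).  Idempotent.
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    flat = sorted(
        (p for ps in peak_sets for p in ps),
        key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end),
    )
    merged: list[Peak] = []
    for peak in flat:
        if merged and merged[-1].interval.overlaps(peak.interval):
            prev = merged[-1]
            merged[-1] = Peak(
                GenomicInterval(
                    prev.interval.chrom,
                    prev.interval.start,
                    max(prev.interval.end, peak.interval.end),
                ),
                max(prev.score, peak.score),
                prev.name,
            )
        else:
            merged.append(
                Peak(
                    GenomicInterval(
                        peak.interval.chrom, peak.interval.start, peak.interval.end
                    ),
                    peak.score,
                    peak.name,
                )
            )
    return merged
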