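"""Deterministic synthetic loop landscapes for testing every other module.

The generator plants clusters of convergent CTCF anchor pairs on small
artificial chromosomes.  Each cluster nests ``nesting_depth`` loops: one
anchor pair per level, the outer pair flanking the inner pairs, with + motifs
on the left and - motifs on the right.  Outer anchors sit in strictly
stronger ChIP-seq peaks than inner anchors (the property the iterative
thresholding of the predictor exploits), noise peaks carry no motif and
noise motifs sit outside every peak.  On top of the landscape the module can
simulate ChIA-PET-like loop files with geometric ligation counts and
positional jitter, feature tracks enriched inside loop bodies, gene
annotations placed inside loops (inducible) and in flanks (housekeeping),
and an expression matrix with the housekeeping/inducible dichotomy: high and
uniform across cell types versus lower, sparse and cell-type-specific.

All randomness flows through one seeded generator; identical config + seed
gives byte-identical fixture files.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .genomic_core import (
    BedRecord,
    ChromSizes,
    ExperimentalLoop,
    GenomicInterval,
    Peak,
    write_bed6,
    write_bedpe,
    write_chrom_sizes,
    write_narrowpeak,
)
from .motif_anchors import MotifHit

__all__ = [
    "FixtureConfig",
    "PlantedLoop",
    "LoopLandscape",
    "generate_loop_landscape",
    "simulate_chiapet",
    "simulate_feature_track",
    "simulate_genes",
    "simulate_expression",
    "write_fixture",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the planted landscape.

    Score ranges are kept non-overlapping (inner < noise < outer) so the
    nesting structure is recoverable by strength thresholding; noise peaks
    default to the band between the anchor classes.  Ligation counts follow
    a geometric law with mean 4 (``("geometric", 4.0)``) or a constant
    (``("constant", k)``).
    """

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_loop_clusters: int = 5
    nesting_depth: int = 2
    outer_anchor_score_range: tuple[float, float] = (800.0, 1000.0)
    inner_anchor_score_range: tuple[float, float] = (200.0, 400.0)
    noise_peak_score_range: tuple[float, float] = (450.0, 750.0)
    motif_score_range: tuple[float, float] = (14.0, 16.0)
    motif_length: int = 19
    peak_halfwidth: int = 150
    n_noise_peaks: int = 10
    n_noise_motifs: int = 20
    ligation_law: tuple[str, float] = ("geometric", 4.0)
    anchor_halfwidth: int = 150
    anchor_jitter_bp: int = 20
    decoy_fraction: float = 0.0
    n_cell_types: int = 15
    housekeeping_mean_fpkm: float = 50.0
    housekeeping_log_sd: float = 0.1
    inducible_mean_fpkm: float = 20.0
    inducible_log_sd: float = 0.5
    inducible_max_active: int = 3
    inducible_background_fpkm: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nesting_depth < 1 or self.n_loop_clusters < 1:
            raise ValueError("need at least one cluster and one nesting level")
        if self.inner_anchor_score_range[1] >= self.outer_anchor_score_range[0]:
            raise ValueError("outer anchor scores must exceed inner anchor scores")
        if min(self.n_noise_peaks, self.n_noise_motifs) < 0:
            raise ValueError("noise counts must be >= 0")
        if self.ligation_law[0] not in ("geometric", "constant"):
            raise ValueError("ligation_law must be ('geometric', mean) or ('constant', k)")


@dataclass(frozen=True)
class PlantedLoop:
    """Ground-truth loop: its two motif intervals and nesting level
    (level 0 = outermost)."""

    left: GenomicInterval  # + strand motif
    right: GenomicInterval  # - strand motif
    level: int
    cluster: int

    @property
    def chrom(self) -> str:
        return self.left.chrom

    def key(self) -> tuple:
        return (self.chrom, self.left.start, self.right.start)


@dataclass
class LoopLandscape:
    chrom_sizes: ChromSizes
    peaks: list[Peak]
    motifs: list[MotifHit]
    planted: list[PlantedLoop]


def _rng(seed_or_rng: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_loop_landscape(
    config: FixtureConfig, rng: Optional[np.random.Generator] = None
) -> LoopLandscape:
    """Plant nested convergent loop clusters plus noise peaks and motifs.

    Clusters are distributed round-robin over the chromosomes in
    non-overlapping slots; anchor peaks never overlap each other.  Noise
    elements are re-drawn when they would collide with existing peaks and a
    bounded number of retries is allowed before giving up.
    """
    rng = _rng(config.seed) if rng is None else rng
    d = config.nesting_depth
    mlen = config.motif_length
    hw = config.peak_halfwidth
    sizes = ChromSizes(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)}
    )
    chrom_names = list(sizes)
    per_chrom = [
        [c for c in range(config.n_loop_clusters) if c % len(chrom_names) == i]
        for i in range(len(chrom_names))
    ]
    peaks: list[Peak] = []
    motifs: list[MotifHit] = []
    planted: list[PlantedLoop] = []
    for chrom, clusters in zip(chrom_names, per_chrom):
        if not clusters:
            continue
        slot = config.chrom_length // len(clusters)
        width = int(slot * 0.5)
        gap = width // (2 * d)
        min_gap = 2 * hw + mlen + 10
        if gap < min_gap:
            raise ValueError(
                "chromosome too short for the requested cluster count/depth"
            )
        for j, cluster_id in enumerate(clusters):
            cstart = j * slot + slot // 8 + int(rng.integers(0, slot // 8))
            cend = cstart + width
            level_motifs = []
            for level in range(d):
                lpos = cstart + level * gap
                rpos = cend - level * gap - mlen
                left = GenomicInterval(chrom, lpos, lpos + mlen, "+")
                right = GenomicInterval(chrom, rpos, rpos + mlen, "-")
                lo, hi = (
                    config.outer_anchor_score_range
                    if level == 0
                    else config.inner_anchor_score_range
                )
                for iv in (left, right):
                    motifs.append(
                        MotifHit(iv, float(rng.uniform(*config.motif_score_range)))
                    )
                    peaks.append(
                        Peak(
                            GenomicInterval(chrom, iv.start - hw, iv.end + hw),
                            round(float(rng.uniform(lo, hi)), 3),
                            f"anchor_c{cluster_id}_l{level}",
                        )
                    )
                level_motifs.append((left, right))
                planted.append(PlantedLoop(left, right, level, cluster_id))

    def collides(chrom: str, start: int, end: int, pad: int = 10) -> bool:
        return any(
            p.interval.chrom == chrom
            and start - pad < p.interval.end
            and p.interval.start < end + pad
            for p in peaks
        )

    for i in range(config.n_noise_peaks):
        for _ in range(200):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            start = int(rng.integers(0, config.chrom_length - 2 * hw))
            end = start + 2 * hw
            if not collides(chrom, start, end):
                peaks.append(
                    Peak(
                        GenomicInterval(chrom, start, end),
                        round(float(rng.uniform(*config.noise_peak_score_range)), 3),
                        f"noise_peak_{i}",
                    )
                )
                break
        else:
            raise RuntimeError("could not place a noise peak without collision")

    for _ in range(config.n_noise_motifs):
        for _ in range(200):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            start = int(rng.integers(0, config.chrom_length - mlen))
            if not collides(chrom, start, start + mlen, pad=0):
                strand = "+" if rng.random() < 0.5 else "-"
                motifs.append(
                    MotifHit(
                        GenomicInterval(chrom, start, start + mlen, strand),
                        float(rng.uniform(*config.motif_score_range)),
                    )
                )
                break
        else:
            raise RuntimeError("could not place a noise motif outside peaks")

    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    motifs.sort(key=lambda m: (m.interval.chrom, m.interval.start))
    planted.sort(key=lambda pl: (pl.chrom, pl.left.start))
    _check_landscape(peaks, motifs, planted)
    return LoopLandscape(sizes, peaks, motifs, planted)


def _check_landscape(
    peaks: Sequence[Peak], motifs: Sequence[MotifHit], planted: Sequence[PlantedLoop]
) -> None:
    """Generation-time validation of the planted invariants."""
    for loop in planted:
        assert loop.left.strand == "+" and loop.right.strand == "-"
        assert loop.left.start < loop.right.start, "planted loops must be convergent"
    for m in motifs:
        assert m.interval.strand in ("+", "-")


def _ligation_counts(
    n: int, law: tuple[str, float], rng: np.random.Generator
) -> np.ndarray:
    kind, param = law
    if kind == "constant":
        return np.full(n, int(param))
    # geometric with mean `param` on support {1, 2, ...}
    return rng.geometric(1.0 / param, size=n)


def simulate_chiapet(
    planted: Sequence[PlantedLoop],
    config: FixtureConfig,
    rng: Optional[np.random.Generator] = None,
    chrom_sizes: Optional[ChromSizes] = None,
) -> list[ExperimentalLoop]:
    """ChIA-PET-like loop list over the truth set.

    Anchors are peak-sized regions around the planted motifs, jittered by up
    to ``anchor_jitter_bp``; ligation counts follow the configured law; a
    ``decoy_fraction`` of additional loops is planted in regions far from
    any true anchor.  All loops are intra-chromosomal.
    """
    if not planted:
        raise ValueError("truth set must be non-empty")
    rng = _rng(config.seed + 1) if rng is None else rng
    hw = config.anchor_halfwidth
    j = config.anchor_jitter_bp
    counts = _ligation_counts(len(planted), config.ligation_law, rng)
    loops = []
    for loop, count in zip(planted, counts):
        anchors = []
        for motif in (loop.left, loop.right):
            off = int(rng.integers(-j, j + 1)) if j else 0
            anchors.append(
                GenomicInterval(
                    loop.chrom,
                    max(0, motif.start - hw + off),
                    motif.end + hw + off,
                )
            )
        loops.append(
            ExperimentalLoop(
                anchors[0],
                anchors[1],
                int(count),
                f"chiapet_c{loop.cluster}_l{loop.level}",
            )
        )
    n_decoys = round(config.decoy_fraction * len(planted))
    if n_decoys:
        if chrom_sizes is None:
            raise ValueError("chrom_sizes required to place decoy loops")
        anchor_positions = {
            (l.chrom, m.start) for l in planted for m in (l.left, l.right)
        }

        def far_from_truth(chrom: str, pos: int, margin: int = 2000) -> bool:
            return all(
                c != chrom or abs(p - pos) > margin for c, p in anchor_positions
            )

        chroms = list(chrom_sizes)
        decoy_counts = _ligation_counts(n_decoys, config.ligation_law, rng)
        for i in range(n_decoys):
            for _ in range(500):
                chrom = chroms[int(rng.integers(len(chroms)))]
                a = int(rng.integers(0, chrom_sizes[chrom] - 50_000))
                b = a + int(rng.integers(10_000, 50_000))
                if far_from_truth(chrom, a) and far_from_truth(chrom, b):
                    loops.append(
                        ExperimentalLoop(
                            GenomicInterval(chrom, a, a + 2 * hw),
                            GenomicInterval(chrom, b, b + 2 * hw),
                            int(decoy_counts[i]),
                            f"decoy_{i}",
                        )
                    )
                    break
            else:
                raise RuntimeError("could not place a decoy loop away from truth")
    return loops


def simulate_feature_track(
    loops: Sequence[GenomicInterval],
    chrom_sizes: ChromSizes,
    within_loop_rate: float,
    background_rate: float,
    seed: Union[int, np.random.Generator],
    feature_length: int = 200,
) -> list[GenomicInterval]:
    """Poisson-placed feature intervals with an elevated rate in loop bodies.

    Rates are events per kilobase.  The background process covers every
    chromosome; the surplus ``within_loop_rate - background_rate`` is added
    inside each loop body, emulating e.g. the within-loop enrichment of an
    enhancer mark.
    """
    if not within_loop_rate >= background_rate >= 0:
        raise ValueError("need within_loop_rate >= background_rate >= 0")
    rng = _rng(seed)
    features = []
    for chrom, length in chrom_sizes.items():
        n = rng.poisson(background_rate * length / 1000.0)
        for start in sorted(rng.integers(0, max(1, length - feature_length), size=n)):
            features.append(
                GenomicInterval(chrom, int(start), int(start) + feature_length)
            )
    surplus = within_loop_rate - background_rate
    if surplus > 0:
        for body in loops:
            n = rng.poisson(surplus * body.length / 1000.0)
            span = max(1, body.length - feature_length)
            for off in sorted(rng.integers(0, span, size=n)):
                features.append(
                    GenomicInterval(
                        body.chrom, body.start + int(off), body.start + int(off) + feature_length
                    )
                )
    features.sort(key=lambda f: (f.chrom, f.start))
    return features


def simulate_genes(
    planted: Sequence[PlantedLoop],
    chrom_sizes: ChromSizes,
    rng: Union[int, np.random.Generator],
    genes_per_loop: int = 2,
    genes_per_flank: int = 2,
    n_distal: int = 20,
    gene_length: int = 5_000,
) -> tuple[list[BedRecord], dict[str, str]]:
    """Gene annotation over the landscape with a planted expression
    dichotomy: within-loop genes are labelled inducible, flank genes
    housekeeping, distal genes split evenly.

    Returns the BED records plus a gene_id -> {housekeeping, inducible}
    label map (the truth labels for :func:`simulate_expression`).
    """
    rng = _rng(rng)
    outer = [p for p in planted if p.level == 0]
    records: list[BedRecord] = []
    labels: dict[str, str] = {}

    def add(chrom: str, start: int, label: str, tag: str) -> None:
        gid = f"{tag}_{len(records)}"
        end = min(start + gene_length, chrom_sizes[chrom])
        if end - start < 100:
            return
        records.append(BedRecord(GenomicInterval(chrom, max(0, start), end), gid))
        labels[gid] = label

    for loop in outer:
        body_start, body_end = loop.left.end, loop.right.start
        span = body_end - body_start - gene_length
        for _ in range(genes_per_loop):
            add(
                loop.chrom,
                body_start + int(rng.integers(0, max(1, span))),
                "inducible",
                "loop_gene",
            )
        L = loop.right.end - loop.left.start
        for flank_start, flank_end in (
            (loop.left.start - L, loop.left.start),
            (loop.right.end, loop.right.end + L),
        ):
            lo = max(0, flank_start)
            hi = min(chrom_sizes[loop.chrom], flank_end) - gene_length
            for _ in range(genes_per_flank):
                if hi > lo:
                    add(
                        loop.chrom,
                        lo + int(rng.integers(0, hi - lo)),
                        "housekeeping",
                        "flank_gene",
                    )
    chroms = list(chrom_sizes)
    occupied = [
        (p.chrom, p.left.start - 2 * (p.right.end - p.left.start), p.right.end + 2 * (p.right.end - p.left.start))
        for p in outer
    ]
    placed = 0
    attempts = 0
    while placed < n_distal and attempts < 50 * n_distal:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_sizes[chrom] - gene_length))
        if any(c == chrom and s < start + gene_length and start < e for c, s, e in occupied):
            continue
        add(chrom, start, "inducible" if placed % 2 else "housekeeping", "distal_gene")
        placed += 1
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return records, labels


def simulate_expression(
    labels: dict[str, str],
    config: FixtureConfig,
    rng: Optional[np.random.Generator] = None,
):
    """FPKM matrix (genes x cell types) realising the planted dichotomy.

    Housekeeping genes draw a common log-normal baseline and vary only by a
    small log-normal factor across cell types (low CV, low TSI).  Inducible
    genes are active in a sparse random subset of 1..``inducible_max_active``
    cell types and sit at a near-zero background elsewhere (high CV and TSI).
    """
    import pandas as pd

    rng = _rng(config.seed + 2) if rng is None else rng
    cell_types = [f"cell_{i + 1}" for i in range(config.n_cell_types)]
    rows = {}
    for gene_id, label in labels.items():
        if label == "housekeeping":
            base = rng.lognormal(math.log(config.housekeeping_mean_fpkm), 0.3)
            values = base * rng.lognormal(
                0.0, config.housekeeping_log_sd, size=config.n_cell_types
            )
        elif label == "inducible":
            n_active = int(rng.integers(1, config.inducible_max_active + 1))
            active = rng.choice(config.n_cell_types, size=n_active, replace=False)
            values = np.full(
                config.n_cell_types, config.inducible_background_fpkm
            ) * rng.lognormal(0.0, 0.2, size=config.n_cell_types)
            values[active] = rng.lognormal(
                math.log(config.inducible_mean_fpkm),
                config.inducible_log_sd,
                size=n_active,
            )
        else:
            raise ValueError(f"unknown gene label {label!r} for {gene_id}")
        rows[gene_id] = np.round(values, 4)
    return pd.DataFrame.from_dict(rows, orient="index", columns=cell_types)


def write_fixture(directory: Union[str, Path], config: FixtureConfig) -> dict[str, Path]:
    """Generate a full fixture and write it as the on-disk formats the
    readers consume (so tests exercise the I/O layer too).

    Emits peaks.narrowPeak, motifs.bed, truth_loops.bedpe, chiapet.bedpe,
    features.bed, genes.bed, expression.tsv, chrom.sizes and config.yaml.
    Byte-identical for identical config + seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = _rng(config.seed)
    landscape = generate_loop_landscape(config, rng)
    chiapet = simulate_chiapet(
        landscape.planted, config, rng, landscape.chrom_sizes
    )
    bodies = [
        GenomicInterval(p.chrom, p.left.end, p.right.start)
        for p in landscape.planted
        if p.level == 0
    ]
    features = simulate_feature_track(
        bodies, landscape.chrom_sizes, within_loop_rate=1.0, background_rate=0.2, seed=rng
    )
    genes, labels = simulate_genes(landscape.planted, landscape.chrom_sizes, rng)
    expression = simulate_expression(labels, config, rng)

    paths = {name: directory / name for name in (
        "peaks.narrowPeak", "motifs.bed", "truth_loops.bedpe", "chiapet.bedpe",
        "features.bed", "genes.bed", "expression.tsv", "chrom.sizes", "config.yaml",
    )}
    write_narrowpeak(landscape.peaks, paths["peaks.narrowPeak"])
    write_bed6(
        [
            BedRecord(m.interval, f"motif_{i}", round(m.motif_score, 3))
            for i, m in enumerate(landscape.motifs, start=1)
        ],
        paths["motifs.bed"],
    )
    write_bedpe(
        [
            ExperimentalLoop(p.left, p.right, 1, f"truth_c{p.cluster}_l{p.level}")
            for p in landscape.planted
        ],
        paths["truth_loops.bedpe"],
    )
    write_bedpe(chiapet, paths["chiapet.bedpe"])
    write_bed6([BedRecord(f, f"feat_{i}") for i, f in enumerate(features)], paths["features.bed"])
    write_bed6(genes, paths["genes.bed"])
    expression.to_csv(paths["expression.tsv"], sep="\t", index_label="gene_id")
    write_chrom_sizes(landscape.chrom_sizes, paths["chrom.sizes"])
    with open(paths["config.yaml"], "w") as out:
        yaml.safe_dump(dataclasses.asdict(config), out, sort_keys=True)
    return paths
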