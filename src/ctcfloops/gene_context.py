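"""Loop-relative gene classification and expression-pattern statistics.

Genes are partitioned against a loop set into three disjoint classes:
*loop* (the gene body overlaps any loop body), *flank* (it overlaps a
loop-flanking region of equal size to the loop, and no loop body - genes
that flank one loop but sit inside another resolve to the loop class) and
*distal* (neither).  Expression patterns across cell types are summarised
with the tissue specificity index

    TSI = sum_i (1 - E_i / E_max) / (n - 1)

(0 for perfectly uniform expression, 1 for single-tissue expression) and
the coefficient of variation CV = SD(E) / mean(E) (sample SD, n-1
denominator).  Class contrasts use the Wilcoxon rank-sum test with
continuity correction or Welch's t-test plus the fold change of medians;
gene-set enrichment (e.g. of housekeeping genes among flank genes) uses the
upper-tail hypergeometric test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .genomic_core import (
    BedRecord,
    ChromSizes,
    ExperimentalLoop,
    GenomicInterval,
    build_interval_trees,
)
from .loop_prediction import PredictedLoop
from .loop_profiles import loop_body

__all__ = [
    "GeneRecord",
    "classify_genes",
    "tsi",
    "cv",
    "compare_gene_classes",
    "enrichment_test",
    "flag_outlier_datasets",
]


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its loop-relative class."""

    interval: GenomicInterval
    gene_id: str
    gene_class: str  # loop | flank | distal

    def __post_init__(self) -> None:
        if self.gene_class not in ("loop", "flank", "distal"):
            raise ValueError(f"unknown gene class {self.gene_class!r}")


def _flanks(
    body: GenomicInterval, chrom_sizes: Optional[ChromSizes]
) -> list[GenomicInterval]:
    """Equal-size flanking regions, clipped at chromosome ends (clipping, not
    discarding, because no binning is involved here)."""
    L = body.length
    limit = chrom_sizes.get(body.chrom, math.inf) if chrom_sizes else math.inf
    out = []
    left_start = max(0, body.start - L)
    if left_start < body.start:
        out.append(GenomicInterval(body.chrom, left_start, body.start))
    right_end = min(limit, body.end + L)
    if right_end > body.end:
        out.append(GenomicInterval(body.chrom, body.end, int(right_end)))
    return out


def classify_genes(
    genes: Sequence[BedRecord],
    loops: Sequence[Union[GenomicInterval, PredictedLoop, ExperimentalLoop]],
    chrom_sizes: Optional[ChromSizes] = None,
) -> list[GeneRecord]:
    """Assign every gene to exactly one of loop / flank / distal.

    Overlap uses the full gene body and >= 1 shared base.  The classes are
    disjoint and exhaustive; flank membership is revoked for genes that also
    overlap any loop body.
    """
    bodies = [loop_body(l) for l in loops]
    body_trees = build_interval_trees(bodies)
    flank_trees = build_interval_trees(
        [f for b in bodies for f in _flanks(b, chrom_sizes)]
    )

    def overlaps(trees, iv: GenomicInterval) -> bool:
        tree = trees.get(iv.chrom)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))

    records = []
    for gene in genes:
        iv = gene.interval
        if overlaps(body_trees, iv):
            cls = "loop"
        elif overlaps(flank_trees, iv):
            cls = "flank"
        else:
            cls = "distal"
        records.append(GeneRecord(iv, gene.name, cls))
    return records


def tsi(expression_vector: Sequence[float]) -> float:
    """Tissue specificity index of one gene across n >= 2 cell types.

    Returns NaN for an all-zero vector (the index is undefined without a
    positive maximum).
    """
    E = np.asarray(expression_vector, dtype=float)
    if E.size < 2:
        raise ValueError("TSI needs expression in at least two cell types")
    if np.any(E < 0):
        raise ValueError("expression values must be non-negative")
    e_max = E.max()
    if e_max <= 0:
        return float("nan")
    return float(np.sum(1.0 - E / e_max) / (E.size - 1))


def cv(expression_vector: Sequence[float]) -> float:
    """Coefficient of variation (sample SD / mean); NaN for a zero mean."""
    E = np.asarray(expression_vector, dtype=float)
    if E.size < 2:
        raise ValueError("CV needs expression in at least two cell types")
    mean = E.mean()
    if mean <= 0:
        return float("nan")
    return float(E.std(ddof=1) / mean)


def compare_gene_classes(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: str = "rank_sum",
) -> dict[str, float]:
    """Contrast two gene classes on a per-gene statistic.

    Returns the fold change of medians (a over b; NaN when median(b) is 0)
    and the two-sided p-value from the Wilcoxon rank-sum test with
    continuity correction (``rank_sum``) or Welch's t-test (``welch_t``).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    med_b = np.median(b)
    fc = float(np.median(a) / med_b) if med_b != 0 else float("nan")
    if test == "rank_sum":
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided", use_continuity=True)
    elif test == "welch_t":
        _, p = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError("test must be 'rank_sum' or 'welch_t'")
    return {"fold_change_of_medians": fc, "p_value": float(p)}


def enrichment_test(
    query_genes: set,
    annotation_genes: set,
    universe: set,
) -> dict[str, float]:
    """Hypergeometric over-representation of an annotation in a query set.

    Fold enrichment is (overlap/|query|) / (|annotation|/|universe|); the
    p-value is the upper-tail hypergeometric probability of drawing at least
    the observed overlap when sampling |query| genes from the universe.
    """
    query = set(query_genes)
    annotation = set(annotation_genes)
    universe = set(universe)
    if not query or not annotation:
        raise ValueError("query and annotation sets must be non-empty")
    if not query <= universe or not annotation <= universe:
        raise ValueError("query and annotation must be subsets of the universe")
    overlap = len(query & annotation)
    fold = (overlap / len(query)) / (len(annotation) / len(universe))
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(annotation), len(query)))
    return {
        "fold_enrichment": float(fold),
        "p_value": p,
        "overlap": float(overlap),
        "expected_overlap": len(query) * len(annotation) / len(universe),
    }


def flag_outlier_datasets(
    per_dataset_gene_counts: Mapping[str, float],
    k: float = 2.0,
) -> dict[str, str]:
    """Flag datasets with abnormally low loop-enclosed gene counts.

    A dataset is excluded when its count falls more than ``k`` sample
    standard deviations below the mean count (only low outliers are removed:
    high counts are not suspicious).  Needs at least three datasets.
    """
    names = list(per_dataset_gene_counts)
    counts = np.asarray([per_dataset_gene_counts[n] for n in names], dtype=float)
    if counts.size < 3:
        raise ValueError("need at least three datasets to flag outliers")
    cutoff = counts.mean() - k * counts.std(ddof=1)
    return {
        name: ("excluded" if count < cutoff else "kept")
        for name, count in zip(names, counts)
    }
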