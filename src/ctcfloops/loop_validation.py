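"""Validation of predicted loops and motif-anchor concordance analysis.

Predicted loops are checked against experimental loop sets (ChIA-PET or
Hi-C anchor pairs): each anchor motif is extended by 100 bp on either side
and a prediction counts as validated when one experimental loop is
overlapped at both anchors.  Significance comes from an orientation
permutation null: the strand labels of the peak-contained motifs are
shuffled (everything else - positions, scores, strand counts - unchanged),
the full prediction pipeline is re-run per permutation, and the observed
validated fraction is compared to a normal distribution fitted to the
permuted fractions.

The concordance analysis asks, motif by motif, whether the motif's 3' end
points into the bodies of the experimental loops whose anchors it overlaps
(+ motif at the left anchor, - motif at the right anchor).  Motifs hit by
anchors in both orientations are called discordant only when at least one
discordant loop is supported by more ligation products than every
concordant loop.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genomic_core import ExperimentalLoop, GenomicInterval, build_interval_trees
from .motif_anchors import Anchor, MotifHit
from .loop_prediction import PredictedLoop

__all__ = [
    "ValidationResult",
    "ConcordanceRecord",
    "validate_predictions",
    "permute_motif_orientations",
    "null_distribution",
    "classify_anchor_concordance",
    "concordance_by_score_bin",
    "format_p_value",
]

P_FLOOR = 1e-323  # smallest machine-representable tail worth printing


@dataclass
class ValidationResult:
    """Outcome of validating predictions against an experimental loop set."""

    n_predicted: int
    n_validated: int
    fraction_validated: float
    random_fractions: Optional[np.ndarray] = None
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_validated <= 1:
            raise ValueError("fraction_validated must lie in [0, 1]")
        if self.n_validated > self.n_predicted:
            raise ValueError("n_validated cannot exceed n_predicted")


def format_p_value(p: float) -> str:
    """Render a normal-fit p-value, flooring at the printable tail."""
    return "< 1e-323" if p < P_FLOOR else f"{p:.3g}"


def _anchor_trees(
    experimental: Sequence[ExperimentalLoop],
) -> tuple[dict[str, IntervalTree], dict[str, IntervalTree]]:
    left = build_interval_trees(
        [l.anchor1 for l in experimental], range(len(experimental))
    )
    right = build_interval_trees(
        [l.anchor2 for l in experimental], range(len(experimental))
    )
    return left, right


def _hits(trees: dict[str, IntervalTree], chrom: str, start: int, end: int) -> set:
    tree = trees.get(chrom)
    if tree is None:
        return set()
    return {hit.data for hit in tree.overlap(max(0, start), end)}


def validate_predictions(
    predicted: Sequence[PredictedLoop],
    experimental: Sequence[ExperimentalLoop],
    extension_bp: int = 100,
) -> ValidationResult:
    """Fraction of predictions overlapping an experimental loop at both
    anchors, after extending each anchor motif by ``extension_bp`` on either
    side.  Both anchor pairings are tried because experimental files do not
    guarantee anchor order.  An empty prediction set is an error (the
    fraction would be undefined).
    """
    if not predicted:
        raise ValueError("empty predicted loop set: validated fraction undefined")
    left, right = _anchor_trees(experimental)
    n_validated = 0
    for loop in predicted:
        m1, m2 = loop.start_anchor.motif.interval, loop.end_anchor.motif.interval
        s = (m1.chrom, m1.start - extension_bp, m1.end + extension_bp)
        e = (m2.chrom, m2.start - extension_bp, m2.end + extension_bp)
        direct = _hits(left, *s) & _hits(right, *e)
        swapped = _hits(left, *e) & _hits(right, *s)
        if direct or swapped:
            n_validated += 1
    return ValidationResult(
        len(predicted), n_validated, n_validated / len(predicted)
    )


def permute_motif_orientations(
    anchors: Sequence[Anchor], seed: int | np.random.Generator
) -> list[Anchor]:
    """Shuffle strand labels among the peak-contained motifs.

    A permutation, not a resampling: the counts of + and - motifs are
    conserved exactly, and positions, motif scores and peak assignments are
    untouched.  Deterministic for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strands = [a.strand for a in anchors]
    order = rng.permutation(len(anchors))
    permuted = []
    for anchor, j in zip(anchors, order):
        new_strand = strands[int(j)]
        new_motif = MotifHit(
            replace(anchor.motif.interval, strand=new_strand),
            anchor.motif.motif_score,
            anchor.motif.p_value,
        )
        permuted.append(Anchor(new_motif, anchor.peak))
    assert sorted(a.strand for a in permuted) == sorted(strands)
    return permuted


def null_distribution(
    predict_pipeline: Callable[[Sequence[Anchor]], Sequence[PredictedLoop]],
    anchors: Sequence[Anchor],
    experimental: Sequence[ExperimentalLoop],
    n_perm: int = 1000,
    seed: int = 0,
    extension_bp: int = 100,
) -> ValidationResult:
    """Orientation-permutation null for the validated fraction.

    Runs ``predict_pipeline`` (the full prediction, with whatever schedule
    and stringency settings the caller baked in) on ``n_perm`` strand-
    permuted anchor sets, validates each against the experimental loops,
    fits a normal distribution to the permuted fractions and reports the
    upper-tail probability of the observed fraction.  A permutation that
    yields no loops contributes a fraction of 0.
    """
    if n_perm < 2:
        raise ValueError("need n_perm >= 2 to fit a null distribution")
    observed = validate_predictions(
        predict_pipeline(anchors), experimental, extension_bp
    )
    child_seeds = np.random.SeedSequence(seed).spawn(n_perm)
    fractions = np.empty(n_perm)
    for i, ss in enumerate(child_seeds):
        permuted = permute_motif_orientations(anchors, np.random.default_rng(ss))
        loops = predict_pipeline(permuted)
        if loops:
            fractions[i] = validate_predictions(
                loops, experimental, extension_bp
            ).fraction_validated
        else:
            fractions[i] = 0.0
    mu = float(fractions.mean())
    sigma = float(fractions.std(ddof=1))
    if sigma == 0:
        warnings.warn("degenerate null: permuted fractions have zero variance")
        if observed.fraction_validated > mu:
            p = 0.0
        elif observed.fraction_validated < mu:
            p = 1.0
        else:
            p = 0.5
    else:
        p = float(stats.norm.sf(observed.fraction_validated, loc=mu, scale=sigma))
    return ValidationResult(
        observed.n_predicted,
        observed.n_validated,
        observed.fraction_validated,
        random_fractions=fractions,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# motif-anchor concordance


@dataclass(frozen=True)
class ConcordanceRecord:
    """Per-motif tally of concordant vs discordant experimental anchors."""

    motif: MotifHit
    n_concordant_anchors: int
    n_discordant_anchors: int
    max_concordant_ligation: float
    max_discordant_ligation: float
    call: str

    @property
    def bidirectional(self) -> bool:
        return self.n_concordant_anchors > 0 and self.n_discordant_anchors > 0


def classify_anchor_concordance(
    motifs: Sequence[MotifHit],
    experimental_loops: Sequence[ExperimentalLoop],
) -> list[ConcordanceRecord]:
    """Tally anchor orientations per motif and call concordance.

    An overlapped anchor is concordant when the motif points into the loop
    body: + strand at the left (5') anchor or - strand at the right (3')
    anchor.  Several loops may anchor at the same motif, so counts and the
    maximum ligation support per orientation are accumulated.  Bidirectional
    motifs are discordant only if some discordant loop outweighs every
    concordant one; motifs overlapping no anchor are omitted.
    """
    left, right = _anchor_trees(experimental_loops)
    records = []
    for motif in motifs:
        iv = motif.interval
        conc = disc = 0
        max_conc = max_disc = 0.0
        for side, trees in (("left", left), ("right", right)):
            for idx in _hits(trees, iv.chrom, iv.start, iv.end):
                loop = experimental_loops[idx]
                concordant = (motif.strand == "+") == (side == "left")
                if concordant:
                    conc += 1
                    max_conc = max(max_conc, loop.ligation_count)
                else:
                    disc += 1
                    max_disc = max(max_disc, loop.ligation_count)
        if conc == 0 and disc == 0:
            continue
        if disc == 0:
            call = "concordant"
        elif conc == 0:
            call = "discordant"
        else:
            call = "concordant" if max_conc >= max_disc else "discordant"
        records.append(ConcordanceRecord(motif, conc, disc, max_conc, max_disc, call))
    return records


def concordance_by_score_bin(
    records: Sequence[ConcordanceRecord],
    bin_edges: Sequence[float],
) -> tuple[pd.DataFrame, float, float]:
    """Concordant fraction per motif-score bin plus an overall goodness test.

    Returns a frame with one row per bin (``n_motifs`` and
    ``fraction_concordant``; NaN for empty bins) and the chi-square statistic
    and p-value of the overall concordant/discordant split against 50/50.
    """
    if len(bin_edges) < 2:
        raise ValueError("need at least two bin edges")
    scores = pd.Series([r.motif.motif_score for r in records])
    concordant = pd.Series([r.call == "concordant" for r in records])
    bins = pd.cut(scores, bins=list(bin_edges), right=False)
    rows = []
    for interval in bins.cat.categories:
        mask = bins == interval
        n = int(mask.sum())
        frac = float(concordant[mask].mean()) if n else float("nan")
        rows.append({"bin": str(interval), "n_motifs": n, "fraction_concordant": frac})
    n_conc = int(concordant.sum())
    n_disc = len(records) - n_conc
    chi2, p = stats.chisquare([n_conc, n_disc])
    return pd.DataFrame(rows), float(chi2), float(p)
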