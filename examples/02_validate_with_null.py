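"""Validate predicted loops against a ChIA-PET-like loop set.

Simulates experimental loops over the planted truth, filters them the way
ChIA-PET interactions are filtered (intra-chromosomal, peaks at both
anchors, >= 3 ligation products), validates predictions with 100 bp anchor
extension, and contrasts the validated fraction with an orientation-
permutation null.
"""

import numpy as np

from ctcfloops import (
    FixtureConfig,
    assign_motifs_to_peaks,
    filter_chiapet_loops,
    format_p_value,
    generate_loop_landscape,
    null_distribution,
    predict_loops,
    simulate_chiapet,
)

config = FixtureConfig(n_loop_clusters=24, nesting_depth=1, seed=7)
land = generate_loop_landscape(config)
chiapet = simulate_chiapet(land.planted, config, np.random.default_rng(8), land.chrom_sizes)
chiapet = filter_chiapet_loops(chiapet, land.peaks, min_ligation=3)
print(f"{len(chiapet)} experimental loops survive the >=3 ligation-product filter")

anchors = assign_motifs_to_peaks(land.motifs, land.peaks)
pipeline = lambda a: predict_loops(a, peaks=land.peaks)
result = null_distribution(pipeline, anchors, chiapet, n_perm=200, seed=9)

nulls = result.random_fractions
print(
    f"observed: {result.n_validated}/{result.n_predicted} validated "
    f"({100 * result.fraction_validated:.1f}%)"
)
print(
    f"null (strand-permuted motifs, 200 runs): "
    f"mean {100 * nulls.mean():.1f}%, max {100 * nulls.max():.1f}%"
)
print(f"normal-fit upper-tail p {format_p_value(result.p_value)}")
# The observed fraction sits far above every permuted control: motif
# orientation, not peak placement, carries the loop signal.
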