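"""Binned feature profile across loop bodies and flanks.

Simulates a feature track 5x enriched inside loop bodies, builds the
30-bin median-FPKM profile (10 bins per flank, 10 for the body) and prints
the mean-centred bin values - the within-loop enrichment shows up as
positive body bins flanked by negative flank bins.
"""

import numpy as np

from ctcfloops import ChromSizes, GenomicInterval, feature_profile, simulate_feature_track

sizes = ChromSizes({"chr1": 2_000_000})
loops = [
    GenomicInterval("chr1", 40_000 * i + 20_000, 40_000 * i + 30_000) for i in range(40)
]
features = simulate_feature_track(
    loops, sizes, within_loop_rate=5.0, background_rate=1.0, seed=11
)
print(f"{len(features)} features over {len(loops)} loops of 10 kb")

profile = feature_profile(loops, features, sizes, n_bins=30, center=True)
body = profile.bin_values[10:20].mean()
flank = np.r_[profile.bin_values[:10], profile.bin_values[20:]].mean()
print(f"profile over {profile.n_loops_used} loops (centered, sums to {profile.bin_values.sum():.1e})")
print("bins  1-10 (left flank): ", np.round(profile.bin_values[:10], 1))
print("bins 11-20 (loop body):  ", np.round(profile.bin_values[10:20], 1))
print("bins 21-30 (right flank):", np.round(profile.bin_values[20:], 1))
print(f"mean body - mean flank = {body - flank:.1f} FPKM")
# Positive body bins against negative flanks reproduce the within-loop
# enrichment pattern of enhancer-associated marks.
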