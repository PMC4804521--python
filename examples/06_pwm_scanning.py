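"""Scan a sequence for CTCF-like motifs with the built-in PWM scanner.

Builds a toy position weight matrix, plants its consensus on both strands
of a random background sequence and scans with a p-value threshold (the
cutoff is derived from the exact background score distribution).
"""

import numpy as np

from ctcfloops import PWM, scan_pwm

rng = np.random.default_rng(3)
counts = np.array(
    [[90, 4, 3, 3], [3, 90, 4, 3], [3, 4, 90, 3], [90, 3, 4, 3],
     [3, 3, 4, 90], [3, 90, 4, 3], [90, 3, 4, 3], [3, 3, 90, 4]],
    dtype=float,
)
pwm = PWM.from_counts(counts, pseudocount=0.01)
print(f"consensus {pwm.consensus}, max log2-odds score {pwm.max_score:.2f}")

background = "".join(rng.choice(list("ACGT"), size=400))
revcomp = pwm.consensus.translate(str.maketrans("ACGT", "TGCA"))[::-1]
sequence = background[:100] + pwm.consensus + background[100:300] + revcomp + background[300:]

cutoff = pwm.score_cutoff(p_value=2.5e-4)
print(f"p = 2.5e-4 converts to a log2-odds cutoff of {cutoff:.2f}")
for hit in scan_pwm(sequence, pwm, p_threshold=2.5e-4, chrom="toy"):
    print(
        f"  {hit.interval.chrom}:{hit.interval.start}-{hit.interval.end} "
        f"({hit.strand})  score {hit.motif_score:.2f}"
    )
# The planted consensus is found once per strand at the planted positions;
# minus-strand hits report forward-strand coordinates.
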