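import numpy as np
import pytest
from hypothesis import settings

from ctcfloops import Anchor, GenomicInterval, MotifHit, Peak

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def make_anchor():
    """Factory for a peak-contained motif anchor at a given position.

    With the default motif score of 10 the anchor score equals the peak
    score, which keeps hand-traced examples readable.
    """

    def _make(
        pos: int,
        strand: str,
        peak_score: float = 100.0,
        motif_score: float = 10.0,
        chrom: str = "chr1",
        motif_len: int = 19,
        peak_pad: int = 50,
    ) -> Anchor:
        motif = MotifHit(GenomicInterval(chrom, pos, pos + motif_len, strand), motif_score)
        peak = Peak(
            GenomicInterval(chrom, max(0, pos - peak_pad), pos + motif_len + peak_pad),
            peak_score,
        )
        return Anchor(motif, peak)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20160322)
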