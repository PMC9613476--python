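import numpy as np
import pytest

from shatterscan.datamodel import GenomicInterval, Segment, SegmentProfile


def make_profile(case_id: str, chrom: str, states, seg_len: int = 1_000_000,
                 start: int = 0) -> SegmentProfile:
    """Build a profile from a list of (cn, loh) states laid end to end."""
    segs = []
    pos = start
    for st in states:
        cn, loh = st if isinstance(st, tuple) else (st, False)
        segs.append(Segment(GenomicInterval(chrom, pos, pos + seg_len), cn, loh))
        pos += seg_len
    return SegmentProfile.from_segments(case_id, segs)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def alternating_profile():
    """21 segments alternating cn 2,1,2,...,1,2: 20 switches, 2 states."""
    return make_profile("alt", "3", [2 if i % 2 == 0 else (1, True) for i in range(21)])


@pytest.fixture
def diploid_profile():
    return make_profile("dip", "3", [2])
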