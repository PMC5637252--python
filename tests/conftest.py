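import random

import pytest
from hypothesis import settings

from repseqprep.io_formats import SequenceRead

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_read(sequence, quality=None, read_id="r1", **kwargs):
    if quality == "flat40":
        quality = [40] * len(sequence)
    return SequenceRead(read_id=read_id, sequence=sequence, quality=quality, **kwargs)


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture
def random_reads(rng):
    """1,000 reads with random sequences and qualities (no planted structure)."""
    reads = []
    for i in range(1000):
        n = rng.randint(5, 80)
        seq = "".join(rng.choice("ACGTN" if rng.random() < 0.3 else "ACGT") for _ in range(n))
        qual = [rng.randint(0, 42) for _ in range(n)]
        reads.append(SequenceRead(read_id=f"r{i}", sequence=seq, quality=qual))
    return reads
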