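import dataclasses

import numpy as np
import pytest

from occushift.simulate import FixtureConfig, generate_bundle


@pytest.fixture
def rng():
    return np.random.default_rng(20140901)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default fixture bundle shared across the session (seed 11)."""
    config = dataclasses.replace(FixtureConfig(), seed=11)
    return generate_bundle(config, tmp_path_factory.mktemp("bundle"))


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=200):
    """n random small intervals for oracle-equivalence tests."""
    from occushift.intervals import Interval

    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        out.append(Interval(chrom, start, start + length))
    return out
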