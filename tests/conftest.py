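import numpy as np
import pytest

import bivalscape as bv


@pytest.fixture(scope="session")
def sim_config():
    return bv.SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def sim_bundle(sim_config):
    """One default synthetic dataset shared across the suite."""
    return bv.simulate_all(sim_config)


@pytest.fixture(scope="session")
def sim_catalog(sim_bundle):
    return bv.build_catalog(
        sim_bundle["genes"], chrom_lengths=sim_bundle["truth"].chrom_lengths
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def dense_intensity(track: bv.SignalTrack, interval: bv.GenomicInterval) -> float:
    """Brute-force per-base oracle for window_intensity (intervals <= 10 kb)."""
    assert len(interval) <= 10_000
    dense = np.zeros(len(interval))
    starts, ends, values = track.runs(interval.chrom)
    for s, e, v in zip(starts, ends, values):
        lo = max(int(s), interval.start) - interval.start
        hi = min(int(e), interval.end) - interval.start
        if hi > lo:
            dense[lo:hi] += v
    return float(dense.mean())
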