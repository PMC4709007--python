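import numpy as np
import pytest

from probmotif import (
    DiscoveryConfig,
    SequenceRecord,
    build_count_matrix,
    build_profile,
    multi_restart,
)
from probmotif.synthetic import SyntheticSpec, make_benchmark

PLANTED_CONSENSUS = "DFKKVDPHVHQLKGSSSSIG"


@pytest.fixture(scope="session")
def k1_profile():
    """Hand-checkable k=1 profile from the single-letter k-mers A, A, C, G."""
    cm = build_count_matrix(["A", "A", "C", "G"], 1)
    return build_profile(cm, M=4, mode="paper")


@pytest.fixture(scope="session")
def benchmark():
    """Default planted-motif benchmark: 100 training, 2000 decoys + 5 carriers."""
    spec = SyntheticSpec(seed=42)
    training, proteome, truth = make_benchmark(spec)
    return spec, training, proteome, truth


@pytest.fixture(scope="session")
def trained_profile(benchmark):
    """Gibbs-trained (20 restarts) profile on the benchmark training set."""
    _, training, _, _ = benchmark
    config = DiscoveryConfig(k=20, iterations=2000, restarts=20, seed=7)
    return multi_restart(training, config)


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(residues: str, rid: str = "seq1") -> SequenceRecord:
    return SequenceRecord(id=rid, residues=residues)
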