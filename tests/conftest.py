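"""Shared fixtures: small synthetic collections and archives."""

import numpy as np
import pytest

from genarc import SimSpec, build_archive, simulate_collection
from genarc.model import Params

ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int) -> bytes:
    return ACGT[rng.integers(0, 4, n)].tobytes()


@pytest.fixture(scope="session")
def small_collection():
    """80 kb reference, 5 mutated haplotypes, with indels and decoration."""
    spec = SimSpec(seed=11, ref_len=80_000, n_samples=5, snp_rate=0.001)
    return simulate_collection(spec)


@pytest.fixture(scope="session")
def small_params():
    return Params(k=17, segment_size=3000, block_size=5)


@pytest.fixture(scope="session")
def small_archive(tmp_path_factory, small_collection, small_params):
    ref, samples, _ = small_collection
    path = tmp_path_factory.mktemp("arc") / "small.gar"
    build_archive(path, ref, samples, small_params)
    return path
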