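"""Shared fixtures: constructed reads and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from sylvamir.qc import ReadRecord
from sylvamir.simulate import DEFAULT_ADAPTER3, SimulationConfig, simulate_genome

ADAPTER = DEFAULT_ADAPTER3


def make_read(
    sequence: str, rid: str = "r", quality: int = 38, qualities: list[int] | None = None
) -> ReadRecord:
    return ReadRecord(
        id=rid,
        sequence=sequence,
        qualities=qualities if qualities is not None else [quality] * len(sequence),
    )


def random_insert(rng: np.random.Generator, length: int = 21) -> str:
    """Random insert guaranteed clean wrt adapter seed and homopolymers."""
    while True:
        s = "".join(rng.choice(list("ACGT"), size=length))
        if max(s.count(b) for b in "ACGT") / length < 0.8 and ADAPTER[:10] not in s:
            return s


def adapter_read(
    insert: str, rid: str = "r", read_length: int = 50, pad_seed: int = 0
) -> ReadRecord:
    rng = np.random.default_rng(pad_seed)
    seq = insert + ADAPTER
    if len(seq) < read_length:
        seq += "".join(rng.choice(list("ACGT"), size=read_length - len(seq)))
    return make_read(seq[:read_length], rid)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced dataset for fast end-to-end tests."""
    return SimulationConfig(
        seed=7,
        n_planted_loci=5,
        n_decoy_stacks=8,
        genome_length=20_000,
        depth_per_sample=4_000,
        n_transcripts=12,
        n_target_sites=3,
        degradome_depth=4_000,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)
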