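"""Shared fixtures: small synthetic germline sets and repertoires."""

from __future__ import annotations

import numpy as np
import pytest

from igkit import SimulationConfig, make_germline_set
from igkit.preprocess import MergedRead, ReadPair, reverse_complement
from igkit.simulate import simulate_repertoire


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_v=5, n_d=4, n_j=3, n_clones=12, n_reads=120)


@pytest.fixture(scope="session")
def germlines(sim_config):
    return make_germline_set(sim_config, np.random.default_rng(sim_config.seed))


@pytest.fixture(scope="session")
def clean_repertoire(germlines, sim_config):
    """One replicate with no SHM and no sequencing error (exact ground truth)."""
    cfg = SimulationConfig(
        seed=sim_config.seed,
        n_clones=sim_config.n_clones,
        n_reads=sim_config.n_reads,
        shm_rate=0.0,
        seq_error_rate=0.0,
    )
    reads, truth = simulate_repertoire(germlines, cfg)
    return reads[0], truth


def pair_from_amplicon(
    amplicon: str,
    read_length: int = 250,
    read_index: int = 0,
    umi: str = "",
    qual: int = 35,
) -> ReadPair:
    """Construct an error-free mate pair covering a known amplicon."""
    fwd = umi + amplicon[: read_length - len(umi)]
    rev = reverse_complement(amplicon[-read_length:])
    return ReadPair(
        read_index=read_index,
        fwd_seq=fwd,
        rev_seq=rev,
        fwd_qual=tuple([qual] * len(fwd)),
        rev_qual=tuple([qual] * len(rev)),
    )


def merged_from(seq: str, qual: int = 35, umi: str | None = None, count: int = 1, indices=None) -> MergedRead:
    return MergedRead(
        sequence=seq,
        quality=tuple([qual] * len(seq)),
        umi=umi,
        read_indices=list(indices) if indices else [0],
        count=count,
    )
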