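"""Shared fixtures: tiny hand-built data and session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pytest

from wgbsbias.biassim import Methylome, ProtocolModel, PcrModel, SimConfig, simulate
from wgbsbias.refio import BsAlignment, GenomicInterval, ReferenceGenome


def make_alignment(
    call_string: str,
    start: int = 0,
    chrom: str = "chr1",
    bs_strand: str = "OT",
    read_id: str = "r",
    is_duplicate: bool = False,
) -> BsAlignment:
    return BsAlignment(
        read_id=read_id,
        interval=GenomicInterval(chrom, start, start + len(call_string)),
        bs_strand=bs_strand,
        call_string=call_string,
        is_duplicate=is_duplicate,
    )


@pytest.fixture
def aln():
    """Factory for quick BsAlignment construction."""
    return make_alignment


@pytest.fixture
def tiny_genome():
    return ReferenceGenome({"chr1": "ACGTACGTCC", "chr2": "TTAACCGGTT"})


@pytest.fixture(scope="session")
def null_bundle():
    """Null-preset simulation: 10-kb genome, 50x depth, no biases."""
    return simulate(
        SimConfig(
            seed=1,
            genome_length=10_000,
            depth=50,
            methylome=Methylome(p_mCG=0.7),
            protocol=ProtocolModel(),
            pcr=PcrModel(cycles=0),
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
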