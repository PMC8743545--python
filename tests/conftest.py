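"""Shared fixtures: a small multi-replicon genome and simulated strains.

All fixtures are generated programmatically with fixed seeds so the suite
is deterministic and self-contained.
"""

from __future__ import annotations

import numpy as np
import pytest

from lintopo import Genome, simulate_reads
from lintopo.simulate import (
    Circularize,
    DropReplicon,
    StrainSpec,
    derive_strain,
    generate_replicon,
)

SMALL_CHR_LEN = 30_000
SMALL_PLASMID_LEN = 4_000
SMALL_TIR = 300


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """30 kb chromosome + 4 kb plasmid, both linear with planted TIRs."""
    return Genome(
        [
            generate_replicon("chr", SMALL_CHR_LEN, 0.70, SMALL_TIR, seed=11),
            generate_replicon("pA", SMALL_PLASMID_LEN, 0.70, 200, seed=12),
        ],
        chromosome_name="chr",
    )


@pytest.fixture(scope="session")
def small_cured_strain(small_genome):
    """The small genome after plasmid loss and chromosome circularization
    (left deletion 400 bp, right deletion 600 bp — ~3% of the molecule,
    matching the few-percent scale of real terminal losses)."""
    spec = StrainSpec(
        events=[DropReplicon("pA"), Circularize("chr", 400, 600)],
    )
    return derive_strain(small_genome, spec), spec


@pytest.fixture(scope="session")
def small_errorfree_reads(small_genome):
    return simulate_reads(
        small_genome, mean_depth=20, read_len=150, sub_error=0.0, seed=21
    )


def rotation_equal(circular_a: str, circular_b: str) -> bool:
    """Equality of circular sequences up to rotation."""
    return len(circular_a) == len(circular_b) and circular_a in circular_b + circular_b
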