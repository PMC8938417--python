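from __future__ import annotations

import numpy as np
import pytest

from peakscape.core import GenomicInterval
from peakscape.synthetic import SimConfig, generate_dataset


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_intervals(
    rng: np.random.Generator,
    n: int,
    chroms: tuple[str, ...] = ("chr1", "chr2", "chr3"),
    span: int = 100_000,
    max_len: int = 500,
) -> list[GenomicInterval]:
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length, name=f"iv{i}"))
    return out


@pytest.fixture(scope="session")
def small_bundle():
    """A small deterministic synthetic bundle shared across tests."""
    return generate_dataset(
        SimConfig(
            n_chroms=2,
            chrom_length=2_000_000,
            n_genes=60,
            n_common=40,
            n_gained=20,
            n_lost=15,
            seed=7,
        )
    )
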