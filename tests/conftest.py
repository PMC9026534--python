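from __future__ import annotations

import numpy as np
import pytest

from herdgen.dataset import GenotypeDataset, MarkerRecord, SampleRecord


def make_ds(
    calls,
    chrom=None,
    pos=None,
    sexes=None,
    alleles=None,
) -> GenotypeDataset:
    """Small-dataset builder: calls is (n_samples x n_markers) list/array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    chrom = chrom if chrom is not None else [1] * m
    pos = pos if pos is not None else [(j + 1) * 1000 for j in range(m)]
    alleles = alleles if alleles is not None else [("A", "G")] * m
    markers = [
        MarkerRecord(f"snp{j + 1}", int(chrom[j]), int(pos[j]), *alleles[j])
        for j in range(m)
    ]
    samples = [
        SampleRecord(
            f"ind{i + 1}", sexes[i] if sexes else "unknown"
        )
        for i in range(n)
    ]
    return GenotypeDataset(samples=samples, markers=markers, calls=calls).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def family_sim():
    """Medium herd simulation shared across tests (deterministic)."""
    from herdgen.sim import simulate_family_dataset

    return simulate_family_dataset(
        n_families=4,
        boars_per_family=3,
        sows_per_family=8,
        n_generations=3,
        inbred_loop_fraction=0.3,
        n_chroms=6,
        n_markers_per_chrom=300,
        founder_fst=0.05,
        missing_rate=0.02,
        seed=42,
    )
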