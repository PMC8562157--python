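"""Shared fixtures: tiny hand fixtures plus a session-scoped simulated
population used by several modules' tests."""

from __future__ import annotations

import numpy as np
import pytest

from pedtrace.iomodel import (
    ALT_HOM,
    GeneticMap,
    GenotypeMatrix,
    Pedigree,
    PedigreeRecord,
    REF_HOM,
)
from pedtrace.simulate import SimConfig, simulate_population
from pedtrace.tracing import trace_generation


@pytest.fixture
def two_chrom_map() -> GeneticMap:
    """8 markers: 5 on chr1, 3 on chr2 (cM positions)."""
    return GeneticMap(
        [f"m{i}" for i in range(1, 9)],
        ["chr1"] * 5 + ["chr2"] * 3,
        [0.0, 10.0, 20.0, 30.0, 40.0, 0.0, 15.0, 30.0],
        unit="cM",
    )


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return Pedigree(
        [
            PedigreeRecord("p1"),
            PedigreeRecord("p2"),
            PedigreeRecord("kid", "p1", "p2"),
        ]
    )


@pytest.fixture
def informative_trio(two_chrom_map, trio_pedigree) -> GenotypeMatrix:
    """Parents differ (hom) at every marker; progeny mosaic."""
    n = len(two_chrom_map)
    p1 = np.full(n, REF_HOM, dtype=np.int8)
    p2 = np.full(n, ALT_HOM, dtype=np.int8)
    kid = np.array([0, 0, 2, 2, 2, 0, 0, 0], dtype=np.int8)
    return GenotypeMatrix(
        ["p1", "p2", "kid"], two_chrom_map.marker_ids, np.stack([p1, p2, kid])
    )


@pytest.fixture(scope="session")
def sim_result():
    """Small simulated RIL population with ground truth (shared, read-only)."""
    cfg = SimConfig(
        seed=11,
        n_founders=4,
        n_families=3,
        lines_per_family=30,
        n_chromosomes=3,
        markers_per_chromosome=60,
        chrom_length_cM=100.0,
        selfing_generations=5,
        maf=(0.2, 0.5),
        n_qtl=8,
        qtl_allele_mode="founder-specific",
        h2_target=0.6,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def sim_traced(sim_result):
    origins, summary = trace_generation(
        sim_result.genotypes, sim_result.pedigree, sim_result.gmap
    )
    return origins, summary
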