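"""Shared fixtures: small pedigrees and a reusable simulated population."""

from __future__ import annotations

import numpy as np
import pytest

import hblup as hb
from hblup.pedigree import Pedigree, PedigreeRecord


@pytest.fixture
def trio_pedigree() -> Pedigree:
    """Two founders and one offspring."""
    return Pedigree([
        PedigreeRecord("1"),
        PedigreeRecord("2"),
        PedigreeRecord("3", "1", "2"),
    ])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_pedigree(n: int, rng: np.random.Generator,
                    n_founders: int | None = None) -> Pedigree:
    """Random acyclic pedigree: each non-founder draws parents from earlier
    individuals (possibly unknown), so generations overlap."""
    n_founders = n_founders or max(2, n // 5)
    recs = [PedigreeRecord(str(i + 1)) for i in range(n_founders)]
    for i in range(n_founders, n):
        pool = [r.id for r in recs]
        sire = rng.choice(pool) if rng.random() < 0.9 else "0"
        dam_pool = [p for p in pool if p != sire]
        dam = rng.choice(dam_pool) if dam_pool and rng.random() < 0.9 else "0"
        recs.append(PedigreeRecord(str(i + 1), str(sire), str(dam)))
    return Pedigree(recs)


@pytest.fixture(scope="session")
def small_population() -> hb.Population:
    """Scenario-1 population at a reduced desk scale, shared across tests.

    5 sires x 10 dams x 2 offspring = 100 offspring per generation over
    5 generations, 55 founders, 6 chromosomes (1,800 markers).
    """
    cfg = hb.ScenarioConfig(scenario=1, n_sires=5, dams_per_sire=10)
    return hb.simulate_scenario(cfg, hb.GenomeSpec(n_chromosomes=6), seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_population) -> hb.EvalDataset:
    phe = hb.simulate_phenotypes(
        small_population,
        hb.PhenotypeSimConfig(n_causal=300, h2=0.8, alpha_true=-0.5, seed=7),
    )
    return hb.EvalDataset.from_population(small_population, phe)
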