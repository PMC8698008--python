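"""Shared fixtures: small simulated populations reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from haplodeficit.genodata import build_cohorts
from haplodeficit.simdata import (
    LethalLocusSpec,
    SimConfig,
    simulate_population,
)


def recovery_config(seed: int, penetrance: float = 1.0) -> SimConfig:
    """~2000 animals, one generation, one planted recessive lethal."""
    locus = LethalLocusSpec(
        chromosome=0,
        center_marker=80,
        span_markers=90,
        target_carrier_frequency=0.085,
        penetrance=penetrance,
        linked_variant_offset_bp=12_345,
    )
    return SimConfig(
        n_chromosomes=1,
        markers_per_chromosome=160,
        chromosome_length_bp=16_000_000,
        n_founders=200,
        n_generations=1,
        matings_per_generation=450,
        offspring_per_mating=4,
        n_ancestral_haplotypes=25,
        lethal_loci=(locus,),
        seed=seed,
    )


def null_config(seed: int, markers: int = 2049) -> SimConfig:
    """~2000 animals, no lethal locus, ~2000 scan windows."""
    return SimConfig(
        n_chromosomes=1,
        markers_per_chromosome=markers,
        chromosome_length_bp=100_000_000,
        n_founders=200,
        n_generations=1,
        matings_per_generation=450,
        offspring_per_mating=4,
        n_ancestral_haplotypes=25,
        seed=seed,
    )


@pytest.fixture(scope="session")
def recovery_pop():
    return simulate_population(recovery_config(seed=11))


@pytest.fixture(scope="session")
def recovery_cohorts(recovery_pop):
    return build_cohorts(
        recovery_pop.pedigree, set(recovery_pop.haplotypes.animal_ids)
    )


@pytest.fixture(scope="session")
def multigen_pop():
    """Two generations so pgp cohorts exist; some dams ungenotyped."""
    cfg = SimConfig(
        n_chromosomes=2,
        markers_per_chromosome=80,
        chromosome_length_bp=8_000_000,
        n_founders=80,
        n_generations=2,
        matings_per_generation=60,
        offspring_per_mating=2,
        n_ancestral_haplotypes=20,
        trio_fraction=0.7,
        seed=42,
    )
    return simulate_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
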