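import numpy as np
import pytest

from ryeassoc.kinship import kinship_matrix
from ryeassoc.markers import filter_maf, phase_gametes
from ryeassoc.simulate import (
    CohortConfig,
    EffectsConfig,
    default_scenario,
    simulate_cohort,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-emulating cohort (201 genotypes, 170 sites)."""
    cfg, _ = default_scenario()
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_kinship(default_cohort):
    return kinship_matrix(default_cohort.ssr)


@pytest.fixture(scope="session")
def phased_markers(default_cohort):
    phased = phase_gametes(default_cohort.s0_calls, default_cohort.sites)
    return filter_maf(phased, 0.05)


def small_cohort_config(seed=11):
    """A reduced cohort for fast model-fitting tests."""
    return CohortConfig(
        population_sizes={"EKOAGRO": 20, "Petkus": 30, "PR2733": 15,
                          "ROM103": 18, "SMH2502": 7},
        n_ssr_loci=20,
        genes={"ScCbf15": (6, 1), "ScIce2": (8, 1), "ScVrn1": (5, 0),
               "ScDhn3": (4, 0)},
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_cohort_config())


@pytest.fixture(scope="session")
def small_kinship(small_cohort):
    return kinship_matrix(small_cohort.ssr)


def null_effects(seed=0, **overrides):
    """Effects with no causal sites or interactions (polygenic only)."""
    kw = dict(causal_sites=[], interactions=[], seed=seed)
    kw.update(overrides)
    return EffectsConfig(**kw)


@pytest.fixture(scope="session")
def small_phenotypes(small_cohort):
    eff = null_effects(
        seed=5,
        causal_sites=[],
        controlled_replicates=2, sc_replicates=2,
        field_env_means={"KAS": 70.0, "SAS1": 60.0},
        field_replicates={"KAS": 2, "SAS1": 2},
    )
    return simulate_phenotypes(small_cohort, eff)
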