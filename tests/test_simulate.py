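"""Synthetic cohort and phenotype generator: design fidelity, determinism
and generative/analytic consistency at small scale."""

import numpy as np
import pandas as pd
import pytest

from ryeassoc.markers import filter_maf, phase_gametes, site_maf
from ryeassoc.simulate import (
    CausalSite,
    CohortConfig,
    EffectsConfig,
    default_scenario,
    simulate_cohort,
    simulate_phenotypes,
)

from conftest import null_effects, small_cohort_config


def test_default_scenario_dimensions(default_cohort):
    cfg, eff = default_scenario()
    assert cfg.n_genotypes == 201
    assert len(cfg.population_sizes) == 5
    n_snp = sum(s for s, _ in cfg.genes.values())
    n_indel = sum(i for _, i in cfg.genes.values())
    assert (n_snp, n_indel) == (161, 9)
    assert cfg.n_sites == 170
    cfg.__post_init__()  # re-validates invariants without error
    assert len(default_cohort.genotype_ids) == 201
    assert default_cohort.ssr.n_loci == 37
    assert len(set(default_cohort.truth.population_of.values())) == 5


def test_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(population_sizes={"A": 0})
    with pytest.raises(ValueError):
        CohortConfig(genes={"G": (0, 0)})
    with pytest.raises(ValueError):
        EffectsConfig(sigma2_chamber=-1.0)
    with pytest.raises(ValueError):
        EffectsConfig(unit_intercept_trend_corr=1.5)


def test_cohort_determinism():
    cfg = small_cohort_config(seed=99)
    a = simulate_cohort(cfg)
    b = simulate_cohort(small_cohort_config(seed=99))
    assert a.s0_calls.equals(b.s0_calls)
    assert np.array_equal(a.ssr.alleles, b.ssr.alleles)
    assert np.allclose(a.q.q.values, b.q.q.values)
    c = simulate_cohort(small_cohort_config(seed=100))
    assert not a.s0_calls.equals(c.s0_calls)


def test_single_population_degenerate_admixture():
    cfg = CohortConfig(population_sizes={"only": 12}, n_ssr_loci=5,
                       genes={"G1": (3, 0)}, seed=1,
                       concentrated_sites={},
                       admixture_concentration={"only": 1e9})
    cohort = simulate_cohort(cfg)
    q = cohort.truth.q_true.values
    assert np.allclose(q[:, 0], 1.0) and np.allclose(q[:, 1:], 0.0)


def test_s0_calls_contain_parent_allele(small_cohort):
    parent = small_cohort.parent_alleles
    for site in small_cohort.s0_calls.columns[:5]:
        ref = str(parent[site])
        assert small_cohort.s0_calls[site].str.split("/").map(
            lambda p: ref in p).all()


def test_phenotypes_zero_variance_equal_intercepts(small_cohort):
    eff = null_effects(
        sigma2_g={"controlled": 0.0, "semi_controlled": 0.0, "field": 0.0},
        sigma2_e={"controlled": 0.0, "semi_controlled": 0.0, "field": 0.0},
        sigma2_chamber=0.0, sigma2_replication=0.0,
        sigma2_unit_intercept=0.0, sigma2_unit_trend=0.0, sigma2_block=0.0,
        controlled_year_effect=0.0, controlled_temp_effect=0.0,
        sc_year_effect=0.0, sc_trend_slope=0.0, sc_year_trend=0.0,
        controlled_replicates=1, sc_replicates=1,
        field_env_means={"KAS": 55.0}, field_replicates={"KAS": 1})
    phen = simulate_phenotypes(small_cohort, eff)
    ctrl = phen.platform("controlled")["value"]
    assert np.allclose(ctrl, eff.controlled_intercept)
    semi = phen.platform("semi_controlled")["value"]
    assert np.allclose(semi, eff.sc_intercept)
    fld = phen.platform("field")["value"]
    assert np.allclose(fld, 55.0)


def test_controlled_design_row_count(small_cohort):
    eff = null_effects(controlled_replicates=5,
                       field_env_means={"KAS": 60.0},
                       field_replicates={"KAS": 2})
    phen = simulate_phenotypes(small_cohort, eff)
    n_geno = len(small_cohort.genotype_ids)
    # genotypes x 2 temperatures x 5 replicates per year, summed over years
    assert len(phen.platform("controlled")) == n_geno * 2 * 5 * 2
    # chambers: 3 in 2008, 4 in 2009
    ctrl = phen.platform("controlled")
    assert ctrl.groupby("year")["chamber"].nunique().tolist() == [3, 4]
    # field: one environment with 2 replicate blocks
    assert len(phen.platform("field")) == n_geno * 2
    # semi-controlled: 3 reps x (3 months 2008 + 2 months 2009)
    semi = phen.platform("semi_controlled")
    assert len(semi) == n_geno * 3 * 5
    assert sorted(semi[semi.year == 2008]["month"].unique()) == [1, 2, 4]
    assert sorted(semi[semi.year == 2009]["month"].unique()) == [2, 3]


def test_polygenic_variance_monte_carlo(small_cohort):
    """Realized polygenic draws have marginal variance sigma2_g
    (the kinship diagonal is 1), within 3 Monte-Carlo standard errors."""
    s2g = 0.5
    reps = 40
    rep_means = []
    for r in range(reps):
        eff = null_effects(
            seed=r, sigma2_g={"controlled": s2g, "semi_controlled": 0.0,
                              "field": 0.0},
            sigma2_e={"controlled": 0.01, "semi_controlled": 0.01,
                      "field": 0.01},
            sigma2_chamber=0.0, controlled_replicates=1,
            field_env_means={"KAS": 50.0}, field_replicates={"KAS": 1})
        simulate_phenotypes(small_cohort, eff)
        poly = small_cohort.truth.polygenic["controlled"].to_numpy()
        rep_means.append(np.mean(poly ** 2))
    mean = np.mean(rep_means)
    se = np.std(rep_means, ddof=1) / np.sqrt(reps)
    assert abs(mean - s2g) < 3 * se


def test_clipping_fraction_reported_and_small(default_cohort):
    _, eff = default_scenario()
    phen = simulate_phenotypes(default_cohort, eff)
    clip = default_cohort.truth.clipped_fraction
    assert set(clip) == {"controlled", "semi_controlled", "field"}
    assert all(0.0 <= v < 0.01 for v in clip.values())


def test_unknown_causal_site_rejected(small_cohort):
    eff = null_effects(causal_sites=[CausalSite("nope_SNP1",
                                                {"controlled": 1.0})])
    with pytest.raises(ValueError, match="unknown"):
        simulate_phenotypes(small_cohort, eff)


def test_default_sites_pass_maf_filter(default_cohort):
    phased = phase_gametes(default_cohort.s0_calls, default_cohort.sites)
    kept = filter_maf(phased, 0.05)
    assert kept.n_sites == 170
    assert min(site_maf(phased, s) for s in phased.site_ids) > 0.05


def test_concentrated_site_population_specific(default_cohort):
    """The large-effect site's allele is concentrated in one population."""
    phased = phase_gametes(default_cohort.s0_calls, default_cohort.sites)
    carrier = phased.calls["ScIce2_SNP7"].astype(str) != "A"
    pops = pd.Series(default_cohort.truth.population_of)
    freq = carrier.groupby(pops).mean()
    assert freq.idxmax() == "PR2733"
    assert freq["PR2733"] > 2 * freq.drop("PR2733").max()
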