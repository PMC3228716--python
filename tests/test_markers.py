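"""Gamete phasing, haplotype definition and MAF filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ryeassoc.markers import (
    binarize_site,
    define_haplotypes,
    filter_maf,
    phase_gametes,
    site_maf,
)
from ryeassoc.types import MarkerMatrix


def _sites(site_defs):
    return pd.DataFrame(
        [{"site_id": s, "gene": g, "site_index": i + 1, "site_type": "SNP",
          "ref_allele": r}
         for i, (s, g, r) in enumerate(site_defs)]).set_index("site_id")


def test_phase_subtraction_cases():
    sites = _sites([("s1", "G1", "A")])
    s0 = pd.DataFrame({"s1": ["A/G", "A/A", "G/T", None]},
                      index=["g1", "g2", "g3", "g4"])
    mm = phase_gametes(s0, sites)
    # heterozygous: the non-parent member is the gamete allele
    assert mm.calls.loc["g1", "s1"] == "G"
    # homozygous for the parent allele: gamete equals the parent allele
    assert mm.calls.loc["g2", "s1"] == "A"
    # neither member is the parent allele: flagged and set missing
    assert pd.isna(mm.calls.loc["g3", "s1"])
    assert mm.n_inconsistent == 1
    assert pd.isna(mm.calls.loc["g4", "s1"])


def test_phase_requires_parent_allele():
    sites = _sites([("s1", "G1", "A")])
    sites.loc["s1", "ref_allele"] = np.nan
    s0 = pd.DataFrame({"s1": ["A/G"]}, index=["g1"])
    with pytest.raises(ValueError, match="parent allele missing"):
        phase_gametes(s0, sites)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.integers(2, 25), st.integers(1, 6))
def test_phase_inverts_parent_addition(seed, n_geno, n_sites):
    """Phasing recovers any gamete matrix after adding the parent allele."""
    rng = np.random.default_rng(seed)
    sites = _sites([(f"s{j}", "G1", "A") for j in range(n_sites)])
    gametes = pd.DataFrame(
        rng.choice(["A", "G", "T"], size=(n_geno, n_sites)),
        index=[f"g{i}" for i in range(n_geno)], columns=sites.index)
    s0 = gametes.apply(lambda col: ["/".join(sorted((a, "A"))) for a in col])
    phased = phase_gametes(s0, sites)
    assert phased.calls.astype(str).equals(gametes.astype(str))


def test_phase_matches_simulator_truth(default_cohort):
    phased = phase_gametes(default_cohort.s0_calls, default_cohort.sites)
    truth = default_cohort.truth.gametes.calls
    assert phased.calls.astype(str).equals(truth.astype(str))
    assert phased.n_inconsistent == 0


def test_define_haplotypes_counts():
    sites = _sites([("s1", "G1", "A"), ("s2", "G1", "G")])
    calls = pd.DataFrame({"s1": ["A", "A", "A", "A"],
                          "s2": ["G", "G", "T", "G"]},
                         index=list("abcd"))
    mm = MarkerMatrix(calls, sites)
    hap = define_haplotypes(mm, "G1")
    assert hap.frequencies["ref"] == pytest.approx(0.75)
    assert hap.frequencies["hap1"] == pytest.approx(0.25)
    assert hap.strings["ref"] == "A|G"
    # all-parent case collapses to a single reference haplotype
    calls2 = calls.copy()
    calls2["s2"] = "G"
    hap2 = define_haplotypes(MarkerMatrix(calls2, sites), "G1")
    assert list(hap2.frequencies.index) == ["ref"]
    assert hap2.frequencies["ref"] == pytest.approx(1.0)


def test_define_haplotypes_unknown_gene_rejected(default_cohort):
    from ryeassoc.markers import phase_gametes as pg
    mm = pg(default_cohort.s0_calls, default_cohort.sites)
    with pytest.raises(KeyError):
        define_haplotypes(mm, "no_such_gene")


def test_haplotypes_match_simulator_pools(default_cohort):
    """Recovered haplotype partition equals the simulator's pool assignment."""
    phased = phase_gametes(default_cohort.s0_calls, default_cohort.sites)
    for gene in ["ScCbf15", "ScIce2"]:
        hap = define_haplotypes(phased, gene)
        truth = default_cohort.truth.pool_assignment[gene]
        # same partition: every recovered label maps to exactly one pool
        # index that carries a distinct allele pattern
        df = pd.DataFrame({"label": hap.assignment, "pool": truth})
        pools = default_cohort.truth.pools[gene]
        pattern_of_pool = {i: tuple(pools[i]) for i in range(len(pools))}
        for lab, grp in df.groupby("label"):
            patterns = {pattern_of_pool[p] for p in grp["pool"]}
            assert len(patterns) == 1


def test_haplotype_frequency_invariants(default_cohort):
    phased = phase_gametes(default_cohort.s0_calls, default_cohort.sites)
    hap = define_haplotypes(phased, "ScCbf12")
    assert hap.frequencies.sum() == pytest.approx(1.0)
    shuffled = phased.calls.sample(frac=1, random_state=3)
    hap2 = define_haplotypes(MarkerMatrix(shuffled, phased.sites), "ScCbf12")
    assert hap.frequencies.sort_index().equals(hap2.frequencies.sort_index())


def test_filter_maf_strict_threshold():
    """A site at exactly the threshold frequency is dropped (strict >)."""
    sites = _sites([("s1", "G1", "A"), ("s2", "G1", "A")])
    col1 = ["G"] + ["A"] * 19          # maf exactly 0.05
    col2 = ["G"] * 10 + ["A"] * 10     # maf 0.5
    mm = MarkerMatrix(pd.DataFrame({"s1": col1, "s2": col2},
                                   index=[f"g{i}" for i in range(20)]), sites)
    kept = filter_maf(mm, 0.05)
    assert kept.site_ids == ["s2"]


def test_filter_maf_matches_bruteforce_recount(default_cohort):
    phased = phase_gametes(default_cohort.s0_calls, default_cohort.sites)
    kept = filter_maf(phased, 0.05)
    expected = []
    for s in phased.site_ids:
        col = phased.calls[s].dropna()
        counts = col.value_counts()
        if 1.0 - counts.iloc[0] / counts.sum() > 0.05:
            expected.append(s)
    assert kept.site_ids == expected


def test_filter_maf_idempotent(phased_markers):
    once = filter_maf(phased_markers, 0.05)
    twice = filter_maf(once, 0.05)
    assert once.site_ids == twice.site_ids
    hap = define_haplotypes(phased_markers, "ScCbf9b")
    f1 = filter_maf(hap, 0.05)
    f2 = filter_maf(f1, 0.05)
    assert f1.assignment.fillna("NA").equals(f2.assignment.fillna("NA"))


def test_filter_maf_threshold_domain(phased_markers):
    with pytest.raises(ValueError):
        filter_maf(phased_markers, 0.0)
    with pytest.raises(ValueError):
        filter_maf(phased_markers, 0.5)


def test_binarize_multiallelic_site():
    """Rarer non-reference alleles are set missing, not pooled."""
    sites = _sites([("s1", "G1", "A")])
    col = ["A"] * 5 + ["G"] * 3 + ["T"]
    mm = MarkerMatrix(pd.DataFrame({"s1": col},
                                   index=[f"g{i}" for i in range(9)]), sites)
    code = binarize_site(mm, "s1")
    assert code.iloc[0] == 0.0
    assert code.iloc[5] == 1.0
    assert np.isnan(code.iloc[8])


def test_site_maf_definition():
    sites = _sites([("s1", "G1", "A")])
    col = ["A"] * 6 + ["G"] * 4
    mm = MarkerMatrix(pd.DataFrame({"s1": col},
                                   index=[f"g{i}" for i in range(10)]), sites)
    assert site_maf(mm, "s1") == pytest.approx(0.4)
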