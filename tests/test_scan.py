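"""Association stages: model recipes, scans, concordance, summaries."""

import numpy as np
import pandas as pd
import pytest

from ryeassoc.lmm import fit_lmm
from ryeassoc.markers import binarize_site, define_haplotypes, filter_maf, phase_gametes
from ryeassoc.scan import (
    PlatformContext,
    cross_platform_correlation,
    epistasis_scan,
    genotype_varcomp_test,
    platform_model,
    snp_scan,
    summarize_significant,
)
from ryeassoc.simulate import simulate_phenotypes
from ryeassoc.types import PhenotypeTable

from conftest import null_effects


@pytest.fixture(scope="module")
def small_markers(small_cohort):
    return filter_maf(phase_gametes(small_cohort.s0_calls,
                                    small_cohort.sites), 0.05)


def test_controlled_model_recipe(small_phenotypes, small_cohort, small_kinship):
    spec = platform_model("controlled", small_phenotypes, small_cohort.q,
                          small_kinship)
    labels = set(spec.x_labels)
    assert "intercept" in labels
    assert any(l.startswith("year_") for l in labels)
    assert any(l.startswith("temp_") for l in labels)
    # k structure columns minus one (identifiability)
    assert sum(l.startswith("Q_") for l in labels) == small_cohort.q.k - 1
    assert [b.label for b in spec.blocks] == ["chamber", "genotype"]
    assert spec.blocks[1].kind == "kinship_root"


def test_field_model_recipe(small_phenotypes, small_cohort, small_kinship):
    spec = platform_model("field", small_phenotypes, small_cohort.q,
                          small_kinship)
    env_cols = [l for l in spec.x_labels if l.startswith("env_")]
    assert len(env_cols) == 2 and "intercept" not in spec.x_labels
    assert [b.label for b in spec.blocks] == ["block", "genotype"]


def test_semi_controlled_model_recipe(small_phenotypes, small_cohort,
                                      small_kinship):
    spec = platform_model("semi_controlled", small_phenotypes,
                          small_cohort.q, small_kinship)
    assert "trend" in spec.x_labels
    assert any("x_trend" in l for l in spec.x_labels)
    kinds = {b.label: b.kind for b in spec.blocks}
    assert kinds == {"replication": "iid", "unit": "intercept_trend",
                     "genotype": "kinship_root"}


def test_phenotypic_analysis_variant_drops_marker_and_q(small_phenotypes,
                                                        small_cohort,
                                                        small_kinship):
    spec = platform_model("controlled", small_phenotypes, small_cohort.q,
                          small_kinship, include_q=False)
    assert not any(l.startswith("Q_") for l in spec.x_labels)
    assert not any(l == "marker" for l in spec.x_labels)


def test_platform_model_errors(small_phenotypes, small_cohort, small_kinship):
    with pytest.raises(ValueError, match="unknown platform"):
        platform_model("greenhouse", small_phenotypes, small_cohort.q,
                       small_kinship)
    q_short = small_cohort.q.q.iloc[:-3]
    from ryeassoc.types import StructureMatrix
    with pytest.raises(ValueError, match="missing from Q"):
        platform_model("controlled", small_phenotypes,
                       StructureMatrix(q_short), small_kinship)


def test_varcomp_test_nesting_and_power(small_cohort, small_kinship):
    eff = null_effects(seed=3, controlled_replicates=2,
                       field_env_means={"KAS": 60.0},
                       field_replicates={"KAS": 2},
                       sigma2_g={"controlled": 0.4, "semi_controlled": 25.0,
                                 "field": 36.0})
    phen = simulate_phenotypes(small_cohort, eff)
    s2g, stat, p = genotype_varcomp_test(
        phen, "controlled", {"year": 2008, "temperature": -19.0},
        small_kinship)
    assert s2g >= 0 and stat >= 0 and 0 <= p <= 1
    # strong genetic signal across 2 replicates: clearly significant
    assert p < 0.01
    with pytest.raises(ValueError, match="needs keys"):
        genotype_varcomp_test(phen, "controlled", {"year": 2008},
                              small_kinship)


def test_snp_scan_detects_causal_site(small_cohort, small_kinship,
                                      small_markers):
    eff = null_effects(
        seed=21, controlled_replicates=2,
        field_env_means={"KAS": 60.0}, field_replicates={"KAS": 2})
    from ryeassoc.simulate import CausalSite
    eff.causal_sites = [CausalSite("ScIce2_SNP3", {"controlled": 0.5})]
    phen = simulate_phenotypes(small_cohort, eff)
    sub = small_markers.subset_sites(
        [s for s in small_markers.site_ids if s.startswith("ScIce2")])
    res = snp_scan(phen, sub, small_cohort.q, small_kinship, "controlled")
    assert (res["p"].dropna() <= 1).all() and (res["p"].dropna() >= 0).all()
    assert (res["var_explained_pct"].dropna() >= 0).all()
    hit = res.set_index("unit").loc["ScIce2_SNP3"]
    assert hit["p"] < 0.01 and hit["beta"] > 0


def test_scan_uses_raw_replicates_not_means(small_cohort, small_kinship,
                                            small_markers, small_phenotypes):
    """One-stage fidelity: collapsing replicates to genotype means changes
    the result."""
    sub = small_markers.subset_sites(small_markers.site_ids[:2])
    res_raw = snp_scan(small_phenotypes, sub, small_cohort.q, small_kinship,
                       "controlled")
    ctrl = small_phenotypes.platform("controlled")
    means = (ctrl.groupby("genotype_id", as_index=False)
             .agg({"value": "mean", "year": "first", "temperature": "first",
                   "chamber": "first", "replicate": "first",
                   "environment": "first", "month": "first",
                   "block": "first", "platform": "first"}))
    res_mean = snp_scan(PhenotypeTable(means), sub, small_cohort.q,
                        small_kinship, "controlled")
    assert not np.allclose(res_raw["t"].to_numpy(),
                           res_mean["t"].to_numpy(), atol=1e-6)


def test_permuted_marker_loses_signal(small_cohort, small_kinship,
                                      small_markers):
    eff = null_effects(seed=8, controlled_replicates=2,
                       field_env_means={"KAS": 60.0},
                       field_replicates={"KAS": 2})
    from ryeassoc.simulate import CausalSite
    eff.causal_sites = [CausalSite("ScIce2_SNP3", {"controlled": 0.6})]
    phen = simulate_phenotypes(small_cohort, eff)
    code = binarize_site(small_markers, "ScIce2_SNP3")
    ctx = PlatformContext(phen, "controlled", small_cohort.q, small_kinship)
    from ryeassoc.lmm import wald_test
    fit = fit_lmm(ctx.model(covariates={"m": code}), "reml")
    _, _, _, p_true = wald_test(fit, "m")
    rng = np.random.default_rng(0)
    p_perms = []
    for _ in range(5):
        perm = pd.Series(rng.permutation(code.to_numpy()), index=code.index)
        fitp = fit_lmm(ctx.model(covariates={"m": perm}), "reml")
        p_perms.append(wald_test(fitp, "m")[3])
    assert p_true < 1e-6
    assert np.median(p_perms) > 0.05


def test_haplotype_scan_outputs(small_cohort, small_kinship, small_markers,
                                small_phenotypes):
    from ryeassoc.scan import haplotype_scan
    haps = [filter_maf(define_haplotypes(small_markers, g), 0.05)
            for g in small_markers.genes]
    res = haplotype_scan(small_phenotypes, haps, small_cohort.q,
                         small_kinship, "controlled")
    overall = res[res["kind"] == "haplotype_overall"]
    assert len(overall) >= 1
    assert overall["p"].between(0, 1).all()
    assert (overall["var_explained_pct"].dropna() >= 0).all()
    contrasts = res[res["kind"] == "haplotype"]
    assert contrasts["note"].str.contains("overall").all()


def test_epistasis_invariant_to_haplotype_relabeling(small_cohort,
                                                     small_kinship,
                                                     small_markers,
                                                     small_phenotypes):
    haps = {g: filter_maf(define_haplotypes(small_markers, g), 0.05)
            for g in ["ScIce2", "ScVrn1"]}
    res1 = epistasis_scan(small_phenotypes, list(haps.values()),
                          small_cohort.q, small_kinship, "controlled",
                          gene_pairs=[("ScIce2", "ScVrn1")])
    # relabel ScVrn1 haplotypes (swap two non-reference labels)
    h = haps["ScVrn1"]
    labs = [l for l in h.frequencies.index if l != "ref"]
    swap = {labs[0]: labs[1], labs[1]: labs[0]}
    h2 = type(h)(gene=h.gene,
                 strings={swap.get(k, k): v for k, v in h.strings.items()},
                 assignment=h.assignment.map(lambda v: swap.get(v, v)),
                 frequencies=h.frequencies.rename(index=swap))
    res2 = epistasis_scan(small_phenotypes, [haps["ScIce2"], h2],
                          small_cohort.q, small_kinship, "controlled",
                          gene_pairs=[("ScIce2", "ScVrn1")])
    assert res1.loc[0, "t"] == pytest.approx(res2.loc[0, "t"], abs=1e-5)
    assert res1.loc[0, "df"] == res2.loc[0, "df"]


def test_cross_platform_correlation_identity_and_errors():
    t = np.arange(10, dtype=float)
    df = pd.DataFrame({"unit": [f"s{i}" for i in range(10)],
                       "t": t, "p": np.linspace(0.01, 0.5, 10)})
    res = cross_platform_correlation({"a": df, "b": df.copy()})
    assert res.loc[0, "r"] == pytest.approx(1.0)
    sig = cross_platform_correlation({"a": df, "b": df.copy()},
                                     subset="significant", alpha=0.3)
    assert sig.loc[0, "n_units"] <= 10
    with pytest.raises(ValueError, match="fewer than 3"):
        cross_platform_correlation({"a": df.iloc[:2], "b": df.iloc[:2]})
    with pytest.raises(ValueError, match="subset"):
        cross_platform_correlation({"a": df, "b": df}, subset="sig")


def test_summarize_counts_match_bruteforce():
    rng = np.random.default_rng(5)
    units = [f"g{i // 4}_s{i}" for i in range(20)]
    genes = [u.split("_")[0] for u in units]
    results = {}
    for plat in ("a", "b", "c"):
        results[plat] = pd.DataFrame({
            "unit": units, "gene": genes, "p": rng.uniform(size=20)})
    summary = summarize_significant(results, alpha=0.3)
    # brute-force recount
    for plat in results:
        for gene in set(genes):
            df = results[plat]
            expected = ((df["gene"] == gene) & (df["p"] < 0.3)).sum()
            got = (summary["per_gene"].loc[gene, plat]
                   if gene in summary["per_gene"].index else 0)
            assert got == expected
    oc = summary["overlap_counts"]
    assert oc["all"] <= oc[">=2"] <= oc[">=1"]
    empty = {p: results[p].assign(p=1.0) for p in results}
    s2 = summarize_significant(empty, alpha=0.05)
    assert s2["per_gene"].values.sum() == 0
    assert s2["overlap_counts"] == {">=1": 0, ">=2": 0, "all": 0}
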