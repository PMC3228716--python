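"""Synthetic gamete-capture cohort and phenotype generator.

The generator reproduces the statistical structure the association
analysis assumes: five cross-pollinated source populations (default sizes
44, 68, 33, 41, 15) crossed to one homozygous tester parent, so each
genotype carries one population gamete; 37 multi-allelic SSR loci for
structure/kinship estimation; 12 candidate genes carrying 161 SNPs and 9
Indels whose within-gene linkage disequilibrium arises from finite
ancestral haplotype pools; and frost-tolerance phenotypes from three
platforms generated from exactly the mixed model the analysis fits
(fixed platform effects + causal allelic effects + kinship-structured
polygenic term + platform random effects + iid residual).

Ground truth for every estimand (Q, gamete matrix, haplotype pools,
effects, realized random draws) is stored in a TruthRecord.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from ryeassoc import kinship as kin
from ryeassoc.types import (
    MarkerMatrix,
    PhenotypeTable,
    SsrGenotypes,
    StructureMatrix,
)

#: source-population names and sizes of the emulated study material
DEFAULT_POPULATIONS = {
    "EKOAGRO": 44, "Petkus": 68, "PR2733": 33, "ROM103": 41, "SMH2502": 15,
}

#: candidate genes and their polymorphic-site counts (SNPs, Indels);
#: totals 161 SNPs + 9 Indels = 170 sites over 12 genes
DEFAULT_GENES = {
    "ScCbf2": (11, 1), "ScCbf6": (7, 1), "ScCbf9b": (17, 1),
    "ScCbf11": (9, 1), "ScCbf12": (14, 1), "ScCbf14": (7, 0),
    "ScCbf15": (13, 1), "ScDhn1": (5, 1), "ScDhn3": (8, 1),
    "ScDreb2": (12, 1), "ScIce2": (37, 0), "ScVrn1": (21, 0),
}

REF_ALLELE = {"SNP": "A", "Indel": "-"}
ALT_ALLELE = {"SNP": "G", "Indel": "+"}


@dataclass
class CohortConfig:
    """Cohort-level generator settings (populations, markers, LD, admixture)."""

    population_sizes: dict = field(
        default_factory=lambda: dict(DEFAULT_POPULATIONS))
    n_ssr_loci: int = 37
    ssr_alleles_per_locus: int = 6
    genes: dict = field(default_factory=lambda: dict(DEFAULT_GENES))
    haplotype_pool_size: int = 6       # finite pools induce within-gene LD
    n_clusters: int = 3                # ancestral clusters behind Q
    admixture_concentration: dict = field(default_factory=dict)
    # site whose favorable allele is concentrated in one ancestral cluster
    # (pool haplotype 1 of its gene carries it; high frequency in the named
    # cluster only), emulating a population-specific large-effect variant
    concentrated_sites: dict = field(
        default_factory=lambda: {"ScIce2_SNP7": 2})
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.population_sizes or any(v <= 0 for v in self.population_sizes.values()):
            raise ValueError("population sizes must be positive")
        if self.n_ssr_loci < 1 or self.haplotype_pool_size < 2:
            raise ValueError("need >= 1 SSR locus and pool size >= 2")
        if self.n_clusters < 2:
            raise ValueError("need k >= 2 ancestral clusters")
        for g, (s, i) in self.genes.items():
            if s + i < 1:
                raise ValueError(f"gene {g} has zero sites")
        if not self.admixture_concentration:
            self.admixture_concentration = {p: 30.0 for p in self.population_sizes}

    @property
    def n_genotypes(self) -> int:
        return sum(self.population_sizes.values())

    @property
    def n_sites(self) -> int:
        return sum(s + i for s, i in self.genes.values())


@dataclass
class CausalSite:
    """One causal polymorphic site with per-platform allelic effects
    (outcome units per copy of the non-reference allele)."""

    site_id: str
    effects: dict                      # platform -> beta


@dataclass
class InteractionEffect:
    """Haplotype-pair epistatic effect between two genes."""

    gene_a: str
    pool_hap_a: int                    # index into gene_a's haplotype pool
    gene_b: str
    pool_hap_b: int
    effects: dict                      # platform -> interaction effect


@dataclass
class EffectsConfig:
    """Phenotype-model settings: fixed effects, variances, causal effects.

    Variance units are squared outcome units of each platform (recovery
    score 0-5 for controlled, percentage points for the others).
    """

    causal_sites: list = field(default_factory=list)
    interactions: list = field(default_factory=list)
    # polygenic genotype variance per platform
    sigma2_g: dict = field(default_factory=lambda: {
        "controlled": 0.15, "semi_controlled": 25.0, "field": 36.0})
    # residual variance per platform
    sigma2_e: dict = field(default_factory=lambda: {
        "controlled": 0.20, "semi_controlled": 49.0, "field": 64.0})
    # controlled platform
    sigma2_chamber: float = 0.04
    controlled_intercept: float = 2.8
    controlled_year_effect: float = -0.5       # 2009 vs 2008
    controlled_temp_effect: float = -0.5       # -21 vs -19 degC
    # semi-controlled platform
    sc_intercept: float = 65.0
    sc_year_effect: float = -5.0
    sc_trend_slope: float = -8.0               # per (centered) calendar month
    sc_year_trend: float = 2.0
    sigma2_replication: float = 4.0
    sigma2_unit_intercept: float = 36.0
    sigma2_unit_trend: float = 4.0
    unit_intercept_trend_corr: float = 0.3
    # field platform
    field_env_means: dict = field(default_factory=lambda: {
        "KAS": 70.0, "LIP1": 65.0, "MIN": 55.0,
        "SAS1": 60.0, "SAS2": 35.0, "LIP2": 50.0})
    sigma2_block: float = 16.0
    # replication structure (defaults follow the emulated designs)
    controlled_replicates: int = 5
    sc_replicates: int = 3
    field_replicates: dict = field(default_factory=lambda: {
        "KAS": 3, "LIP1": 3, "MIN": 3, "SAS1": 2, "SAS2": 2, "LIP2": 3})
    # optional per-cluster mean shifts (platform -> one value per ancestral
    # cluster, applied as true_Q @ shifts); models population-level
    # differences in frost tolerance, the classic stratification confounder
    structure_effects: dict = field(default_factory=dict)
    # polygenic draws from the realized SSR kinship (self-consistent with
    # the estimator) or from the true cluster-based relatedness
    use_true_relatedness: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.sigma2_g, self.sigma2_e):
            if any(v < 0 for v in d.values()):
                raise ValueError("variances must be non-negative")
        for v in (self.sigma2_chamber, self.sigma2_replication,
                  self.sigma2_unit_intercept, self.sigma2_unit_trend,
                  self.sigma2_block):
            if v < 0:
                raise ValueError("variances must be non-negative")
        if abs(self.unit_intercept_trend_corr) > 1:
            raise ValueError("|intercept-trend correlation| must be <= 1")


@dataclass
class TruthRecord:
    """Ground truth stored alongside a simulated cohort."""

    q_true: pd.DataFrame
    gametes: MarkerMatrix
    pool_assignment: pd.DataFrame      # genotype x gene -> pool haplotype index
    pools: dict                        # gene -> (n_pool x n_sites) 0/1 array
    population_of: dict                # genotype_id -> source population
    causal_sites: list = field(default_factory=list)
    interactions: list = field(default_factory=list)
    polygenic: dict = field(default_factory=dict)      # platform -> Series
    random_effects: dict = field(default_factory=dict)  # platform -> dict
    clipped_fraction: dict = field(default_factory=dict)


@dataclass
class Cohort:
    """A simulated gamete-capture cohort (S0 plants of one tester parent)."""

    ssr: SsrGenotypes
    s0_calls: pd.DataFrame             # diploid "a/b" calls at candidate sites
    sites: pd.DataFrame                # site metadata incl. parent ref allele
    parent_alleles: pd.Series
    q: StructureMatrix
    truth: TruthRecord

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.s0_calls.index)


# ------------------------------------------------------------------ helpers

def _site_table(genes: dict) -> pd.DataFrame:
    rows = []
    for gene, (n_snp, n_indel) in genes.items():
        kinds = ["SNP"] * n_snp + ["Indel"] * n_indel
        for i, kind in enumerate(kinds, start=1):
            rows.append({"site_id": f"{gene}_SNP{i}", "gene": gene,
                         "site_index": i, "site_type": kind,
                         "ref_allele": REF_ALLELE[kind]})
    return pd.DataFrame(rows).set_index("site_id")


def _cluster_base(populations: list[str], k: int) -> dict[str, np.ndarray]:
    """Base membership vector per source population over k clusters.

    The first min(k, n_pops) populations anchor one cluster each; any
    further populations are admixed, mostly in the last cluster with a
    minority share of the first.  A single population degenerates to a
    pure unit-vector base (no admixture).
    """
    if set(populations) == set(DEFAULT_POPULATIONS) and k == 3:
        # the emulated study's structure: Petkus and PR2733 form distinct
        # clusters; the three Polish populations are admixed in a third
        # cluster with a minority share of PR2733's cluster
        story = {
            "EKOAGRO": [0.80, 0.05, 0.15], "ROM103": [0.80, 0.05, 0.15],
            "SMH2502": [0.80, 0.05, 0.15], "Petkus": [0.05, 0.90, 0.05],
            "PR2733": [0.05, 0.05, 0.90],
        }
        return {p: np.array(story[p]) for p in populations}
    bases = {}
    n_anchor = min(k, len(populations))
    for i, p in enumerate(populations):
        if len(populations) == 1:
            b = np.zeros(k)
            b[0] = 1.0
        elif i < n_anchor:
            b = np.full(k, 0.075)
            b[i] = 1.0
        else:
            b = np.full(k, 0.05)
            b[k - 1] = 0.70
            b[0] = 0.30
        bases[p] = b / b.sum()
    return {p: b / b.sum() for p, b in bases.items()}


def _dirichlet_on_support(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw allowing zero alpha entries (mass stays on the support)."""
    out = np.zeros_like(alpha, dtype=float)
    support = alpha > 0
    if support.sum() == 1:
        out[support] = 1.0
        return out
    out[support] = rng.dirichlet(alpha[support])
    return out


def _build_pools(rng: np.random.Generator, gene_sites: int,
                 pool_size: int) -> np.ndarray:
    """0/1 alt-allele patterns of a gene's ancestral haplotype pool.

    Row 0 is the tester parent's (all-reference) haplotype.  Every site
    carries the alt allele on an intermediate share of pool haplotypes so
    that cohort-level minor-allele frequencies stay well inside (0.05,
    0.95) for any seed.
    """
    n_alt = pool_size - 1
    pools = np.zeros((pool_size, gene_sites), dtype=np.int8)
    for s in range(gene_sites):
        # alt on 40-60% of the non-reference pool haplotypes
        k = int(np.clip(round(n_alt * rng.uniform(0.4, 0.6)), 1, n_alt - 1)) \
            if n_alt > 1 else 1
        carriers = rng.choice(n_alt, size=k, replace=False) + 1
        pools[carriers, s] = 1
    # deduplicate identical pool haplotypes by flipping a site
    for h in range(2, pool_size):
        tries = 0
        while any((pools[h] == pools[j]).all() for j in range(h)) and tries < 20:
            s = int(rng.integers(gene_sites))
            pools[h, s] = 1 - pools[h, s]
            tries += 1
    return pools


def _pool_frequencies(rng: np.random.Generator, pool_size: int,
                      k: int) -> np.ndarray:
    """Cluster-specific sampling frequencies over a gene's pool (k x pool).

    Moderately differentiated across clusters (Dirichlet draws around a
    common base) so that unadjusted association tests are confounded by
    structure while every pool haplotype keeps appreciable frequency.
    """
    base = rng.dirichlet(np.full(pool_size, 8.0))
    freqs = np.vstack([rng.dirichlet(base * 40.0) for _ in range(k)])
    # keep every pool haplotype sampleable in every cluster
    freqs = np.clip(freqs, 0.02, None)
    return freqs / freqs.sum(axis=1, keepdims=True)


# --------------------------------------------------------------- operations

def simulate_cohort(config: CohortConfig) -> Cohort:
    """Draw a gamete-capture cohort with stored ground truth.

    Per population, each genotype draws admixture proportions (Dirichlet
    around the population's base membership), then per gene samples an
    ancestry component and one gamete from that cluster's haplotype pool;
    its S0 call is gamete + parent allele.  SSR genotypes are one allele
    from ancestry-specific frequencies plus the parent allele.
    Deterministic given (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    pops = list(config.population_sizes)
    k = config.n_clusters
    bases = _cluster_base(pops, k)
    sites = _site_table(config.genes)
    genes = list(config.genes)

    genotype_ids, population_of = [], {}
    for p in pops:
        for i in range(config.population_sizes[p]):
            gid = f"{p}_{i + 1:03d}"
            genotype_ids.append(gid)
            population_of[gid] = p
    n = len(genotype_ids)

    # admixture proportions (true Q)
    q_rows = np.vstack([
        _dirichlet_on_support(
            rng, config.admixture_concentration[population_of[g]]
            * bases[population_of[g]])
        for g in genotype_ids])
    q_true = pd.DataFrame(q_rows, index=genotype_ids,
                          columns=[f"cluster{j + 1}" for j in range(k)])

    # ancestral haplotype pools and cluster-specific pool frequencies
    pools, pool_freqs = {}, {}
    site_pos_in_gene = {sid: int(np.flatnonzero(
        sites[sites["gene"] == sites.loc[sid, "gene"]].index == sid)[0])
        for sid in config.concentrated_sites if sid in sites.index}
    for gene in genes:
        m = sum(config.genes[gene])
        pools[gene] = _build_pools(rng, m, config.haplotype_pool_size)
        pool_freqs[gene] = _pool_frequencies(rng, config.haplotype_pool_size, k)
        for sid, cluster in config.concentrated_sites.items():
            if sid in sites.index and sites.loc[sid, "gene"] == gene:
                j = site_pos_in_gene[sid]
                # only pool haplotype 1 carries the concentrated allele
                pools[gene][:, j] = 0
                pools[gene][1, j] = 1
                f = pool_freqs[gene]
                rest = np.delete(np.arange(config.haplotype_pool_size), 1)
                for c in range(k):
                    target = 0.55 if c == cluster % k else 0.05
                    f[c, 1] = target
                    f[c, rest] *= (1.0 - target) / f[c, rest].sum()
                pool_freqs[gene] = f / f.sum(axis=1, keepdims=True)

    # one gamete per gene per genotype
    pool_assignment = pd.DataFrame(0, index=genotype_ids, columns=genes,
                                   dtype=int)
    gamete_cols = {}
    for gene in genes:
        gene_site_ids = list(sites[sites["gene"] == gene].index)
        m = len(gene_site_ids)
        anc = np.array([rng.choice(k, p=q_rows[i]) for i in range(n)])
        hap_idx = np.array([rng.choice(config.haplotype_pool_size,
                                       p=pool_freqs[gene][a]) for a in anc])
        pool_assignment[gene] = hap_idx
        patterns = pools[gene][hap_idx]  # (n, m) 0/1
        for j, sid in enumerate(gene_site_ids):
            kind = sites.loc[sid, "site_type"]
            ref, alt = REF_ALLELE[kind], ALT_ALLELE[kind]
            gamete_cols[sid] = np.where(patterns[:, j] == 1, alt, ref)
    gametes = MarkerMatrix(
        pd.DataFrame(gamete_cols, index=genotype_ids,
                     columns=list(sites.index)).astype(object),
        sites.copy())

    # S0 diploid calls = gamete + parent (reference) allele
    parent_alleles = sites["ref_allele"].copy()
    s0 = {}
    for sid in sites.index:
        ref = str(parent_alleles[sid])
        s0[sid] = ["/".join(sorted((str(a), ref)))
                   for a in gamete_cols[sid]]
    s0_calls = pd.DataFrame(s0, index=genotype_ids, columns=list(sites.index))

    # SSR genotypes: population gamete allele + parent allele per locus
    n_all = config.ssr_alleles_per_locus
    ssr_alleles = np.zeros((n, config.n_ssr_loci, 2), dtype=np.int64)
    for loc in range(config.n_ssr_loci):
        freqs = np.vstack([rng.dirichlet(np.full(n_all, 0.6))
                           for _ in range(k)])
        parent_allele = int(rng.integers(n_all))
        labels = 100 + 2 * np.arange(n_all) + 20 * loc
        for i in range(n):
            a = rng.choice(k, p=q_rows[i])
            gam = rng.choice(n_all, p=freqs[a])
            ssr_alleles[i, loc] = sorted((labels[gam], labels[parent_allele]))
    ssr = SsrGenotypes(genotype_ids, [f"SSR{j + 1:02d}"
                                      for j in range(config.n_ssr_loci)],
                       ssr_alleles)

    truth = TruthRecord(q_true=q_true, gametes=gametes,
                        pool_assignment=pool_assignment, pools=pools,
                        population_of=population_of)
    return Cohort(ssr=ssr, s0_calls=s0_calls, sites=sites,
                  parent_alleles=parent_alleles,
                  q=StructureMatrix(q_true.copy()), truth=truth)


# ------------------------------------------------------- phenotype designs

def _month_codes(year: int) -> list[int]:
    """Calendar month indices of the semi-controlled scoring dates."""
    return [1, 2, 4] if year == 2008 else [2, 3]


CHAMBERS = {2008: ["C1", "C2", "C3"], 2009: ["C4", "C5", "C6", "C7"]}


def _genetic_values(cohort: Cohort, effects: EffectsConfig,
                    platform: str, rng: np.random.Generator,
                    kin_root: np.ndarray) -> tuple[pd.Series, pd.Series]:
    """Per-genotype causal marker value and polygenic draw for a platform."""
    gids = cohort.genotype_ids
    gam = cohort.truth.gametes
    causal = pd.Series(0.0, index=gids)
    for cs in effects.causal_sites:
        if cs.site_id not in gam.calls.columns:
            raise ValueError(f"causal site {cs.site_id!r} unknown")
        beta = cs.effects.get(platform, 0.0)
        ref = str(gam.sites.loc[cs.site_id, "ref_allele"])
        ind = (gam.calls[cs.site_id].astype(str) != ref).astype(float)
        causal += beta * ind
    for ia in effects.interactions:
        for g in (ia.gene_a, ia.gene_b):
            if g not in cohort.truth.pool_assignment.columns:
                raise ValueError(f"interaction references unknown gene {g!r}")
        eff = ia.effects.get(platform, 0.0)
        both = ((cohort.truth.pool_assignment[ia.gene_a] == ia.pool_hap_a)
                & (cohort.truth.pool_assignment[ia.gene_b] == ia.pool_hap_b))
        causal += eff * both.astype(float)

    shifts = effects.structure_effects.get(platform)
    if shifts is not None:
        qv = cohort.truth.q_true.to_numpy()
        if len(shifts) != qv.shape[1]:
            raise ValueError("structure_effects length must match the "
                             "number of ancestral clusters")
        causal += pd.Series(qv @ np.asarray(shifts, dtype=float), index=gids)

    s2g = effects.sigma2_g.get(platform, 0.0)
    z = rng.standard_normal(len(gids))
    poly = pd.Series(np.sqrt(s2g) * (kin_root @ z), index=gids)
    return causal, poly


def simulate_phenotypes(cohort: Cohort, effects: EffectsConfig) -> PhenotypeTable:
    """Generate three-platform phenotypes from the analysis's own model.

    Outcomes are intercept + platform fixed effects + causal allelic
    effects + polygenic effect N(0, K sigma_g^2) + platform random effects
    + iid residual, then clipped to the platform's admissible range
    (clipped fractions recorded in the cohort's TruthRecord).
    Replication follows the emulated designs: controlled 2 temperatures x
    2 years x 5 replicates in 7 chambers; semi-controlled 3 replicates
    with months Jan/Feb/Apr 2008 and Feb/Mar 2009; field 6 environments
    with 2 or 3 replicate blocks.
    """
    rng = np.random.default_rng(effects.seed)
    gids = cohort.genotype_ids
    n = len(gids)

    if effects.use_true_relatedness:
        qv = cohort.truth.q_true.values
        K = qv @ qv.T
        d = np.sqrt(np.clip(np.diag(K), 1e-12, None))
        K = K / np.outer(d, d)
        np.fill_diagonal(K, 1.0)
        km = kin.ensure_psd(kin.KinshipMatrix(gids, (K + K.T) / 2))
    else:
        km = kin.kinship_matrix(cohort.ssr)
    kin_root = kin.covariance_root(km)

    truth = cohort.truth
    truth.random_effects = {}
    truth.polygenic = {}
    truth.clipped_fraction = {}

    # ----------------------------------------------------------- controlled
    causal, poly = _genetic_values(cohort, effects, "controlled", rng, kin_root)
    truth.polygenic["controlled"] = poly
    chamber_eff = {c: rng.normal(0.0, np.sqrt(effects.sigma2_chamber))
                   for yr in CHAMBERS for c in CHAMBERS[yr]}
    truth.random_effects["controlled"] = {"chamber": chamber_eff}
    rows = []
    for year in (2008, 2009):
        chambers = CHAMBERS[year]
        assigned = {g: chambers[int(rng.integers(len(chambers)))] for g in gids}
        for temp in (-19.0, -21.0):
            for rep in range(1, effects.controlled_replicates + 1):
                mu = (effects.controlled_intercept
                      + (effects.controlled_year_effect if year == 2009 else 0.0)
                      + (effects.controlled_temp_effect if temp == -21.0 else 0.0))
                eps = rng.normal(0.0, np.sqrt(effects.sigma2_e["controlled"]), n)
                for i, g in enumerate(gids):
                    rows.append((g, "controlled", year, None, temp, None,
                                 assigned[g], f"{year}_r{rep}", None,
                                 mu + causal[g] + poly[g]
                                 + chamber_eff[assigned[g]] + eps[i]))
    all_rows = list(rows)

    # ------------------------------------------------------ semi-controlled
    causal, poly = _genetic_values(cohort, effects, "semi_controlled", rng,
                                   kin_root)
    truth.polygenic["semi_controlled"] = poly
    sc_reps = list(range(1, effects.sc_replicates + 1))
    rep_eff = {f"{yr}_r{r}": rng.normal(0.0, np.sqrt(effects.sigma2_replication))
               for yr in (2008, 2009) for r in sc_reps}
    v1, v2 = effects.sigma2_unit_intercept, effects.sigma2_unit_trend
    rho = effects.unit_intercept_trend_corr
    cov = np.array([[v1, rho * np.sqrt(v1 * v2)],
                    [rho * np.sqrt(v1 * v2), v2]])
    croot = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    unit_draws = {}
    rows = []
    for year in (2008, 2009):
        months = _month_codes(year)
        center = float(np.mean(months))
        for g in gids:
            unit_draws[(g, year)] = croot @ rng.standard_normal(2)
        for rep in sc_reps:
            for month in months:
                tt = month - center
                mu = (effects.sc_intercept
                      + (effects.sc_year_effect if year == 2009 else 0.0)
                      + effects.sc_trend_slope * tt
                      + (effects.sc_year_trend * tt if year == 2009 else 0.0))
                eps = rng.normal(0.0, np.sqrt(effects.sigma2_e["semi_controlled"]), n)
                for i, g in enumerate(gids):
                    b0, b1 = unit_draws[(g, year)]
                    rows.append((g, "semi_controlled", year, None, None, month,
                                 None, f"{year}_r{rep}", None,
                                 mu + causal[g] + poly[g] + b0 + b1 * tt
                                 + rep_eff[f"{year}_r{rep}"] + eps[i]))
    truth.random_effects["semi_controlled"] = {
        "replication": rep_eff, "unit": unit_draws}
    all_rows.extend(rows)

    # ---------------------------------------------------------------- field
    causal, poly = _genetic_values(cohort, effects, "field", rng, kin_root)
    truth.polygenic["field"] = poly
    field_reps = {e: n for e, n in effects.field_replicates.items()
                  if e in effects.field_env_means}
    block_eff = {f"{env}_b{r}": rng.normal(0.0, np.sqrt(effects.sigma2_block))
                 for env, nr in field_reps.items() for r in range(1, nr + 1)}
    truth.random_effects["field"] = {"block": block_eff}
    rows = []
    for env, nr in field_reps.items():
        year = 2010 if env == "LIP2" else 2009
        mu_env = effects.field_env_means[env]
        for rep in range(1, nr + 1):
            block = f"{env}_b{rep}"
            eps = rng.normal(0.0, np.sqrt(effects.sigma2_e["field"]), n)
            for i, g in enumerate(gids):
                rows.append((g, "field", year, env, None, None, None,
                             f"r{rep}", block,
                             mu_env + causal[g] + poly[g]
                             + block_eff[block] + eps[i]))
    all_rows.extend(rows)
    df = pd.DataFrame(all_rows, columns=PhenotypeTable.COLUMNS)
    # clip to admissible outcome ranges; record clipped fractions
    from ryeassoc.types import PLATFORM_RANGE
    for plat, (lo, hi) in PLATFORM_RANGE.items():
        m = df["platform"] == plat
        clipped = ((df.loc[m, "value"] < lo) | (df.loc[m, "value"] > hi)).mean()
        truth.clipped_fraction[plat] = float(clipped)
        df.loc[m, "value"] = df.loc[m, "value"].clip(lo, hi)
    df["year"] = df["year"].astype("Int64")
    df["month"] = df["month"].astype("Int64")
    truth.causal_sites = list(effects.causal_sites)
    truth.interactions = list(effects.interactions)
    return PhenotypeTable(df)


def default_scenario() -> tuple[CohortConfig, EffectsConfig]:
    """The study-emulating configuration.

    Three moderate-effect causal sites in two Cbf-family genes (two in
    ScCbf15, one in ScCbf12, acting across all platforms) plus one
    large-effect site in ScIce2 whose favorable allele is concentrated in
    the PR2733-like population, and one epistatic haplotype pair.
    """
    cohort = CohortConfig()
    effects = EffectsConfig(
        causal_sites=[
            CausalSite("ScCbf15_SNP3", {"controlled": 0.30,
                                        "semi_controlled": 2.0, "field": 3.0}),
            CausalSite("ScCbf15_SNP8", {"controlled": -0.25,
                                        "semi_controlled": -1.7, "field": -2.5}),
            CausalSite("ScCbf12_SNP5", {"controlled": 0.25,
                                        "semi_controlled": 1.8, "field": 2.5}),
            CausalSite("ScIce2_SNP7", {"controlled": 0.30,
                                       "semi_controlled": 1.5, "field": 4.3}),
        ],
        interactions=[
            InteractionEffect("ScVrn1", 1, "ScDhn3", 1,
                              {"controlled": 0.45, "semi_controlled": 4.0,
                               "field": 5.0}),
        ],
    )
    return cohort, effects

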