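# Methods

`ryeassoc` implements a candidate-gene association analysis of frost
tolerance (FT) in winter rye under a gamete-capture design, together
with a synthetic-data generator that produces cohorts with exactly the
statistical structure the analysis assumes. This note records the
models, the generator's assumptions, the numerical choices, and what the
tests do and do not demonstrate.

## The design and the data

Heterozygous plants from five cross-pollinated source populations are
crossed to a single homozygous inbred tester, so each S0 offspring
carries one population gamete plus the tester gamete. Phase is
recovered by *parent subtraction*: at every polymorphic site the gamete
allele is the member of the diploid pair that is not the tester's
allele (a homozygous call means the gamete carries the tester allele; a
call containing no tester allele cannot arise under the design, is
flagged as a genotyping inconsistency, counted, and set missing).
Marker data are therefore effectively haploid, and within-gene
haplotypes are simply the distinct allele strings over a gene's sites.
Insertion/deletion polymorphisms are ordinary single sites.

FT is phenotyped on three platforms with different fixed/random-effect
structure:

| platform | outcome | fixed effects | random effects |
|---|---|---|---|
| controlled | recovery score 0–5 | year, freezing temperature | chamber (iid, 7 labels over two years), genotype |
| semi-controlled | % plants with undamaged leaves | year, linear within-year month trend, year×trend | replication (iid), per genotype-by-year unit random intercept + month trend (unstructured 2×2), genotype |
| field | % winter survival | full environment-indicator set (no separate intercept) | block nested in environment (iid), genotype |

## The association model

All tests use one-stage Gaussian linear mixed models on raw
replicate-level observations (never genotype means):

    y = β₁ + X_SNP β_SNP + Q β_STRUCTURE + X_PLATFORM β_PLATFORM
        + Z_PLATFORM γ_PLATFORM + Z_GENOTYPE γ_GENOTYPE + ε,

with γ_GENOTYPE ~ N(0, K σ²_g) for a kinship matrix K,
γ_PLATFORM ~ N(0, D σ²) per the platform recipes above, and
ε ~ N(0, I σ²). Population-structure membership fractions Q enter as
fixed covariates; because the k columns of Q sum to one and collide with
the intercept, the last column is dropped (a pure reparameterization —
other estimates are unaffected).

The kinship-structured genotype effect is realized by the
*root-embedding trick*: with L any matrix root (L Lᵀ = K), replacing the
genotype incidence design Z by Z L turns the K-structured block into an
iid block with identical likelihood. The engine relies on this
everywhere; a dedicated test verifies at random parameter points that
the embedded likelihood equals the explicit Z K Zᵀ σ²_g evaluation to
1e-10.

Inference:

* **Single-site scan** — each site's 0/1 non-reference-allele indicator
  is added to the platform model (REML); effect, Wald t and two-sided P
  are reported. P uses the standard-normal reference by default (the
  analysis tradition this follows reports t values without denominator
  degrees of freedom); a Student-t reference is available as an option.
  Sites are tested one at a time (single-marker models), complete-case
  on the marker.
* **Variance explained** — 100·(σ²_g,without − σ²_g,with)/σ²_g,without
  from matching REML fits on identical rows, truncated below at zero
  (variance components need not decrease under added adjustment);
  defined as 0 when the reduced genetic variance is 0.
* **Haplotype tests** — per gene, an ML likelihood-ratio test of all
  retained non-reference haplotype indicators versus none (overall P),
  then Wald contrasts of each haplotype against the tester parent's
  reference haplotype from the matching REML fit. Contrasts are
  reported for every gene with the overall-gate outcome flagged, since
  users may want them even when the overall test misses the threshold.
* **Epistasis** — per gene pair, an ML LRT of main effects plus all
  pairwise haplotype-interaction indicators versus main effects only;
  the df is the number of estimable interaction columns after
  collinearity pruning; complete-case on both genes.
* **Genotypic variance tests** — within each stratum (temperature×year,
  month×year, or location), a REML fit with and without the genotype
  block, compared by a χ²₁ LRT. The χ² reference is deliberately
  conservative for variance components, whose true null distribution is
  a chi-square mixture; the calibration test confirms rejection below
  the nominal level.
* **Cross-platform concordance** — Pearson correlation of per-site t
  values between platform pairs, overall and restricted to sites
  significant (P < α) in at least one member of the pair.
* **Multiple testing** — raw two-sided α = 0.05 is the primary
  threshold (sites within genes are in strong LD, making Bonferroni
  overly conservative); exact P values and a Bonferroni column are
  emitted for downstream adjustment.

ML is used for all LRTs that compare fixed-effect sets (haplotype
overall, epistasis) — REML likelihoods are not comparable across
different fixed effects and the engine enforces this; REML is used for
variance-component reporting and variance explained.

## Kinship

For two diploid SSR genotypes at one locus the similarity index is the
fraction of alleles shared under the best pairing: 1 for identical
pairs, 0.5 for one shared allele, 0 for none. (A strict
identical/different {0,1} variant is available via `het_mode="strict"`;
the allele-sharing fraction is the standard choice and the default.)
Similarities are averaged over loci with non-missing data for both
genotypes and standardized as Ŝ = (S − S_min)/(1 − S_min), where S_min
is the minimum off-diagonal raw similarity — the only reading of the
standardization that maps the observed range onto [0, 1]; the diagonal
is pinned at 1. Any residual negative eigenvalues are clipped to zero,
the matrix reconstructed and its diagonal rescaled (eigenvalue clipping
rather than nearest-correlation iteration: simple, deterministic, and
adequate at n ≈ 200). `covariance_root` returns the Cholesky factor
when the repaired matrix is positive definite and a symmetric
eigendecomposition root when singular (e.g. duplicated genotypes).

## The estimation engine

Variance parameters are optimized as log variance *ratios*
γ_b = σ²_b/σ² (correlation of the 2×2 intercept-trend block via tanh),
with the fixed effects profiled out by GLS and σ² profiled analytically,
leaving a low-dimensional bounded quasi-Newton problem (L-BFGS-B,
projected-gradient tolerance 1e-8, three deterministic starts at ratio
values 0.5/0.05/3, best optimum kept; scans warm-start each fit from the
matching no-marker optimum). Ratios are floored at 1e-10 internally and
reported as variance 0 with a boundary flag when at the floor. A
line-search failure at an already-flat optimum is accepted when the
projected gradient is small; genuine non-convergence raises with
diagnostics.

All per-iteration algebra runs on cross-products of the stacked random
design, so the cost is O(q³) in the number of random-effect columns and
independent of n. For the semi-controlled platform (whose per-unit
intercept/trend block contributes 2·(genotypes×years) columns) the inner
matrix is factored as a 2×2-block-diagonal core bordered by the dense
replication and genotype columns, reducing the cost to O(U·m²); the
factorization is verified against the dense path and against
`direct_loglik`, a deliberately naive oracle that forms the full n×n
covariance and evaluates the exact (restricted) likelihood (guarded to
small n).

Collinear fixed-effect columns are pruned at model construction by QR
with column pivoting (relative tolerance 1e-8); dropped labels are
recorded and testing a dropped coefficient is an error.

## The synthetic-data generator

Cohort defaults emulate the study material: populations of sizes
44/68/33/41/15 (201 genotypes), 37 SSR loci with six alleles each, and
12 candidate genes carrying 161 SNPs + 9 Indels (170 sites). Three
ancestral clusters stand behind the structure matrix: two populations
anchor their own clusters and the remaining three are admixed in a
third, one cluster sharing partially with the admixed group — mirroring
the emulated study's reported clustering. Each genotype draws its
membership row from a Dirichlet around its population's base vector
(concentration 30 by default); per gene it samples an ancestry component
from that row and one gamete from a finite ancestral haplotype pool
(six haplotypes per gene by default). Finite pools are what create
within-gene linkage disequilibrium; no explicit r² target is imposed,
since LD estimation is outside the package's scope. Pool allele
patterns place every site's non-reference allele on an intermediate
share of pool haplotypes so that realized minor-allele frequencies stay
well inside (0.05, 0.95) for any seed, making the default panel's 170
sites all pass the MAF filter. One designated site (`ScIce2_SNP7` by
default) is carried by a single pool haplotype whose frequency is high
(0.55) in one cluster and low (0.05) elsewhere, emulating a
population-concentrated large-effect variant.

Phenotypes are generated from exactly the model the analysis fits:
platform fixed effects, causal allelic effects at configured sites,
optional haplotype-pair interaction effects, optional per-cluster mean
shifts (true-Q × shift vector; the classic stratification confounder),
a polygenic effect drawn N(0, K σ²_g) from the realized SSR-based
kinship (self-consistent with the estimator; a switch substitutes a
cluster-derived relatedness for robustness experiments), the platform's
random effects, and iid Gaussian noise. Bounded outcomes are clipped to
their admissible ranges rather than simulated from truncated
distributions — the analysis models bounded outcomes with Gaussian
LMMs, so default variance magnitudes are chosen to keep the clipped
fraction below 1% (it is recorded per platform in the truth record).
Replication follows the emulated designs: controlled 2 temperatures × 2
years × 5 replicates with 3/4 chambers per year; semi-controlled 3
replicates with months Jan/Feb/Apr 2008 and Feb/Mar 2009; field 6
environments with 2 or 3 replicate blocks. Two simplifications: all
201 genotypes appear in both controlled years (the original had a
139-genotype first year), and selfing-generation differences are not
modeled (they are confounded with year effects). The lattice design's
incomplete blocks are simplified to one block per replicate nested in
environment.

Default effect sizes (recovery-score units / percentage points) follow
the magnitudes the emulated study reports: three moderate causal sites
in two Cbf-family genes (|β| 0.25–0.3 on the controlled scale, 2–3
points on the percentage scales), one large field effect (4.3 points)
at the population-concentrated ScIce2 site, and one ScVrn1 × ScDhn3
interaction. No within-platform heritabilities were available to
calibrate variance components; the defaults (e.g. controlled σ²_g =
0.15, σ²_chamber = 0.04, σ² = 0.20) were chosen once to give mid-range
power at n = 201 and are documented as such.

Month-trend coding uses calendar spacing (Jan/Feb/Apr → 1/2/4, centered
within year) because the gaps between scoring dates are unequal; rank
spacing is available as a switch. The semi-controlled random
intercept/trend grouping unit is the genotype-by-year test unit — the
repeated measures are months within that unit.

## What the tests show — and what they do not

The generator and the analysis share their model family, so parameter
recovery, calibration and power results demonstrate *internal*
consistency: the estimator recovers the truth when the model is true.
They do not establish robustness to non-Gaussian outcomes (real recovery
scores are ordinal), to kinship misestimation, to genotyping error
beyond the flagged non-parental calls, or to selection in real breeding
material. The type-I-error study does include the realistic confounded
case (cluster mean shifts plus kinship-structured polygenic signal with
differentiated marker frequencies) and its positive control (omitting Q
and K inflates rejection), which is the central operating
characteristic a Q+K analysis must have.

Test problem sizes are scaled for a fast suite: the type-I study uses
six cohorts × 170 sites (≥1000 site-tests) on a one-replicate controlled
design; parameter recovery uses 25 replicates of a two-replicate design;
LRT calibration uses 80 variance-component nulls, ≥50 haplotype-overall
nulls and 15 epistasis nulls; power checks use 10 replicates at the
full default design. The end-to-end reproducibility check runs a
reduced scenario (67 genotypes, 5 genes); the full default demo
(`ryeassoc demo`) runs all stages on the complete scenario.

## Known limitations

* Bounded outcomes are modeled and simulated as Gaussian; heavy
  clipping scenarios would bias both.
* Wald P values use a normal reference by default; for small strata a
  t reference (exposed) is more appropriate.
* The epistasis LRT's asymptotics degrade when the interaction df is
  large relative to the number of genotypes; results for gene pairs
  with many haplotypes deserve caution. It is calibrated under a clean
  null, but when other genes carry strong unmodeled effects the
  interaction cells of an unrelated pair can proxy for them through
  shared ancestry, so pair-level significance counts on data with
  several large causal signals should be read as screening output, not
  as confirmed interactions.
* Haplotype frequencies, rare-haplotype missingness and the MAF filter
  all operate on gametes (one per genotype), as the design implies;
  diploid panels would need a different frequency estimator.
* The STRUCTURE clustering itself is out of scope: Q is an input
  (supplied by the simulator's ground truth in the synthetic pipeline).
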