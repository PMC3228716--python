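"""Association analysis stages: per-platform Q+K models, genotypic
variance tests, single-SNP scans, haplotype tests, gene x gene epistasis
and cross-platform concordance.

All stages are one-stage analyses: they model raw replicate-level
phenotypes, never genotype means.  Every model contains the population
structure covariates Q (minus one column for identifiability) and a
kinship-structured polygenic genotype effect unless explicitly disabled.

Platform recipes
----------------
controlled        fixed: year + temperature; random: chamber (iid),
                  genotype (kinship)
semi_controlled   fixed: year + centered within-year month trend +
                  year x trend; random: replication (iid), per
                  genotype-by-year unit random intercept and month trend
                  (unstructured 2x2), genotype (kinship)
field             fixed: full environment indicator set (no separate
                  intercept); random: block nested in environment (iid),
                  genotype (kinship)
"""

from __future__ import annotations

import itertools
import logging
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from ryeassoc import kinship as kin
from ryeassoc.lmm import (
    LMMFit,
    ModelSpec,
    RandomBlock,
    fit_lmm,
    lrt,
    variance_explained,
    wald_test,
)
from ryeassoc.markers import binarize_site
from ryeassoc.types import HaplotypeAssignment, MarkerMatrix, PhenotypeTable, PLATFORMS
from ryeassoc.types import StructureMatrix

log = logging.getLogger(__name__)

RESULT_COLUMNS = ["unit", "gene", "platform", "kind", "beta", "se", "t", "p",
                  "df", "var_explained_pct", "n", "converged", "note"]


def _result_row(**kw) -> dict:
    row = {c: np.nan for c in RESULT_COLUMNS}
    row.update(kw)
    return row


def _rows_for(phenotypes: Union[PhenotypeTable, pd.DataFrame],
              platform: str) -> pd.DataFrame:
    if isinstance(phenotypes, PhenotypeTable):
        return phenotypes.platform(platform)
    return phenotypes.reset_index(drop=True)


def _trend(rows: pd.DataFrame, coding: str) -> np.ndarray:
    """Within-year centered month trend (calendar spacing by default)."""
    month = rows["month"].astype(float).to_numpy()
    year = rows["year"].astype(int).to_numpy()
    t = np.empty(len(rows))
    for yr in np.unique(year):
        m = year == yr
        vals = month[m]
        if coding == "rank":
            uniq = np.unique(vals)
            ranks = {v: float(i + 1) for i, v in enumerate(uniq)}
            vals = np.array([ranks[v] for v in vals])
        elif coding != "calendar":
            raise ValueError(f"unknown trend coding {coding!r}")
        t[m] = vals - np.mean(np.unique(vals))
    return t


def _indicator(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(labels.astype(str)))
    Z = np.zeros((len(labels), len(levels)))
    idx = {lv: j for j, lv in enumerate(levels)}
    for i, lv in enumerate(labels.astype(str)):
        Z[i, idx[lv]] = 1.0
    return Z, levels


class PlatformContext:
    """Reusable design scaffolding for one platform's fits.

    Builds fixed and random designs once and caches per-subset random
    cross-products and reduced (no-marker) fits so that scans over many
    sites or gene pairs stay cheap.
    """

    def __init__(self, phenotypes, platform: str,
                 q: Optional[StructureMatrix] = None,
                 k: Optional[kin.KinshipMatrix] = None,
                 include_q: bool = True, include_kinship: bool = True,
                 trend_coding: str = "calendar"):
        if platform not in PLATFORMS:
            raise ValueError(f"unknown platform {platform!r}")
        rows = _rows_for(phenotypes, platform)
        if rows.empty:
            raise ValueError(f"no phenotype rows for platform {platform!r}")
        self.platform = platform
        self.rows = rows
        self.trend_coding = trend_coding
        self.include_q = include_q and q is not None
        self.include_kinship = include_kinship and k is not None
        self.q = q
        self.k = k
        genos = sorted(pd.unique(rows["genotype_id"].astype(str)))
        if self.include_q:
            missing = [g for g in genos if g not in q.q.index]
            if missing:
                raise ValueError(f"genotypes missing from Q: {missing[:5]}")
        if self.include_kinship:
            missing = [g for g in genos if g not in k.genotype_ids]
            if missing:
                raise ValueError(f"genotypes missing from K: {missing[:5]}")
        self._root_cache: dict = {}
        self._spec_cache: dict = {}
        self._base_fit_cache: dict = {}

    # ------------------------------------------------------------- designs

    def _fixed_design(self, rows: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        cols, labels = [], []
        if self.platform == "field":
            Z, envs = _indicator(rows["environment"])
            # full indicator set, no separate intercept (equivalent
            # parameterization of environment means)
            for j, e in enumerate(envs):
                cols.append(Z[:, j])
                labels.append(f"env_{e}")
        else:
            cols.append(np.ones(len(rows)))
            labels.append("intercept")
            years = sorted(pd.unique(rows["year"].astype(int)))
            for yr in years[1:]:
                cols.append((rows["year"].astype(int) == yr).to_numpy(float))
                labels.append(f"year_{yr}")
            if self.platform == "controlled":
                temps = sorted(pd.unique(rows["temperature"].astype(float)))
                for tp in temps[1:]:
                    cols.append((rows["temperature"].astype(float) == tp)
                                .to_numpy(float))
                    labels.append(f"temp_{tp:g}")
            else:
                t = _trend(rows, self.trend_coding)
                cols.append(t)
                labels.append("trend")
                for yr in years[1:]:
                    yv = (rows["year"].astype(int) == yr).to_numpy(float)
                    cols.append(yv * t)
                    labels.append(f"year_{yr}_x_trend")
        if self.include_q:
            qrows = self.q.q.loc[rows["genotype_id"].astype(str)].to_numpy()
            # the k membership columns sum to 1 and collide with the
            # intercept/environment set; drop the last column
            for j, c in enumerate(self.q.q.columns[:-1]):
                cols.append(qrows[:, j])
                labels.append(f"Q_{c}")
        return np.column_stack(cols), labels

    def _random_blocks(self, rows: pd.DataFrame,
                       genos: list[str]) -> list[RandomBlock]:
        blocks: list[RandomBlock] = []
        if self.platform == "controlled":
            Z, _ = _indicator(rows["chamber"])
            blocks.append(RandomBlock("chamber", Z, "iid"))
        elif self.platform == "semi_controlled":
            Z, _ = _indicator(rows["replicate"])
            blocks.append(RandomBlock("replication", Z, "iid"))
            unit = (rows["genotype_id"].astype(str) + "::"
                    + rows["year"].astype(int).astype(str))
            Zi, units = _indicator(unit)
            t = _trend(rows, self.trend_coding)
            Zit = np.concatenate([Zi, Zi * t[:, None]], axis=1)
            blocks.append(RandomBlock("unit", Zit, "intercept_trend",
                                      n_units=len(units)))
        else:
            Z, _ = _indicator(rows["block"])
            blocks.append(RandomBlock("block", Z, "iid"))
        if self.include_kinship:
            Zg, levels = _indicator(rows["genotype_id"])
            key = tuple(levels)
            if key not in self._root_cache:
                sub = self.k.reindex(list(levels))
                self._root_cache[key] = kin.covariance_root(kin.ensure_psd(sub))
            blocks.append(RandomBlock("genotype", Zg, "kinship_root",
                                      root=self._root_cache[key]))
        else:
            # plain iid genotype block keeps the polygenic term when no
            # kinship is supplied
            Zg, _ = _indicator(rows["genotype_id"])
            blocks.append(RandomBlock("genotype", Zg, "iid"))
        return blocks

    # --------------------------------------------------------------- models

    def model(self, covariates: Optional[dict] = None,
              subset_genotypes: Optional[Sequence[str]] = None,
              drop_genotype_block: bool = False) -> ModelSpec:
        """Assemble a ModelSpec, optionally with genotype-level covariates.

        ``covariates`` maps column labels to per-genotype Series (e.g. a
        site's 0/1 non-reference indicator); rows whose genotype has a
        missing covariate value are dropped (complete-case analysis).
        ``subset_genotypes`` restricts the rows without adding columns.
        """
        rows = self.rows
        if subset_genotypes is not None:
            rows = rows[rows["genotype_id"].astype(str)
                        .isin(set(subset_genotypes))].reset_index(drop=True)
        if covariates:
            ok = pd.Series(True, index=rows.index)
            for lab, ser in covariates.items():
                vals = rows["genotype_id"].astype(str).map(ser)
                ok &= vals.notna()
            rows = rows[ok].reset_index(drop=True)
        if rows.empty:
            raise ValueError("no rows left after complete-case filtering")
        genos = sorted(pd.unique(rows["genotype_id"].astype(str)))
        X, labels = self._fixed_design(rows)
        if covariates:
            extra = [rows["genotype_id"].astype(str).map(ser).to_numpy(float)
                     for ser in covariates.values()]
            # marker/haplotype columns go right after the lead column
            X = np.column_stack([X[:, :1]] + extra + [X[:, 1:]])
            labels = labels[:1] + list(covariates) + labels[1:]
        all_blocks = self._random_blocks(rows, genos)
        if drop_genotype_block:
            all_blocks = [b for b in all_blocks if b.label != "genotype"]
        spec = ModelSpec(rows["value"].to_numpy(float), X, labels, all_blocks)
        key = (tuple(genos), drop_genotype_block)
        cached = self._spec_cache.get(key)
        if cached is not None:
            cached.share_random_design(spec)
        else:
            self._spec_cache[key] = spec
        spec.subset_genotypes = genos  # type: ignore[attr-defined]
        return spec

    def base_fit(self, method: str,
                 subset_genotypes: Optional[Sequence[str]] = None) -> LMMFit:
        """Reduced (no-marker) fit, cached per method and genotype subset."""
        key = (method, tuple(sorted(subset_genotypes))
               if subset_genotypes is not None else None)
        if key not in self._base_fit_cache:
            spec = self.model(subset_genotypes=subset_genotypes)
            self._base_fit_cache[key] = fit_lmm(spec, method)
        return self._base_fit_cache[key]


def platform_model(platform: str, phenotypes, q=None, k=None,
                   marker_column: Optional[pd.Series] = None,
                   include_q: bool = True, include_kinship: bool = True,
                   trend_coding: str = "calendar") -> ModelSpec:
    """Assemble the Q+K mixed model for one platform.

    ``marker_column`` is a per-genotype 0/1 non-reference indicator; rows
    with a missing marker value are dropped.  ``include_q=False`` drops the
    structure covariates (the phenotypic-analysis variant also omits the
    marker).
    """
    ctx = PlatformContext(phenotypes, platform, q, k, include_q=include_q,
                          include_kinship=include_kinship,
                          trend_coding=trend_coding)
    cov = {"marker": marker_column} if marker_column is not None else None
    return ctx.model(covariates=cov)


# ------------------------------------------------------------ varcomp test

_STRATUM_KEYS = {
    "controlled": ("year", "temperature"),
    "semi_controlled": ("year", "month"),
    "field": ("environment",),
}


def genotype_varcomp_test(phenotypes, platform: str, stratum: dict,
                          k: Optional[kin.KinshipMatrix] = None
                          ) -> tuple[float, float, float]:
    """Genotypic-variance LRT within one stratum of a platform.

    The stratum selects one temperature x year (controlled), month x year
    (semi-controlled) or location (field); the stratum model (no marker,
    no Q) is fitted with and without the genotype random effect and the
    chi-square(1) LRT reported — conservative, since the null
    distribution of a variance-component LRT is a chi-square mixture.
    """
    keys = _STRATUM_KEYS[platform]
    if set(stratum) != set(keys):
        raise ValueError(f"stratum for {platform} needs keys {keys}")
    rows = _rows_for(phenotypes, platform)
    m = pd.Series(True, index=rows.index)
    for key, val in stratum.items():
        col = rows[key]
        if key in ("year", "month"):
            m &= col.astype(float) == float(val)
        else:
            m &= col.astype(str) == str(val)
    rows = rows[m].reset_index(drop=True)
    if rows["genotype_id"].nunique() < 2:
        raise ValueError(f"stratum {stratum} has < 2 genotypes")

    ctx = PlatformContext(rows, platform, q=None, k=k, include_q=False,
                          include_kinship=k is not None)
    # within a single month there is no trend; replace the 2x2 unit block
    # by nothing (the replication block remains)
    spec_full = _stratum_spec(ctx, rows, with_genotype=True)
    spec_red = _stratum_spec(ctx, rows, with_genotype=False)
    fit_full = fit_lmm(spec_full, "reml")
    fit_red = fit_lmm(spec_red, "reml")
    stat, _, p = lrt(fit_full, fit_red, df=1)
    return float(fit_full.varcomp["genotype"]), stat, p


def _stratum_spec(ctx: PlatformContext, rows: pd.DataFrame,
                  with_genotype: bool) -> ModelSpec:
    X = np.ones((len(rows), 1))
    labels = ["intercept"]
    blocks: list[RandomBlock] = []
    groups = {"controlled": "chamber", "semi_controlled": "replicate",
              "field": "block"}[ctx.platform]
    if rows[groups].nunique() > 1:
        Z, _ = _indicator(rows[groups])
        label = "chamber" if ctx.platform == "controlled" else (
            "replication" if ctx.platform == "semi_controlled" else "block")
        blocks.append(RandomBlock(label, Z, "iid"))
    if with_genotype:
        Zg, levels = _indicator(rows["genotype_id"])
        if ctx.include_kinship:
            sub = ctx.k.reindex(list(levels))
            root = kin.covariance_root(kin.ensure_psd(sub))
            blocks.append(RandomBlock("genotype", Zg, "kinship_root", root=root))
        else:
            blocks.append(RandomBlock("genotype", Zg, "iid"))
    return ModelSpec(rows["value"].to_numpy(float), X, labels, blocks)


# ------------------------------------------------------------------- scans

def snp_scan(phenotypes, markers: MarkerMatrix, q, k, platform: str,
             alpha: float = 0.05, trend_coding: str = "calendar",
             include_q: bool = True, include_kinship: bool = True,
             wald_reference: str = "normal") -> pd.DataFrame:
    """Single-marker scan: one Q+K mixed-model fit per polymorphic site.

    Each site's 0/1 non-reference indicator enters the platform model as
    a fixed effect; effect, Wald t and P, and the percent genetic
    variance explained relative to the matching no-marker model (same
    rows) are reported.  Per-site failures are logged and flagged; the
    scan continues.
    """
    ctx = PlatformContext(phenotypes, platform, q, k, include_q=include_q,
                          include_kinship=include_kinship,
                          trend_coding=trend_coding)
    out = []
    for site in markers.site_ids:
        gene = markers.sites.loc[site, "gene"]
        code = binarize_site(markers, site)
        try:
            subset = sorted(code.dropna().index.astype(str))
            base = ctx.base_fit("reml", subset_genotypes=subset)
            spec = ctx.model(covariates={site: code})
            fit = fit_lmm(spec, "reml", n_starts=1, warm_start=base.theta)
            est, se, t, p = wald_test(fit, site, reference=wald_reference)
            ve = variance_explained(base, fit)
            out.append(_result_row(unit=site, gene=gene, platform=platform,
                                   kind="snp", beta=est, se=se, t=t, p=p,
                                   var_explained_pct=ve, n=fit.n,
                                   converged=fit.converged))
        except Exception as exc:  # per-site failures do not stop the scan
            log.warning("snp_scan: site %s failed: %s", site, exc)
            out.append(_result_row(unit=site, gene=gene, platform=platform,
                                   kind="snp", converged=False,
                                   note=str(exc)))
    return pd.DataFrame(out, columns=RESULT_COLUMNS)


def haplotype_scan(phenotypes, haplotypes: Sequence[HaplotypeAssignment],
                   q, k, platform: str, alpha: float = 0.05,
                   trend_coding: str = "calendar",
                   wald_reference: str = "normal") -> pd.DataFrame:
    """Within-gene haplotype tests: overall ML LRT plus reference contrasts.

    Per gene, the model with indicators for every retained non-reference
    haplotype is compared against the no-haplotype model by an ML
    likelihood-ratio test (overall P); individual haplotype effects vs
    the reference are Wald contrasts from the matching REML fit.
    Contrasts are reported for all genes with the overall-gate outcome
    flagged in ``note``.  Genes with <= 1 retained haplotype are skipped.
    """
    ctx = PlatformContext(phenotypes, platform, q, k,
                          trend_coding=trend_coding)
    out = []
    for hap in haplotypes:
        labels = [l for l in hap.frequencies.index if l != "ref"]
        if len(hap.frequencies) <= 1 or not labels:
            log.info("haplotype_scan: gene %s has <= 1 retained haplotype; "
                     "skipped", hap.gene)
            continue
        covs = {f"{hap.gene}:{l}": (hap.assignment == l).astype(float)
                .where(hap.assignment.notna()) for l in labels}
        try:
            spec_full_ml = ctx.model(covariates=covs)
            subset = spec_full_ml.subset_genotypes
            base_ml = ctx.base_fit("ml", subset_genotypes=subset)
            fit_full_ml = fit_lmm(spec_full_ml, "ml", n_starts=1,
                                  warm_start=base_ml.theta)
            df = sum(1 for c in covs if c in fit_full_ml.x_labels)
            stat, df, p_overall = lrt(fit_full_ml, base_ml, df=df)

            base_reml = ctx.base_fit("reml", subset_genotypes=subset)
            fit_reml = fit_lmm(ctx.model(covariates=covs), "reml", n_starts=1,
                               warm_start=base_reml.theta)
            ve = variance_explained(base_reml, fit_reml)
            gate = "overall significant" if p_overall < alpha \
                else "overall not significant"
            out.append(_result_row(unit=f"{hap.gene}:overall", gene=hap.gene,
                                   platform=platform, kind="haplotype_overall",
                                   t=stat, p=p_overall, df=df,
                                   var_explained_pct=ve, n=fit_full_ml.n,
                                   converged=fit_full_ml.converged,
                                   note=f"missing_fraction="
                                        f"{hap.missing_fraction:.3f}"))
            for lab in labels:
                col = f"{hap.gene}:{lab}"
                if col not in fit_reml.x_labels:
                    continue
                est, se, t, p = wald_test(fit_reml, col,
                                          reference=wald_reference)
                out.append(_result_row(unit=col, gene=hap.gene,
                                       platform=platform, kind="haplotype",
                                       beta=est, se=se, t=t, p=p,
                                       n=fit_reml.n,
                                       converged=fit_reml.converged,
                                       note=gate))
        except Exception as exc:
            log.warning("haplotype_scan: gene %s failed: %s", hap.gene, exc)
            out.append(_result_row(unit=f"{hap.gene}:overall", gene=hap.gene,
                                   platform=platform, kind="haplotype_overall",
                                   converged=False, note=str(exc)))
    return pd.DataFrame(out, columns=RESULT_COLUMNS)


def epistasis_scan(phenotypes, haplotypes: Sequence[HaplotypeAssignment],
                   q, k, platform: str,
                   gene_pairs: Optional[Sequence[tuple[str, str]]] = None,
                   trend_coding: str = "calendar") -> pd.DataFrame:
    """Gene x gene interaction LRTs on the basis of within-gene haplotypes.

    Per pair, the ML model with both genes' main-effect indicators plus
    all pairwise interaction indicators is compared to the main-effects
    model; df equals the number of estimable interaction columns after
    collinearity pruning.  Complete-case on both genes.
    """
    ctx = PlatformContext(phenotypes, platform, q, k,
                          trend_coding=trend_coding)
    by_gene = {h.gene: h for h in haplotypes}
    if gene_pairs is None:
        gene_pairs = list(itertools.combinations(sorted(by_gene), 2))
    out = []
    for ga, gb in gene_pairs:
        ha, hb = by_gene[ga], by_gene[gb]
        labs_a = [l for l in ha.frequencies.index if l != "ref"]
        labs_b = [l for l in hb.frequencies.index if l != "ref"]
        if not labs_a or not labs_b:
            log.info("epistasis_scan: pair %s x %s lacks usable haplotypes; "
                     "skipped", ga, gb)
            continue
        main = {}
        for h, labs in ((ha, labs_a), (hb, labs_b)):
            for l in labs:
                main[f"{h.gene}:{l}"] = (h.assignment == l).astype(float) \
                    .where(h.assignment.notna())
        inter = {}
        for la in labs_a:
            for lb in labs_b:
                inter[f"{ga}:{la}*{gb}:{lb}"] = main[f"{ga}:{la}"] * main[f"{gb}:{lb}"]
        try:
            spec_main = ctx.model(covariates=main)
            spec_full = ctx.model(covariates={**main, **inter})
            df = spec_full.p - spec_main.p
            if df <= 0:
                log.info("epistasis_scan: pair %s x %s interaction design "
                         "fully collinear; skipped", ga, gb)
                continue
            fit_main = fit_lmm(spec_main, "ml")
            fit_full = fit_lmm(spec_full, "ml", n_starts=1,
                               warm_start=fit_main.theta)
            stat, df, p = lrt(fit_full, fit_main, df=df)
            out.append(_result_row(unit=f"{ga}*{gb}", gene=f"{ga}*{gb}",
                                   platform=platform, kind="epistasis",
                                   t=stat, df=df, p=p, n=fit_full.n,
                                   converged=fit_full.converged
                                   and fit_main.converged))
        except Exception as exc:
            log.warning("epistasis_scan: pair %s x %s failed: %s", ga, gb, exc)
            out.append(_result_row(unit=f"{ga}*{gb}", gene=f"{ga}*{gb}",
                                   platform=platform, kind="epistasis",
                                   converged=False, note=str(exc)))
    return pd.DataFrame(out, columns=RESULT_COLUMNS)


# ------------------------------------------------------------- concordance

def cross_platform_correlation(results_by_platform: dict,
                               subset: str = "all",
                               alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-unit t values across platforms.

    ``subset="significant"`` restricts each platform pair to units with
    P < alpha in at least one member of the pair.
    """
    if subset not in ("all", "significant"):
        raise ValueError("subset must be 'all' or 'significant'")
    tables = {p: df.dropna(subset=["t"]).set_index("unit")
              for p, df in results_by_platform.items()}
    out = []
    for pa, pb in itertools.combinations(sorted(tables), 2):
        merged = tables[pa][["t", "p"]].join(tables[pb][["t", "p"]],
                                             lsuffix="_a", rsuffix="_b",
                                             how="inner").dropna()
        if subset == "significant":
            merged = merged[(merged["p_a"] < alpha) | (merged["p_b"] < alpha)]
        if len(merged) < 3:
            raise ValueError(f"fewer than 3 paired units for {pa} vs {pb}")
        r, _ = stats.pearsonr(merged["t_a"], merged["t_b"])
        out.append({"platform_a": pa, "platform_b": pb, "r": float(r),
                    "n_units": len(merged), "subset": subset})
    return pd.DataFrame(out)


def summarize_significant(results_by_platform: dict,
                          alpha: float = 0.05) -> dict:
    """Significance counts per gene and platform plus platform overlaps.

    Returns ``per_gene`` (gene x platform counts of significant units,
    with totals), ``overlap`` (units significant in >=1, >=2 and all
    platforms) and ``overlap_counts``.
    """
    sig_units: dict[str, set] = {}
    counts: dict[tuple, int] = {}
    gene_of: dict[str, str] = {}
    for plat, df in results_by_platform.items():
        ok = df.dropna(subset=["p"])
        sig = ok[ok["p"] < alpha]
        sig_units[plat] = set(sig["unit"])
        for _, row in sig.iterrows():
            counts[(row["gene"], plat)] = counts.get((row["gene"], plat), 0) + 1
        gene_of.update(dict(zip(ok["unit"], ok["gene"])))
    platforms = sorted(results_by_platform)
    genes = sorted({g for g, _ in counts})
    per_gene = pd.DataFrame(0, index=genes, columns=platforms, dtype=int)
    for (g, p), c in counts.items():
        per_gene.loc[g, p] = c
    membership: dict[str, int] = {}
    for plat in platforms:
        for u in sig_units.get(plat, ()):  # count of platforms a unit hits
            membership[u] = membership.get(u, 0) + 1
    n_plat = len(platforms)
    overlap = {
        ">=1": {u for u, c in membership.items() if c >= 1},
        ">=2": {u for u, c in membership.items() if c >= 2},
        "all": {u for u, c in membership.items() if c == n_plat},
    }
    return {"per_gene": per_gene,
            "overlap": overlap,
            "overlap_counts": {k: len(v) for k, v in overlap.items()},
            "genes_hit": {k: sorted({gene_of[u] for u in v})
                          for k, v in overlap.items()}}
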