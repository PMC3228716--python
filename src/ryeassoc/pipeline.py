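"""End-to-end pipeline orchestration and run configuration.

Every stage reads/writes the TSV artifacts of :mod:`ryeassoc.io`, so any
contiguous sub-chain can be run and rerun; all randomness flows from one
root seed split deterministically per stage, making a run reproducible
from its provenance header alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd

import ryeassoc
from ryeassoc import io as rio
from ryeassoc import kinship as kin
from ryeassoc import markers as mk
from ryeassoc import scan as sc
from ryeassoc import simulate as sim
from ryeassoc.types import PLATFORMS

log = logging.getLogger(__name__)

STAGES = ["simulate", "kinship", "varcomp", "scan", "haplotest",
          "epistasis", "xplatform", "summarize", "report"]


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (file < CLI flag semantics
    are applied by the CLI before this object is built)."""

    outdir: str = "ryeassoc_run"
    seed: int = 0
    alpha: float = 0.05
    maf_threshold: float = 0.05
    het_mode: str = "half"             # kinship heterozygote similarity
    trend_coding: str = "calendar"     # semi-controlled month spacing
    wald_reference: str = "normal"     # P reference for Wald t
    platforms: tuple = PLATFORMS
    stages: tuple = tuple(STAGES)
    quick: bool = False                # reduced cohort for smoke runs

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must lie in (0, 0.5)")
        if self.het_mode not in ("half", "strict"):
            raise ValueError("het_mode must be 'half' or 'strict'")
        if self.trend_coding not in ("calendar", "rank"):
            raise ValueError("trend_coding must be 'calendar' or 'rank'")
        if self.wald_reference not in ("normal", "t"):
            raise ValueError("wald_reference must be 'normal' or 't'")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        bad = set(self.platforms) - set(PLATFORMS)
        if bad:
            raise ValueError(f"unknown platforms: {sorted(bad)}")

    def provenance(self) -> dict:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str)
            .encode()).hexdigest()[:12]
        return {"tool": f"ryeassoc {ryeassoc.__version__}",
                "seed": self.seed, "config_hash": digest}


def quick_scenario() -> tuple[sim.CohortConfig, sim.EffectsConfig]:
    """A reduced scenario (fewer genotypes, genes and replicates) for
    smoke runs and fast end-to-end checks."""
    cohort, effects = sim.default_scenario()
    cohort = replace(cohort, population_sizes={
        "EKOAGRO": 15, "Petkus": 22, "PR2733": 11, "ROM103": 14, "SMH2502": 5},
        genes={"ScCbf12": (6, 1), "ScCbf15": (6, 1), "ScDhn3": (4, 0),
               "ScIce2": (8, 1), "ScVrn1": (5, 0)},
        n_ssr_loci=20)
    effects = replace(
        effects,
        causal_sites=[
            sim.CausalSite("ScCbf15_SNP3", {"controlled": 0.30,
                                            "semi_controlled": 2.0,
                                            "field": 3.0}),
            sim.CausalSite("ScCbf12_SNP5", {"controlled": 0.25,
                                            "semi_controlled": 1.8,
                                            "field": 2.5}),
            sim.CausalSite("ScIce2_SNP7", {"controlled": 0.30,
                                           "semi_controlled": 1.5,
                                           "field": 4.3}),
        ],
        controlled_replicates=2, sc_replicates=2,
        field_replicates={"KAS": 2, "SAS1": 2},
        field_env_means={"KAS": 70.0, "SAS1": 60.0})
    return cohort, effects


class Pipeline:
    """Stage runner over a shared artifact directory."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.prov = config.provenance()
        self._truth = None

    # paths ---------------------------------------------------------------
    def path(self, name: str) -> Path:
        return self.outdir / name

    # stages --------------------------------------------------------------
    def stage_simulate(self) -> None:
        cohort_cfg, effects_cfg = (quick_scenario() if self.cfg.quick
                                   else sim.default_scenario())
        cohort_cfg = replace(cohort_cfg, seed=self.cfg.seed)
        effects_cfg = replace(effects_cfg, seed=self.cfg.seed + 1)
        cohort = sim.simulate_cohort(cohort_cfg)
        phen = sim.simulate_phenotypes(cohort, effects_cfg)
        rio.write_ssr_table(cohort.ssr, self.path("ssr.tsv"), self.prov)
        s0 = cohort.s0_calls.copy()
        s0.index.name = "genotype_id"
        rio._write_tsv(s0, self.path("s0_calls.tsv"), self.prov,
                       index_label="genotype_id")
        meta = cohort.sites.copy()
        meta.index.name = "site_id"
        rio._write_tsv(meta, self.path("sites.tsv"), self.prov,
                       index_label="site_id")
        rio.write_q_matrix(cohort.q, self.path("q.tsv"), self.prov)
        rio.write_phenotype_table(phen, self.path("phenotypes.tsv"), self.prov)
        truth = {
            "clipped_fraction": cohort.truth.clipped_fraction,
            "causal_sites": [{"site_id": c.site_id, "effects": c.effects}
                             for c in cohort.truth.causal_sites],
            "interactions": [{"gene_a": i.gene_a, "hap_a": i.pool_hap_a,
                              "gene_b": i.gene_b, "hap_b": i.pool_hap_b,
                              "effects": i.effects}
                             for i in cohort.truth.interactions],
            "population_of": cohort.truth.population_of,
        }
        with open(self.path("truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        self._truth = cohort.truth

    def _load_markers(self) -> mk.MarkerMatrix:
        s0 = rio._read_tsv(self.path("s0_calls.tsv"), dtype=str) \
            .set_index("genotype_id")
        s0.index.name = None
        sites = rio._read_tsv(self.path("sites.tsv"), dtype={"site_id": str}) \
            .set_index("site_id")
        sites["site_index"] = sites["site_index"].astype(int)
        phased = mk.phase_gametes(s0, sites)
        return mk.filter_maf(phased, self.cfg.maf_threshold)

    def stage_kinship(self) -> None:
        ssr = rio.read_ssr_table(self.path("ssr.tsv"))
        k = kin.kinship_matrix(ssr, het_mode=self.cfg.het_mode)
        rio.write_matrix(k.to_frame(), self.path("kinship.tsv"), self.prov)

    def _qk(self):
        q = rio.read_q_matrix(self.path("q.tsv"))
        kf = rio.read_matrix(self.path("kinship.tsv"))
        k = kin.ensure_psd(kin.KinshipMatrix(list(kf.index), kf.values))
        return q, k

    def stage_varcomp(self) -> None:
        phen = rio.read_phenotype_table(self.path("phenotypes.tsv"))
        _, k = self._qk()
        rows = []
        for plat in self.cfg.platforms:
            sub = phen.platform(plat)
            if sub.empty:
                continue
            keys = sc._STRATUM_KEYS[plat]
            for vals, _ in sub.groupby(list(keys)):
                stratum = dict(zip(keys, vals if isinstance(vals, tuple)
                                   else (vals,)))
                s2g, stat, p = sc.genotype_varcomp_test(phen, plat, stratum, k)
                rows.append({"platform": plat, **stratum, "sigma2_g": s2g,
                             "lrt": stat, "p": p})
        rio.write_results(pd.DataFrame(rows), self.path("varcomp.tsv"),
                          self.prov)

    def stage_scan(self) -> None:
        phen = rio.read_phenotype_table(self.path("phenotypes.tsv"))
        q, k = self._qk()
        markers = self._load_markers()
        for plat in self.cfg.platforms:
            res = sc.snp_scan(phen, markers, q, k, plat,
                              alpha=self.cfg.alpha,
                              trend_coding=self.cfg.trend_coding,
                              wald_reference=self.cfg.wald_reference)
            # Bonferroni column provided for downstream use, raw P is primary
            res["p_bonferroni"] = np.minimum(res["p"] * len(res), 1.0)
            rio.write_results(res, self.path(f"scan_{plat}.tsv"), self.prov)

    def _haplotypes(self, markers: mk.MarkerMatrix):
        haps = []
        for gene in markers.genes:
            h = mk.filter_maf(mk.define_haplotypes(markers, gene),
                              self.cfg.maf_threshold)
            haps.append(h)
        return haps

    def stage_haplotest(self) -> None:
        phen = rio.read_phenotype_table(self.path("phenotypes.tsv"))
        q, k = self._qk()
        haps = self._haplotypes(self._load_markers())
        for plat in self.cfg.platforms:
            res = sc.haplotype_scan(phen, haps, q, k, plat,
                                    alpha=self.cfg.alpha,
                                    trend_coding=self.cfg.trend_coding,
                                    wald_reference=self.cfg.wald_reference)
            rio.write_results(res, self.path(f"haplo_{plat}.tsv"), self.prov)

    def stage_epistasis(self) -> None:
        phen = rio.read_phenotype_table(self.path("phenotypes.tsv"))
        q, k = self._qk()
        haps = self._haplotypes(self._load_markers())
        for plat in self.cfg.platforms:
            res = sc.epistasis_scan(phen, haps, q, k, plat,
                                    trend_coding=self.cfg.trend_coding)
            rio.write_results(res, self.path(f"epistasis_{plat}.tsv"),
                              self.prov)

    def _scan_results(self) -> dict:
        out = {}
        for plat in self.cfg.platforms:
            p = self.path(f"scan_{plat}.tsv")
            if p.exists():
                out[plat] = rio.read_results(p)
        return out

    def stage_xplatform(self) -> None:
        results = self._scan_results()
        frames = []
        for subset in ("all", "significant"):
            try:
                frames.append(sc.cross_platform_correlation(
                    results, subset=subset, alpha=self.cfg.alpha))
            except ValueError as exc:
                log.warning("xplatform subset %s skipped: %s", subset, exc)
        table = (pd.concat(frames, ignore_index=True) if frames
                 else pd.DataFrame(columns=["platform_a", "platform_b", "r",
                                            "n_units", "subset"]))
        rio.write_results(table, self.path("xplatform.tsv"), self.prov)

    def stage_summarize(self) -> None:
        results = self._scan_results()
        summary = sc.summarize_significant(results, alpha=self.cfg.alpha)
        per_gene = summary["per_gene"].copy()
        per_gene.index.name = "gene"
        rio._write_tsv(per_gene, self.path("summary_per_gene.tsv"),
                       self.prov, index_label="gene")
        with open(self.path("summary.json"), "w") as fh:
            json.dump({"overlap_counts": summary["overlap_counts"],
                       "genes_hit": summary["genes_hit"],
                       "overlap": {kk: sorted(vv) for kk, vv
                                   in summary["overlap"].items()}},
                      fh, indent=1, sort_keys=True)

    def stage_report(self) -> None:
        from ryeassoc.report import render_report
        render_report(self.outdir, self.path("report.md"),
                      alpha=self.cfg.alpha)

    def run(self) -> None:
        for stage in STAGES:
            if stage not in self.cfg.stages:
                continue
            log.info("stage %s ...", stage)
            try:
                getattr(self, f"stage_{stage}")()
            except Exception:
                log.error("stage %s failed", stage)
                raise PipelineError(stage)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str):
        super().__init__(f"pipeline stage {stage!r} failed")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stage chain; returns the artifact directory."""
    Pipeline(config).run()
    return Path(config.outdir)
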