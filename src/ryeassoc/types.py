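"""Domain containers shared by all pipeline stages.

Conventions
-----------
* Genotypes are S0 testcross plants: each carries one gamete of its source
  population plus the common tester parent's gamete, so marker data are
  effectively haploid once phased.
* Missing data: ``None``/``NaN`` in memory, the string ``"NA"`` on disk.
* Tables are thin dataclass wrappers around pandas objects; invariants are
  validated at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: on-disk missing-value sentinel
NA = "NA"

PLATFORMS = ("controlled", "semi_controlled", "field")

#: phenotype-table design columns each platform requires to be non-missing
PLATFORM_REQUIRED = {
    "controlled": ["year", "temperature", "chamber", "replicate"],
    "semi_controlled": ["year", "month", "replicate"],
    "field": ["environment", "block", "replicate"],
}

#: admissible outcome range per platform
PLATFORM_RANGE = {
    "controlled": (0.0, 5.0),
    "semi_controlled": (0.0, 100.0),
    "field": (0.0, 100.0),
}


@dataclass
class SsrGenotypes:
    """Diploid multi-allelic SSR genotypes (genotype x locus allele pairs).

    ``alleles`` has shape ``(n_genotypes, n_loci, 2)`` with integer allele
    labels (fragment sizes); ``-1`` in both slots marks a missing call.
    Allele pairs are unordered; they are stored sorted.
    """

    genotype_ids: list[str]
    locus_ids: list[str]
    alleles: np.ndarray

    MISSING: int = field(default=-1, repr=False)

    def __post_init__(self) -> None:
        self.genotype_ids = list(self.genotype_ids)
        self.locus_ids = list(self.locus_ids)
        if len(set(self.genotype_ids)) != len(self.genotype_ids):
            raise ValueError("duplicate genotype_id in SSR table")
        if len(self.locus_ids) < 1:
            raise ValueError("SSR table needs at least one locus")
        a = np.asarray(self.alleles, dtype=np.int64)
        if a.shape != (len(self.genotype_ids), len(self.locus_ids), 2):
            raise ValueError(
                f"allele array shape {a.shape} does not match "
                f"{len(self.genotype_ids)} genotypes x {len(self.locus_ids)} loci"
            )
        # enforce unordered-pair canonical form; half-missing pairs are
        # treated as fully missing
        a = np.sort(a, axis=2)
        half_missing = (a == self.MISSING).any(axis=2)
        a[half_missing] = self.MISSING
        self.alleles = a

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_genotypes, n_loci) mask of missing calls."""
        return (self.alleles == self.MISSING).all(axis=2)


@dataclass
class MarkerMatrix:
    """Gamete alleles at candidate-gene polymorphic sites.

    ``calls`` is a genotype x site DataFrame of allele strings (one gamete
    allele per genotype per site; NaN = missing).  ``sites`` is indexed by
    site_id with columns ``gene``, ``site_index`` (ordinal within the gene),
    ``site_type`` ("SNP" or "Indel") and ``ref_allele`` (the common tester
    parent's allele).  Indels are ordinary single polymorphic sites.
    """

    calls: pd.DataFrame
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        if self.sites.index.has_duplicates:
            raise ValueError("duplicate site_id in site metadata")
        if self.calls.index.has_duplicates:
            raise ValueError("duplicate genotype_id in marker calls")
        missing_meta = [c for c in self.calls.columns if c not in self.sites.index]
        if missing_meta:
            raise ValueError(f"sites lack metadata: {missing_meta}")
        need = {"gene", "site_index", "site_type", "ref_allele"}
        lacking = need - set(self.sites.columns)
        if lacking:
            raise ValueError(f"site metadata missing columns: {sorted(lacking)}")
        # align metadata to call columns, one gene per site by construction
        self.sites = self.sites.loc[list(self.calls.columns)]

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def gene_sites(self, gene: str) -> list[str]:
        """Site ids of one gene in sequence order."""
        sub = self.sites[self.sites["gene"] == gene]
        if sub.empty:
            raise KeyError(f"gene {gene!r} has no sites")
        return list(sub.sort_values("site_index").index)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.sites["gene"]:
            seen.setdefault(g, None)
        return list(seen)

    def subset_sites(self, site_ids: list[str]) -> "MarkerMatrix":
        return MarkerMatrix(self.calls[list(site_ids)].copy(),
                            self.sites.loc[list(site_ids)].copy())

    def allele_frequencies(self, site_id: str) -> pd.Series:
        """Gamete allele frequencies at one site over non-missing calls."""
        col = self.calls[site_id].dropna()
        if col.empty:
            return pd.Series(dtype=float)
        return col.value_counts(normalize=True)


@dataclass
class HaplotypeAssignment:
    """Within-gene haplotypes over a gene's phased sites.

    Labels are assigned in decreasing frequency order ("hap1", "hap2", ...)
    except the tester parent's allele string, which is always labelled
    ``"ref"``.  ``assignment`` maps genotype_id to label (NaN where any site
    of the gene is missing); ``frequencies`` are over non-missing genotypes
    and sum to one.
    """

    gene: str
    strings: dict[str, str]          # label -> concatenated allele string
    assignment: pd.Series            # genotype_id -> label (or NaN)
    frequencies: pd.Series           # label -> frequency

    def __post_init__(self) -> None:
        freq = self.frequencies
        if len(freq) and abs(float(freq.sum()) - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies of {self.gene} do not sum to 1")
        if "ref" not in self.strings:
            raise ValueError("reference haplotype label 'ref' absent")

    @property
    def labels(self) -> list[str]:
        return list(self.frequencies.index)

    @property
    def missing_fraction(self) -> float:
        return float(self.assignment.isna().mean())


@dataclass
class PhenotypeTable:
    """Long-format multi-platform frost-tolerance observations.

    One row per raw replicate-level observation.  Columns: genotype_id,
    platform, year, environment, temperature, month, chamber, replicate,
    block, value.  Platform-specific design columns are NaN outside their
    platform; outcome ranges are 0-5 (recovery score) for the controlled
    platform and 0-100 (%) otherwise.
    """

    data: pd.DataFrame

    COLUMNS = ["genotype_id", "platform", "year", "environment", "temperature",
               "month", "chamber", "replicate", "block", "value"]

    def __post_init__(self) -> None:
        df = self.data
        lacking = [c for c in self.COLUMNS if c not in df.columns]
        if lacking:
            raise ValueError(f"phenotype table missing columns: {lacking}")
        bad_platform = set(df["platform"].unique()) - set(PLATFORMS)
        if bad_platform:
            raise ValueError(f"unknown platforms: {sorted(bad_platform)}")
        for plat, cols in PLATFORM_REQUIRED.items():
            rows = df[df["platform"] == plat]
            if rows.empty:
                continue
            for c in cols:
                if rows[c].isna().any():
                    raise ValueError(f"platform {plat} has missing {c!r} entries")
            lo, hi = PLATFORM_RANGE[plat]
            v = rows["value"].dropna()
            if ((v < lo) | (v > hi)).any():
                raise ValueError(f"platform {plat} outcomes outside [{lo}, {hi}]")
        self.data = df.reset_index(drop=True)

    def platform(self, name: str) -> pd.DataFrame:
        if name not in PLATFORMS:
            raise KeyError(f"unknown platform {name!r}")
        return self.data[self.data["platform"] == name].reset_index(drop=True)

    @property
    def genotype_ids(self) -> list[str]:
        return list(pd.unique(self.data["genotype_id"]))


@dataclass
class StructureMatrix:
    """Population-structure membership fractions Q (genotype x cluster).

    Rows are non-negative and sum to one; used as fixed covariates to
    absorb stratification in the association models.
    """

    q: pd.DataFrame

    TOL: float = field(default=1e-6, repr=False)

    def __post_init__(self) -> None:
        q = self.q.astype(float)
        if q.shape[1] < 2:
            raise ValueError("Q needs at least 2 clusters")
        if (q.values < -self.TOL).any():
            raise ValueError("Q has negative membership fractions")
        sums = q.sum(axis=1)
        off = (sums - 1.0).abs()
        if (off > self.TOL).any():
            bad = list(q.index[off > self.TOL])
            raise ValueError(f"Q rows do not sum to 1 within {self.TOL}: {bad[:5]}")
        # renormalize small numeric drift
        self.q = q.div(sums, axis=0)

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.q.index)

    @property
    def k(self) -> int:
        return self.q.shape[1]
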