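"""Gamete phasing, haplotype definition and frequency filtering.

Phase recovery exploits the gamete-capture design: every S0 plant is a
cross of one population gamete with the homozygous tester parent, so the
gamete allele at a site is simply the member of the diploid pair that is
not the parent's allele (or the parent allele itself when the pair is
homozygous for it).
"""

from __future__ import annotations

import logging
from typing import Union

import numpy as np
import pandas as pd

from ryeassoc.types import HaplotypeAssignment, MarkerMatrix

log = logging.getLogger(__name__)

PAIR_SEP = "/"


def phase_gametes(s0_calls: pd.DataFrame, sites: pd.DataFrame,
                  parent_alleles: Union[pd.Series, None] = None) -> MarkerMatrix:
    """Phase S0 diploid calls into gamete alleles by parent subtraction.

    Parameters
    ----------
    s0_calls : DataFrame (genotype x site) of unordered diploid pairs
        encoded ``"a/b"`` (NaN = missing).
    sites : site metadata with the ``ref_allele`` column (the parent allele).
    parent_alleles : optional explicit parent alleles overriding
        ``sites["ref_allele"]``.

    Returns
    -------
    MarkerMatrix of gamete alleles.  Pairs in which neither member equals
    the parent allele cannot arise under the crossing design; they are set
    missing and counted (reported via the logger and the attribute
    ``n_inconsistent`` on the result).
    """
    if parent_alleles is None:
        parent_alleles = sites["ref_allele"]
    absent = [s for s in s0_calls.columns if s not in parent_alleles.index
              or pd.isna(parent_alleles[s])]
    if absent:
        raise ValueError(f"parent allele missing for sites: {absent}")

    out = {}
    n_inconsistent = 0
    for site in s0_calls.columns:
        parent = str(parent_alleles[site])
        col = s0_calls[site]
        gametes = []
        for v in col:
            if pd.isna(v):
                gametes.append(np.nan)
                continue
            a, b = str(v).split(PAIR_SEP)
            if a == parent:
                gametes.append(b)
            elif b == parent:
                gametes.append(a)
            else:
                gametes.append(np.nan)
                n_inconsistent += 1
        out[site] = gametes
    calls = pd.DataFrame(out, index=s0_calls.index, columns=s0_calls.columns)
    mm = MarkerMatrix(calls, sites.loc[list(s0_calls.columns)].copy())
    mm.n_inconsistent = n_inconsistent  # type: ignore[attr-defined]
    if n_inconsistent:
        log.warning("phase_gametes: %d calls carried no parent allele; set missing",
                    n_inconsistent)
    return mm


def define_haplotypes(markers: MarkerMatrix, gene: str) -> HaplotypeAssignment:
    """Collapse one gene's phased sites into within-gene haplotypes.

    Every distinct allele string over the gene's sites is one haplotype;
    a genotype with any missing site in the gene is missing.  Labels are
    assigned in decreasing frequency order except the tester parent's
    string, which is always ``"ref"``.
    """
    site_ids = markers.gene_sites(gene)  # raises on zero sites
    sub = markers.calls[site_ids]
    ref_string = "|".join(str(markers.sites.loc[s, "ref_allele"]) for s in site_ids)

    complete = sub.notna().all(axis=1)
    strings = pd.Series(np.nan, index=sub.index, dtype=object)
    if complete.any():
        strings[complete] = sub[complete].astype(str).agg("|".join, axis=1)

    counts = strings.dropna().value_counts()
    labels: dict[str, str] = {}
    rank = 1
    for s in counts.index:  # value_counts sorts by decreasing frequency
        if s == ref_string:
            labels[s] = "ref"
        else:
            labels[s] = f"hap{rank}"
            rank += 1
    label_strings = {lab: s for s, lab in labels.items()}
    label_strings.setdefault("ref", ref_string)

    assignment = strings.map(labels)
    n = counts.sum()
    frequencies = pd.Series({labels[s]: c / n for s, c in counts.items()}) \
        if n else pd.Series(dtype=float)
    return HaplotypeAssignment(gene=gene, strings=label_strings,
                               assignment=assignment, frequencies=frequencies)


def site_maf(markers: MarkerMatrix, site_id: str) -> float:
    """Minor-allele frequency over non-missing gametes at a site.

    Defined as one minus the major-allele frequency, which coincides with
    the usual minor-allele frequency for biallelic sites and aggregates
    all non-major alleles at multi-allelic ones.
    """
    col = markers.calls[site_id].dropna()
    if col.empty:
        return 0.0
    counts = col.value_counts()
    # integer arithmetic keeps boundary frequencies exact (1/20 == 0.05)
    return float((counts.sum() - counts.iloc[0]) / counts.sum())


def filter_maf(data: Union[MarkerMatrix, HaplotypeAssignment],
               threshold: float = 0.05):
    """Drop rare sites or haplotypes (frequency <= threshold; strict '>').

    For a MarkerMatrix, sites whose minor-allele frequency is <= threshold
    are removed.  For a HaplotypeAssignment, genotypes carrying haplotypes
    at frequency <= threshold are set missing and the frequencies of the
    retained haplotypes are renormalized; the reference haplotype is kept
    whenever it is observed at all (it is the contrast baseline).
    Idempotent.
    """
    if not 0.0 < threshold < 0.5:
        raise ValueError("MAF threshold must lie in (0, 0.5)")
    if isinstance(data, MarkerMatrix):
        keep = [s for s in data.site_ids if site_maf(data, s) > threshold]
        if not keep:
            log.warning("filter_maf: no sites survive MAF > %g", threshold)
            return MarkerMatrix(data.calls.iloc[:, :0].copy(),
                                data.sites.iloc[:0].copy())
        return data.subset_sites(keep)

    hap = data
    keep_labels = [lab for lab, f in hap.frequencies.items()
                   if f > threshold or lab == "ref"]
    if not keep_labels:
        log.warning("filter_maf: gene %s has no haplotypes above MAF %g",
                    hap.gene, threshold)
    assignment = hap.assignment.where(hap.assignment.isin(keep_labels))
    counts = assignment.dropna().value_counts()
    n = counts.sum()
    frequencies = (counts / n) if n else pd.Series(dtype=float)
    strings = {lab: hap.strings[lab] for lab in set(keep_labels) | {"ref"}}
    return HaplotypeAssignment(gene=hap.gene, strings=strings,
                               assignment=assignment,
                               frequencies=frequencies)


def binarize_site(markers: MarkerMatrix, site_id: str) -> pd.Series:
    """0/1 non-reference indicator per genotype for one site.

    The allelic effect is expressed for the most frequent non-reference
    allele against the tester parent's reference allele; gametes carrying
    any other (rarer) non-reference allele are set missing for this
    site's test.
    """
    ref = str(markers.sites.loc[site_id, "ref_allele"])
    col = markers.calls[site_id]
    freqs = markers.allele_frequencies(site_id)
    non_ref = [a for a in freqs.index if str(a) != ref]
    if not non_ref:
        return pd.Series(np.nan, index=col.index, dtype=float)
    alt = str(non_ref[0])  # most frequent non-reference allele

    def code(v):
        if pd.isna(v):
            return np.nan
        v = str(v)
        if v == ref:
            return 0.0
        if v == alt:
            return 1.0
        return np.nan

    return col.map(code).astype(float)
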