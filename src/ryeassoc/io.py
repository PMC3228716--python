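"""Tab-separated readers/writers for every pipeline artifact.

All tables are UTF-8 TSV with a header row, ``NA`` as the missing sentinel
and optional ``#``-prefixed provenance lines (tool version, seed, config
hash) at the top, which readers skip.  Floats round-trip to 1e-12 or
better (written with 17 significant digits).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ryeassoc.types import NA, MarkerMatrix, PhenotypeTable, SsrGenotypes, StructureMatrix

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


def _provenance_lines(provenance: Optional[dict]) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in provenance.items())


def _write_tsv(df: pd.DataFrame, path, provenance: Optional[dict] = None,
               index_label: Optional[str] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, sep="\t", na_rep=NA, float_format=_FLOAT_FMT,
                  index=index_label is not None, index_label=index_label)


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NA],
                       keep_default_na=False, **kw)


# ---------------------------------------------------------------- SSR tables

def read_ssr_table(path) -> SsrGenotypes:
    """Read a diploid SSR genotype table (one ``a/b`` column per locus).

    Unparseable allele cells become missing with a logged warning;
    duplicated genotype ids or zero locus columns are hard errors.
    """
    df = _read_tsv(path, dtype=str)
    if "genotype_id" not in df.columns:
        raise ValueError("SSR table needs a 'genotype_id' column")
    ids = list(df["genotype_id"])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genotype_id in SSR table")
    loci = [c for c in df.columns if c != "genotype_id"]
    if not loci:
        raise ValueError("SSR table has zero locus columns")
    alleles = np.full((len(ids), len(loci), 2), -1, dtype=np.int64)
    n_bad = 0
    for j, locus in enumerate(loci):
        for i, cell in enumerate(df[locus]):
            if pd.isna(cell):
                continue
            try:
                a, b = str(cell).split("/")
                alleles[i, j] = (int(a), int(b))
            except (ValueError, TypeError):
                n_bad += 1
    if n_bad:
        log.warning("read_ssr_table: %d unparseable allele cells set missing", n_bad)
    return SsrGenotypes(ids, loci, alleles)


def write_ssr_table(ssr: SsrGenotypes, path, provenance: Optional[dict] = None) -> None:
    cells = {}
    miss = ssr.missing_mask()
    for j, locus in enumerate(ssr.locus_ids):
        col = [NA if miss[i, j] else f"{ssr.alleles[i, j, 0]}/{ssr.alleles[i, j, 1]}"
               for i in range(ssr.n_genotypes)]
        cells[locus] = col
    df = pd.DataFrame(cells, index=pd.Index(ssr.genotype_ids, name="genotype_id"))
    _write_tsv(df, path, provenance, index_label="genotype_id")


# ------------------------------------------------------------- marker tables

def read_marker_table(path, site_metadata_path) -> MarkerMatrix:
    """Read a genotype x site allele table plus its site-metadata table.

    A site present in the data but absent from the metadata is a hard
    error.  Indel sites are ordinary single polymorphic sites.
    """
    calls = _read_tsv(path, dtype=str).set_index("genotype_id")
    calls.index.name = None
    meta = _read_tsv(site_metadata_path, dtype={"site_id": str}).set_index("site_id")
    missing = [s for s in calls.columns if s not in meta.index]
    if missing:
        raise ValueError(f"sites absent from metadata: {missing}")
    meta["site_index"] = meta["site_index"].astype(int)
    return MarkerMatrix(calls, meta)


def write_marker_table(markers: MarkerMatrix, path, site_metadata_path,
                       provenance: Optional[dict] = None) -> None:
    df = markers.calls.copy()
    df.index.name = "genotype_id"
    _write_tsv(df, path, provenance, index_label="genotype_id")
    meta = markers.sites.copy()
    meta.index.name = "site_id"
    _write_tsv(meta, site_metadata_path, provenance, index_label="site_id")


# ----------------------------------------------------------------- Q and K

def read_q_matrix(path) -> StructureMatrix:
    """Read a structure membership matrix; rows renormalized if off by
    <= 1e-6, otherwise a hard error (raised by StructureMatrix)."""
    df = _read_tsv(path).set_index("genotype_id")
    df.index.name = None
    return StructureMatrix(df.astype(float))


def write_q_matrix(q: StructureMatrix, path, provenance: Optional[dict] = None) -> None:
    df = q.q.copy()
    _write_tsv(df, path, provenance, index_label="genotype_id")


def write_matrix(m: pd.DataFrame, path, provenance: Optional[dict] = None) -> None:
    """Write a square labelled matrix (e.g. kinship) as TSV."""
    _write_tsv(m, path, provenance, index_label="genotype_id")


def read_matrix(path) -> pd.DataFrame:
    df = _read_tsv(path).set_index("genotype_id")
    df.index.name = None
    df.columns.name = None
    return df.astype(float)


# -------------------------------------------------------------- phenotypes

def read_phenotype_table(path) -> PhenotypeTable:
    df = _read_tsv(path, dtype={"genotype_id": str, "platform": str,
                                "environment": str, "chamber": str,
                                "replicate": str, "block": str})
    for c in ("year", "month"):
        df[c] = pd.to_numeric(df[c], errors="coerce").astype("Int64")
    df["temperature"] = pd.to_numeric(df["temperature"], errors="coerce")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return PhenotypeTable(df)


def write_phenotype_table(phen: PhenotypeTable, path,
                          provenance: Optional[dict] = None) -> None:
    _write_tsv(phen.data, path, provenance)


# ------------------------------------------------------------------ results

def write_results(table: pd.DataFrame, path, provenance: Optional[dict] = None) -> None:
    """Write a scan-results table (one row per tested unit x platform)."""
    _write_tsv(table.reset_index(drop=True), path, provenance)


def read_results(path) -> pd.DataFrame:
    return _read_tsv(path)
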