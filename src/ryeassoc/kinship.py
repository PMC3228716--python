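"""Allele-similarity kinship from SSR genotypes.

The relationship matrix is built in three steps: (i) a per-locus
similarity index between two diploid genotypes — the fraction of alleles
shared under the best pairing (1 identical pairs, 0.5 one shared allele,
0 none; a strict identical/different {0,1} variant is available); (ii)
averaging over jointly non-missing loci; (iii) min-standardization
S_hat = (S - S_min) / (1 - S_min) with S_min the minimum off-diagonal raw
similarity, which maps the observed range onto [0, 1] and, after an
eigenvalue repair, yields a positive semi-definite matrix suitable as
the covariance of the polygenic genotype effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ryeassoc.types import SsrGenotypes

log = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    """Standardized allele-similarity relationship matrix among genotypes."""

    genotype_ids: list[str]
    values: np.ndarray                 # (n, n) standardized similarities
    s_min: float = np.nan              # raw off-diagonal minimum, metadata
    psd_repair_delta: float = 0.0      # Frobenius change of the PSD repair

    TOL: float = field(default=1e-8, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.genotype_ids)
        if v.shape != (n, n):
            raise ValueError("kinship matrix shape does not match genotype ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.genotype_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genotype_ids,
                            columns=self.genotype_ids)

    def reindex(self, genotype_ids: Sequence[str]) -> "KinshipMatrix":
        idx = [self.genotype_ids.index(g) for g in genotype_ids]
        return KinshipMatrix(list(genotype_ids),
                             self.values[np.ix_(idx, idx)],
                             s_min=self.s_min,
                             psd_repair_delta=self.psd_repair_delta)


def similarity_index(pair_x, pair_y, het_mode: str = "half") -> float:
    """Per-locus similarity between two unordered diploid allele pairs.

    ``het_mode="half"``: fraction of alleles shared under the best pairing
    (0, 0.5 or 1).  ``het_mode="strict"``: 1 for identical pairs, else 0.
    Missing input raises ValueError so the caller can exclude the locus.
    """
    x = sorted(pair_x)
    y = sorted(pair_y)
    if any(a is None or (isinstance(a, float) and np.isnan(a)) or a == -1
           for a in x + y):
        raise ValueError("missing allele call")
    if het_mode == "strict":
        return 1.0 if x == y else 0.0
    if het_mode != "half":
        raise ValueError(f"unknown het_mode {het_mode!r}")
    # best pairing = maximum over both ways to match the two pairs
    direct = int(x[0] == y[0]) + int(x[1] == y[1])
    crossed = int(x[0] == y[1]) + int(x[1] == y[0])
    return max(direct, crossed) / 2.0


def kinship_matrix(ssr: SsrGenotypes, het_mode: str = "half",
                   standardize: bool = True) -> KinshipMatrix:
    """Standardized allele-similarity kinship from an SSR panel.

    Raw similarities are averaged over loci with non-missing data for both
    genotypes; the matrix is then min-standardized (unless
    ``standardize=False``, for diagnostics), the diagonal pinned at 1, and
    negative eigenvalues repaired.  A genotype pair with zero jointly
    non-missing loci is a hard error.
    """
    if ssr.n_genotypes < 2:
        raise ValueError("kinship needs at least 2 genotypes")
    a = ssr.alleles  # (n, L, 2), sorted pairs, -1 missing
    present = ~ssr.missing_mask()  # (n, L)

    # vectorized best-pairing similarity for all pairs and loci
    a0 = a[:, :, 0]
    a1 = a[:, :, 1]
    direct = ((a0[:, None, :] == a0[None, :, :]).astype(np.int8)
              + (a1[:, None, :] == a1[None, :, :]).astype(np.int8))
    crossed = ((a0[:, None, :] == a1[None, :, :]).astype(np.int8)
               + (a1[:, None, :] == a0[None, :, :]).astype(np.int8))
    if het_mode == "half":
        sim = np.maximum(direct, crossed) / 2.0
    elif het_mode == "strict":
        sim = (np.maximum(direct, crossed) == 2).astype(float)
    else:
        raise ValueError(f"unknown het_mode {het_mode!r}")

    both = present[:, None, :] & present[None, :, :]
    counts = both.sum(axis=2)
    if (counts == 0).any():
        i, j = np.argwhere(counts == 0)[0]
        raise ValueError(
            f"genotypes {ssr.genotype_ids[i]!r} and {ssr.genotype_ids[j]!r} "
            "share no non-missing loci")
    raw = np.where(both, sim, 0.0).sum(axis=2) / counts

    off = ~np.eye(ssr.n_genotypes, dtype=bool)
    s_min = float(raw[off].min())
    if standardize:
        denom = 1.0 - s_min
        values = (raw - s_min) / denom if denom > 0 else np.ones_like(raw)
    else:
        values = raw.copy()
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0

    k = KinshipMatrix(list(ssr.genotype_ids), values, s_min=s_min)
    return ensure_psd(k)


def ensure_psd(k: KinshipMatrix, tol: float = 1e-8) -> KinshipMatrix:
    """Repair a kinship matrix to positive semi-definiteness.

    If the minimum eigenvalue is below -tol, negative eigenvalues are
    clipped to zero, the matrix reconstructed, the diagonal rescaled to 1
    and the Frobenius-norm change logged; otherwise returned unchanged.
    """
    v = k.values
    if not np.allclose(v, v.T, atol=1e-10):
        raise ValueError("ensure_psd: input not symmetric")
    w = np.linalg.eigvalsh(v)
    if w.min() >= -tol:
        return k
    evals, evecs = np.linalg.eigh(v)
    evals = np.clip(evals, 0.0, None)
    repaired = (evecs * evals) @ evecs.T
    d = np.sqrt(np.clip(np.diag(repaired), 1e-12, None))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    delta = float(np.linalg.norm(repaired - v, "fro"))
    log.info("ensure_psd: clipped eigenvalues, Frobenius change %.3g", delta)
    return KinshipMatrix(k.genotype_ids, repaired, s_min=k.s_min,
                         psd_repair_delta=delta)


def covariance_root(k: KinshipMatrix, tol: float = 1e-8) -> np.ndarray:
    """Matrix root L with L @ L.T = K, for embedding kinship in the LMM.

    Cholesky factor when K is positive definite; a symmetric
    eigendecomposition root when singular.  Non-PSD input (beyond the
    tolerance) is a hard error — run ensure_psd first.
    """
    v = k.values
    try:
        return np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        pass
    evals, evecs = np.linalg.eigh(v)
    if evals.min() < -tol:
        raise ValueError(
            f"covariance_root: matrix is not PSD (min eigenvalue {evals.min():.3g}); "
            "run ensure_psd first")
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    if np.abs(root @ root.T - v).max() > 1e-8:
        raise ValueError("covariance_root: reconstruction failed")
    return root


def within_between_means(k: KinshipMatrix,
                         population_of: dict[str, str]) -> tuple[float, float]:
    """Mean standardized similarity within vs between source populations."""
    pops = np.array([population_of[g] for g in k.genotype_ids])
    same = pops[:, None] == pops[None, :]
    off = ~np.eye(k.n, dtype=bool)
    return (float(k.values[same & off].mean()),
            float(k.values[~same].mean()))
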