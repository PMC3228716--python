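"""Gaussian linear mixed models with multiple random-effect blocks.

The model is

    y = X beta + sum_b Z_b u_b + e,      e ~ N(0, I sigma^2)

with each random block ``u_b`` one of

* ``iid``              u ~ N(0, I sigma_b^2)  (chambers, replications, blocks)
* ``kinship_root``     genotype effects u ~ N(0, K sigma_g^2), realized by
                       multiplying the genotype incidence design by a root L
                       of the kinship matrix (L L' = K) and treating the
                       transformed coefficients as iid — the
                       root-embedding trick;
* ``intercept_trend``  per-unit random intercept and slope with an
                       unstructured 2x2 covariance (repeated monthly
                       measures of the semi-controlled platform).

Estimation profiles the fixed effects (GLS) and the residual variance out
of the (restricted) likelihood and maximizes over variance *ratios*
gamma_b = sigma_b^2 / sigma^2 on the log scale (correlation via atanh),
with bounded quasi-Newton iterations from several deterministic starts.
All per-iteration algebra runs on cross-products of the stacked random
design, so the cost per evaluation is O(q^3) in the total number of
random-effect columns, independent of n.

``direct_loglik`` is a deliberately naive oracle: it forms the full n x n
covariance matrix and evaluates the exact (restricted) log-likelihood,
for verifying the profiled objective on small problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg as sla
from scipy import optimize, stats

log = logging.getLogger(__name__)

#: internal floor for variance ratios; components at the floor report as 0
GAMMA_FLOOR = 1e-10
GAMMA_CEIL = 1e10
_LOG_FLOOR = np.log(GAMMA_FLOOR)
_LOG_CEIL = np.log(GAMMA_CEIL)

VALID_KINDS = ("iid", "kinship_root", "intercept_trend")


@dataclass
class RandomBlock:
    """One random-effect block of the mixed model.

    For ``kinship_root``, ``Z`` is the raw genotype incidence matrix and
    ``root`` the matrix root L with L L' = K; the effective design is
    ``Z @ root``.  For ``intercept_trend``, ``Z`` has 2*U columns ordered
    [unit intercepts..., unit trends...] and ``n_units`` = U.
    """

    label: str
    Z: np.ndarray
    kind: str = "iid"
    root: Optional[np.ndarray] = None
    n_units: int = 0

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown random-block kind {self.kind!r}")
        self.Z = np.asarray(self.Z, dtype=float)
        if self.kind == "kinship_root":
            if self.root is None:
                raise ValueError("kinship_root block needs a covariance root")
            self.root = np.asarray(self.root, dtype=float)
            if self.Z.shape[1] != self.root.shape[0]:
                raise ValueError("incidence/root dimension mismatch")
        if self.kind == "intercept_trend":
            if self.n_units <= 0 or self.Z.shape[1] != 2 * self.n_units:
                raise ValueError("intercept_trend block needs Z with 2*n_units columns")

    @property
    def n_params(self) -> int:
        return 3 if self.kind == "intercept_trend" else 1

    def effective_design(self) -> np.ndarray:
        if self.kind == "kinship_root":
            return self.Z @ self.root
        return self.Z


class ModelSpec:
    """Response, fixed design and random blocks for one mixed-model fit.

    Collinear fixed-effect columns are pruned at construction (QR with
    column pivoting); dropped labels are recorded in ``dropped_columns``.
    At most one kinship block is allowed.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, x_labels: Sequence[str],
                 blocks: Sequence[RandomBlock] = ()):
        y = np.asarray(y, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        if X.shape[1] != len(x_labels):
            raise ValueError("x_labels length does not match X columns")
        if not np.isfinite(y).all() or not np.isfinite(X).all():
            raise ValueError("non-finite values in y or X; drop incomplete rows first")
        n_kin = sum(b.kind == "kinship_root" for b in blocks)
        if n_kin > 1:
            raise ValueError("at most one kinship block allowed")
        for b in blocks:
            if b.Z.shape[0] != y.shape[0]:
                raise ValueError(f"random block {b.label!r} row count differs from y")

        keep, dropped = _prune_collinear(X, list(x_labels))
        self.dropped_columns: list[str] = dropped
        self.x_labels: list[str] = [x_labels[i] for i in keep]
        self.X = X[:, keep]
        self.y = y
        self.blocks = list(blocks)
        self.n, self.p = self.X.shape
        if self.n <= self.p:
            raise ValueError("need more observations than fixed-effect columns")
        self._xprod: Optional[dict] = None
        self._uu_override: Optional[np.ndarray] = None

    # ---------------------------------------------------------------- algebra

    def _cross_products(self) -> dict:
        """Cache cross-products of [U, X, y] with U the stacked random design."""
        if self._xprod is None:
            U = (np.concatenate([b.effective_design() for b in self.blocks], axis=1)
                 if self.blocks else np.empty((self.n, 0)))
            uu = self._uu_override
            if uu is None or uu.shape[0] != U.shape[1]:
                uu = U.T @ U
            self._xprod = {
                "Uy": U.T @ self.y,
                "UX": U.T @ self.X,
                "UU": uu,
                "Xy": self.X.T @ self.y,
                "XX": self.X.T @ self.X,
                "yy": float(self.y @ self.y),
                "q": U.shape[1],
            }
            self._xprod["paired"] = self._paired_structure(self._xprod)
        return self._xprod

    def _paired_structure(self, cp: dict) -> Optional[dict]:
        """Pre-split cross-products around a single intercept-trend block.

        The unit columns of an intercept-trend block only couple within
        their own (intercept, trend) pair, so the inner q x q system is a
        2x2-block-diagonal matrix bordered by the remaining (dense)
        columns; factoring it that way makes the per-iteration cost
        O(U m^2) instead of O(q^3).
        """
        it_blocks = [b for b in self.blocks if b.kind == "intercept_trend"]
        if len(it_blocks) != 1:
            return None
        b = it_blocks[0]
        off = 0
        for blk in self.blocks:
            if blk is b:
                break
            off += blk.effective_design().shape[1]
        U_units = b.n_units
        int_idx = np.arange(off, off + U_units)
        tr_idx = np.arange(off + U_units, off + 2 * U_units)
        dense_idx = np.array([j for j in range(cp["q"])
                              if not (off <= j < off + 2 * U_units)], dtype=int)
        UU = cp["UU"]
        return {
            "block": b,
            "int_idx": int_idx, "tr_idx": tr_idx, "dense_idx": dense_idx,
            "nn": UU[int_idx, int_idx], "st": UU[int_idx, tr_idx],
            "tt": UU[tr_idx, tr_idx],
            "pd_int": UU[np.ix_(int_idx, dense_idx)],
            "pd_tr": UU[np.ix_(tr_idx, dense_idx)],
            "dd": UU[np.ix_(dense_idx, dense_idx)],
        }

    def share_random_design(self, other: "ModelSpec") -> None:
        """Let ``other`` reuse this spec's U'U cross-product (identical
        random blocks, different fixed design)."""
        other._uu_override = self._cross_products()["UU"]


def _prune_collinear(X: np.ndarray, labels: list[str],
                     rtol: float = 1e-8) -> tuple[list[int], list[str]]:
    if X.shape[1] == 0:
        return [], []
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = rtol * (d.max() if d.size else 0.0)
    rank = int((d > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [labels[i] for i in piv[rank:]]
    return list(keep), dropped


# ----------------------------------------------------------- parameterization

def _theta_slices(blocks: Sequence[RandomBlock]) -> list[tuple[RandomBlock, slice]]:
    out, at = [], 0
    for b in blocks:
        out.append((b, slice(at, at + b.n_params)))
        at += b.n_params
    return out


def _block_gamma_half(b: RandomBlock, th: np.ndarray) -> np.ndarray:
    """Square root of the variance-ratio covariance of one block's columns."""
    if b.kind == "intercept_trend":
        g1, g2 = np.exp(th[0]), np.exp(th[1])
        rho = np.tanh(th[2])
        G = np.array([[g1, rho * np.sqrt(g1 * g2)],
                      [rho * np.sqrt(g1 * g2), g2]])
        w, v = np.linalg.eigh(G)
        return (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T  # 2x2 symmetric sqrt
    return np.array([[np.exp(0.5 * th[0])]])


def _apply_gamma_half(blocks, theta, M: np.ndarray, axis: int) -> np.ndarray:
    """Multiply the q-dim axis of M by the block-diagonal Gamma^{1/2}."""
    M = np.moveaxis(np.atleast_2d(M), axis, 0).copy()
    at = 0
    for b, sl in _theta_slices(blocks):
        qb = b.Z.shape[1] if b.kind != "kinship_root" else b.root.shape[1]
        A = _block_gamma_half(b, theta[sl])
        if b.kind == "intercept_trend":
            U = b.n_units
            mi = M[at:at + U].copy()
            mt = M[at + U:at + 2 * U].copy()
            M[at:at + U] = A[0, 0] * mi + A[0, 1] * mt
            M[at + U:at + 2 * U] = A[1, 0] * mi + A[1, 1] * mt
        else:
            M[at:at + qb] *= A[0, 0]
        at += qb
    return np.moveaxis(M, 0, axis)


def _paired_inner(spec: ModelSpec, theta: np.ndarray,
                  cp: dict) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Bordered block-diagonal factorization of M = I + G^.5 U'U G^.5.

    The intercept-trend unit columns only couple within their own
    (intercept, trend) pair; eliminating them first leaves a dense Schur
    complement on the remaining columns.
    """
    ps = cp["paired"]
    b_it = ps["block"]
    th_it = None
    g_parts = []
    for b, sl in _theta_slices(spec.blocks):
        if b is b_it:
            th_it = theta[sl]
        else:
            qb = b.effective_design().shape[1]
            g_parts.append(np.full(qb, np.exp(0.5 * theta[sl][0])))
    g_d = np.concatenate(g_parts) if g_parts else np.empty(0)
    A = _block_gamma_half(b_it, th_it)
    a, bb, c = A[0, 0], A[0, 1], A[1, 1]

    n_, s_, t_ = ps["nn"], ps["st"], ps["tt"]
    R11 = n_ * a + s_ * bb
    R12 = n_ * bb + s_ * c
    R21 = s_ * a + t_ * bb
    R22 = s_ * bb + t_ * c
    P11 = 1.0 + a * R11 + bb * R21
    P12 = a * R12 + bb * R22
    P22 = 1.0 + bb * R12 + c * R22
    L11 = np.sqrt(P11)
    L21 = P12 / L11
    L22 = np.sqrt(np.clip(P22 - L21 ** 2, 1e-300, None))

    Bi = (a * ps["pd_int"] + bb * ps["pd_tr"]) * g_d[None, :]
    Bt = (bb * ps["pd_int"] + c * ps["pd_tr"]) * g_d[None, :]
    Y1 = Bi / L11[:, None]
    Y2 = (Bt - L21[:, None] * Y1) / L22[:, None]
    m = len(ps["dense_idx"])
    S_e = np.eye(m) + g_d[:, None] * ps["dd"] * g_d[None, :] \
        - Y1.T @ Y1 - Y2.T @ Y2
    Ls = np.linalg.cholesky((S_e + S_e.T) / 2.0)
    logdet_w = 2.0 * float(np.sum(np.log(L11)) + np.sum(np.log(L22))
                           + np.sum(np.log(np.diag(Ls))))

    RX = np.column_stack([cp["UX"], cp["Uy"]])
    Ri, Rt, Rd = RX[ps["int_idx"]], RX[ps["tr_idx"]], RX[ps["dense_idx"]]
    r1 = (a * Ri + bb * Rt) / L11[:, None]
    r2 = ((bb * Ri + c * Rt) - L21[:, None] * r1) / L22[:, None]
    rd = sla.solve_triangular(
        Ls, g_d[:, None] * Rd - Y1.T @ r1 - Y2.T @ r2, lower=True)
    T = r1.T @ r1 + r2.T @ r2 + rd.T @ rd
    p = spec.p
    XtWiX = cp["XX"] - T[:p, :p]
    XtWiy = cp["Xy"] - T[:p, p]
    ytWiy = cp["yy"] - T[p, p]
    return XtWiX, XtWiy, float(ytWiy), logdet_w


def _profiled_quantities(spec: ModelSpec, theta: np.ndarray) -> dict:
    """GLS solution and log-determinants for W = I + U Gamma U'."""
    cp = spec._cross_products()
    q = cp["q"]
    if q and cp.get("paired") is not None:
        XtWiX, XtWiy, ytWiy, logdet_w = _paired_inner(spec, theta, cp)
    elif q:
        B = _apply_gamma_half(spec.blocks, theta, cp["UX"], 0)
        by = _apply_gamma_half(spec.blocks, theta, cp["Uy"][:, None], 0)[:, 0]
        S = _apply_gamma_half(spec.blocks, theta,
                              _apply_gamma_half(spec.blocks, theta, cp["UU"], 0), 1)
        M = S + np.eye(q)
        R = np.linalg.cholesky(M)
        TB = sla.solve_triangular(R, B, lower=True)
        ty = sla.solve_triangular(R, by, lower=True)
        XtWiX = cp["XX"] - TB.T @ TB
        XtWiy = cp["Xy"] - TB.T @ ty
        ytWiy = cp["yy"] - ty @ ty
        logdet_w = 2.0 * float(np.sum(np.log(np.diag(R))))
    else:
        XtWiX, XtWiy, ytWiy, logdet_w = cp["XX"], cp["Xy"], cp["yy"], 0.0

    XtWiX = (XtWiX + XtWiX.T) / 2.0
    cf, low = sla.cho_factor(XtWiX)
    beta = sla.cho_solve((cf, low), XtWiy)
    rss = max(float(ytWiy - beta @ XtWiy), 1e-300)
    logdet_xwx = 2.0 * float(np.sum(np.log(np.abs(np.diag(cf)))))
    return {"beta": beta, "rss": rss, "XtWiX": XtWiX,
            "logdet_w": logdet_w, "logdet_xwx": logdet_xwx,
            "cho": (cf, low)}


def _profiled_loglik(spec: ModelSpec, theta: np.ndarray, method: str) -> float:
    pq = _profiled_quantities(spec, theta)
    n, p = spec.n, spec.p
    if method == "reml":
        s2 = pq["rss"] / (n - p)
        return -0.5 * ((n - p) * (np.log(2 * np.pi * s2) + 1.0)
                       + pq["logdet_w"] + pq["logdet_xwx"])
    s2 = pq["rss"] / n
    return -0.5 * (n * (np.log(2 * np.pi * s2) + 1.0) + pq["logdet_w"])


# ------------------------------------------------------------------- results

@dataclass
class LMMFit:
    """Fitted mixed model: variance components, GLS fixed effects, loglik."""

    method: str
    varcomp: dict                     # label -> sigma^2 (tuple for 2x2 blocks)
    beta: dict                        # label -> estimate
    se: dict                          # label -> standard error
    loglik: float
    n: int
    p: int
    x_labels: list = field(default_factory=list)
    dropped_columns: list = field(default_factory=list)
    boundary: dict = field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0
    grad_norm: float = np.nan
    theta: np.ndarray = field(default=None, repr=False)
    spec: ModelSpec = field(default=None, repr=False)

    @property
    def sigma2(self) -> float:
        return self.varcomp["residual"]

    def to_dict(self) -> dict:
        """JSON-serializable summary of the fit."""
        return {
            "method": self.method,
            "varcomp": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in self.varcomp.items()},
            "beta": dict(self.beta), "se": dict(self.se),
            "loglik": self.loglik, "n": self.n, "p": self.p,
            "converged": self.converged, "n_iter": self.n_iter,
            "boundary": dict(self.boundary),
            "dropped_columns": list(self.dropped_columns),
        }


_DEFAULT_STARTS = (np.log(0.5), np.log(0.05), np.log(3.0))


def fit_lmm(spec: ModelSpec, method: str = "reml", n_starts: int = 3,
            warm_start: Optional[np.ndarray] = None,
            gtol: float = 1e-8) -> LMMFit:
    """Maximize the (restricted) likelihood over the variance components.

    Variance ratios are optimized on the log scale (correlation of the
    2x2 block via tanh) by bounded quasi-Newton from ``n_starts``
    deterministic starting points (plus ``warm_start`` if given); the best
    optimum is kept.  Ratios reaching the internal floor are reported as
    variance 0 with a boundary flag.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    d = sum(b.n_params for b in spec.blocks)

    if d == 0:
        return _fit_no_random(spec, method)

    def objective(theta):
        try:
            return -_profiled_loglik(spec, theta, method)
        except np.linalg.LinAlgError:
            return 1e12

    bounds = []
    for b, sl in _theta_slices(spec.blocks):
        bounds.append((_LOG_FLOOR, _LOG_CEIL))
        if b.kind == "intercept_trend":
            bounds.append((_LOG_FLOOR, _LOG_CEIL))
            bounds.append((-5.0, 5.0))

    starts = []
    if warm_start is not None:
        starts.append(np.asarray(warm_start, dtype=float))
    for s in _DEFAULT_STARTS[:max(n_starts, 1)]:
        th = np.full(d, s)
        for b, sl in _theta_slices(spec.blocks):
            if b.kind == "intercept_trend":
                th[sl.start + 2] = 0.0
        starts.append(th)

    best = None
    any_success = False
    for th0 in starts:
        res = optimize.minimize(objective, th0, method="L-BFGS-B",
                                bounds=bounds,
                                options={"gtol": gtol, "maxiter": 500})
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("fit_lmm failed to converge from all starts")
    # a line-search failure at a flat optimum still yields a usable
    # maximizer; flag as non-converged only when the gradient is large
    grad_ok = (getattr(best, "jac", None) is not None
               and np.max(np.abs(best.jac)) < 1e-2)
    if not (best.success or any_success or grad_ok):
        raise RuntimeError(f"fit_lmm non-convergence: {best.message}")

    theta = best.x
    pq = _profiled_quantities(spec, theta)
    dof = spec.n - spec.p if method == "reml" else spec.n
    s2 = pq["rss"] / dof
    cov_beta = s2 * sla.cho_solve(pq["cho"], np.eye(spec.p))

    varcomp: dict = {}
    boundary: dict = {}
    for b, sl in _theta_slices(spec.blocks):
        th = theta[sl]
        if b.kind == "intercept_trend":
            g1, g2 = np.exp(th[0]), np.exp(th[1])
            rho = float(np.tanh(th[2]))
            at_floor = (th[0] <= _LOG_FLOOR + 1e-6, th[1] <= _LOG_FLOOR + 1e-6)
            v1 = 0.0 if at_floor[0] else g1 * s2
            v2 = 0.0 if at_floor[1] else g2 * s2
            varcomp[b.label] = (v1, v2, rho)
            boundary[b.label] = any(at_floor)
        else:
            at_floor = th[0] <= _LOG_FLOOR + 1e-6
            varcomp[b.label] = 0.0 if at_floor else float(np.exp(th[0]) * s2)
            boundary[b.label] = bool(at_floor)
    varcomp["residual"] = float(s2)

    beta = dict(zip(spec.x_labels, pq["beta"]))
    se = dict(zip(spec.x_labels, np.sqrt(np.clip(np.diag(cov_beta), 0, None))))
    ll = _profiled_loglik(spec, theta, method)
    grad = getattr(best, "jac", None)
    return LMMFit(method=method, varcomp=varcomp, beta=beta, se=se,
                  loglik=float(ll), n=spec.n, p=spec.p,
                  x_labels=list(spec.x_labels),
                  dropped_columns=list(spec.dropped_columns),
                  boundary=boundary, converged=bool(best.success or grad_ok),
                  n_iter=int(best.nit),
                  grad_norm=float(np.max(np.abs(grad))) if grad is not None else np.nan,
                  theta=theta, spec=spec)


def _fit_no_random(spec: ModelSpec, method: str) -> LMMFit:
    """Closed-form fit when the model has no random blocks (GLS = OLS)."""
    pq = _profiled_quantities(spec, np.empty(0))
    dof = spec.n - spec.p if method == "reml" else spec.n
    s2 = pq["rss"] / dof
    cov_beta = s2 * sla.cho_solve(pq["cho"], np.eye(spec.p))
    ll = _profiled_loglik(spec, np.empty(0), method)
    return LMMFit(method=method, varcomp={"residual": float(s2)},
                  beta=dict(zip(spec.x_labels, pq["beta"])),
                  se=dict(zip(spec.x_labels,
                              np.sqrt(np.clip(np.diag(cov_beta), 0, None)))),
                  loglik=float(ll), n=spec.n, p=spec.p,
                  x_labels=list(spec.x_labels),
                  dropped_columns=list(spec.dropped_columns),
                  boundary={}, converged=True, n_iter=0,
                  theta=np.empty(0), spec=spec)


# -------------------------------------------------------------------- oracle

def direct_loglik(spec: ModelSpec, variances: dict, method: str = "reml",
                  n_guard: int = 500) -> float:
    """Exact (restricted) log-likelihood via the full n x n covariance.

    ``variances`` maps block labels to sigma_b^2 (a
    ``(var_int, var_trend, corr)`` triple for intercept-trend blocks) and
    ``"residual"`` to sigma^2.  Kinship blocks contribute Z K Z' sigma_g^2
    with K reconstructed from the stored root.  Intended as a brute-force
    verification oracle; guarded to small n.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    n = spec.n
    if n > n_guard:
        raise ValueError(f"direct_loglik guarded to n <= {n_guard}")
    V = np.eye(n) * float(variances["residual"])
    for b in spec.blocks:
        v = variances[b.label]
        if b.kind == "iid":
            V += float(v) * b.Z @ b.Z.T
        elif b.kind == "kinship_root":
            K = b.root @ b.root.T
            V += float(v) * b.Z @ K @ b.Z.T
        else:
            v1, v2, rho = v
            G2 = np.array([[v1, rho * np.sqrt(v1 * v2)],
                           [rho * np.sqrt(v1 * v2), v2]])
            U = b.n_units
            G = np.kron(G2, np.eye(U))
            V += b.Z @ G @ b.Z.T
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular covariance in direct_loglik")
    Vi = np.linalg.inv(V)
    X, y = spec.X, spec.y
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    quad = float(r @ Vi @ r)
    if method == "ml":
        return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    sign2, logdet_x = np.linalg.slogdet(XtViX)
    if sign2 <= 0:
        raise np.linalg.LinAlgError("singular X'V^-1X in direct_loglik")
    p = spec.p
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet + logdet_x + quad)


# ----------------------------------------------------------------- inference

def wald_test(fit: LMMFit, label: str, reference: str = "normal",
              df: Optional[float] = None) -> tuple[float, float, float, float]:
    """(estimate, SE, t, two-sided P) for one fixed-effect coefficient.

    The default reference for the t statistic is the standard normal
    (no denominator-df correction); pass ``reference="t"`` with ``df``
    for a Student-t reference.
    """
    if label in fit.dropped_columns:
        raise ValueError(f"coefficient {label!r} was dropped as collinear")
    if label not in fit.beta:
        raise ValueError(f"no coefficient {label!r} in fit")
    est, se = float(fit.beta[label]), float(fit.se[label])
    if se <= 0:
        raise ValueError(f"coefficient {label!r} has non-positive SE")
    t = est / se
    if reference == "normal":
        p = 2.0 * stats.norm.sf(abs(t))
    elif reference == "t":
        if df is None:
            df = fit.n - fit.p
        p = 2.0 * stats.t.sf(abs(t), df)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return est, se, t, p


def lrt(fit_full: LMMFit, fit_reduced: LMMFit,
        df: Optional[int] = None) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: (statistic, df, P).

    The chi-square reference is deliberately conservative for
    variance-component tests, whose true null distribution is a mixture
    of chi-squares.  Fixed-effect comparisons require ML; comparing REML
    fits with different fixed-effect sets is a hard error.
    """
    if fit_full.method != fit_reduced.method:
        raise ValueError("LRT requires both fits to use the same method")
    if fit_full.method == "reml" and set(fit_full.x_labels) != set(fit_reduced.x_labels):
        raise ValueError("REML likelihoods are not comparable across different "
                         "fixed effects; refit with ML")
    if df is None:
        n_par_full = fit_full.p + sum(3 if isinstance(v, tuple) else 1
                                      for k, v in fit_full.varcomp.items()
                                      if k != "residual")
        n_par_red = fit_reduced.p + sum(3 if isinstance(v, tuple) else 1
                                        for k, v in fit_reduced.varcomp.items()
                                        if k != "residual")
        df = n_par_full - n_par_red
    if df <= 0:
        raise ValueError("reduced model is not nested in the full model (df <= 0)")
    stat = max(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df))
    return stat, int(df), p


def variance_explained(fit_without: LMMFit, fit_with: LMMFit,
                       genotype_label: str = "genotype") -> float:
    """Percent genetic variance explained by the added marker term.

    100 * (sigma_g,without^2 - sigma_g,with^2) / sigma_g,without^2,
    truncated below at zero; defined as 0 (with a logged flag) when the
    reduced genetic variance is 0.  Both fits must share the response.
    """
    if fit_without.spec is None or fit_with.spec is None or \
            not np.array_equal(fit_without.spec.y, fit_with.spec.y):
        raise ValueError("variance_explained: fits have mismatched responses")
    if fit_without.method != fit_with.method:
        raise ValueError("variance_explained: fits use different methods")
    s_red = float(fit_without.varcomp[genotype_label])
    s_with = float(fit_with.varcomp[genotype_label])
    if s_red <= 0.0:
        log.warning("variance_explained: reduced genetic variance is 0; "
                    "returning 0")
        return 0.0
    return max(100.0 * (s_red - s_with) / s_red, 0.0)
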