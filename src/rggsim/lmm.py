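"""General REML/BLUP engine for MET mixed models.

Fits linear mixed models of the form

    y = X b + sum_r Z_r u_r + e,   u_r ~ N(0, K_r(theta_r)),   e ~ N(0, R)

by direct maximization of the restricted log-likelihood over unconstrained
(log-variance / loading) parameters with analytic gradients (L-BFGS-B).
Term-wise covariance structures: identity, diagonal-by-group, first-order
factor-analytic (FA1, ``lambda lambda' + Psi`` across an environment index
within independent subject blocks), and a known genomic relationship matrix
(GRM).  Residuals are homogeneous, scaled known weights (two-stage
entry-mean analyses), or heterogeneous by group (per-trial plot variances).

The likelihood is evaluated through the dense marginal covariance
``V = sum_r Z_r K_r Z_r' + R``; problem sizes targeted here (a few thousand
records) make that the simplest reliable route.  Variance parameters are
kept positive by log-parameterization; estimates pinned at the lower bound
are reported as boundary cases rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, sparse

__all__ = ["RandomEffect", "ModelSpec", "FitResult", "fit_reml"]

_LOG_FLOOR = -9.2    # lower bound on log-variance parameters (~1e-4)
_LOG_CEIL = 25.0


@dataclass
class RandomEffect:
    """Declarative random model term.

    ``factors``: column name or tuple of columns whose combination indexes
    the levels.  ``extra_factors``: optional second factor set loading on the
    same levels (general combining ability: each observation carries both
    parents' effects).

    ``cov`` is one of:
      * "identity" -- homogeneous variance.
      * "diagonal" -- one variance per value of ``group_by`` (a column
        constant within each level, e.g. the location for GL effects).
      * "fa1"      -- ``inner`` names the environment-like column (loadings
        dimension), ``block`` the subject-like column; levels in different
        blocks are independent.
      * "grm"      -- ``K`` is the relationship matrix with row labels
        ``K_ids``; variance is a single scale on ``K``.
    """

    name: str
    factors: object
    cov: str = "identity"
    group_by: str | None = None
    inner: str | None = None
    block: str | None = None
    extra_factors: object = None
    K: np.ndarray | None = None
    K_ids: list | None = None
    init: float | None = None   # starting variance guess (optimizer only)


@dataclass
class ModelSpec:
    """Mixed-model structure: response, fixed part, random terms, residual."""

    response: str
    fixed_factors: list = field(default_factory=list)
    fixed_covariates: list = field(default_factory=list)
    random: list = field(default_factory=list)
    weights: str | None = None          # known relative residual variances
    residual_groups: str | None = None  # heterogeneous residual classes
    residual_init: float | None = None  # starting residual-variance guess


@dataclass
class FitResult:
    fixed_effects: pd.Series
    fixed_se: pd.Series
    fixed_cov: pd.DataFrame
    varcomp: dict
    blups: dict
    loglik: float
    converged: bool
    n_iter: int
    boundary: list
    n_obs: int
    packed: np.ndarray | None = None

    def blup(self, term: str) -> pd.Series:
        return self.blups[term]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _level_key(data: pd.DataFrame, factors) -> pd.Series:
    if isinstance(factors, (list, tuple)):
        key = data[factors[0]].astype(str)
        for f in factors[1:]:
            key = key + "\x1f" + data[f].astype(str)
        return key
    return data[factors].astype(str)


def _indicator(data: pd.DataFrame, factors, level_index=None):
    key = _level_key(data, factors)
    if level_index is None:
        levels = pd.Index(sorted(key.unique()))
    else:
        levels = pd.Index(level_index)
    codes = levels.get_indexer(key)
    if (codes < 0).any():
        raise ValueError("observation level missing from supplied level index")
    n, q = len(data), len(levels)
    Z = sparse.csr_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, q))
    return Z, levels, codes


def _build_fixed(data: pd.DataFrame, spec: ModelSpec):
    cols, names = [np.ones(len(data))], ["(Intercept)"]
    for f in spec.fixed_factors:
        if isinstance(f, tuple) and len(f) > 1 and f[0] == "+":
            # summed indicators over several columns sharing one level set
            # (fixed general combining ability: both parents' effects load)
            levels = pd.Index(sorted(set().union(
                *[data[c].astype(str).unique() for c in f[1:]])))
            D = np.zeros((len(data), len(levels)))
            for c in f[1:]:
                codes = levels.get_indexer(data[c].astype(str))
                np.add.at(D, (np.arange(len(data)), codes), 1.0)
            fname = "+".join(f[1:])
            for i, lev in enumerate(levels[1:], start=1):  # drop first level
                cols.append(D[:, i])
                names.append(f"{fname}[{lev}]")
            continue
        key = _level_key(data, f)
        d = pd.get_dummies(key, drop_first=True, dtype=float)
        fname = f if isinstance(f, str) else "_".join(f)
        for c in d.columns:
            cols.append(d[c].to_numpy())
            names.append(f"{fname}[{c}]")
    for c in spec.fixed_covariates:
        cols.append(data[c].to_numpy(float))
        names.append(c)
    X = np.column_stack(cols)
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    return X[:, keep], [names[i] for i in keep]


# ---------------------------------------------------------------------------
# random terms
# ---------------------------------------------------------------------------

class _Term:
    """Per-term state: sparse design, covariance parameterization, gradients."""

    def __init__(self, eff: RandomEffect, data: pd.DataFrame, var_y: float):
        self.eff = eff
        self.name = eff.name
        self.kind = eff.cov
        if self.kind == "grm":
            if eff.K is None or eff.K_ids is None:
                raise ValueError(f"term {eff.name}: grm requires K and K_ids")
            levels = [str(i) for i in eff.K_ids]
            Z, self.levels, self.codes = _indicator(data, eff.factors, levels)
            self.K0 = np.asarray(eff.K, float)
        elif eff.extra_factors is not None:
            # levels span both factor sets (e.g. both parents of a cross)
            union = sorted(set(_level_key(data, eff.factors))
                           | set(_level_key(data, eff.extra_factors)))
            Z, self.levels, self.codes = _indicator(data, eff.factors, union)
        else:
            Z, self.levels, self.codes = _indicator(data, eff.factors)
        if eff.extra_factors is not None:
            Z2, _, _ = _indicator(data, eff.extra_factors, self.levels)
            Z = Z + Z2
        self.Z = Z.tocsr()
        self.Zt = self.Z.T.tocsr()
        self.q = Z.shape[1]
        self.var_y = var_y
        if self.kind == "identity":
            self.ZZt = (self.Z @ self.Zt).tocoo()
            self.n_params = 1
        elif self.kind == "diagonal":
            groups = self._level_attr(data, eff.group_by)
            self.group_labels = pd.Index(sorted(set(groups)))
            self.group_codes = self.group_labels.get_indexer(groups)
            self.n_params = len(self.group_labels)
        elif self.kind == "fa1":
            inner = self._level_attr(data, eff.inner)
            self.inner_labels = pd.Index(sorted(set(inner)))
            self.inner_codes = self.inner_labels.get_indexer(inner)
            self.m = len(self.inner_labels)
            block = self._level_attr(data, eff.block)
            bl = pd.Index(sorted(set(block)))
            bcodes = bl.get_indexer(block)
            order = np.argsort(bcodes, kind="stable")
            bounds = np.searchsorted(bcodes[order], np.arange(len(bl) + 1))
            la, lb = [], []
            for s in range(len(bl)):
                members = order[bounds[s]:bounds[s + 1]]
                A, B = np.meshgrid(members, members, indexing="ij")
                la.append(A.ravel())
                lb.append(B.ravel())
            self.pair_a = np.concatenate(la) if la else np.empty(0, int)
            self.pair_b = np.concatenate(lb) if lb else np.empty(0, int)
            self.pair_ja = self.inner_codes[self.pair_a]
            self.pair_jb = self.inner_codes[self.pair_b]
            self.n_params = 2 * self.m
        elif self.kind == "grm":
            self.simple = eff.extra_factors is None
            self.n_params = 1
        else:
            raise ValueError(f"unknown covariance kind {self.kind!r}")

    def _level_attr(self, data: pd.DataFrame, col: str):
        vals = data[col].astype(str).to_numpy()
        out = np.empty(self.q, dtype=object)
        out[self.codes] = vals  # constant within level by construction
        return out

    # -- parameterization ---------------------------------------------------

    def init_params(self, k_terms: int) -> np.ndarray:
        v0 = self.eff.init
        if v0 is None or v0 <= 0:
            v0 = max(self.var_y, 1e-6) / (k_terms + 1.0)
        if self.kind in ("identity", "grm"):
            return np.array([np.log(v0)])
        if self.kind == "diagonal":
            return np.full(self.n_params, np.log(v0))
        lam = np.full(self.m, np.sqrt(v0 / 2.0))
        return np.concatenate([lam, np.full(self.m, np.log(v0 / 2.0))])

    def bounds(self) -> list:
        if self.kind == "fa1":
            return ([(-np.inf, np.inf)] * self.m
                    + [(_LOG_FLOOR, _LOG_CEIL)] * self.m)
        return [(_LOG_FLOOR, _LOG_CEIL)] * self.n_params

    def K_matrix(self, th: np.ndarray):
        """Covariance over levels (sparse/dense) for V assembly."""
        if self.kind == "identity":
            return None  # handled via precomputed ZZt
        if self.kind == "diagonal":
            return sparse.diags(np.exp(th)[self.group_codes])
        if self.kind == "grm":
            return np.exp(th[0]) * self.K0
        lam, psi = th[:self.m], np.exp(th[self.m:])
        vals = lam[self.pair_ja] * lam[self.pair_jb]
        vals = vals + np.where(self.pair_ja == self.pair_jb,
                               psi[self.pair_ja], 0.0)
        return sparse.coo_matrix((vals, (self.pair_a, self.pair_b)),
                                 shape=(self.q, self.q)).tocsr()

    def add_to_V(self, V: np.ndarray, th: np.ndarray) -> None:
        if self.kind == "identity":
            s2 = np.exp(th[0])
            V[self.ZZt.row, self.ZZt.col] += s2 * self.ZZt.data
            return
        K = self.K_matrix(th)
        if self.kind == "grm":
            if self.simple:
                V += K[np.ix_(self.codes, self.codes)]
            else:
                A = np.asarray(self.Z @ K)          # (n, q) dense
                V += np.asarray(self.Z @ A.T).T     # Z K Z'
        else:
            S = (self.Z @ K @ self.Zt).tocoo()
            V[S.row, S.col] += S.data

    # -- gradient pieces ----------------------------------------------------

    def grad_and_quad(self, th: np.ndarray, P: np.ndarray, t: np.ndarray):
        """d(-2*loglik) pieces: tr(P dV) and t' dV t for each parameter."""
        v = self.Zt @ t                                  # (q,)
        tr = np.empty(self.n_params)
        qd = np.empty(self.n_params)
        if self.kind == "identity":
            s2 = np.exp(th[0])
            trM = float(np.sum(P[self.ZZt.row, self.ZZt.col] * self.ZZt.data))
            tr[0] = s2 * trM
            qd[0] = s2 * float(v @ v)
            return tr, qd
        if self.kind == "diagonal":
            s2 = np.exp(th)
            Mdiag = self._M_diag(P)
            trg = np.bincount(self.group_codes, weights=Mdiag,
                              minlength=self.n_params)
            qdg = np.bincount(self.group_codes, weights=v * v,
                              minlength=self.n_params)
            return s2 * trg, s2 * qdg
        if self.kind == "grm":
            s2 = np.exp(th[0])
            M = self._M_full(P)
            tr[0] = s2 * float(np.sum(M * self.K0))
            qd[0] = s2 * float(v @ self.K0 @ v)
            return tr, qd
        # fa1
        lam, psi = th[:self.m], np.exp(th[self.m:])
        Mp = self._M_pairs(P)
        vp = v[self.pair_a] * v[self.pair_b]
        ja, jb = self.pair_ja, self.pair_jb
        tr_lam = (np.bincount(ja, weights=Mp * lam[jb], minlength=self.m)
                  + np.bincount(jb, weights=Mp * lam[ja], minlength=self.m))
        qd_lam = (np.bincount(ja, weights=vp * lam[jb], minlength=self.m)
                  + np.bincount(jb, weights=vp * lam[ja], minlength=self.m))
        diag = ja == jb
        tr_psi = psi * np.bincount(ja[diag], weights=Mp[diag], minlength=self.m)
        qd_psi = psi * np.bincount(ja[diag], weights=vp[diag], minlength=self.m)
        return (np.concatenate([tr_lam, tr_psi]),
                np.concatenate([qd_lam, qd_psi]))

    def dV_t(self, th: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Columns ``(dV/dtheta_i) t`` for the average-information update."""
        v = self.Zt @ t
        if self.kind == "identity":
            return np.asarray(self.Z @ (np.exp(th[0]) * v))[:, None]
        if self.kind == "diagonal":
            s2 = np.exp(th)
            U = np.zeros((self.q, self.n_params))
            U[np.arange(self.q), self.group_codes] = s2[self.group_codes] * v
            return np.asarray(self.Z @ U)
        if self.kind == "grm":
            return np.asarray(self.Z @ (np.exp(th[0]) * (self.K0 @ v)))[:, None]
        lam, psi = th[:self.m], np.exp(th[self.m:])
        ja, jb = self.pair_ja, self.pair_jb
        vb = v[self.pair_b]
        U = np.zeros((self.q, self.n_params))
        np.add.at(U, (self.pair_a, ja), lam[jb] * vb)
        np.add.at(U, (self.pair_a, jb), lam[ja] * vb)
        U[np.arange(self.q), self.m + self.inner_codes] = \
            psi[self.inner_codes] * v
        return np.asarray(self.Z @ U)

    def _PZ(self, P: np.ndarray) -> np.ndarray:
        return (self.Zt @ P).T                            # (n, q)

    def _M_full(self, P: np.ndarray) -> np.ndarray:
        return np.asarray(self.Zt @ self._PZ(P))          # (q, q)

    def _M_diag(self, P: np.ndarray) -> np.ndarray:
        PZ = self._PZ(P)
        return np.asarray(self.Z.multiply(PZ).sum(axis=0)).ravel()

    def _M_pairs(self, P: np.ndarray) -> np.ndarray:
        PZ = self._PZ(P)
        M_rows = self.Zt @ PZ                             # (q, q) dense
        return np.asarray(M_rows)[self.pair_a, self.pair_b]

    # -- reporting ----------------------------------------------------------

    def varcomp(self, th: np.ndarray) -> dict:
        if self.kind == "identity":
            return {"sigma2": float(np.exp(th[0]))}
        if self.kind == "diagonal":
            return {"sigma2_by_group": pd.Series(np.exp(th),
                                                 index=self.group_labels)}
        if self.kind == "grm":
            return {"sigma2": float(np.exp(th[0]))}
        lam, psi = th[:self.m], np.exp(th[self.m:])
        Sig = np.outer(lam, lam) + np.diag(psi)
        return {"loadings": pd.Series(lam, index=self.inner_labels),
                "psi": pd.Series(psi, index=self.inner_labels),
                "Sigma": pd.DataFrame(Sig, index=self.inner_labels,
                                      columns=self.inner_labels)}

    def blup(self, th: np.ndarray, t: np.ndarray) -> pd.Series:
        """u_hat = K Z' P y  (t = Py)."""
        v = self.Zt @ t
        if self.kind == "identity":
            u = np.exp(th[0]) * v
        elif self.kind == "diagonal":
            u = np.exp(th)[self.group_codes] * v
        elif self.kind == "grm":
            u = np.exp(th[0]) * (self.K0 @ v)
        else:
            u = np.asarray(self.K_matrix(th) @ v).ravel()
        return pd.Series(u, index=self.levels, name=self.name)


class _Residual:
    """Residual covariance: scaled known weights or per-group variances."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, var_y: float):
        n = len(data)
        self.n = n
        self.var_y = var_y
        self.init_var = spec.residual_init
        if spec.residual_groups is not None:
            key = _level_key(data, spec.residual_groups)
            self.group_labels = pd.Index(sorted(key.unique()))
            self.group_codes = self.group_labels.get_indexer(key)
            self.w = np.ones(n)
            self.n_params = len(self.group_labels)
        else:
            self.group_labels = None
            self.group_codes = np.zeros(n, dtype=int)
            self.w = (data[spec.weights].to_numpy(float)
                      if spec.weights else np.ones(n))
            if np.any(self.w <= 0):
                raise ValueError("residual weights must be positive variances")
            self.n_params = 1

    def init_params(self, k_terms: int) -> np.ndarray:
        v0 = self.init_var
        if v0 is None or v0 <= 0:
            v0 = max(self.var_y, 1e-6) / (k_terms + 1.0)
        if self.group_labels is not None:
            return np.full(self.n_params, np.log(v0))
        return np.array([np.log(v0 / np.median(self.w))])

    def bounds(self):
        return [(_LOG_FLOOR, _LOG_CEIL)] * self.n_params

    def diag(self, th: np.ndarray) -> np.ndarray:
        return np.exp(th)[self.group_codes] * self.w

    def grad_and_quad(self, th: np.ndarray, P: np.ndarray, t: np.ndarray):
        d = self.diag(th)
        pd_ = np.diag(P) * d
        td = t * t * d
        tr = np.bincount(self.group_codes, weights=pd_, minlength=self.n_params)
        qd = np.bincount(self.group_codes, weights=td, minlength=self.n_params)
        return tr, qd

    def dV_t(self, th: np.ndarray, t: np.ndarray) -> np.ndarray:
        d = self.diag(th) * t
        if self.n_params == 1:
            return d[:, None]
        S = np.zeros((self.n, self.n_params))
        S[np.arange(self.n), self.group_codes] = d
        return S

    def varcomp(self, th: np.ndarray) -> dict:
        if self.group_labels is not None:
            return {"sigma2_by_group": pd.Series(np.exp(th),
                                                 index=self.group_labels)}
        return {"sigma2": float(np.exp(th[0]))}


# ---------------------------------------------------------------------------
# REML fit
# ---------------------------------------------------------------------------

def fit_reml(spec: ModelSpec, data: pd.DataFrame, maxiter: int = 200,
             tol: float = 1e-12, gtol: float = 1e-9,
             start: np.ndarray | None = None, method: str = "ai") -> FitResult:
    """Fit a mixed model by REML and return estimates, eBLUPs and diagnostics.

    ``method="ai"`` runs average-information Newton steps with step-halving
    (the restricted likelihood never decreases across accepted iterations);
    ``"lbfgs"`` uses gradient-based quasi-Newton and serves as the fallback
    when an AI step cannot be taken from the starting values.  ``start`` may
    carry packed parameters from a previous fit of the same spec on similar
    data (warm start).  Non-convergence is reported through
    ``converged``/``n_iter`` rather than by raising.
    """
    data = data.reset_index(drop=True)
    y = data[spec.response].to_numpy(float)
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    n = len(y)
    X, xnames = _build_fixed(data, spec)
    p = X.shape[1]
    var_y = float(np.var(y)) if n > 1 else 1.0
    terms = [_Term(r, data, var_y) for r in spec.random]
    resid = _Residual(spec, data, var_y)
    k = len(terms)

    blocks = terms + [resid]
    sizes = [b.n_params for b in blocks]
    offs = np.concatenate([[0], np.cumsum(sizes)]).astype(int)

    if start is not None and len(start) == offs[-1]:
        th0 = np.asarray(start, float)
    else:
        th0 = np.concatenate([b.init_params(k) for b in blocks])
    bounds = [bd for b in blocks for bd in b.bounds()]

    state = {"evals": 0}
    max_evals = 5 * maxiter + 20   # hard budget on objective evaluations

    def unpack(th):
        return [th[offs[i]:offs[i + 1]] for i in range(len(blocks))]

    def objective(th):
        state["evals"] += 1
        ths = unpack(th)
        V = np.zeros((n, n))
        for term, t_th in zip(terms, ths[:-1]):
            term.add_to_V(V, t_th)
        V[np.diag_indices(n)] += resid.diag(ths[-1])
        cfac, info = sla.lapack.dpotrf(V, lower=1, overwrite_a=False)
        if info != 0:
            return 1e10, np.zeros_like(th)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(cfac))))
        Vi, info = sla.lapack.dpotri(cfac, lower=1)
        if info != 0:
            return 1e10, np.zeros_like(th)
        Vi = np.tril(Vi) + np.tril(Vi, -1).T
        A = Vi @ X                                   # (n, p)
        XtViX = X.T @ A
        try:
            cx = sla.cho_factor(XtViX, lower=True, check_finite=False)
        except sla.LinAlgError:
            return 1e10, np.zeros_like(th)
        logdetX = 2.0 * float(np.sum(np.log(np.diag(cx[0]))))
        B = sla.cho_solve(cx, A.T, check_finite=False)   # (p, n)
        P = Vi - A @ B
        t = P @ y
        ytPy = float(y @ t)
        nll = 0.5 * (logdetV + logdetX + ytPy)
        grad = np.empty_like(th)
        for i, b in enumerate(blocks):
            tr, qd = b.grad_and_quad(ths[i], P, t)
            grad[offs[i]:offs[i + 1]] = 0.5 * (tr - qd)
        state["P"] = P
        state["Vi"] = Vi
        state["cx"] = cx
        state["t"] = t
        state["nll"] = nll
        state["th"] = th.copy()
        return nll, grad

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def ai_matrix(th):
        """Average information in the unconstrained parameterization."""
        ths = unpack(th)
        t = state["t"]
        S = np.hstack([b.dV_t(ths[i], t) for i, b in enumerate(blocks)])
        PS = state["P"] @ S
        return 0.5 * (S.T @ PS)

    th = th0.copy()
    converged = False
    n_iter = 0
    n_accepted = 0
    if method == "ai":
        nll, grad = objective(th)
        if nll >= 1e10:  # bad start: fall back immediately
            method = "lbfgs"
        else:
            for n_iter in range(1, maxiter + 1):
                AI = ai_matrix(th)
                ridge = 1e-8 * max(np.abs(np.diag(AI)).max(), 1.0)
                try:
                    step = np.linalg.solve(AI + ridge * np.eye(len(th)), -grad)
                except np.linalg.LinAlgError:
                    step = -grad
                improved = False
                for _ in range(8):   # step-halving keeps the likelihood monotone
                    th_new = np.clip(th + step, lo, hi)
                    nll_new, grad_new = objective(th_new)
                    if nll_new <= nll + 1e-12:
                        improved = True
                        break
                    step *= 0.5
                if not improved:
                    converged = float(np.max(np.abs(grad))) < 10 * gtol
                    objective(th)  # restore state at the accepted point
                    break
                n_accepted += 1
                delta = nll - nll_new
                th, nll, grad = th_new, nll_new, grad_new
                if delta < tol * max(abs(nll), 1.0) or np.max(np.abs(grad)) < gtol:
                    converged = True
                    break
                if state["evals"] > max_evals:
                    break
            if not converged and n_accepted == 0:
                # AI information is uninformative here (e.g. a degenerate
                # exact-fit dataset); let the quasi-Newton path take over
                method = "lbfgs"
    if method == "lbfgs":
        res = optimize.minimize(objective, th, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": maxiter, "ftol": tol,
                                         "gtol": gtol, "maxfun": max_evals})
        th = res.x
        converged = bool(res.success) or res.status == 0
        n_iter = int(res.nit)
    if not np.array_equal(state.get("th"), th):
        objective(th)
    ths = unpack(th)
    t = state["t"]
    Vi = state["Vi"]
    cx = state["cx"]
    XtViX_inv = sla.cho_solve(cx, np.eye(p), check_finite=False)
    beta = XtViX_inv @ (X.T @ (Vi @ y))
    se = np.sqrt(np.maximum(np.diag(XtViX_inv), 0.0))
    varcomp = {b.name if hasattr(b, "name") else "residual": b.varcomp(ths[i])
               for i, b in enumerate(blocks)}
    blups = {term.name: term.blup(ths[i], t) for i, term in enumerate(terms)}
    boundary = [name for name, lo in zip(_param_names(blocks), th)
                if lo <= _LOG_FLOOR + 1e-6]
    return FitResult(
        fixed_effects=pd.Series(beta, index=xnames),
        fixed_se=pd.Series(se, index=xnames),
        fixed_cov=pd.DataFrame(XtViX_inv, index=xnames, columns=xnames),
        varcomp=varcomp,
        blups=blups,
        loglik=-state["nll"],
        converged=converged,
        n_iter=n_iter,
        boundary=boundary,
        n_obs=n,
        packed=th.copy(),
    )


def _param_names(blocks) -> list:
    names = []
    for b in blocks:
        base = b.name if hasattr(b, "name") else "residual"
        names.extend([f"{base}[{i}]" for i in range(b.n_params)])
    return names
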