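"""REML engine for Gaussian linear mixed models with an optional GRM term.

Model
-----
y = X b + sum_r Z_r u_r + e,  u_r ~ N(0, s2_r K_r),  e ~ N(0, s2_e I),

with K_r the identity or a genomic relationship matrix (at most one GRM
term).  Estimation maximises the restricted log-likelihood

    l_R = -1/2 [ (n-p) log 2*pi + log|V| + log|X' V^-1 X| + y' P y ]

over the variance components, constrained positive, using L-BFGS-B on the
log scale with the analytic gradient.  All quantities are evaluated through
Henderson's mixed-model equations rather than the dense n x n covariance:
each GRM-structured effect is absorbed as u = L a with K = L L' (eigenvalue
square root, rank-truncated), so every transformed effect has identity
covariance and the coefficient matrix stays (p + q) x (p + q).  This also
handles exactly singular GRMs (a column-centred frequency GRM always has
null vector 1).

Prediction-error covariances of variety effects come from the inverse
coefficient matrix: var(u_hat_i - u_hat_j - (u_i - u_j)) =
C_ii + C_jj - 2 C_ij, mapped back through L for GRM terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from dusgp.data_io import TrialTable, ValidationError
from dusgp.relationship import GRMatrix

RESIDUAL = "residual"
_EIG_TRUNC = 1e-10  # relative eigenvalue cutoff for the GRM square root
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelSpec:
    """Declarative description of one mixed model.

    fixed_terms   column names in the prepared data frame; categorical
                  columns enter with treatment coding (first level as
                  reference), numeric columns as covariates.
    random_terms  (name, covariance) pairs, covariance in {'identity','grm'};
                  at most one 'grm' term, whose levels are the GRM labels.
    """

    response: str
    fixed_terms: list = field(default_factory=list)
    random_terms: list = field(default_factory=list)
    grm: Optional[GRMatrix] = None

    def __post_init__(self):
        self.random_terms = [tuple(t) for t in self.random_terms]
        n_grm = sum(1 for _, cov in self.random_terms if cov == "grm")
        if n_grm > 1:
            raise ValidationError("at most one GRM-structured random term")
        if n_grm == 1 and self.grm is None:
            raise ValidationError("grm term declared but no GRMatrix supplied")
        for _, cov in self.random_terms:
            if cov not in ("identity", "grm"):
                raise ValidationError(f"unknown covariance {cov!r}")


@dataclass
class _RandomTermDesign:
    name: str
    covariance: str
    levels: list          # levels of the original effect u
    q: int                # transformed dimension (columns of Zt)
    L: Optional[np.ndarray]  # K^(1/2) for grm terms, None for identity
    sl: slice             # slice of this term in the stacked a vector


@dataclass
class FittedLMM:
    """REML fit: variance components, BLUEs, BLUPs and PEV blocks."""

    sigma2: dict
    beta: pd.Series
    blups: dict
    loglik_reml: float
    converged: bool
    n_iter: int
    pinned: list
    spec: ModelSpec
    _pev: dict = field(repr=False, default_factory=dict)   # term -> (index map, matrix)
    meta: dict = field(default_factory=dict)
    # joint error covariance of (beta_hat - beta, a_hat - a) and the design
    # metadata needed to form arbitrary prediction contrasts
    _Cinv: np.ndarray | None = field(repr=False, default=None)
    _xnames: list = field(repr=False, default_factory=list)
    _terms: list = field(repr=False, default_factory=list)

    def pev(self, term: str, i, j) -> float:
        """Prediction-error covariance between effects i and j of a term."""
        idx, mat = self._pev[term]
        try:
            a, b = idx[str(i)], idx[str(j)]
        except KeyError as exc:
            raise ValidationError(f"unknown level {exc} in term {term!r}") from None
        return float(mat[a, b])

    def pev_matrix(self, term: str):
        idx, mat = self._pev[term]
        return idx, mat

    def pair_difference(self, term: str, i, j, covariate_diffs: dict | None = None):
        """Estimate and SE of the genetic difference between levels i and j.

        The difference is u_i - u_j plus, for every fixed covariate named in
        ``covariate_diffs`` (column name -> x_i - x_j), the fixed-effect
        contribution beta * (x_i - x_j); QTL covariates enter candidate
        predictions this way.  The SE comes from the joint prediction-error
        covariance of (beta_hat, u_hat) in the inverse coefficient matrix.
        """
        des = next((t for t in self._terms if t.name == term), None)
        if des is None:
            raise ValidationError(f"no random term {term!r} in fit")
        levidx = {lev: k for k, lev in enumerate(des.levels)}
        si, sj = str(i), str(j)
        for lab in (si, sj):
            if lab not in levidx:
                raise ValidationError(f"unknown level {lab!r} in term {term!r}")
        if si == sj and not covariate_diffs:
            return 0.0, 0.0
        p = len(self._xnames)
        lam = np.zeros(self._Cinv.shape[0])
        est = 0.0
        for name, dx in (covariate_diffs or {}).items():
            if name not in self._xnames:
                raise ValidationError(f"fixed covariate {name!r} not in fit")
            k = self._xnames.index(name)
            lam[k] = dx
            est += float(self.beta.iloc[k]) * dx
        row = np.zeros(des.q)
        if des.L is not None:
            row = des.L[levidx[si]] - des.L[levidx[sj]]
        else:
            row[levidx[si]] += 1.0
            row[levidx[sj]] -= 1.0
        lam[p + des.sl.start: p + des.sl.stop] = row
        u = self.blups[term]
        est += float(u[si] - u[sj])
        sed = float(np.sqrt(max(lam @ self._Cinv @ lam, 0.0)))
        return est, sed


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _is_numeric(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s)


def _fixed_design(df: pd.DataFrame, fixed_terms: Sequence[str]):
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    for term in fixed_terms:
        if term not in df.columns:
            raise ValidationError(f"fixed term {term!r} not in data")
        s = df[term]
        if _is_numeric(s):
            cols.append(s.to_numpy(dtype=float))
            names.append(term)
        else:
            levels = sorted(s.astype(str).unique())
            for lev in levels[1:]:  # treatment coding, first level reference
                cols.append((s.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
    X = np.column_stack(cols)
    # drop aliased columns deterministically in column order
    keep, dropped = [], []
    Q = np.zeros((X.shape[0], 0))
    for k in range(X.shape[1]):
        v = X[:, k]
        r = v - Q @ (Q.T @ v)
        if np.linalg.norm(r) > 1e-8 * max(np.linalg.norm(v), 1.0):
            Q = np.column_stack([Q, r / np.linalg.norm(r)])
            keep.append(k)
        else:
            dropped.append(names[k])
    return X[:, keep], [names[k] for k in keep], dropped


def _grm_sqrt(grm: GRMatrix):
    w, U = np.linalg.eigh(grm.values)
    cut = _EIG_TRUNC * max(w.max(), 1.0)
    sel = w > cut
    if not sel.any():
        raise ValidationError("GRM has no positive eigenvalues")
    return U[:, sel] * np.sqrt(w[sel])


def _random_design(df: pd.DataFrame, spec: ModelSpec):
    Zts, terms = [], []
    offset = 0
    for name, cov in spec.random_terms:
        if name not in df.columns:
            raise ValidationError(f"random term {name!r} not in data")
        s = df[name].astype(str)
        if cov == "grm":
            levels = [str(l) for l in spec.grm.labels]
            index = {l: k for k, l in enumerate(levels)}
            unknown = set(s.unique()) - set(levels)
            if unknown:
                raise ValidationError(f"varieties absent from GRM: {sorted(unknown)[:5]}")
            Z = np.zeros((len(df), len(levels)))
            Z[np.arange(len(df)), [index[v] for v in s]] = 1.0
            L = _grm_sqrt(spec.grm)
            Zt = Z @ L
            q = L.shape[1]
        else:
            levels = sorted(s.unique())
            index = {l: k for k, l in enumerate(levels)}
            Zt = np.zeros((len(df), len(levels)))
            Zt[np.arange(len(df)), [index[v] for v in s]] = 1.0
            L = None
            q = len(levels)
        terms.append(_RandomTermDesign(name, cov, levels, q, L,
                                       slice(offset, offset + q)))
        Zts.append(Zt)
        offset += q
    Z = np.hstack(Zts) if Zts else np.zeros((len(df), 0))
    return Z, terms


def build_design(data, spec: ModelSpec):
    """Build (y, X, fixed names, Z, random-term designs) for a model."""
    df = data.df if isinstance(data, TrialTable) else data
    if "characteristic" in df.columns and spec.response in set(df["characteristic"]):
        df = df[df["characteristic"] == spec.response]
    if "value" in df.columns:
        y = df["value"].to_numpy(dtype=float)
    elif spec.response in df.columns:
        y = df[spec.response].to_numpy(dtype=float)
    else:
        raise ValidationError(f"response {spec.response!r} not found")
    df = df.reset_index(drop=True)
    X, xnames, dropped = _fixed_design(df, spec.fixed_terms)
    Z, terms = _random_design(df, spec)
    return y, X, xnames, dropped, Z, terms


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

class _REMLProblem:
    def __init__(self, y, X, Z, terms):
        self.y, self.X, self.Z, self.terms = y, X, Z, terms
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.R = len(terms)
        W = np.hstack([X, Z])
        self.W = W
        self.WtW = W.T @ W
        self.Wty = W.T @ y
        self.yty = float(y @ y)
        if self.n - self.p < 1:
            raise ValidationError("no residual degrees of freedom")

    def _assemble(self, sig):
        se = sig[-1]
        C = self.WtW / se
        d = np.empty(self.q)
        for t, s in zip(self.terms, sig[:-1]):
            d[t.sl] = 1.0 / s
        C[self.p:, self.p:] += np.diag(d) if self.q else 0.0
        rhs = self.Wty / se
        return C, rhs

    def nll_grad(self, x):
        sig = np.exp(x)
        se = sig[-1]
        C, rhs = self._assemble(sig)
        try:
            cf = linalg.cho_factor(C, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return 1e30, np.zeros_like(x)
        sol = linalg.cho_solve(cf, rhs, check_finite=False)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        yPy = max((self.yty - float(rhs @ sol) * se) / se, 1e-300)
        m2ll = ((self.n - self.p) * _LOG2PI + self.n * np.log(se)
                + sum(t.q * np.log(s) for t, s in zip(self.terms, sig[:-1]))
                + logdetC + yPy)
        # gradient via MME identities
        Cinv = linalg.cho_solve(cf, np.eye(C.shape[0]), check_finite=False)
        e = self.y - self.W @ sol
        Py = e / se
        grad = np.empty(self.R + 1)
        sum_tr = 0.0
        for r, (t, s) in enumerate(zip(self.terms, sig[:-1])):
            a_r = sol[self.p + t.sl.start: self.p + t.sl.stop]
            tr_r = float(np.trace(Cinv[self.p + t.sl.start: self.p + t.sl.stop,
                                       self.p + t.sl.start: self.p + t.sl.stop]))
            trPZZ = (t.q - tr_r / s) / s
            sum_tr += s * trPZZ
            dl = -0.5 * (trPZZ - float(a_r @ a_r) / s ** 2)
            grad[r] = dl
        trP = (self.n - self.p - sum_tr) / se
        grad[self.R] = -0.5 * (trP - float(Py @ Py))
        # d(-l)/d log sigma2 = -dl/dsigma2 * sigma2
        return 0.5 * m2ll, -grad * sig

    def nll(self, x):
        return self.nll_grad(x)[0]

    def solve(self, sig):
        """MME solution and inverse coefficient matrix at given components."""
        C, rhs = self._assemble(sig)
        nc = C.shape[0]
        jitter = 0.0
        for _ in range(3):
            try:
                cf = linalg.cho_factor(C + jitter * np.eye(nc), lower=True,
                                       check_finite=False)
                break
            except linalg.LinAlgError:
                jitter = max(jitter * 10, 1e-10 * np.trace(C) / nc)
        sol = linalg.cho_solve(cf, rhs, check_finite=False)
        Cinv = linalg.cho_solve(cf, np.eye(nc), check_finite=False)
        return sol, Cinv


def fit_reml(spec: ModelSpec, data, *, fixed_sigma2: Optional[dict] = None,
             max_iter: int = 200) -> FittedLMM:
    """Fit a linear mixed model by REML.

    Parameters
    ----------
    spec : ModelSpec
    data : TrialTable or prepared DataFrame with a ``value`` column
    fixed_sigma2 : dict, optional
        Known variance components (term name -> value, incl. ``'residual'``);
        skips estimation and solves the mixed-model equations directly.
    """
    y, X, xnames, dropped, Z, terms = build_design(data, spec)
    prob = _REMLProblem(y, X, Z, terms)
    term_names = [t.name for t in terms] + [RESIDUAL]
    vary = float(np.var(y, ddof=1)) if len(y) > 1 else 1.0
    if not np.isfinite(vary) or vary <= 0:
        vary = 1.0

    if fixed_sigma2 is not None:
        missing = [t for t in term_names if t not in fixed_sigma2]
        if missing:
            raise ValidationError(f"fixed_sigma2 missing components {missing}")
        sig = np.array([float(fixed_sigma2[t]) for t in term_names])
        if np.any(sig <= 0):
            raise ValidationError("fixed variance components must be > 0")
        nll = prob.nll(np.log(sig))
        loglik = -nll
        converged, n_iter, pinned = True, 0, []
    else:
        lo, hi = np.log(vary * 1e-8), np.log(vary * 1e6)
        x0 = np.full(prob.R + 1, np.log(vary / (prob.R + 1)))
        res = optimize.minimize(
            prob.nll_grad, x0, jac=True, method="L-BFGS-B",
            bounds=[(lo, hi)] * (prob.R + 1),
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
        )
        if not res.success:
            # derivative-free polish from the best point found so far
            res2 = optimize.minimize(prob.nll, res.x, method="Nelder-Mead",
                                     options={"maxiter": 2000, "xatol": 1e-10,
                                              "fatol": 1e-12})
            if res2.fun <= res.fun:
                res2.x = np.clip(res2.x, lo, hi)
                res = res2
        sig = np.exp(np.clip(res.x, lo, hi))
        loglik = -float(res.fun)
        n_iter = int(getattr(res, "nit", 0))
        pinned = [t for t, v in zip(term_names, np.clip(res.x, lo, hi))
                  if v <= lo + 1e-9]
        gnorm = float(np.linalg.norm(prob.nll_grad(np.log(sig))[1]))
        converged = bool(res.success or gnorm < 1e-4)

    sol, Cinv = prob.solve(sig)
    beta = pd.Series(sol[:prob.p], index=xnames, name="beta")
    blups, pev = {}, {}
    for t in terms:
        a_r = sol[prob.p + t.sl.start: prob.p + t.sl.stop]
        block = Cinv[prob.p + t.sl.start: prob.p + t.sl.stop,
                     prob.p + t.sl.start: prob.p + t.sl.stop]
        if t.covariance == "grm":
            u = t.L @ a_r
            P = t.L @ block @ t.L.T
        else:
            u = a_r
            P = block
        blups[t.name] = pd.Series(u, index=t.levels, name=t.name)
        pev[t.name] = ({lev: k for k, lev in enumerate(t.levels)}, P)

    sigma2 = {name: float(s) for name, s in zip(term_names, sig)}
    return FittedLMM(
        sigma2=sigma2, beta=beta, blups=blups, loglik_reml=float(loglik),
        converged=converged, n_iter=n_iter, pinned=pinned, spec=spec,
        _pev=pev,
        meta={"n": prob.n, "p": prob.p, "dropped_fixed": dropped,
              "term_names": term_names},
        _Cinv=Cinv, _xnames=list(xnames), _terms=list(terms),
    )


# ---------------------------------------------------------------------------
# inference on variety effects
# ---------------------------------------------------------------------------

def contrast(fit: FittedLMM, term: str, i, j):
    """Estimate and standard error of the effect difference u_i - u_j."""
    return fit.pair_difference(term, i, j)


def normal_test(estimate: float, sed: float, alpha: float = 0.01):
    """Two-sided normal (z) test of a contrast.

    Returns (z, p, distinct) with distinct <=> p <= alpha.  The normal
    approximation to the t test is used throughout: contrast degrees of
    freedom in these layouts are well above 100.
    """
    if sed <= 0:
        raise ValidationError("normal_test requires sed > 0")
    z = abs(float(estimate)) / float(sed)
    p = 2.0 * float(stats.norm.sf(z))
    # the boundary counts as distinct; compare on the z scale so that a
    # difference exactly equal to the LSD is not lost to rounding of p
    zc = float(stats.norm.ppf(1.0 - alpha / 2.0))
    return z, p, bool(z >= zc * (1.0 - 1e-12))
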