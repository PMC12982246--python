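"""Single-marker mixed-model association scan with GRM background.

Variance components are estimated once under the null (no-marker) model and
held fixed across markers; each marker is then tested by a Wald z test of
its fixed effect under generalized least squares with the null-model
covariance.  This is the usual two-stage approximation for genome-wide
scans; its exactness at fixed components is checked against a dense GLS
oracle in the test suite.

Thresholds: Bonferroni at an overall level of 0.05 across tested markers,
and Benjamini-Hochberg FDR.  Forward selection adds the most significant
passing marker as a fixed covariate, rescans, and caps selection at one
marker per chromosome.  A relaxation factor on the Bonferroni limit is
exposed for expert use (sub-threshold candidates); the default is strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from dusgp.data_io import GenotypeTable, TrialTable, ValidationError
from dusgp.gblup import LayoutSpec, make_spec, prepare_data
from dusgp.mixedmodel import RESIDUAL, build_design, fit_reml
from dusgp.relationship import GRMatrix, build_grm

GWAS_ALPHA = 0.05  # family-wise level for the Bonferroni limit


@dataclass
class GwasResult:
    table: pd.DataFrame          # marker, chrom, pos, effect, se, z, p, p_bh, tested
    bonferroni_p: float
    fdr_q: float
    n_tested: int
    selected_qtls: list = field(default_factory=list)  # [(marker, round)]
    sigma2: dict = field(default_factory=dict)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _observation_covariance(y, X, Z, terms, sigma2):
    n = len(y)
    V = sigma2[RESIDUAL] * np.eye(n)
    for t in terms:
        Zt = Z[:, t.sl]
        V += sigma2[t.name] * (Zt @ Zt.T)
    return V


def scan(geno: GenotypeTable, trials: TrialTable, layout: LayoutSpec,
         characteristic, grm: GRMatrix | None = None,
         sigma2: dict | None = None, fdr_q: float = 0.05) -> GwasResult:
    """Mixed-model single-marker scan for one characteristic.

    Any QTL markers already in ``layout`` enter the null model as fixed
    covariates (used by forward selection).  ``sigma2`` fixes the variance
    components instead of estimating them under the null.
    """
    grm = grm or build_grm(geno)
    df = prepare_data(trials, geno, layout, characteristic)
    spec = make_spec(layout, characteristic, grm)
    fit = fit_reml(spec, df, fixed_sigma2=sigma2)
    y, X0, xnames, _, Z, terms = build_design(df, spec)
    V = _observation_covariance(y, X0, Z, terms, fit.sigma2)
    cf = linalg.cho_factor(V, lower=True, check_finite=False)

    # variety incidence for expanding per-variety covariates to observations
    vars_in = sorted(df["variety"].unique())
    vidx = {v: k for k, v in enumerate(vars_in)}
    Zv = np.zeros((len(df), len(vars_in)))
    Zv[np.arange(len(df)), [vidx[v] for v in df["variety"]]] = 1.0

    ViZv = linalg.cho_solve(cf, Zv, check_finite=False)
    ViX0 = linalg.cho_solve(cf, X0, check_finite=False)
    Viy = linalg.cho_solve(cf, y, check_finite=False)
    S = Zv.T @ ViZv                      # (q, q)
    U = Zv.T @ ViX0                      # (q, p)
    t_vec = Zv.T @ Viy                   # (q,)
    M0inv = np.linalg.inv(X0.T @ ViX0)
    b0 = X0.T @ Viy

    # per-variety centred frequencies for every marker, over included varieties
    rows = [geno.index_of(v) for v in vars_in]
    F = geno.freq[rows, :]
    col_mean = np.nanmean(np.where(np.isfinite(F), F, np.nan), axis=0)
    W = np.where(np.isfinite(F), F, col_mean) - col_mean
    var_w = W.var(axis=0, ddof=1) if len(vars_in) > 1 else np.zeros(F.shape[1])
    already = {f"M:{m}" for m in layout.qtl_markers}
    tested = (var_w > 0) & ~np.isin(geno.marker_ids, list(layout.qtl_markers))

    xVx = np.einsum("qm,qm->m", W, S @ W)
    A = W.T @ U                          # (M, p)
    xVy = W.T @ t_vec
    s_xx = xVx - np.einsum("mp,pq,mq->m", A, M0inv, A)
    s_xy = xVy - A @ (M0inv @ b0)
    with np.errstate(invalid="ignore", divide="ignore"):
        effect = np.where(tested, s_xy / s_xx, np.nan)
        se = np.where(tested & (s_xx > 0), np.sqrt(1.0 / np.maximum(s_xx, 1e-300)),
                      np.nan)
        z = np.abs(effect) / se
    p = np.where(np.isfinite(z), 2.0 * stats.norm.sf(np.where(np.isfinite(z), z, 0.0)),
                 np.nan)
    n_tested = int(tested.sum())
    if n_tested == 0:
        import warnings
        warnings.warn("no polymorphic markers to test")
    p_bh = np.full(p.shape, np.nan)
    if n_tested:
        p_bh[tested] = fdr_adjust(p[tested])
    table = pd.DataFrame({
        "marker": geno.marker_ids,
        "chrom": geno.markers["chrom"].astype(str),
        "pos": geno.markers["pos"].astype(int),
        "effect": effect, "se": se, "z": z, "p": p, "p_bh": p_bh,
        "tested": tested,
    })
    bonf = GWAS_ALPHA / n_tested if n_tested else np.nan
    return GwasResult(table=table, bonferroni_p=bonf, fdr_q=fdr_q,
                      n_tested=n_tested, sigma2=dict(fit.sigma2))


def forward_select(geno: GenotypeTable, trials: TrialTable, layout: LayoutSpec,
                   characteristic, threshold_rule: str = "bonferroni",
                   relax: float = 1.0, fdr_q: float = 0.05,
                   grm: GRMatrix | None = None, max_rounds: int = 10) -> GwasResult:
    """Forward selection of QTL markers, one per chromosome.

    Each round rescans all remaining markers conditional on the markers
    already selected (which enter as fixed covariates, with variance
    components re-estimated), picks the most significant marker passing the
    threshold on a chromosome not yet represented, and stops when none pass.
    """
    if threshold_rule not in ("bonferroni", "fdr"):
        raise ValidationError("threshold_rule must be 'bonferroni' or 'fdr'")
    grm = grm or build_grm(geno)
    selected: list = []
    current = LayoutSpec(layout.layout, list(layout.qtl_markers))
    result = None
    for rnd in range(1, max_rounds + 1):
        result = scan(geno, trials, current, characteristic, grm=grm, fdr_q=fdr_q)
        tab = result.table
        taken_chrom = {tab.loc[tab["marker"] == m, "chrom"].iloc[0]
                       for m, _ in selected if (tab["marker"] == m).any()}
        ok = tab["tested"] & ~tab["chrom"].isin(taken_chrom)
        if threshold_rule == "bonferroni":
            ok &= tab["p"] <= result.bonferroni_p * relax
        else:
            ok &= tab["p_bh"] <= fdr_q
        if not ok.any():
            break
        best = tab.loc[ok, "p"].idxmin()
        marker = tab.loc[best, "marker"]
        selected.append((marker, rnd))
        current = LayoutSpec(layout.layout, current.qtl_markers + [marker])
    result.selected_qtls = list(selected)
    return result
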