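"""COYD and COYD-GP distinctness tests, and the wheat two-note rule.

Long-term COYD fits the over-years mixed model with variety as a simple
(identity-covariance) random effect: fixed ploidy, random variety, year and
year-by-ploidy; the residual is the variety-by-year interaction.  Each
within-ploidy pair of variety effects is compared to a least significant
difference referenced to k trial years,

    LSD = z_{1-alpha/2} * sqrt(2 * s2_eps / k),

with k = 3 by convention (configurable).  Year and year-by-ploidy effects
cancel in within-group over-years differences, so only the residual
component enters the LSD.  A pair is distinct when |difference| >= LSD,
equivalently when the reported normal p-value is <= alpha; the boundary
counts as distinct.

COYD-GP is the same model and the same decision rule with the variety
random effect carrying GRM-structured covariance: the genomic information
sharpens the estimated variety effects, which is the only change.  With an
identity GRM, COYD-GP reduces to COYD exactly.

An alternative rule comparing each difference to its own prediction-error
standard error (sed) instead of the LSD is exposed via ``rule='sed'``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from dusgp.data_io import GenotypeTable, RunConfig, TrialTable, ValidationError
from dusgp.gblup import ENV_GROUP
from dusgp.mixedmodel import RESIDUAL, ModelSpec, contrast, fit_reml
from dusgp.relationship import GRMatrix, build_grm


@dataclass
class DistinctnessMatrix:
    """Pairwise per-characteristic distinctness decisions and p-values."""

    characteristic: str
    labels: list
    p: np.ndarray
    decision: np.ndarray
    method: str  # 'coyd' | 'coyd_gp' | 'gblup_cv' | 'actual_notes' | collated
    threshold: float
    estimate: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.labels)
        self.p = np.asarray(self.p, dtype=float)
        self.decision = np.asarray(self.decision, dtype=bool)
        if self.p.shape != (n, n) or self.decision.shape != (n, n):
            raise ValidationError("matrix shapes must match labels")
        if np.any(np.diag(self.decision)):
            raise ValidationError("diagonal decisions must be False")
        if not np.array_equal(self.decision, self.decision.T):
            raise ValidationError("decisions must be symmetric")

    @property
    def n_distinct_pairs(self) -> int:
        return int(np.triu(self.decision, k=1).sum())

    def distinct_proportion(self, groups: dict | None = None) -> float:
        """Fraction of comparable (finite-p or decided) pairs found distinct."""
        mask = np.triu(np.isfinite(self.p) | self.decision, k=1)
        total = int(mask.sum())
        return float(np.triu(self.decision, 1).sum() / total) if total else 0.0

    def to_long(self) -> pd.DataFrame:
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                est = self.estimate[i, j] if self.estimate is not None else np.nan
                rows.append((self.characteristic, self.labels[i], self.labels[j],
                             est, self.p[i, j], bool(self.decision[i, j]),
                             self.method))
        return pd.DataFrame(rows, columns=["characteristic", "variety_i",
                                           "variety_j", "estimate", "p",
                                           "distinct", "method"])


def lsd_threshold(sigma2_resid: float, k: int, alpha: float) -> float:
    """Least significant difference from the residual component and k years."""
    return float(stats.norm.ppf(1 - alpha / 2) * np.sqrt(2 * sigma2_resid / k))


def _coyd_engine(trials: TrialTable, characteristic, config: RunConfig,
                 grm: GRMatrix | None, method: str, rule: str = "lsd"):
    df = trials.for_characteristic(characteristic).copy()
    if df["environment"].nunique() < 2:
        raise ValidationError("COYD needs at least 2 years of data")
    df[ENV_GROUP] = df["environment"] + ":" + df["group"]
    cov = "grm" if grm is not None else "identity"
    spec = ModelSpec(
        response=str(characteristic),
        fixed_terms=["group"],
        random_terms=[("variety", cov), ("environment", "identity"),
                      (ENV_GROUP, "identity")],
        grm=grm,
    )
    fit = fit_reml(spec, df)
    present = sorted(df["variety"].unique())
    labels = present
    group_of = dict(zip(df["variety"], df["group"]))
    n = len(labels)
    idx = {v: i for i, v in enumerate(labels)}
    P = np.full((n, n), np.nan)
    D = np.zeros((n, n), dtype=bool)
    E = np.full((n, n), np.nan)
    sed0 = np.sqrt(2 * fit.sigma2[RESIDUAL] / config.lsd_years)
    zc = float(stats.norm.ppf(1.0 - config.alpha / 2.0))
    u = fit.blups["variety"]
    for a, b in itertools.combinations(present, 2):
        if group_of[a] != group_of[b]:
            continue
        est, sed = contrast(fit, "variety", a, b)
        s = sed if rule == "sed" else sed0
        if s <= 0:
            z, p = 0.0, 1.0
        else:
            z = abs(est) / s
            p = 2 * float(stats.norm.sf(z))
        i, j = idx[a], idx[b]
        E[i, j], E[j, i] = est, -est
        P[i, j] = P[j, i] = p
        # |difference| >= LSD, boundary inclusive (compared on the z scale)
        D[i, j] = D[j, i] = z >= zc * (1.0 - 1e-12)
    mat = DistinctnessMatrix(str(characteristic), labels, P, D, method,
                             threshold=config.alpha, estimate=E)
    mat.fit = fit
    return mat


def coyd(trials: TrialTable, characteristic, config: RunConfig,
         rule: str = "lsd") -> DistinctnessMatrix:
    """Long-term COYD: identity-covariance variety effects vs the LSD."""
    return _coyd_engine(trials, characteristic, config, None, "coyd", rule)


def coyd_gp(trials: TrialTable, geno: GenotypeTable | None, characteristic,
            config: RunConfig, grm: GRMatrix | None = None,
            rule: str = "lsd") -> DistinctnessMatrix:
    """Long-term COYD-GP: GRM-structured variety effects vs the same LSD."""
    if grm is None:
        if geno is None:
            raise ValidationError("coyd_gp needs a GenotypeTable or GRMatrix")
        grm = build_grm(geno)
    missing = sorted(set(trials.for_characteristic(characteristic)["variety"])
                     - set(map(str, grm.labels)))
    if missing:
        raise ValidationError(f"varieties missing from GRM: {missing[:5]}")
    return _coyd_engine(trials, characteristic, config, grm, "coyd_gp", rule)


def actual_note_decision(trials: TrialTable, characteristic,
                         config: RunConfig) -> DistinctnessMatrix:
    """Wheat rule: distinct iff notes differ by >= the threshold in a shared country."""
    if trials.layout != "wheat":
        raise ValidationError("actual_note_decision requires the wheat layout")
    df = trials.for_characteristic(characteristic)
    notes = df.pivot(index="variety", columns="environment", values="value")
    labels = notes.index.tolist()
    X = notes.to_numpy()
    n = len(labels)
    D = np.zeros((n, n), dtype=bool)
    P = np.full((n, n), np.nan)
    for i in range(n):
        shared = np.isfinite(X[i]) & np.isfinite(X)
        gap = np.where(shared, np.abs(X - X[i]), -np.inf)
        maxgap = gap.max(axis=1)
        comparable = shared.any(axis=1)
        D[i] = comparable & (maxgap >= config.note_threshold)
        P[i, comparable] = 0.0  # marker of comparability; notes carry no p-value
    np.fill_diagonal(D, False)
    np.fill_diagonal(P, np.nan)
    D = D | D.T
    return DistinctnessMatrix(str(characteristic), labels, P, D,
                              "actual_notes", threshold=config.note_threshold)


def collate(per_characteristic) -> DistinctnessMatrix:
    """Overall distinctness: OR of decisions, minimum of p-values.

    A pair distinct in any single characteristic is distinct overall.
    """
    mats = list(per_characteristic)
    if not mats:
        raise ValidationError("nothing to collate")
    labels = list(map(str, mats[0].labels))
    for m in mats[1:]:
        if list(map(str, m.labels)) != labels:
            raise ValidationError("collate: label mismatch between matrices")
    D = np.zeros((len(labels), len(labels)), dtype=bool)
    P = np.full((len(labels), len(labels), len(mats)), np.nan)
    for k, m in enumerate(mats):
        D |= m.decision
        P[:, :, k] = m.p
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        Pmin = np.nanmin(P, axis=2)
    return DistinctnessMatrix("collated", labels, Pmin, D,
                              method=mats[0].method, threshold=mats[0].threshold)
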