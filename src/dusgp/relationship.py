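"""Genomic relationships and distances from per-variety allele frequencies.

The genomic relationship matrix (GRM) follows the VanRaden construction
adapted to pooled allele frequencies: columns of the frequency matrix are
centred on their across-variety means and the cross-product is scaled by the
*empirical* sampling variance summed over markers,

    G = W W' / c,    W = F - colmean(F),    c = sum_m s2_m,

with s2_m the sample variance (divisor n-1) of the frequencies at marker m.
The empirical scaling replaces the parametric sum 2 p (1-p) and needs no
ploidy-specific constant, which is what makes mixed diploid/tetraploid
panels workable.  Under exchangeable varieties the mean diagonal of G is
close to 1 by construction.

Rogers' distance between two varieties reduces, for biallelic frequencies,
to the mean absolute frequency difference over shared markers.  Phenotypic
distance is the Euclidean distance over characteristic means scaled by their
across-variety standard deviations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from dusgp.data_io import GenotypeTable, TrialTable, ValidationError

logger = logging.getLogger(__name__)

MISSING_RATE_MAX = 0.10  # markers missing in more than 10% of varieties are dropped


@dataclass
class GRMatrix:
    """Symmetric additive relationship matrix between varieties."""

    labels: list
    values: np.ndarray
    scaling_constant: float
    ridge_applied: float = 0.0
    excluded_markers: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("GRM shape must match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"variety {label!r} absent from GRM") from None

    @classmethod
    def identity(cls, labels) -> "GRMatrix":
        return cls(list(labels), np.eye(len(labels)), scaling_constant=float("nan"))


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray
    kind: str  # 'rogers' | 'phenotypic'

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape must match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValidationError("distances must be non-negative")


def build_grm(geno: GenotypeTable) -> GRMatrix:
    """Compute the GRM with empirical sampling-variance scaling.

    Markers with a missing rate above 10% or with zero variance are excluded
    (and logged).  Missing frequencies are imputed to the marker mean, i.e.
    centred value 0 — no information.  If the result has a smallest
    eigenvalue below -1e-8 a minimal diagonal ridge is added and recorded.
    """
    if geno.n_varieties < 2:
        raise ValidationError("GRM needs at least 2 varieties")
    F = geno.freq
    n = F.shape[0]
    miss_rate = np.mean(~np.isfinite(F), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        var = np.nanvar(F, axis=0, ddof=1)
    var = np.where(np.isfinite(var), var, 0.0)
    keep = (miss_rate <= MISSING_RATE_MAX) & (var > 1e-12)
    excluded = [m for m, k in zip(geno.marker_ids, keep) if not k]
    if excluded:
        logger.info("build_grm: excluded %d markers (missing>%.0f%% or monomorphic)",
                    len(excluded), 100 * MISSING_RATE_MAX)
    if not keep.any():
        raise ValidationError("no informative markers")
    Fk = F[:, keep]
    col_mean = np.nanmean(Fk, axis=0)
    W = Fk - col_mean
    W[~np.isfinite(W)] = 0.0
    c = float(var[keep].sum())
    G = (W @ W.T) / c
    G = (G + G.T) / 2.0
    ridge = 0.0
    lam_min = float(np.linalg.eigvalsh(G)[0])
    if lam_min < -1e-8:
        ridge = abs(lam_min) + 1e-6
        G = G + ridge * np.eye(n)
    return GRMatrix(list(geno.varieties), G, scaling_constant=c,
                    ridge_applied=ridge, excluded_markers=excluded)


def rogers_distance(geno: GenotypeTable) -> DistanceMatrix:
    """Rogers' distance: mean absolute frequency difference over shared markers."""
    F = geno.freq
    n = F.shape[0]
    D = np.zeros((n, n))
    finite = np.isfinite(F)
    for i in range(n):
        shared = finite[i] & finite  # (n, m)
        L = shared.sum(axis=1)
        diff = np.abs(np.where(shared, F - F[i], 0.0))
        no_shared = np.flatnonzero(L == 0)
        no_shared = no_shared[no_shared != i]
        if no_shared.size:
            j = int(no_shared[0])
            raise ValidationError(
                f"varieties {geno.varieties[i]!r} and {geno.varieties[j]!r} "
                "share no genotyped markers"
            )
        with np.errstate(invalid="ignore"):
            D[i] = diff.sum(axis=1) / np.maximum(L, 1)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return DistanceMatrix(list(geno.varieties), D, kind="rogers")


def phenotypic_distance(trials: TrialTable, characteristics=None) -> DistanceMatrix:
    """Scaled Euclidean distance over per-variety characteristic means.

    Each characteristic's variety means are divided by their standard
    deviation across varieties (divisor n-1); zero-variance characteristics
    are excluded with a warning.  Pairs are compared over the
    characteristics observed in both.
    """
    df = trials.df
    if characteristics is not None:
        df = df[df["characteristic"].isin([str(c) for c in characteristics])]
    means = df.groupby(["variety", "characteristic"])["value"].mean().unstack()
    sd = means.std(axis=0, ddof=1)
    zero = sd.index[~(sd > 0)].tolist()
    if zero:
        warnings.warn(f"characteristics with zero variance excluded: {zero}")
        means = means.drop(columns=zero)
    if means.shape[1] == 0:
        raise ValidationError("no characteristics with variance to compare")
    X = (means / means.std(axis=0, ddof=1)).to_numpy()
    labels = means.index.tolist()
    n = len(labels)
    D = np.zeros((n, n))
    finite = np.isfinite(X)
    for i in range(n):
        shared = finite[i] & finite
        if np.any((shared.sum(axis=1) == 0) & (np.arange(n) != i)):
            j = int(np.flatnonzero((shared.sum(axis=1) == 0) & (np.arange(n) != i))[0])
            raise ValidationError(
                f"varieties {labels[i]!r} and {labels[j]!r} share no characteristics"
            )
        d2 = np.where(shared, (X - X[i]) ** 2, 0.0).sum(axis=1)
        D[i] = np.sqrt(d2)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return DistanceMatrix(labels, D, kind="phenotypic")


def distance_correlation(a: DistanceMatrix, b: DistanceMatrix) -> float:
    """Pearson correlation of the strict upper triangles of two distance matrices."""
    if list(map(str, a.labels)) != list(map(str, b.labels)):
        raise ValidationError("distance matrices have mismatched labels")
    iu = np.triu_indices(len(a.labels), k=1)
    r, _ = stats.pearsonr(a.values[iu], b.values[iu])
    return float(r)
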