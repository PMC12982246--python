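"""Model layouts for gBLUP / gBLUP+QTL and candidate-vs-known prediction.

Two layouts are supported:

ryegrass : fixed ploidy effect (+ optional QTL frequency covariates);
           random variety (GRM), year, year-by-ploidy; residual is the
           variety-by-year interaction.  Comparisons are made within
           ploidy groups.
wheat    : intercept (+ optional QTL covariates); random variety (GRM) and
           country; with a single record per variety-country the
           variety-by-country interaction is inseparable from the residual
           and is absorbed there.  Comparisons are made within countries.

QTL covariates enter as centred allele frequencies of the selected markers.
A candidate is a variety with genotype data whose phenotype records are
masked; because the GRM carries its covariances with the knowns, its BLUP
(and hence all candidate-vs-known contrasts) remains estimable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dusgp.data_io import GenotypeTable, TrialTable, ValidationError
from dusgp.mixedmodel import FittedLMM, ModelSpec, contrast, normal_test
from dusgp.relationship import GRMatrix

ENV_GROUP = "env_group"  # combined environment-by-group factor column


@dataclass
class LayoutSpec:
    layout: str  # 'ryegrass' | 'wheat'
    qtl_markers: list = field(default_factory=list)

    def __post_init__(self):
        if self.layout not in ("ryegrass", "wheat"):
            raise ValidationError("layout must be 'ryegrass' or 'wheat'")
        self.qtl_markers = [str(m) for m in self.qtl_markers]


def qtl_covariate(geno: GenotypeTable, marker) -> pd.Series:
    """Centred allele frequency of one marker, indexed by variety."""
    j = geno.marker_index(marker)
    w = geno.freq[:, j].astype(float)
    m = np.nanmean(w)
    w = np.where(np.isfinite(w), w, m) - m
    return pd.Series(w, index=[str(v) for v in geno.varieties],
                     name=f"qtl_{marker}")


def prepare_data(trials: TrialTable, geno: GenotypeTable,
                 layout: LayoutSpec, characteristic=None) -> pd.DataFrame:
    """Merge trial records with per-variety model columns.

    Adds a categorical ``ploidy`` column, the environment-by-group factor
    and one centred-frequency covariate per QTL marker.
    """
    df = (trials.for_characteristic(characteristic)
          if characteristic is not None else trials.df.copy())
    known = {str(v) for v in geno.varieties}
    missing = sorted(set(df["variety"]) - known)
    if missing:
        raise ValidationError(f"varieties without genotype data: {missing[:5]}")
    pmap = {str(v): str(p) for v, p in zip(geno.varieties, geno.ploidy)}
    df = df.copy()
    df["ploidy"] = df["variety"].map(pmap)
    df[ENV_GROUP] = df["environment"] + ":" + df["group"]
    for m in layout.qtl_markers:
        cov = qtl_covariate(geno, m)
        df[cov.name] = df["variety"].map(cov)
    if layout.layout == "wheat":
        dup = df.duplicated(subset=["variety", "environment", "characteristic"])
        if dup.any():
            raise ValidationError(
                "wheat layout requires one record per variety and country; "
                "replicated records belong in the ryegrass layout"
            )
    return df


def make_spec(layout: LayoutSpec, characteristic, grm: GRMatrix) -> ModelSpec:
    """Assemble the per-characteristic mixed-model specification."""
    qtl_terms = [f"qtl_{m}" for m in layout.qtl_markers]
    if layout.layout == "ryegrass":
        return ModelSpec(
            response=str(characteristic),
            fixed_terms=["ploidy"] + qtl_terms,
            random_terms=[("variety", "grm"), ("environment", "identity"),
                          (ENV_GROUP, "identity")],
            grm=grm,
        )
    return ModelSpec(
        response=str(characteristic),
        fixed_terms=qtl_terms,
        random_terms=[("variety", "grm"), ("environment", "identity")],
        grm=grm,
    )


def predict_candidate(fit: FittedLMM, candidate, knowns, alpha: float = 0.01,
                      group_of: dict | None = None,
                      geno: GenotypeTable | None = None) -> pd.DataFrame:
    """Predicted candidate-vs-known differences with normal-test decisions.

    Comparisons are restricted to the candidate's group when a
    variety -> group mapping is supplied (ploidy group for ryegrass,
    country sets for wheat; set-valued entries intersect).  When the fit
    carries QTL covariates, ``geno`` must be supplied so the fixed-effect
    part beta_q * (w_candidate - w_known) of each predicted difference (and
    its error covariance with the variety BLUPs) is included.
    """
    cand = str(candidate)
    if "variety" not in fit.blups:
        raise ValidationError("fit has no variety term")
    if cand not in fit.blups["variety"].index:
        raise ValidationError(f"candidate {cand!r} absent from GRM/fit")
    qtl_terms = [t for t in fit.spec.fixed_terms if t.startswith("qtl_")]
    covs = {}
    if qtl_terms:
        if geno is None:
            raise ValidationError("fit has QTL covariates; pass geno to "
                                  "predict_candidate")
        covs = {t: qtl_covariate(geno, t[len("qtl_"):]) for t in qtl_terms}
    rows = []
    for k in knowns:
        k = str(k)
        if k == cand:
            continue
        if group_of is not None:
            gc, gk = group_of.get(cand), group_of.get(k)
            if gc is None or gk is None:
                continue
            if isinstance(gc, (set, frozenset)) or isinstance(gk, (set, frozenset)):
                if not set(gc if isinstance(gc, (set, frozenset)) else {gc}) & \
                        set(gk if isinstance(gk, (set, frozenset)) else {gk}):
                    continue
            elif gc != gk:
                continue
        diffs = {t: float(c[cand] - c[k]) for t, c in covs.items()}
        est, sed = fit.pair_difference("variety", cand, k,
                                       covariate_diffs=diffs or None)
        if sed <= 0:
            # genomically identical pair: difference is identically zero
            z, p, distinct = 0.0, 1.0, False
        else:
            z, p, distinct = normal_test(est, sed, alpha)
        rows.append((cand, k, est, sed, z, p, distinct))
    return pd.DataFrame(rows, columns=["candidate", "known", "estimate",
                                       "sed", "z", "p", "distinct"])
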