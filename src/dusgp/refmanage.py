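"""Reference-collection management evaluation.

``crossvalidate`` runs the leave-one-out candidate scheme: each variety in
turn has its phenotype records masked, the layout model is refitted to the
remaining data (variance components re-estimated by default; ``reuse_vc``
reuses the full-data components for speed), and its differences from every
within-group known variety are predicted and tested at alpha.  The truth
standard per pair is the long-term COYD decision (ryegrass) or the two-note
rule (wheat).  Per-characteristic results are collated by OR across
characteristics — distinctness in a single characteristic suffices.

``simulate_reduction`` estimates the trial-size reduction: a random set of
m varieties plays the candidates and the proportion of remaining (known)
varieties distinct from *all* of them is the fraction of the reference
collection that would not need planting; the mean over seeded Monte-Carlo
samples (or exhaustive enumeration when feasible) is reported per m.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from dusgp.data_io import GenotypeTable, RunConfig, TrialTable, ValidationError
from dusgp.distinctness import DistinctnessMatrix, actual_note_decision, collate, coyd
from dusgp.gblup import LayoutSpec, make_spec, predict_candidate, prepare_data
from dusgp.mixedmodel import fit_reml
from dusgp.relationship import GRMatrix, build_grm

EXACT_LIMIT = 10_000  # enumerate candidate sets exhaustively up to this count


@dataclass
class CrossValReport:
    per_characteristic: pd.DataFrame  # characteristic, prop_cv, prop_truth, r2, n_pairs
    pairs: pd.DataFrame               # per (characteristic, candidate, known) records
    collated_cv: float
    collated_truth: float
    cv_matrices: dict = field(default_factory=dict)
    truth_matrices: dict = field(default_factory=dict)


@dataclass
class ReductionReport:
    table: pd.DataFrame  # m, proportion, mc_se, n_sim, exact
    n_sim: int
    seed: int


def _truth_matrix(trials, characteristic, config) -> DistinctnessMatrix:
    if config.layout == "ryegrass":
        return coyd(trials, characteristic, config)
    return actual_note_decision(trials, characteristic, config)


def _pair_groups(trials: TrialTable, config: RunConfig) -> dict:
    if config.layout == "ryegrass":
        return trials.group_of()
    return trials.groups_of()  # wheat: set of countries per variety


def _observed_mean_diff(df_char: pd.DataFrame) -> pd.Series:
    return df_char.groupby("variety")["value"].mean()


def crossvalidate(geno: GenotypeTable, trials: TrialTable, layout: LayoutSpec,
                  config: RunConfig, grm: GRMatrix | None = None,
                  characteristics=None) -> CrossValReport:
    """Leave-one-out candidate evaluation over all characteristics."""
    if layout.layout != config.layout:
        raise ValidationError("layout and config.layout disagree")
    grm = grm or build_grm(geno)
    chars = [str(c) for c in (characteristics or trials.characteristics)]
    group_of = _pair_groups(trials, config)
    rows, per_char = [], []
    cv_mats, truth_mats = {}, {}
    for ch in chars:
        truth = _truth_matrix(trials, ch, config)
        truth_mats[ch] = truth
        tidx = {v: i for i, v in enumerate(truth.labels)}
        df_char = trials.for_characteristic(ch)
        obs_mean = _observed_mean_diff(df_char)
        varieties = sorted(df_char["variety"].unique())
        full_fit = None
        if config.reuse_vc:
            full_df = prepare_data(trials, geno, layout, ch)
            full_fit = fit_reml(make_spec(layout, ch, grm), full_df)
        for cand in varieties:
            masked = trials.mask_variety(cand, ch)
            df = prepare_data(masked, geno, layout, ch)
            spec = make_spec(layout, ch, grm)
            if config.reuse_vc:
                fit = fit_reml(spec, df, fixed_sigma2=full_fit.sigma2)
            else:
                fit = fit_reml(spec, df)
            knowns = [v for v in varieties if v != cand]
            pred = predict_candidate(fit, cand, knowns, alpha=config.alpha,
                                     group_of=group_of, geno=geno)
            for r in pred.itertuples(index=False):
                i, j = tidx.get(cand), tidx.get(r.known)
                truth_distinct = bool(truth.decision[i, j]) if None not in (i, j) \
                    else False
                obs = float(obs_mean.get(cand, np.nan) - obs_mean.get(r.known, np.nan))
                rows.append((ch, cand, r.known, r.estimate, r.sed, r.z, r.p,
                             bool(r.distinct), obs, truth_distinct))
    pairs = pd.DataFrame(rows, columns=["characteristic", "candidate", "known",
                                        "estimate", "sed", "z", "p", "distinct",
                                        "observed_diff", "truth_distinct"])
    for ch in chars:
        sub = pairs[pairs["characteristic"] == ch]
        n_pairs = len(sub)
        prop_cv = float(sub["distinct"].mean()) if n_pairs else 0.0
        prop_truth = float(sub["truth_distinct"].mean()) if n_pairs else 0.0
        ok = np.isfinite(sub["estimate"]) & np.isfinite(sub["observed_diff"])
        if ok.sum() > 2 and sub.loc[ok, "estimate"].std() > 0 \
                and sub.loc[ok, "observed_diff"].std() > 0:
            r, _ = stats.pearsonr(sub.loc[ok, "estimate"],
                                  sub.loc[ok, "observed_diff"])
            r2 = float(r ** 2)
        else:
            r2 = np.nan
        per_char.append((ch, prop_cv, prop_truth, r2, n_pairs))
        cv_mats[ch] = _pairs_to_matrix(sub, ch, config.alpha)
    per_char_df = pd.DataFrame(per_char, columns=["characteristic", "prop_cv",
                                                  "prop_truth", "r2", "n_pairs"])
    key = pairs.groupby(["candidate", "known"])
    collated_cv = float(key["distinct"].any().mean()) if len(pairs) else 0.0
    collated_truth = float(key["truth_distinct"].any().mean()) if len(pairs) else 0.0
    return CrossValReport(per_characteristic=per_char_df, pairs=pairs,
                          collated_cv=collated_cv, collated_truth=collated_truth,
                          cv_matrices=cv_mats, truth_matrices=truth_mats)


def _pairs_to_matrix(sub: pd.DataFrame, characteristic, alpha) -> DistinctnessMatrix:
    labels = sorted(set(sub["candidate"]) | set(sub["known"]))
    idx = {v: i for i, v in enumerate(labels)}
    n = len(labels)
    P = np.full((n, n), np.nan)
    D = np.zeros((n, n), dtype=bool)
    for r in sub.itertuples(index=False):
        i, j = idx[r.candidate], idx[r.known]
        # ordered (candidate, known) roles: a pair is distinct if either
        # direction of the candidate simulation declares it so
        if np.isfinite(r.p):
            P[i, j] = r.p if not np.isfinite(P[i, j]) else min(P[i, j], r.p)
            P[j, i] = P[i, j]
        if r.distinct:
            D[i, j] = D[j, i] = True
    np.fill_diagonal(D, False)
    return DistinctnessMatrix(str(characteristic), labels, P, D, "gblup_cv",
                              threshold=alpha)


def simulate_reduction(collated: DistinctnessMatrix, m_values,
                       config: RunConfig, method: str = "auto") -> ReductionReport:
    """Expected fraction of known varieties distinct from all m candidates.

    method: 'auto' enumerates exhaustively when C(n, m) <= 10,000, else
    Monte-Carlo with config.n_sim seeded samples; 'exact'/'mc' force a mode.
    """
    D = np.asarray(collated.decision, dtype=bool)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValidationError("collated matrix must be square")
    rng = np.random.default_rng(config.seed)
    rows = []
    for m in m_values:
        m = int(m)
        if not 0 < m < n:
            raise ValidationError(f"candidate count m={m} must satisfy 0 < m < n={n}")
        exact = method == "exact" or (method == "auto" and comb(n, m) <= EXACT_LIMIT)
        if exact:
            props = [_prop_knowns_distinct(D, s, n)
                     for s in itertools.combinations(range(n), m)]
            props = np.array(props)
            rows.append((m, float(props.mean()), 0.0, len(props), True))
        else:
            props = np.empty(config.n_sim)
            for b in range(config.n_sim):
                s = rng.choice(n, size=m, replace=False)
                props[b] = _prop_knowns_distinct(D, tuple(s), n)
            mc_se = float(props.std(ddof=1) / np.sqrt(config.n_sim))
            rows.append((m, float(props.mean()), mc_se, config.n_sim, False))
    table = pd.DataFrame(rows, columns=["m", "proportion", "mc_se", "n_sim", "exact"])
    return ReductionReport(table=table, n_sim=config.n_sim, seed=config.seed)


def _prop_knowns_distinct(D: np.ndarray, cand_idx, n: int) -> float:
    mask = np.ones(n, dtype=bool)
    mask[list(cand_idx)] = False
    sub = D[np.ix_(mask, list(cand_idx))]
    return float(sub.all(axis=1).mean()) if mask.any() else 0.0
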