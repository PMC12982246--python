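"""Synthetic genotype panels and trial data with known truth.

The generator emulates the two study layouts:

ryegrass  : per-variety pooled allele frequencies (mixed diploid/tetraploid
            panel), a polygenic + optional QTL trait architecture, and
            multi-year trial means with year, year-by-ploidy and
            variety-by-year (residual) effects;
wheat     : single 1-9 note per variety per country, with country and
            residual effects.

Variety pools are simulated directly as Beta-distributed allele frequencies
around a founder frequency: freq ~ Beta(p*nu, (1-p)*nu) with
nu = (1-d)/d, so that var(freq) = d * p * (1-p).  The differentiation
parameter d plays the role of an Fst-like divergence between varieties.
Markers are assigned to chromosomes in contiguous blocks; no linkage
disequilibrium beyond the block assignment is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from dusgp.data_io import GenotypeTable, TrialTable, ValidationError
from dusgp.relationship import build_grm


@dataclass
class TruthParams:
    """Simulation variance components and fixed effects (trait units squared)."""

    mean: float = 5.0
    sigma2_poly: float = 1.0        # polygenic variety variance (via GRM)
    sigma2_env: float = 0.5         # year (ryegrass) or country (wheat)
    sigma2_env_group: float = 0.25  # year-by-ploidy (ryegrass only)
    sigma2_resid: float = 1.0       # variety-by-environment residual
    ploidy_effect: float = 0.5      # fixed tetraploid - diploid offset

    def __post_init__(self):
        for name in ("sigma2_poly", "sigma2_env", "sigma2_env_group", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated trial set."""

    params: TruthParams
    qtl: list                      # [(marker, effect)] shared by all characteristics
    genetic_values: pd.DataFrame   # variety x characteristic true genetic values
    heritability: dict             # characteristic -> s2_g / (s2_g + s2_eps/k)
    seed: int
    layout: str

    def as_dict(self) -> dict:
        return {
            "params": asdict(self.params),
            "qtl": [(m, float(e)) for m, e in self.qtl],
            "heritability": {k: float(v) for k, v in self.heritability.items()},
            "seed": self.seed,
            "layout": self.layout,
        }


def simulate_panel(n_varieties: int, n_markers: int, n_chromosomes: int = 7,
                   ploidy_mix: float = 0.5, differentiation: float = 0.3,
                   family_size: int | None = None,
                   within_family_differentiation: float = 0.05,
                   seed: int = 0, prefix: str = "V") -> GenotypeTable:
    """Simulate a variety panel of pooled allele frequencies.

    Parameters
    ----------
    ploidy_mix : fraction of tetraploid varieties (rest diploid).
    differentiation : Fst-like divergence d in (0, 1); per-marker frequency
        variance across varieties (or across families when ``family_size``
        is set) is d * p * (1 - p).
    family_size : when set, varieties come in families of this size sharing
        a family-level frequency profile (two-level Beta hierarchy), with
        ``within_family_differentiation`` governing divergence around it.
        Families share ploidy, mirroring separate diploid and tetraploid
        breeding programmes.  Reference collections contain related
        varieties; without families all varieties are exchangeable and the
        GRM off-diagonals are pure sampling noise.
    """
    if n_varieties < 1 or n_markers < 1 or n_chromosomes < 1:
        raise ValidationError("all counts must be positive")
    if not 0 < differentiation < 1:
        raise ValidationError("differentiation must be in (0, 1)")
    if not 0 < within_family_differentiation < 1:
        raise ValidationError("within_family_differentiation must be in (0, 1)")
    if not 0 <= ploidy_mix <= 1:
        raise ValidationError("ploidy_mix must be in [0, 1]")
    rng = np.random.default_rng(seed)
    founder = rng.uniform(0.05, 0.95, size=n_markers)
    nu = (1.0 - differentiation) / differentiation
    if family_size is None:
        F = rng.beta(founder * nu, (1.0 - founder) * nu,
                     size=(n_varieties, n_markers))
        n_tetra = int(round(ploidy_mix * n_varieties))
        ploidy = np.array([2] * (n_varieties - n_tetra) + [4] * n_tetra)
        rng.shuffle(ploidy)
    else:
        if family_size < 1:
            raise ValidationError("family_size must be >= 1")
        n_fam = int(np.ceil(n_varieties / family_size))
        fam_p = rng.beta(founder * nu, (1.0 - founder) * nu,
                         size=(n_fam, n_markers))
        fam_p = np.clip(fam_p, 0.02, 0.98)
        nu_w = (1.0 - within_family_differentiation) / within_family_differentiation
        fam_of = np.repeat(np.arange(n_fam), family_size)[:n_varieties]
        F = rng.beta(fam_p[fam_of] * nu_w, (1.0 - fam_p[fam_of]) * nu_w)
        n_tetra_fam = int(round(ploidy_mix * n_fam))
        fam_ploidy = np.array([2] * (n_fam - n_tetra_fam) + [4] * n_tetra_fam)
        rng.shuffle(fam_ploidy)
        ploidy = fam_ploidy[fam_of]
    width = len(str(n_varieties))
    varieties = [f"{prefix}{i + 1:0{width}d}" for i in range(n_varieties)]
    # contiguous chromosome blocks with integer positions
    chrom_of = np.array_split(np.arange(n_markers), n_chromosomes)
    chrom = np.empty(n_markers, dtype=object)
    pos = np.empty(n_markers, dtype=int)
    for c, block in enumerate(chrom_of, start=1):
        chrom[block] = str(c)
        pos[block] = np.arange(len(block)) * 1000
    markers = pd.DataFrame({
        "marker": [f"M{c}_{p}" for c, p in zip(chrom, pos)],
        "chrom": chrom, "pos": pos,
    })
    return GenotypeTable(varieties, ploidy, F, markers)


def duplicate_panel(panel: GenotypeTable, suffix: str = "_dup") -> GenotypeTable:
    """Append an identical genotypic copy of every variety (clone pairs)."""
    return GenotypeTable(
        list(panel.varieties) + [v + suffix for v in panel.varieties],
        np.concatenate([panel.ploidy, panel.ploidy]),
        np.vstack([panel.freq, panel.freq]),
        panel.markers.copy(),
    )


def qtl_effect_for_fraction(panel: GenotypeTable, marker, fraction: float,
                            sigma2_poly: float) -> float:
    """Effect size beta so a QTL explains a given fraction of genetic variance.

    With centred frequencies w, var(QTL) = beta^2 var(w); the polygenic
    variance is sigma2_poly * mean(diag G) ~ sigma2_poly.  Solving
    var(QTL) / (var(QTL) + sigma2_poly) = fraction gives beta.
    """
    if not 0 < fraction < 1:
        raise ValidationError("fraction must be in (0, 1)")
    j = panel.marker_index(marker)
    w = panel.freq[:, j]
    vw = np.nanvar(w, ddof=1)
    if vw <= 0:
        raise ValidationError(f"marker {marker!r} has zero variance")
    return float(np.sqrt(fraction / (1.0 - fraction) * sigma2_poly / vw))


def _genetic_values(panel, G_half, params, qtl, rng, n_characteristics):
    n = panel.n_varieties
    g = np.zeros((n, n_characteristics))
    if params.sigma2_poly > 0:
        z = rng.standard_normal((G_half.shape[1], n_characteristics))
        g += np.sqrt(params.sigma2_poly) * (G_half @ z)
    for marker, effect in qtl:
        j = panel.marker_index(marker)
        w = panel.freq[:, j]
        w = np.where(np.isfinite(w), w, np.nanmean(w)) - np.nanmean(w)
        g += np.outer(w * effect, np.ones(n_characteristics))
    return g


def _grm_half(panel, sigma2_poly):
    if sigma2_poly <= 0:
        return np.zeros((panel.n_varieties, 1))
    G = build_grm(panel).values
    w, U = np.linalg.eigh(G)
    sel = w > 1e-10 * max(w.max(), 1.0)
    return U[:, sel] * np.sqrt(w[sel])


def simulate_trials(panel: GenotypeTable, layout: str = "ryegrass",
                    n_characteristics: int = 3, n_environments: int = 10,
                    params: TruthParams | None = None, qtl=None,
                    seed: int = 0, notes: bool | None = None,
                    countries_per_variety: int = 1,
                    years_per_variety: int | None = None):
    """Simulate trial data over a genotype panel.

    ryegrass layout: one trial-mean record per variety x year,
        y = mu + ploidy + g + year + year-by-ploidy + eps.
        ``years_per_variety`` restricts each variety to a contiguous,
        randomly placed window of trial years, emulating historical DUS
        data where varieties were trialled in different eras; by default
        every variety is observed in every year.
    wheat layout: one record per variety x country (each variety assigned to
        ``countries_per_variety`` countries), y = mu + g + country + eps,
        optionally rank-binned to 1-9 notes (default for wheat).

    Returns (TrialTable, SimTruth).
    """
    if layout not in ("ryegrass", "wheat"):
        raise ValidationError("layout must be 'ryegrass' or 'wheat'")
    if n_environments < 1 or n_characteristics < 1:
        raise ValidationError("counts must be positive")
    params = params or TruthParams()
    qtl = list(qtl or [])
    if notes is None:
        notes = layout == "wheat"
    rng = np.random.default_rng(seed)
    n = panel.n_varieties
    chars = [f"trait_{k + 1}" for k in range(n_characteristics)]
    G_half = _grm_half(panel, params.sigma2_poly)
    g = _genetic_values(panel, G_half, params, qtl, rng, n_characteristics)

    records = []
    if layout == "ryegrass":
        groups = np.where(panel.ploidy == 4, "4x", "2x")
        years = [f"Y{e + 1:02d}" for e in range(n_environments)]
        if years_per_variety is None:
            lo = np.zeros(n, dtype=int)
            hi = np.full(n, n_environments)
        else:
            if not 2 <= years_per_variety <= n_environments:
                raise ValidationError(
                    "years_per_variety must be in [2, n_environments]")
            lo = rng.integers(0, n_environments - years_per_variety + 1, size=n)
            hi = lo + years_per_variety
        for k, ch in enumerate(chars):
            year_eff = rng.normal(0, np.sqrt(params.sigma2_env), n_environments)
            yg_eff = rng.normal(0, np.sqrt(params.sigma2_env_group),
                                (n_environments, 2))
            eps = rng.normal(0, np.sqrt(params.sigma2_resid), (n, n_environments))
            base = (params.mean + g[:, k]
                    + params.ploidy_effect * (panel.ploidy == 4))
            for e, yr in enumerate(years):
                yvals = base + year_eff[e] + yg_eff[e, (groups == "4x").astype(int)] \
                    + eps[:, e]
                for i, v in enumerate(panel.varieties):
                    if lo[i] <= e < hi[i]:
                        records.append((v, yr, groups[i], ch, yvals[i]))
    else:
        countries = [f"C{e + 1}" for e in range(n_environments)]
        if countries_per_variety > n_environments:
            raise ValidationError("countries_per_variety exceeds country count")
        assign = [list(rng.choice(n_environments, size=countries_per_variety,
                                  replace=False)) for _ in range(n)]
        for k, ch in enumerate(chars):
            ctry_eff = rng.normal(0, np.sqrt(params.sigma2_env), n_environments)
            raw = []
            for i, v in enumerate(panel.varieties):
                for e in assign[i]:
                    eps = rng.normal(0, np.sqrt(params.sigma2_resid))
                    raw.append([v, countries[e], countries[e], ch,
                                params.mean + g[i, k] + ctry_eff[e] + eps])
            if notes:
                vals = np.array([r[4] for r in raw])
                ranks = np.argsort(np.argsort(vals))
                binned = np.floor(ranks / len(vals) * 9).astype(int) + 1
                for r, b in zip(raw, binned):
                    r[4] = float(b)
            records.extend(tuple(r) for r in raw)

    df = pd.DataFrame(records, columns=list(TrialTable.COLUMNS))
    trials = TrialTable(df, layout=layout)
    s2g = {ch: float(np.var(g[:, k], ddof=1)) if n > 1 else 0.0
           for k, ch in enumerate(chars)}
    k_env = ((years_per_variety or n_environments) if layout == "ryegrass"
             else countries_per_variety)
    herit = {ch: s2g[ch] / (s2g[ch] + params.sigma2_resid / k_env)
             if (s2g[ch] + params.sigma2_resid) > 0 else 0.0 for ch in chars}
    truth = SimTruth(params=params, qtl=qtl,
                     genetic_values=pd.DataFrame(g, index=panel.varieties,
                                                 columns=chars),
                     heritability=herit, seed=seed, layout=layout)
    return trials, truth


def default_benchmark(seed: int = 0, n_varieties: int = 200,
                      n_markers: int = 1000, n_characteristics: int = 3,
                      n_years: int = 10, years_per_variety: int | None = 3,
                      params: TruthParams | None = None, qtl=None):
    """The package's reference ryegrass study conditions.

    A mixed diploid/tetraploid panel of related varieties (families of 5,
    between-family differentiation 0.25, within-family 0.20, giving
    within-family relationship around 0.6 — reference collections contain
    relatives from the same breeding programmes), with historical-style
    trials: each variety observed in a contiguous 3-year window within a
    10-year period.  Trait architecture is polygenic with unit variety
    variance and unit variety-by-year residual (per-year heritability 0.5),
    year variance 0.5 and year-by-ploidy 0.25.

    Returns (panel, trials, truth).
    """
    panel = simulate_panel(n_varieties, n_markers, differentiation=0.25,
                           family_size=5, within_family_differentiation=0.20,
                           seed=seed)
    trials, truth = simulate_trials(panel, layout="ryegrass",
                                    n_characteristics=n_characteristics,
                                    n_environments=n_years, params=params,
                                    qtl=qtl, seed=seed + 1,
                                    years_per_variety=years_per_variety)
    return panel, trials, truth
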