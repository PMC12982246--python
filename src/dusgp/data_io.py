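"""Readers, writers and core containers for genotype, trial and matrix data.

Genotype tables hold per-variety *allele frequencies* rather than individual
genotypes: for pooled GBS data of outbreeding varieties the natural datum is
the non-reference read fraction at each site; for array/genotype data the
alternate-allele dosage divided by the ploidy plays the same role.

CSV dialects
------------
genotypes  : varieties as rows; first column ``variety``, second ``ploidy``,
             remaining columns one per marker.  Missing frequencies are empty
             cells.  A marker map is an optional 3-column sidecar CSV
             ``marker,chrom,pos``.
trials     : long format with header ``variety,environment,group,
             characteristic,value``.  Environments are opaque labels (years
             for the ryegrass layout, countries for the wheat layout).
matrices   : square labelled CSV, first column ``label``.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml


class DusgpError(Exception):
    """Base class for all package errors."""


class ParseError(DusgpError):
    """A file could not be parsed at all (malformed structure)."""


class SchemaError(DusgpError):
    """A file parsed but does not have the expected columns."""


class ValidationError(DusgpError):
    """Parsed content violates a container invariant."""


LAYOUTS = ("ryegrass", "wheat")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Variety x marker allele-frequency matrix with ploidy and marker map.

    Attributes
    ----------
    varieties : list of str
        Ordered, unique variety identifiers.
    ploidy : ndarray of int, shape (n_varieties,)
        Per-variety ploidy, 2 (diploid) or 4 (tetraploid).
    freq : ndarray of float, shape (n_varieties, n_markers)
        Non-reference allele frequencies in [0, 1]; NaN marks missing.
    markers : DataFrame with columns ``marker``, ``chrom``, ``pos``
        Marker map in column order of ``freq``.
    """

    varieties: list
    ploidy: np.ndarray
    freq: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self):
        self.varieties = list(self.varieties)
        self.ploidy = np.asarray(self.ploidy, dtype=int)
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[0] != len(self.varieties):
            raise ValidationError("freq must be (n_varieties, n_markers)")
        if len(set(self.varieties)) != len(self.varieties):
            raise ValidationError("variety ids must be unique")
        if not set(np.unique(self.ploidy)) <= {2, 4}:
            raise ValidationError("ploidy must be 2 or 4")
        finite = self.freq[np.isfinite(self.freq)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("allele frequencies must lie in [0, 1]")
        self.markers = self.markers.reset_index(drop=True)
        need = {"marker", "chrom", "pos"}
        if not need <= set(self.markers.columns):
            raise SchemaError(f"marker map needs columns {sorted(need)}")
        if len(self.markers) != self.freq.shape[1]:
            raise ValidationError("marker map length != number of marker columns")
        ids = self.markers["marker"].astype(str)
        if ids.duplicated().any():
            raise ValidationError("marker ids must be unique")
        if (self.markers["pos"].astype(int) < 0).any():
            raise ValidationError("positions must be non-negative")

    @property
    def n_varieties(self) -> int:
        return len(self.varieties)

    @property
    def n_markers(self) -> int:
        return self.freq.shape[1]

    @property
    def marker_ids(self) -> list:
        return self.markers["marker"].astype(str).tolist()

    def index_of(self, variety) -> int:
        try:
            return self.varieties.index(variety)
        except ValueError:
            raise ValidationError(f"unknown variety {variety!r}") from None

    def marker_index(self, marker) -> int:
        ids = self.marker_ids
        try:
            return ids.index(str(marker))
        except ValueError:
            raise ValidationError(f"unknown marker {marker!r}") from None

    def ploidy_of(self, variety) -> int:
        return int(self.ploidy[self.index_of(variety)])

    def subset(self, varieties: Sequence) -> "GenotypeTable":
        idx = [self.index_of(v) for v in varieties]
        return GenotypeTable(
            varieties=[self.varieties[i] for i in idx],
            ploidy=self.ploidy[idx],
            freq=self.freq[idx, :].copy(),
            markers=self.markers.copy(),
        )


@dataclass
class TrialTable:
    """Long-format trial records: (variety, environment, group, characteristic, value)."""

    df: pd.DataFrame
    layout: str = "ryegrass"

    COLUMNS = ("variety", "environment", "group", "characteristic", "value")

    def __post_init__(self):
        if self.layout not in LAYOUTS:
            raise ValidationError(f"layout must be one of {LAYOUTS}")
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"trial table missing columns {missing}")
        df = self.df.loc[:, list(self.COLUMNS)].copy()
        for c in ("variety", "environment", "group", "characteristic"):
            df[c] = df[c].astype(str)
        vals = pd.to_numeric(df["value"], errors="coerce")
        bad = df.index[~np.isfinite(vals.to_numpy(dtype=float))]
        if len(bad):
            raise ValidationError(
                f"non-numeric or missing value in trial rows {list(bad[:5])}"
            )
        df["value"] = vals.astype(float)
        dup = df.duplicated(subset=["variety", "environment", "characteristic"])
        if dup.any():
            rows = df.loc[dup, ["variety", "environment", "characteristic"]]
            raise ValidationError(
                "duplicate (variety, environment, characteristic) records: "
                f"{rows.iloc[0].tolist()}"
            )
        self.df = df.reset_index(drop=True)

    @property
    def varieties(self) -> list:
        return sorted(self.df["variety"].unique())

    @property
    def environments(self) -> list:
        return sorted(self.df["environment"].unique())

    @property
    def characteristics(self) -> list:
        return sorted(self.df["characteristic"].unique())

    def group_of(self) -> dict:
        """Mapping variety -> group label (first seen; groups are per-variety
        for the ryegrass layout).  Wheat varieties may sit in several
        countries; use :meth:`groups_of` there."""
        return dict(zip(self.df["variety"], self.df["group"]))

    def groups_of(self) -> dict:
        out: dict = {}
        for v, g in zip(self.df["variety"], self.df["group"]):
            out.setdefault(v, set()).add(g)
        return out

    def for_characteristic(self, characteristic) -> pd.DataFrame:
        sub = self.df[self.df["characteristic"] == str(characteristic)]
        if sub.empty:
            raise ValidationError(f"characteristic {characteristic!r} not in trials")
        return sub.reset_index(drop=True)

    def mask_variety(self, variety, characteristic=None) -> "TrialTable":
        """Drop a variety's phenotype records (candidate masking)."""
        df = self.df
        keep = df["variety"] != str(variety)
        if characteristic is not None:
            keep |= df["characteristic"] != str(characteristic)
        return TrialTable(df[keep].reset_index(drop=True), layout=self.layout)


@dataclass
class RunConfig:
    """Run parameters shared across the framework.

    alpha          significance level of the distinctness tests (default 0.01)
    note_threshold minimum note gap declaring wheat distinctness (default 2)
    lsd_years      number of trial years the COYD LSD is referenced to (3)
    n_sim          Monte-Carlo samples in the reduction simulation (1000)
    reuse_vc       reuse full-data variance components across LOO folds
    fdr_q          FDR threshold for GWAS (0.05)
    """

    layout: str = "ryegrass"
    alpha: float = 0.01
    note_threshold: int = 2
    lsd_years: int = 3
    n_sim: int = 1000
    seed: int = 0
    reuse_vc: bool = False
    fdr_q: float = 0.05

    def __post_init__(self):
        if self.layout not in LAYOUTS:
            raise ValidationError(f"layout must be one of {LAYOUTS}")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.note_threshold < 1:
            raise ValidationError("note_threshold must be >= 1")
        if self.lsd_years < 1:
            raise ValidationError("lsd_years must be >= 1")
        if self.n_sim < 1:
            raise ValidationError("n_sim must be >= 1")
        if not 0 < self.fdr_q < 1:
            raise ValidationError("fdr_q must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise SchemaError(f"unknown config keys {sorted(extra)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

def _default_marker_map(marker_ids: Iterable) -> pd.DataFrame:
    ids = [str(m) for m in marker_ids]
    return pd.DataFrame({"marker": ids, "chrom": "1", "pos": np.arange(len(ids))})


def read_marker_map(path) -> pd.DataFrame:
    mm = pd.read_csv(path, dtype={0: str, 1: str})
    need = {"marker", "chrom", "pos"}
    if not need <= set(mm.columns):
        raise SchemaError(f"marker map {path}: needs columns {sorted(need)}")
    mm["pos"] = pd.to_numeric(mm["pos"], errors="raise").astype(int)
    return mm.loc[:, ["marker", "chrom", "pos"]]


def read_genotypes(path, format: str = "csv", marker_map=None) -> GenotypeTable:
    """Read a genotype table from CSV or VCF.

    For VCF, per variety-site frequencies follow the non-reference-read
    convention: with an AD field, alternate reads over total reads; with
    genotypes only, alternate-allele dosage over ploidy.
    """
    if format == "csv":
        return _read_genotypes_csv(path, marker_map)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValidationError(f"unknown genotype format {format!r}")


def _read_genotypes_csv(path, marker_map=None) -> GenotypeTable:
    try:
        df = pd.read_csv(path, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message wrapped
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: need variety, ploidy and marker columns")
    cols = list(df.columns)
    if cols[0].lower() != "variety" or "ploidy" not in [c.lower() for c in cols]:
        raise SchemaError(f"{path}: first column must be 'variety' with a 'ploidy' column")
    df = df.rename(columns={cols[0]: "variety"})
    ploidy_col = [c for c in df.columns if c.lower() == "ploidy"][0]
    marker_cols = [c for c in df.columns if c not in ("variety", ploidy_col)]
    try:
        ploidy = df[ploidy_col].astype(int).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-integer ploidy") from exc
    freq = df[marker_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw = df[marker_cols]
    # distinguish empty cells (missing, allowed) from garbage (rejected)
    garbage = raw.notna().to_numpy() & ~np.isfinite(freq)
    if garbage.any():
        i, j = np.argwhere(garbage)[0]
        raise ValidationError(
            f"{path}: non-numeric frequency at variety "
            f"{df['variety'].iloc[i]!r}, marker {marker_cols[j]!r}"
        )
    if marker_map is not None:
        mm = read_marker_map(marker_map)
        order = {m: k for k, m in enumerate(mm["marker"].astype(str))}
        missing = [m for m in marker_cols if str(m) not in order]
        if missing:
            raise ValidationError(f"markers absent from map: {missing[:5]}")
        mm = mm.set_index("marker").loc[[str(m) for m in marker_cols]].reset_index()
    else:
        mm = _default_marker_map(marker_cols)
    return GenotypeTable(df["variety"].tolist(), ploidy, freq, mm)


def _read_genotypes_vcf(path) -> GenotypeTable:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise DusgpError("VCF ingestion requires cyvcf2") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    freqs, markers, rejected = [], [], []
    ploidy = None
    for var in vcf:
        mid = var.ID or f"{var.CHROM}_{var.POS}"
        if len(var.ALT) != 1:
            rejected.append((mid, "not biallelic"))
            continue
        gts = var.genotypes  # [allele, allele, ..., phased]
        pl = np.array([len(g) - 1 for g in gts])
        if ploidy is None:
            ploidy = pl
        ad = None
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        row = np.full(len(samples), np.nan)
        if ad is not None:
            ad = np.asarray(ad, dtype=float)
            ad[ad < 0] = np.nan
            tot = np.nansum(ad, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                row = np.where(tot > 0, ad[:, 1] / tot, np.nan)
        else:
            for s, g in enumerate(gts):
                alleles = [a for a in g[:-1] if a >= 0]
                if alleles:
                    row[s] = sum(a > 0 for a in alleles) / len(alleles)
        if np.isfinite(row).any():
            bad = np.isfinite(row) & ((row < 0) | (row > 1))
            if bad.any():
                raise ValidationError(f"{path}: frequency outside [0,1] at {mid}")
            freqs.append(row)
            markers.append((mid, str(var.CHROM), int(var.POS)))
        else:
            rejected.append((mid, "no informative calls"))
    if not markers:
        raise ValidationError(f"{path}: no usable biallelic sites (rejected {len(rejected)})")
    if ploidy is None or not set(np.unique(ploidy)) <= {2, 4}:
        raise ValidationError(f"{path}: sample ploidies must be 2 or 4")
    mm = pd.DataFrame(markers, columns=["marker", "chrom", "pos"])
    tbl = GenotypeTable(samples, ploidy, np.array(freqs).T, mm)
    tbl.rejected_markers = rejected  # report, not silently dropped
    return tbl


def write_genotypes(geno: GenotypeTable, path, marker_map_path=None) -> None:
    df = pd.DataFrame(geno.freq, columns=geno.marker_ids)
    df.insert(0, "ploidy", geno.ploidy)
    df.insert(0, "variety", geno.varieties)
    df.to_csv(path, index=False)
    if marker_map_path is not None:
        geno.markers.to_csv(marker_map_path, index=False)


# ---------------------------------------------------------------------------
# trial I/O
# ---------------------------------------------------------------------------

def read_trials(path, layout: str = "ryegrass") -> TrialTable:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in TrialTable.COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    vals = pd.to_numeric(df["value"], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(vals))
    if bad.size:
        # +2: header line and 1-based numbering
        raise ValidationError(f"{path}: empty or non-numeric value at line {bad[0] + 2}")
    return TrialTable(df, layout=layout)


def write_trials(trials: TrialTable, path) -> None:
    trials.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# labelled square matrices
# ---------------------------------------------------------------------------

def write_matrix(labels: Sequence, values: np.ndarray, path) -> None:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError("matrix must be square")
    if values.shape[0] != len(labels):
        raise ValidationError("label count must match matrix dimension")
    if len(set(map(str, labels))) != len(labels):
        raise ValidationError("labels must be unique")
    df = pd.DataFrame(values, columns=[str(l) for l in labels])
    df.insert(0, "label", [str(l) for l in labels])
    df.to_csv(path, index=False)


def read_matrix(path):
    try:
        df = pd.read_csv(path, dtype={0: str})
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.columns[0] != "label":
        raise SchemaError(f"{path}: first column must be 'label'")
    labels = df["label"].tolist()
    values = df.drop(columns="label").to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValidationError(f"{path}: matrix not square")
    return labels, values
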