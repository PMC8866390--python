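"""Genomic relationship (kinship) matrices from biallelic marker dosages.

The relationship matrix used throughout the package is the VanRaden genomic
relationship matrix

    K = W W' / (2 * sum_j p_j (1 - p_j)),

where ``W`` is the dosage matrix column-centered at ``2 p_j`` and ``p_j`` the
allele frequency of marker *j* estimated from the sample, subsequently
rescaled so that the mean of its diagonal elements equals 1 exactly
(``K <- K * N / trace(K)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "vanraden_kinship",
    "read_genotypes",
    "write_genotypes",
    "read_kinship",
    "write_kinship",
]

_SYM_TOL = 1e-8


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} ids: {dups}")
    return ids


@dataclass
class GenotypeMatrix:
    """Biallelic marker dosages (0/1/2, NaN = missing) for N genotypes."""

    ids: Sequence[str]
    dosages: np.ndarray
    markers: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.ids = _check_unique(self.ids, "genotype")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (genotype x marker) array")
        if self.dosages.shape[0] != len(self.ids):
            raise ValueError("number of ids does not match dosage rows")
        if self.dosages.shape[1] < 1:
            raise ValueError("at least one marker is required")
        vals = self.dosages[~np.isnan(self.dosages)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = np.unique(vals[~np.isin(vals, (0.0, 1.0, 2.0))])
            raise ValueError(f"dosages must be in {{0,1,2}}; found {bad[:5]}")
        if self.markers is None:
            self.markers = [f"m{j}" for j in range(self.dosages.shape[1])]

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]


@dataclass
class KinshipMatrix:
    """N x N symmetric relatedness matrix with an id index."""

    ids: Sequence[str]
    K: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.ids = _check_unique(self.ids, "genotype")
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.ids)
        if self.K.shape != (n, n):
            raise ValueError(f"kinship must be {n}x{n}, got {self.K.shape}")
        asym = np.max(np.abs(self.K - self.K.T)) if n else 0.0
        scale = max(1.0, np.max(np.abs(self.K))) if n else 1.0
        if asym > _SYM_TOL * scale:
            raise ValueError(f"kinship is asymmetric (max |K - K'| = {asym:.3g})")
        self.K = 0.5 * (self.K + self.K.T)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, ids: Sequence[str]) -> np.ndarray:
        """Row/column positions of ``ids`` (raises on unknown ids)."""
        pos = {g: i for i, g in enumerate(self.ids)}
        missing = [g for g in ids if str(g) not in pos]
        if missing:
            raise KeyError(f"genotypes not in kinship: {missing[:5]}")
        return np.array([pos[str(g)] for g in ids], dtype=int)

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        idx = self.index(ids)
        return KinshipMatrix([str(g) for g in ids], self.K[np.ix_(idx, idx)])


def vanraden_kinship(geno: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix, mean diagonal scaled to 1.

    Allele frequencies are estimated from the sample; missing dosages are
    imputed to the marker mean before centering; monomorphic markers
    contribute nothing (p(1-p) = 0 drops them from the denominator and their
    centered column is identically zero).
    """
    if geno.n < 2:
        raise ValueError("at least 2 genotypes are required")
    X = geno.dosages.copy()
    if np.isnan(X).all(axis=0).any():
        bad = [geno.markers[j] for j in np.flatnonzero(np.isnan(X).all(axis=0))]
        raise ValueError(f"markers with no non-missing call: {bad[:5]}")
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    p = col_mean / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("zero denominator: all markers are monomorphic")
    W = X - 2.0 * p
    K = (W @ W.T) / denom
    tr = float(np.trace(K))
    if tr <= 0.0:
        raise ValueError("zero denominator: trace of raw kinship is zero")
    K *= geno.n / tr
    return KinshipMatrix(list(geno.ids), K)


# ---------------------------------------------------------------------------
# file plumbing: delimited text, comma or tab autodetected


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a genotype file: rows genotypes, columns markers, NA missing."""
    df = _read_table(path)
    return GenotypeMatrix(
        [str(i) for i in df.index],
        df.to_numpy(dtype=float),
        [str(c) for c in df.columns],
    )


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(geno.dosages, index=list(geno.ids), columns=list(geno.markers))
    df.to_csv(path)


def read_kinship(path: str | Path) -> KinshipMatrix:
    """Read a square kinship matrix with id header row and column."""
    df = _read_table(path)
    ids = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if ids != cols:
        raise ValueError("kinship row ids and column ids differ")
    return KinshipMatrix(ids, df.to_numpy(dtype=float))


def write_kinship(kin: KinshipMatrix, path: str | Path) -> None:
    df = pd.DataFrame(kin.K, index=list(kin.ids), columns=list(kin.ids))
    df.to_csv(path, float_format="%.17g")
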