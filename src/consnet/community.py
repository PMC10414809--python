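"""Site-by-species and site-by-covariate data containers.

A :class:`CommunityMatrix` holds occupancy (presence/absence) or abundance
(non-negative counts) of species across sites; a :class:`CovariateMatrix`
holds environmental factors for the same sites, with categorical
microhabitat labels expanded to one-hot columns.  Both round-trip to plain
CSV with a leading ``site_id`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CommunityMatrix", "CovariateMatrix", "one_hot_covariates"]


def _check_unique(labels: Sequence, what: str) -> None:
    seen: dict = {}
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what}: {lab!r}")
        seen[lab] = True


@dataclass
class CommunityMatrix:
    """Sites x species occupancy or abundance matrix.

    Parameters
    ----------
    site_ids
        Unique, opaque site identifiers (one per row).
    species_names
        Unique species labels (one per column).
    values
        Non-negative integer matrix of shape ``(n_sites, n_species)``;
        entries are restricted to {0, 1} when ``mode == "occurrence"``.
    mode
        Either ``"occurrence"`` or ``"abundance"``.
    """

    site_ids: list
    species_names: list
    values: np.ndarray
    mode: str = "occurrence"

    def __post_init__(self) -> None:
        self.site_ids = list(self.site_ids)
        self.species_names = [str(s) for s in self.species_names]
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.site_ids), len(self.species_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.species_names)} species"
            )
        _check_unique(self.site_ids, "site_id")
        _check_unique(self.species_names, "species name")
        if np.any(self.values < 0):
            raise ValueError("community matrix has negative entries")
        if not np.all(self.values == np.floor(self.values)):
            raise ValueError("community matrix entries must be integers")
        self.values = self.values.astype(np.int64)
        if self.mode not in ("occurrence", "abundance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "occurrence" and np.any(self.values > 1):
            raise ValueError("occurrence-mode matrix has entries > 1")

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def prevalence(self) -> np.ndarray:
        """Fraction of sites occupied, per species (presence-based)."""
        return (self.values > 0).mean(axis=0)

    # -- CSV round trip -------------------------------------------------
    @classmethod
    def from_csv(cls, path, mode: str | None = None) -> "CommunityMatrix":
        """Read a community CSV (first column ``site_id``).

        ``mode`` is auto-detected when not given: a matrix whose entries
        are all in {0, 1} is treated as occurrence data, anything else as
        abundance counts.
        """
        df = pd.read_csv(path, dtype={0: str})
        if df.columns[0] != "site_id":
            raise ValueError(f"{path}: first column must be 'site_id', got {df.columns[0]!r}")
        vals = df.iloc[:, 1:]
        bad = vals.columns[vals.isna().any(axis=0)]
        if len(bad):
            raise ValueError(f"{path}: missing values in column {bad[0]!r}")
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            col = vals.columns[[not np.issubdtype(d, np.number) for d in vals.dtypes]][0]
            raise ValueError(f"{path}: non-numeric entries in column {col!r}")
        if np.any(arr != np.floor(arr)):
            r, c = np.argwhere(arr != np.floor(arr))[0]
            raise ValueError(
                f"{path}: non-integer entry at site {df.iloc[r, 0]!r}, column {vals.columns[c]!r}"
            )
        if np.any(arr < 0):
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"{path}: negative entry at site {df.iloc[r, 0]!r}, column {vals.columns[c]!r}"
            )
        if mode is None:
            mode = "occurrence" if np.all((arr == 0) | (arr == 1)) else "abundance"
        return cls(df.iloc[:, 0].tolist(), list(vals.columns), arr.astype(np.int64), mode)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.species_names)
        df.insert(0, "site_id", self.site_ids)
        df.to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.species_names)


@dataclass
class CovariateMatrix:
    """Sites x environmental-factor matrix (real-valued).

    Categorical microhabitat labels should be expanded to one-hot columns
    (see :func:`one_hot_covariates`); an intercept, when wanted, is simply
    an all-ones column the caller includes.
    """

    site_ids: list
    factor_names: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.site_ids = list(self.site_ids)
        self.factor_names = [str(f) for f in self.factor_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.site_ids), len(self.factor_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.factor_names)} factors"
            )
        _check_unique(self.site_ids, "site_id")
        _check_unique(self.factor_names, "factor name")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariate matrix has non-finite entries")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    def aligned_to(self, site_ids: Sequence) -> "CovariateMatrix":
        """Return a copy with rows reordered to match ``site_ids``."""
        index = {s: i for i, s in enumerate(self.site_ids)}
        missing = [s for s in site_ids if s not in index]
        if missing:
            raise ValueError(f"covariate matrix lacks site_ids: {missing[:5]}")
        order = [index[s] for s in site_ids]
        return CovariateMatrix(list(site_ids), self.factor_names, self.values[order])

    @classmethod
    def from_csv(cls, path) -> "CovariateMatrix":
        df = pd.read_csv(path, dtype={0: str})
        if df.columns[0] != "site_id":
            raise ValueError(f"{path}: first column must be 'site_id', got {df.columns[0]!r}")
        vals = df.iloc[:, 1:]
        if vals.isna().any().any():
            bad = vals.columns[vals.isna().any(axis=0)][0]
            raise ValueError(f"{path}: missing values in column {bad!r}")
        return cls(df.iloc[:, 0].tolist(), list(vals.columns), vals.to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.factor_names)
        df.insert(0, "site_id", self.site_ids)
        df.to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.factor_names)


def one_hot_covariates(site_ids: Sequence, labels: Sequence, prefix: str = "") -> CovariateMatrix:
    """One-hot-expand a categorical microhabitat label per site.

    The resulting block of columns sums to exactly 1 in every row, one
    column per distinct label (sorted for determinism).
    """
    labels = [str(lab) for lab in labels]
    if len(labels) != len(site_ids):
        raise ValueError("one label per site required")
    levels = sorted(set(labels))
    vals = np.zeros((len(labels), len(levels)))
    for i, lab in enumerate(labels):
        vals[i, levels.index(lab)] = 1.0
    names = [f"{prefix}{lev}" for lev in levels]
    return CovariateMatrix(list(site_ids), names, vals)
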