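"""Core in-memory containers for amplicon community data.

The package operates on three aligned objects: an :class:`AbundanceTable`
(taxa x samples counts or relative abundances), a rooted phylogeny whose
leaves index the table's taxa (a :class:`skbio.TreeNode`), and per-sample
:class:`SampleMetadata` (habitat group, coordinates, environmental
variables).  Distance matrices are :class:`skbio.DistanceMatrix` throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

TROPHIC_LABELS = ("chloroplast_containing", "heterotroph")

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "TrophicMap",
    "DistanceMatrix",
    "TROPHIC_LABELS",
    "to_relative",
    "rare_biosphere",
    "trophic_subset",
]


@dataclass
class AbundanceTable:
    """Non-negative taxon x sample abundance matrix.

    Parameters
    ----------
    data
        DataFrame with taxa as the index and samples as the columns.
    is_relative
        True when every sample column sums to one (relative abundances).
    """

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.validate()

    # -- basic views -------------------------------------------------
    @property
    def taxa_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """taxa x samples matrix as a float array."""
        return self.data.to_numpy()

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def validate(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate taxon identifiers: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundance table contains negative entries")
        if self.is_relative:
            sums = self.data.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("is_relative set but columns do not sum to 1")

    # -- convenience -------------------------------------------------
    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def taxon_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def select_taxa(self, taxa: Iterable[str]) -> "AbundanceTable":
        taxa = [t for t in self.taxa_ids if t in set(taxa)]
        return AbundanceTable(self.data.loc[taxa], is_relative=False)

    def select_samples(self, samples: Iterable[str]) -> "AbundanceTable":
        samples = [s for s in self.sample_ids if s in set(samples)]
        return AbundanceTable(self.data[samples], is_relative=self.is_relative)

    def has_integer_counts(self) -> bool:
        vals = self.data.to_numpy()
        return bool(np.all(vals == np.round(vals)))


@dataclass
class SampleMetadata:
    """Per-sample station metadata: group label, coordinates, environment.

    ``frame`` is indexed by sample id and must carry a ``group`` column;
    ``latitude`` / ``longitude`` are decimal degrees.  All remaining numeric
    columns are treated as environmental variables; empty cells are missing.
    """

    frame: pd.DataFrame
    group_col: str = "group"
    lat_col: str = "latitude"
    lon_col: str = "longitude"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.frame.index.duplicated().any():
            raise ValueError("duplicate sample identifiers in metadata")
        if self.lat_col in self.frame:
            lat = self.frame[self.lat_col].dropna()
            if ((lat < -90) | (lat > 90)).any():
                raise ValueError("latitude outside [-90, 90]")
        if self.lon_col in self.frame:
            lon = self.frame[self.lon_col].dropna()
            if ((lon < -180) | (lon > 180)).any():
                raise ValueError("longitude outside [-180, 180]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def groups(self) -> pd.Series:
        if self.group_col not in self.frame:
            raise KeyError(f"metadata lacks a '{self.group_col}' column")
        return self.frame[self.group_col]

    def coordinates(self) -> pd.DataFrame:
        return self.frame[[self.lat_col, self.lon_col]].astype(float)

    def env_frame(self) -> pd.DataFrame:
        """Numeric environmental variables (excludes coordinates)."""
        skip = {self.group_col, self.lat_col, self.lon_col}
        cols = [
            c
            for c in self.frame.columns
            if c not in skip and pd.api.types.is_numeric_dtype(self.frame[c])
        ]
        return self.frame[cols].astype(float)

    def subset(self, samples: Iterable[str]) -> "SampleMetadata":
        samples = [s for s in self.sample_ids if s in set(samples)]
        return SampleMetadata(
            self.frame.loc[samples], self.group_col, self.lat_col, self.lon_col
        )


@dataclass
class TrophicMap:
    """taxon id -> trophic label ('chloroplast_containing' or 'heterotroph')."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {v for v in self.mapping.values()} - set(TROPHIC_LABELS)
        if bad:
            raise ValueError(
                f"invalid trophic labels {sorted(bad)}; allowed: {TROPHIC_LABELS}"
            )

    def taxa_with(self, label: str) -> list[str]:
        if label not in TROPHIC_LABELS:
            raise ValueError(f"label {label!r} not in {TROPHIC_LABELS}")
        return [t for t, v in self.mapping.items() if v == label]


# ---------------------------------------------------------------------------
# Table-level operations
# ---------------------------------------------------------------------------

def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to per-sample relative abundances (columns sum to 1)."""
    if table.is_relative:
        return table
    totals = table.sample_totals()
    empty = totals[totals <= 0]
    if len(empty):
        raise ValueError(f"samples with zero total count: {list(empty.index)}")
    rel = table.data.div(totals, axis=1)
    return AbundanceTable(rel, is_relative=True)


def rare_biosphere(table: AbundanceTable, threshold: float = 1e-4) -> AbundanceTable:
    """Subset to rare taxa: study-wide relative abundance strictly below
    ``threshold`` (default 0.01%).

    Rarity is assessed on taxon totals relative to the grand total of the
    raw count table; the sample set is unchanged.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    grand = float(table.data.to_numpy().sum())
    if grand <= 0:
        raise ValueError("empty table")
    frac = table.taxon_totals() / grand
    keep = frac.index[frac < threshold]
    return AbundanceTable(table.data.loc[keep], is_relative=False)


def trophic_subset(
    table: AbundanceTable, trophic_map: TrophicMap, label: str
) -> AbundanceTable:
    """Restrict the table to taxa carrying a trophic ``label``.

    Taxa absent from the map are excluded from either subset; a warning
    reports how many were unmapped.
    """
    if label not in TROPHIC_LABELS:
        raise ValueError(f"label {label!r} not in {TROPHIC_LABELS}")
    mapped = set(trophic_map.mapping)
    unmapped = [t for t in table.taxa_ids if t not in mapped]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} taxa lack a trophic assignment and were dropped",
            stacklevel=2,
        )
    keep = [t for t in table.taxa_ids if trophic_map.mapping.get(t) == label]
    return AbundanceTable(table.data.loc[keep], is_relative=False)
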