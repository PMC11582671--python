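"""Environmental-context analyses.

Stations are standardized per variable (z-scores), compared with a
Euclidean distance matrix tolerating missing values by pairwise deletion,
clustered hierarchically, and contrasted between station groups with
Welch's unequal-variance t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.cluster.hierarchy import linkage
from skbio import DistanceMatrix

from .containers import SampleMetadata

__all__ = [
    "ZScoreMatrix",
    "Dendrogram",
    "zscore",
    "euclidean_distance",
    "hclust_complete",
    "welch_t",
]


@dataclass
class ZScoreMatrix:
    """Station x variable standardized values with the moments used."""

    values: pd.DataFrame          # NaN = missing
    means: pd.Series
    sds: pd.Series

    @property
    def stations(self) -> list[str]:
        return list(self.values.index)


@dataclass
class Dendrogram:
    """Hierarchical-clustering result: scipy linkage plus leaf labels.

    ``heights`` are the node heights used when writing Newick; for
    average linkage (UPGMA) they are merge distance / 2, for complete
    linkage the merge distance itself.
    """

    linkage_matrix: np.ndarray
    labels: list[str]
    heights: np.ndarray

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of every internal node."""
        n = len(self.labels)
        sets: dict[int, frozenset[str]] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        out = []
        for k, (a, b, *_rest) in enumerate(self.linkage_matrix):
            merged = sets[int(a)] | sets[int(b)]
            sets[n + k] = merged
            out.append(merged)
        return out

    def to_newick(self) -> str:
        n = len(self.labels)
        node: dict[int, str] = {}
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        for i, lab in enumerate(self.labels):
            node[i] = lab
        for k, (a, b, *_rest) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            h = float(self.heights[k])
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[n + k] = f"({node[a]}:{la:.10g},{node[b]}:{lb:.10g})"
            height[n + k] = h
        return node[n + len(self.linkage_matrix) - 1] + ";"


def zscore(metadata: SampleMetadata | pd.DataFrame) -> ZScoreMatrix:
    """Standardize each environmental variable to mean 0, sample sd 1.

    Missing entries stay missing; a constant variable maps to zeros with a
    warning.  Variables observed fewer than twice are an error.
    """
    env = metadata.env_frame() if isinstance(metadata, SampleMetadata) else metadata
    env = env.astype(float)
    means, sds, cols = {}, {}, {}
    for c in env.columns:
        x = env[c]
        obs = x.dropna()
        if len(obs) < 2:
            raise ValueError(f"variable {c!r} has fewer than 2 observations")
        mu = obs.mean()
        sd = obs.std(ddof=1)
        if sd == 0:
            warnings.warn(f"variable {c!r} is constant; z-scores set to 0", stacklevel=2)
            cols[c] = x * 0.0
            sd = 0.0
        else:
            cols[c] = (x - mu) / sd
        means[c], sds[c] = mu, sd
    return ZScoreMatrix(pd.DataFrame(cols), pd.Series(means), pd.Series(sds))


def euclidean_distance(z: ZScoreMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances with pairwise deletion of missing values.

    Each pair is compared only on variables observed in both stations; no
    rescaling for the number of shared variables is applied, matching the
    NA behaviour of the common R distance routines.
    """
    X = z.values.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 stations")
    obs = ~np.isnan(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = obs[i] & obs[j]
            if not shared.any():
                raise ValueError(
                    f"stations {z.stations[i]!r} and {z.stations[j]!r} share no "
                    "observed variables"
                )
            diff = X[i, shared] - X[j, shared]
            D[i, j] = D[j, i] = float(np.sqrt((diff**2).sum()))
    return DistanceMatrix(D, ids=z.stations)


def _hclust(dm: DistanceMatrix, method: str, halve_heights: bool) -> Dendrogram:
    if dm.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = linkage(dm.condensed_form(), method=method)
    heights = Z[:, 2] / 2.0 if halve_heights else Z[:, 2].copy()
    return Dendrogram(Z, list(dm.ids), heights)


def hclust_complete(dm: DistanceMatrix) -> Dendrogram:
    """Complete-linkage hierarchical clustering (ties by smallest index)."""
    return _hclust(dm, "complete", halve_heights=False)


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's two-sample t-test: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
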