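"""Beta diversity, ordination and group tests.

Distances: Bray-Curtis plus unweighted and (normalized) weighted UniFrac.
Ordination: non-metric multidimensional scaling (Kruskal stress-1).
Group tests: one-factor PERMANOVA (pseudo-F on a distance matrix with a
permutation p-value) and PERMDISP-style homogeneity of dispersion
(distance to group spatial medians in principal-coordinate space, classical
one-way ANOVA).  Sample clustering: UPGMA, optionally as a majority-rule
consensus over rarefaction iterations with clade supports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity as _skbio_beta
from sklearn.manifold import MDS

from .alpha import rarefy
from .containers import AbundanceTable
from .env import Dendrogram, _hclust

__all__ = [
    "OrdinationResult",
    "PermanovaResult",
    "ConsensusTree",
    "bray_curtis",
    "unifrac_unweighted",
    "unifrac_weighted",
    "nmds",
    "permanova",
    "permdisp",
    "upgma",
    "consensus_upgma",
]


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _check_nonempty(table: AbundanceTable) -> None:
    totals = table.sample_totals()
    empty = totals[totals <= 0]
    if len(empty):
        raise ValueError(f"samples with no taxa: {list(empty.index)}")


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, 1 - 2*sum(min)/(sum_x + sum_y)."""
    _check_nonempty(table)
    X = table.counts.T  # samples x taxa
    return DistanceMatrix(squareform(pdist(X, metric="braycurtis")),
                          ids=table.sample_ids)


def unifrac_unweighted(table: AbundanceTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: unique / total branch length per sample pair."""
    _check_nonempty(table)
    return _skbio_beta(
        "unweighted_unifrac",
        table.counts.T,
        ids=table.sample_ids,
        taxa=table.taxa_ids,
        tree=tree,
    )


def unifrac_weighted(
    table: AbundanceTable, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac on per-sample branch abundance proportions."""
    _check_nonempty(table)
    return _skbio_beta(
        "weighted_unifrac",
        table.counts.T,
        ids=table.sample_ids,
        taxa=table.taxa_ids,
        tree=tree,
        normalized=normalized,
    )


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    converged: bool
    n_starts: int


def _pcoa_coords(D: np.ndarray, k: int) -> np.ndarray:
    """Classical scaling start: top-k principal coordinates."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1][:k]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return coords


def nmds(
    dm: DistanceMatrix, k: int = 2, n_starts: int = 20, seed: int = 0
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1; best of ``n_starts``
    random starts plus one principal-coordinates start."""
    D = dm.data
    if D.shape[0] < k + 1:
        raise ValueError("need at least k+1 samples")
    if np.allclose(D, 0):
        raise ValueError("all distances are zero")
    rng = np.random.default_rng(seed)
    best_X, best_stress = None, np.inf
    n = D.shape[0]
    inits: list = [_pcoa_coords(D, k)]
    inits += [rng.standard_normal((n, k)) for _ in range(max(n_starts - 1, 0))]
    for init in inits:
        m = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            n_init=1,
            init="random",  # overridden by the explicit start below
            max_iter=500,
            random_state=int(rng.integers(2**31)),
            normalized_stress=True,
        )
        X = m.fit_transform(D, init=init)
        if m.stress_ < best_stress:
            best_stress, best_X = float(m.stress_), X
    coords = pd.DataFrame(
        best_X, index=dm.ids, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(coords, best_stress, best_stress < 0.3, len(inits))


# ---------------------------------------------------------------------------
# PERMANOVA / PERMDISP
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    pseudo_f: float
    r2: float
    p_value: float
    n_perm: int


def _permanova_ss(D2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer labels."""
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-factor PERMANOVA (adonis-style) with label-permutation p-value."""
    labels = pd.Series(groups)
    if hasattr(groups, "loc"):
        labels = labels.loc[list(dm.ids)]
    labels = pd.factorize(labels.to_numpy())[0]
    a = len(np.unique(labels))
    n = dm.shape[0]
    if a < 2:
        raise ValueError("need at least 2 groups")
    D2 = dm.data**2
    ss_total, ss_within = _permanova_ss(D2, labels)
    ss_between = ss_total - ss_within
    df_b, df_w = a - 1, n - a
    f_obs = (ss_between / df_b) / (ss_within / df_w)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        sst, ssw = _permanova_ss(D2, perm)
        f_perm = ((sst - ssw) / df_b) / (ssw / df_w)
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(
        ss_between, ss_within, ss_total, df_b, df_w, float(f_obs),
        float(ss_between / ss_total), float(p), n_perm,
    )


def _spatial_median(X: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Weiszfeld algorithm for the geometric (spatial) median."""
    m = X.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(X - m, axis=1)
        if (d < 1e-12).any():
            return m
        w = 1.0 / d
        new = (X * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - m) < tol:
            return new
        m = new
    return m


def permdisp(
    dm: DistanceMatrix, groups, center: str = "median"
) -> tuple[float, float]:
    """Homogeneity of group dispersions (betadisper-style) + one-way ANOVA.

    Samples are embedded by principal coordinates retaining negative
    eigenvalues; the distance of a sample to its group centre combines the
    real- and imaginary-axis components as sqrt(|d_real^2 - d_imag^2|).
    Returns the classical ANOVA (F, p) on those distances.
    """
    if center not in ("median", "centroid"):
        raise ValueError("center must be 'median' or 'centroid'")
    labels = pd.Series(groups)
    if hasattr(groups, "loc"):
        labels = labels.loc[list(dm.ids)]
    codes = pd.factorize(labels.to_numpy())[0]
    if len(np.unique(codes)) < 2:
        raise ValueError("need at least 2 groups")
    D = dm.data
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    neg = vals < -1e-10
    Xr = vecs[:, pos] * np.sqrt(vals[pos])
    Xi = vecs[:, neg] * np.sqrt(-vals[neg])

    dists = np.zeros(n)
    for g in np.unique(codes):
        idx = np.flatnonzero(codes == g)
        if center == "median":
            cr = _spatial_median(Xr[idx]) if Xr.shape[1] else np.zeros(0)
            ci = _spatial_median(Xi[idx]) if Xi.shape[1] else np.zeros(0)
        else:
            cr = Xr[idx].mean(axis=0) if Xr.shape[1] else np.zeros(0)
            ci = Xi[idx].mean(axis=0) if Xi.shape[1] else np.zeros(0)
        dr2 = ((Xr[idx] - cr) ** 2).sum(axis=1) if Xr.shape[1] else np.zeros(len(idx))
        di2 = ((Xi[idx] - ci) ** 2).sum(axis=1) if Xi.shape[1] else np.zeros(len(idx))
        dists[idx] = np.sqrt(np.abs(dr2 - di2))
    if np.allclose(dists, dists[0]):
        raise ValueError("all dispersion distances identical; ANOVA undefined")
    samples = [dists[codes == g] for g in np.unique(codes)]
    if all(len(s) == 1 for s in samples):
        raise ValueError("every group has a single sample")
    f, p = scipy.stats.f_oneway(*samples)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# UPGMA and consensus
# ---------------------------------------------------------------------------

def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage clustering; Newick heights are merge distance / 2."""
    return _hclust(dm, "average", halve_heights=True)


@dataclass
class ConsensusTree:
    """Majority-rule consensus of rooted dendrograms with clade supports."""

    clades: dict[frozenset[str], float]     # clade -> support in [0, 1]
    labels: list[str]
    n_iterations: int = 0
    newick: str = ""


def _consensus_newick(clades: dict[frozenset[str], float], labels: list[str]) -> str:
    # nest clades; every clade carries its support as an internal label
    def build(members: frozenset[str], children: list[frozenset[str]],
              support: float | None) -> str:
        direct: list[frozenset[str]] = []
        for c in sorted(children, key=len, reverse=True):
            if c < members and not any(c < d for d in direct):
                direct.append(c)
        covered = frozenset().union(*direct) if direct else frozenset()
        parts = [
            build(c, [d for d in children if d < c], clades.get(c))
            for c in sorted(direct, key=lambda s: sorted(s)[0])
        ]
        parts += [m for m in sorted(members - covered)]
        inner = ",".join(parts)
        lab = f"{support:.3g}" if support is not None else ""
        return f"({inner}){lab}"

    all_members = frozenset(labels)
    children = [c for c in clades if c != all_members]
    return build(all_members, children, clades.get(all_members)) + ";"


def consensus_upgma(
    table: AbundanceTable,
    tree: TreeNode,
    depth: int = 20000,
    n_iter: int = 1000,
    metric: str = "weighted_unifrac",
    seed: int = 0,
) -> ConsensusTree:
    """Rarefaction-resampled UPGMA consensus with clade supports.

    Per iteration: rarefy -> distance -> UPGMA.  Clades occurring in more
    than half of the iterations enter the consensus; support is the clade's
    frequency across iterations.
    """
    metrics = {
        "weighted_unifrac": lambda t: unifrac_weighted(t, tree),
        "unweighted_unifrac": lambda t: unifrac_unweighted(t, tree),
        "bray_curtis": bray_curtis,
    }
    if metric not in metrics:
        raise ValueError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    labels: list[str] | None = None
    for _ in range(n_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rt = rarefy(table, depth, seed=int(rng.integers(2**31)))
        dend = upgma(metrics[metric](rt))
        if labels is None:
            labels = dend.labels
        for clade in dend.clades():
            counts[clade] = counts.get(clade, 0) + 1
    assert labels is not None
    supports = {c: k / n_iter for c, k in counts.items() if k / n_iter > 0.5}
    ct = ConsensusTree(supports, sorted(labels), n_iter)
    ct.newick = _consensus_newick(supports, ct.labels)
    return ct
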