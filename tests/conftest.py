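"""Shared fixtures: tiny trees and tables, plus independent oracle helpers.

The oracle functions here are deliberately naive (explicit loops and tree
traversals) so they stay independent of the vectorized implementations they
check.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from commsig.containers import AbundanceTable


def make_tree(newick: str) -> TreeNode:
    tree = TreeNode.read(io.StringIO(newick))
    for n in tree.traverse(include_self=True):
        if n.length is None:
            n.length = 0.0
    return tree


@pytest.fixture
def star_tree() -> TreeNode:
    """Four unit branches from the root."""
    return make_tree("(A:1,B:1,C:1,D:1):0;")


@pytest.fixture
def rooted_star_tree() -> TreeNode:
    """Star geometry (unit tip branches) with a bifurcating zero-length root."""
    return make_tree("((A:1,B:1):0,(C:1,D:1):0):0;")


@pytest.fixture
def balanced_tree() -> TreeNode:
    return make_tree("((A:1,B:1):1,(C:1,D:1):1):0;")


@pytest.fixture
def ladder_tree() -> TreeNode:
    """Caterpillar over 8 tips, unit branches."""
    nwk = "(((((((A:1,B:1):1,C:1):1,D:1):1,E:1):1,F:1):1,G:1):1,H:1):0;"
    return make_tree(nwk)


@pytest.fixture
def small_table() -> AbundanceTable:
    data = pd.DataFrame(
        {"s1": [5, 3, 0, 2], "s2": [0, 1, 4, 5], "s3": [2, 2, 2, 2]},
        index=["A", "B", "C", "D"],
    )
    return AbundanceTable(data)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def branch_iter(tree: TreeNode):
    """(length, set of descendant tip names) for every non-root branch."""
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips(include_self=True)}
        yield float(node.length or 0.0), tips


def oracle_faith_pd(taxa: set[str], tree: TreeNode) -> float:
    return sum(l for l, tips in branch_iter(tree) if tips & taxa)


def oracle_mpd_weighted(f: np.ndarray, D: np.ndarray) -> float:
    num = den = 0.0
    n = len(f)
    for i in range(n):
        for j in range(n):
            if i != j:
                num += D[i, j] * f[i] * f[j]
                den += f[i] * f[j]
    return num / den


def oracle_bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    return 1.0 - 2.0 * np.minimum(x, y).sum() / (x.sum() + y.sum())


def oracle_unweighted_unifrac(a: set[str], b: set[str], tree: TreeNode) -> float:
    unique = shared_or_either = 0.0
    for l, tips in branch_iter(tree):
        in_a, in_b = bool(tips & a), bool(tips & b)
        if in_a or in_b:
            shared_or_either += l
            if in_a != in_b:
                unique += l
    return unique / shared_or_either


def oracle_weighted_unifrac(
    x: np.ndarray, y: np.ndarray, taxa: list[str], tree: TreeNode,
    normalized: bool = True,
) -> float:
    px = {t: v / x.sum() for t, v in zip(taxa, x)}
    py = {t: v / y.sum() for t, v in zip(taxa, y)}
    num = den = 0.0
    for l, tips in branch_iter(tree):
        pa = sum(px.get(t, 0.0) for t in tips)
        pb = sum(py.get(t, 0.0) for t in tips)
        num += l * abs(pa - pb)
        den += l * (pa + pb)
    if not normalized:
        return num
    return num / den


def oracle_upgma(D: np.ndarray, labels: list[str]):
    """Naive UPGMA; returns merge list [(clade_set, height), ...]."""
    clusters = {i: frozenset([labels[i]]) for i in range(len(labels))}
    sizes = {i: 1 for i in clusters}
    dist = {
        (i, j): D[i, j]
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    merges = []
    nxt = len(labels)
    while len(clusters) > 1:
        (i, j), dmin = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merged = clusters[i] | clusters[j]
        merges.append((merged, dmin / 2.0))
        new_d = {}
        for k in clusters:
            if k in (i, j):
                continue
            a = dist.get((min(i, k), max(i, k)))
            b = dist.get((min(j, k), max(j, k)))
            new_d[k] = (a * sizes[i] + b * sizes[j]) / (sizes[i] + sizes[j])
        del clusters[i], clusters[j]
        dist = {
            (a, b): v for (a, b), v in dist.items()
            if a not in (i, j) and b not in (i, j)
        }
        clusters[nxt] = merged
        sizes[nxt] = len(merged)
        for k, v in new_d.items():
            dist[(min(k, nxt), max(k, nxt))] = v
        nxt += 1
    return merges


def oracle_asv_index(V: np.ndarray, W: np.ndarray, H: np.ndarray):
    """Straight-from-the-equations index: rho * cos * score per (i, k)."""
    import scipy.stats

    n_taxa, n_samples = V.shape
    q = W.shape[1]
    rho = np.zeros((n_taxa, q))
    cos = np.zeros((n_taxa, q))
    score = np.zeros(n_taxa)
    for i in range(n_taxa):
        p = W[i] / W[i].sum()
        s = 0.0
        for k in range(q):
            if p[k] > 0:
                s += p[k] * np.log2(p[k])
        score[i] = 1.0 + s / np.log2(q)
        a = V[i] / np.linalg.norm(V[i])
        for k in range(q):
            r, _ = scipy.stats.spearmanr(V[i], H[k])
            rho[i, k] = r
            cos[i, k] = float(np.dot(a, H[k] / np.linalg.norm(H[k])))
    return rho, cos, score, rho * cos * score[:, None]
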