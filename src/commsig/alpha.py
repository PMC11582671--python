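"""Alpha diversity under rarefaction and phylogenetic structure statistics.

Per-sample species richness (SR), Faith's phylogenetic diversity (PD) and
the Simpson index are averaged over repeated rarefactions to an even depth.
Community phylogenetic structure is measured by the standardized effect
size of abundance-weighted mean pairwise distance (SES_MPD) — reported as
the net relatedness index NRI = -SES_MPD, positive for phylogenetic
clustering — and by SES of Faith's PD against an equal-richness null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import AbundanceTable
from .phylo import BranchMatrix, patristic_distances

__all__ = [
    "AlphaResult",
    "SESResult",
    "rarefy",
    "faith_pd",
    "simpson",
    "rarefied_alpha",
    "mpd_weighted",
    "nri",
    "ses_pd",
]


@dataclass
class AlphaResult:
    """Mean per-sample SR / PD / Simpson over rarefaction iterations."""

    summary: pd.DataFrame            # index: samples; columns: SR, PD, simpson
    depth: int
    n_iterations: int
    per_iteration: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class SESResult:
    """Observed statistic vs a randomization null."""

    observed: float
    null_mean: float
    null_sd: float
    n_null: int

    @property
    def ses(self) -> float:
        if self.null_sd == 0 or not np.isfinite(self.null_sd):
            return float("nan")
        return (self.observed - self.null_mean) / self.null_sd

    @property
    def nri(self) -> float:
        return -self.ses


def rarefy(table: AbundanceTable, depth: int, seed: int = 0) -> AbundanceTable:
    """Subsample each sample to ``depth`` sequences without replacement.

    Uses the multivariate hypergeometric distribution per sample; samples
    with fewer than ``depth`` sequences are dropped with a warning.
    """
    if not table.has_integer_counts():
        raise ValueError("rarefaction requires integer counts")
    rng = np.random.default_rng(seed)
    counts = table.counts.astype(np.int64)
    totals = counts.sum(axis=0)
    keep = totals >= depth
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        warnings.warn(
            f"{len(dropped)} samples below depth {depth} dropped: {dropped[:10]}",
            stacklevel=2,
        )
    out = np.zeros((counts.shape[0], int(keep.sum())), dtype=np.int64)
    kept_ids = []
    j = 0
    for s, ok in enumerate(keep):
        if not ok:
            continue
        out[:, j] = rng.multivariate_hypergeometric(counts[:, s], depth)
        kept_ids.append(table.sample_ids[s])
        j += 1
    return AbundanceTable(
        pd.DataFrame(out, index=table.taxa_ids, columns=kept_ids)
    )


def faith_pd(
    sample_taxa,
    tree: TreeNode,
    branch_matrix: BranchMatrix | None = None,
    include_root: bool = True,
) -> float:
    """Faith's PD: branch length of the minimal subtree spanning the
    present taxa and (by default) the root."""
    bm = branch_matrix or BranchMatrix.from_tree(tree)
    taxa = set(sample_taxa)
    if not taxa:
        raise ValueError("empty taxon set")
    missing = taxa - set(bm.taxa)
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)[:10]}")
    presence = np.array([t in taxa for t in bm.taxa])
    return bm.pd(presence, include_root=include_root)


def simpson(sample_counts) -> float:
    """Simpson diversity 1 - sum(p_i^2)."""
    x = np.asarray(sample_counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("empty sample")
    p = x / total
    return float(1.0 - (p**2).sum())


def rarefied_alpha(
    table: AbundanceTable,
    tree: TreeNode,
    depth: int,
    n_iter: int = 100,
    seed: int = 0,
    include_root: bool = True,
) -> AlphaResult:
    """Mean SR, Faith's PD and Simpson over ``n_iter`` rarefactions."""
    bm = BranchMatrix.from_tree(tree, table.taxa_ids)
    rng = np.random.default_rng(seed)
    first = rarefy(table, depth, seed=int(rng.integers(2**31)))
    samples = first.sample_ids
    sr = np.zeros((n_iter, len(samples)))
    pdv = np.zeros((n_iter, len(samples)))
    sim = np.zeros((n_iter, len(samples)))

    def _accumulate(i: int, rt: AbundanceTable) -> None:
        X = rt.data[samples].to_numpy()
        sr[i] = (X > 0).sum(axis=0)
        pdv[i] = bm.pd_many(X > 0, include_root=include_root)
        p = X / X.sum(axis=0, keepdims=True)
        sim[i] = 1.0 - (p**2).sum(axis=0)

    _accumulate(0, first)
    for i in range(1, n_iter):
        _accumulate(i, rarefy(table, depth, seed=int(rng.integers(2**31))))

    summary = pd.DataFrame(
        {"SR": sr.mean(axis=0), "PD": pdv.mean(axis=0), "simpson": sim.mean(axis=0)},
        index=samples,
    )
    return AlphaResult(summary, depth, n_iter, {"SR": sr, "PD": pdv, "simpson": sim})


def mpd_weighted(rel_abund, patristic: np.ndarray) -> float:
    """Abundance-weighted mean pairwise patristic distance.

    MPD = sum_{i!=j} d_ij f_i f_j / sum_{i!=j} f_i f_j.
    """
    f = np.asarray(rel_abund, dtype=float)
    if (f > 0).sum() < 2:
        raise ValueError("need at least 2 taxa with positive abundance")
    num = f @ patristic @ f          # diagonal of d is 0
    den = f.sum() ** 2 - (f**2).sum()
    return float(num / den)


def nri(
    sample,
    tree: TreeNode | None = None,
    n_null: int = 1000,
    seed: int = 0,
    patristic: np.ndarray | None = None,
    taxa: list[str] | None = None,
) -> SESResult:
    """SES of abundance-weighted MPD via permutation of the abundance vector.

    The null permutes the sample's relative-abundance vector across *all*
    taxa of the tree (label shuffle); SES = (obs - null mean)/null sd and
    NRI = -SES.  A degenerate null (sd 0) yields NaN with a warning.
    """
    f = np.asarray(sample, dtype=float)
    if patristic is None:
        if tree is None:
            raise ValueError("provide a tree or a precomputed patristic matrix")
        taxa = taxa or [t.name for t in tree.tips()]
        patristic = patristic_distances(tree, taxa)
    total = f.sum()
    if total <= 0:
        raise ValueError("empty sample")
    f = f / total
    obs = mpd_weighted(f, patristic)
    rng = np.random.default_rng(seed)
    n = len(f)
    perms = np.empty((n_null, n))
    for b in range(n_null):
        perms[b] = f[rng.permutation(n)]
    num = ((perms @ patristic) * perms).sum(axis=1)
    den = perms.sum(axis=1) ** 2 - (perms**2).sum(axis=1)
    nulls = num / den
    sd = float(nulls.std(ddof=1))
    if sd == 0:
        warnings.warn("degenerate MPD null (sd = 0); NRI is NaN", stacklevel=2)
    return SESResult(obs, float(nulls.mean()), sd, n_null)


def ses_pd(
    sample,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    branch_matrix: BranchMatrix | None = None,
    include_root: bool = True,
) -> SESResult:
    """SES of Faith's PD against a richness-preserving random-leaf null."""
    bm = branch_matrix or BranchMatrix.from_tree(tree)
    presence = np.asarray(sample, dtype=float) > 0
    if not presence.any():
        raise ValueError("empty sample")
    k = int(presence.sum())
    n = len(presence)
    obs = bm.pd(presence, include_root=include_root)
    if k == n:
        warnings.warn("sample contains every leaf; SES_PD null is degenerate",
                      stacklevel=2)
        return SESResult(obs, obs, 0.0, n_null)
    rng = np.random.default_rng(seed)
    nulls_presence = np.zeros((n, n_null), dtype=bool)
    for b in range(n_null):
        nulls_presence[rng.choice(n, size=k, replace=False), b] = True
    nulls = bm.pd_many(nulls_presence, include_root=include_root)
    sd = float(nulls.std(ddof=1))
    if sd == 0:
        warnings.warn("degenerate PD null (sd = 0); SES_PD is NaN", stacklevel=2)
    return SESResult(obs, float(nulls.mean()), sd, n_null)
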