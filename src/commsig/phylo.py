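"""Branch-level tree machinery shared by the diversity modules.

Faith's PD, MPD nulls and rarefaction loops all reduce to linear algebra
over a branch incidence matrix: row b of ``incidence`` flags the tips that
descend from branch b.  Building it once per tree makes 100-iteration
rarefaction and 1000-draw null models cheap matrix products instead of
repeated tree traversals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

__all__ = ["BranchMatrix", "patristic_distances"]


@dataclass
class BranchMatrix:
    """Branch lengths plus a branches x taxa descendant-incidence matrix."""

    taxa: list[str]
    lengths: np.ndarray          # (n_branches,)
    incidence: np.ndarray        # (n_branches, n_taxa) boolean

    @classmethod
    def from_tree(cls, tree: TreeNode, taxa: list[str] | None = None) -> "BranchMatrix":
        tips = [t.name for t in tree.tips()]
        if taxa is None:
            taxa = tips
        missing = set(taxa) - set(tips)
        if missing:
            raise ValueError(f"taxa not in tree: {sorted(missing)[:10]}")
        col = {name: j for j, name in enumerate(taxa)}
        rows, lengths = [], []
        # every non-root node contributes the branch above it
        for node in tree.postorder(include_self=False):
            mask = np.zeros(len(taxa), dtype=bool)
            for tip in node.tips(include_self=True):
                j = col.get(tip.name)
                if j is not None:
                    mask[j] = True
            if mask.any():
                rows.append(mask)
                lengths.append(float(node.length or 0.0))
        return cls(list(taxa), np.asarray(lengths), np.asarray(rows))

    # -- Faith's PD ---------------------------------------------------
    def pd(self, presence: np.ndarray, include_root: bool = True) -> float:
        """Faith's phylogenetic diversity of one presence/absence vector.

        The minimal spanning subtree always includes the path to the root;
        ``include_root=False`` instead drops branches shared by *all*
        present taxa (the crown-group variant).
        """
        presence = np.asarray(presence, dtype=bool)
        if not presence.any():
            raise ValueError("empty taxon set")
        spanned = self.incidence @ presence > 0
        if not include_root:
            n_present = int(presence.sum())
            on_all = (self.incidence @ presence) == n_present
            spanned &= ~on_all
        return float(self.lengths[spanned].sum())

    def pd_many(self, presence: np.ndarray, include_root: bool = True) -> np.ndarray:
        """PD for each column of a taxa x k presence matrix."""
        P = np.asarray(presence, dtype=bool)
        counts = self.incidence.astype(np.float64) @ P
        spanned = counts > 0
        if not include_root:
            spanned &= counts < P.sum(axis=0)[None, :]
        return self.lengths @ spanned

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())


def patristic_distances(tree: TreeNode, taxa: list[str]) -> np.ndarray:
    """Dense tip-to-tip patristic distance matrix in ``taxa`` order."""
    dm = tree.tip_tip_distances()
    idx = [dm.index(t) for t in taxa]
    return dm.data[np.ix_(idx, idx)]
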