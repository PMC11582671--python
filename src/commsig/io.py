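"""Readers, writers and dataset-level validation.

File conventions: count tables are TSV with taxa as rows (first column =
taxon id) and samples as columns; trees are Newick with branch lengths;
metadata is a TSV with a header row and empty cells for missing values;
trophic maps are two-column TSV (taxon id, label).  Distance matrices are
written as labelled square TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .containers import AbundanceTable, SampleMetadata, TrophicMap

__all__ = [
    "read_table",
    "write_table",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "read_trophic_map",
    "write_trophic_map",
    "read_distance_matrix",
    "write_distance_matrix",
    "load_dataset",
]


def read_table(path: str | Path, transpose: bool = False) -> AbundanceTable:
    """Read a taxa-x-samples count TSV; ``transpose`` for the other dialect."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AbundanceTable(df)


def write_table(table: AbundanceTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="taxon_id")


def read_tree(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(f"negative branch length on node {node.name!r}")
    tree.length = 0.0  # a root edge carries no information
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_metadata(
    path: str | Path,
    group_col: str = "group",
    lat_col: str = "latitude",
    lon_col: str = "longitude",
) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df, group_col=group_col, lat_col=lat_col, lon_col=lon_col)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_trophic_map(path: str | Path) -> TrophicMap:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("trophic map must have two columns (taxon id, label)")
    return TrophicMap(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_trophic_map(trophic_map: TrophicMap, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(trophic_map.mapping.items()), columns=["taxon_id", "trophic_mode"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="id"
    )


def _check_rooted(tree: TreeNode) -> None:
    root_children = len(tree.children)
    if root_children > 2:
        raise ValueError(
            f"tree appears unrooted (root has {root_children} children); "
            "root it before loading"
        )


def load_dataset(
    table_path: str | Path,
    tree_path: str | Path,
    metadata_path: str | Path,
    prune: bool = False,
    transpose: bool = False,
    group_col: str = "group",
) -> tuple[AbundanceTable, TreeNode, SampleMetadata]:
    """Load and cross-validate a table / tree / metadata triple.

    Every table taxon must be a tree leaf and every table sample must appear
    in the metadata.  With ``prune=True`` the tree is sheared down to the
    table's taxa instead of erroring on extra leaves; taxa missing from the
    tree are always a hard error (silent data loss is never acceptable).
    """
    table = read_table(table_path, transpose=transpose)
    tree = read_tree(tree_path)
    metadata = read_metadata(metadata_path, group_col=group_col)
    _check_rooted(tree)

    leaves = {t.name for t in tree.tips()}
    missing_from_tree = sorted(set(table.taxa_ids) - leaves)
    if missing_from_tree:
        raise ValueError(
            f"{len(missing_from_tree)} table taxa absent from the tree: "
            f"{missing_from_tree[:10]}"
        )
    extra = leaves - set(table.taxa_ids)
    if extra:
        if not prune:
            raise ValueError(
                f"tree has {len(extra)} leaves absent from the table "
                f"(pass prune=True to shear): {sorted(extra)[:10]}"
            )
        tree = tree.shear(table.taxa_ids)
        tree.prune()

    missing_meta = sorted(set(table.sample_ids) - set(metadata.sample_ids))
    if missing_meta:
        raise ValueError(f"samples missing from metadata: {missing_meta[:10]}")
    metadata = metadata.subset(table.sample_ids)
    return table, tree, metadata
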