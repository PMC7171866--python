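"""Rooted phylogenies: Newick I/O, validation and cophenetic distances.

Trees are represented by :class:`skbio.TreeNode`.  The helpers here enforce
the contracts the assembly metrics rely on: a rooted topology, unique tip
labels and branch lengths on every edge (phylogenetic distances are in
branch-length units).
"""

from __future__ import annotations

import io

import numpy as np
import skbio

from .distances import DistanceMatrix


class TreeError(ValueError):
    """Raised for malformed or unusable phylogenies."""


def _validate(tree: skbio.TreeNode, allow_zero_lengths: bool) -> skbio.TreeNode:
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise TreeError("duplicate tip labels")
    if None in tips:
        raise TreeError("unnamed tip in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if allow_zero_lengths:
                node.length = 0.0
            else:
                raise TreeError(
                    "missing branch length (pass allow_zero_lengths=True to "
                    "treat absent lengths as zero)"
                )
        elif node.length < 0:
            raise TreeError(f"negative branch length on {node.name or 'internal node'}")
    if tree.length is None:
        tree.length = 0.0
    return tree


def read_tree(source, midpoint_root: bool = False,
              allow_zero_lengths: bool = False) -> skbio.TreeNode:
    """Parse a rooted Newick tree with branch lengths.

    ``source`` may be a path or a Newick string.  A basal polytomy (>= 3
    children at the root) is rejected unless ``midpoint_root`` is set, in
    which case the tree is midpoint-rooted first.
    """
    if isinstance(source, str) and source.lstrip().startswith("("):
        handle = io.StringIO(source)
    else:
        handle = source
    try:
        tree = skbio.TreeNode.read(handle, format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise TreeError(f"unparseable Newick input: {exc}") from exc
    if len(tree.children) > 2:
        if not midpoint_root:
            raise TreeError(
                "tree appears unrooted (basal polytomy); re-root it or pass "
                "midpoint_root=True"
            )
        tree = tree.root_at_midpoint()
    return _validate(tree, allow_zero_lengths)


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def tip_labels(tree: skbio.TreeNode) -> list[str]:
    return [t.name for t in tree.tips()]


def check_taxa_in_tree(taxon_ids, tree: skbio.TreeNode) -> None:
    missing = sorted(set(taxon_ids) - set(tip_labels(tree)))
    if missing:
        raise TreeError(f"taxa absent from tree: {missing[:10]}"
                        + (" ..." if len(missing) > 10 else ""))


def cophenetic_distances(tree: skbio.TreeNode) -> DistanceMatrix:
    """Pairwise tip-to-tip path-length distances (branch-length units)."""
    dm = tree.tip_tip_distances()
    return DistanceMatrix(list(dm.ids), np.asarray(dm.data, dtype=float),
                          "dissimilarity", "branch length")


def is_ultrametric(tree: skbio.TreeNode, tol: float = 1e-9) -> bool:
    depths = [tip.accumulate_to_ancestor(tree) for tip in tree.tips()]
    return max(depths) - min(depths) <= tol
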