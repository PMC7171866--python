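"""Compositional and phylogenetic beta-diversity.

Bray-Curtis dissimilarity, generalized UniFrac (the Chen family with a
moderation exponent ``alpha`` on branch weights) and the sequential
beta-diversity analysis along a cruise track, where each community is
compared with the one sampled immediately before it and dissimilarities
above a threshold flag abrupt compositional change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform

from .distances import DistanceMatrix
from .table import EmptyTableError, OtuTable, SampleMetadata
from .tree import check_taxa_in_tree


def bray_curtis(table: OtuTable, use_relative: bool = False) -> DistanceMatrix:
    """Pairwise Bray-Curtis: d(A,B) = sum|x_i - y_i| / sum(x_i + y_i).

    Computed on raw counts by default; at equal sampling depth this equals
    the relative-abundance version, which ``use_relative`` forces.
    """
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    x = table.relative_abundances() if use_relative else table.counts.astype(float)
    if (x.sum(axis=1) == 0).any():
        raise EmptyTableError("zero-sum sample")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d, "dissimilarity")


def _branch_matrix(tree: skbio.TreeNode, taxon_ids: list[str]):
    """Per-branch tip membership (branches x taxa) and branch lengths.

    Tree tips absent from the table simply carry zero abundance; the root's
    stem (no length, no contrast) is excluded.
    """
    col = {t: j for j, t in enumerate(taxon_ids)}
    members: dict[int, np.ndarray] = {}
    rows, lengths = [], []
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            vec = np.zeros(len(taxon_ids))
            if node.name in col:
                vec[col[node.name]] = 1.0
        else:
            vec = np.zeros(len(taxon_ids))
            for child in node.children:
                vec += members[id(child)]
        members[id(node)] = vec
        rows.append(vec)
        lengths.append(node.length or 0.0)
    return np.array(rows), np.array(lengths)


def gunifrac(table: OtuTable, tree: skbio.TreeNode, alpha: float = 0.5) -> DistanceMatrix:
    """Generalized UniFrac with branch-weight exponent ``alpha`` in [0, 1].

    d(A,B) = sum_b L_b (pA+pB)^alpha |pA-pB|/(pA+pB) / sum_b L_b (pA+pB)^alpha
    over branches with nonzero subtended abundance; ``alpha=1`` recovers
    normalized weighted UniFrac, ``alpha=0.5`` is the usual compromise that
    moderates the dominance of highly abundant lineages.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    check_taxa_in_tree(table.taxon_ids, tree)
    branch, lengths = _branch_matrix(tree, list(table.taxon_ids))
    prop = branch @ table.relative_abundances().T        # branches x samples
    n = table.n_samples
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            tot = prop[:, a] + prop[:, b]
            mask = tot > 0
            w = lengths[mask] * tot[mask] ** alpha
            den = w.sum()
            if den == 0:
                raise EmptyTableError("both samples empty on the tree")
            num = (w * np.abs(prop[mask, a] - prop[mask, b]) / tot[mask]).sum()
            out[a, b] = out[b, a] = num / den
    return DistanceMatrix(list(table.sample_ids), out, "dissimilarity")


@dataclass
class SequentialBetaResult:
    """Dissimilarity of each station to its immediate predecessor in cruise order."""

    entries: pd.DataFrame     # station, previous_station, dissimilarity, abrupt
    threshold: float

    @property
    def abrupt_stations(self) -> list[str]:
        return list(self.entries.loc[self.entries["abrupt"], "station"])


def sequential_beta(dist: DistanceMatrix, meta: SampleMetadata,
                    threshold: float) -> SequentialBetaResult:
    """Walk the cruise track comparing consecutive communities.

    The abrupt flag is strict: a dissimilarity exactly at the threshold is
    not flagged.
    """
    order = [s for s in meta.cruise_sorted_ids() if s in dist.labels]
    missing = set(dist.labels) - set(meta.sample_ids)
    if missing:
        raise ValueError(f"samples missing cruise_order: {sorted(missing)}")
    rows = []
    for prev, cur in zip(order, order[1:]):
        d = dist.loc(cur, prev)
        rows.append({"station": cur, "previous_station": prev,
                     "dissimilarity": d, "abrupt": d > threshold})
    return SequentialBetaResult(pd.DataFrame(rows), threshold)


#: Abrupt-change presets for the two picoplankton components on ocean transects.
ABRUPT_THRESHOLD_PICOEUKARYOTES = 0.8
ABRUPT_THRESHOLD_PROKARYOTES = 0.7
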