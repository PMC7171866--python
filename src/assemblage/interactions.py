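"""Interaction-adjusted community similarity (TINA / PINA).

Classic compositional indices treat taxa as unrelated; TINA replaces the
identity kernel with pairwise association strengths a_ij in [0, 1] derived
from co-occurrence profiles, and PINA with phylogenetic similarities.  The
similarity between samples A and B is a generalized cosine:

    s(A,B) = p_A' K p_B / sqrt( (p_A' K p_A) (p_B' K p_B) )

with p the relative-abundance (weighted) or presence-normalised
(unweighted) vectors and K the association kernel.  Identical communities
score 1 for any kernel with unit diagonal; disjoint communities score the
mean cross-association — 0.5 under neutral associations, 0 under complete
avoidance.  Dissimilarities are taken as 1 - s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import skbio
from scipy.stats import rankdata

from .distances import DistanceMatrix
from .table import OtuTable
from .tree import check_taxa_in_tree, cophenetic_distances

logger = logging.getLogger(__name__)


@dataclass
class AssociationMatrix:
    """Taxon-by-taxon association strengths in [0, 1], unit diagonal."""

    taxon_ids: list[str]
    values: np.ndarray
    estimator: str = "pearson"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxon_ids)
        if self.values.shape != (n, n):
            raise ValueError("association matrix shape mismatch")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-12:
            raise ValueError("association matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("association values must lie in [0, 1]")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.values, 1.0)

    def reorder(self, taxon_ids: list[str]) -> "AssociationMatrix":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return AssociationMatrix(list(taxon_ids), self.values[np.ix_(idx, idx)],
                                 self.estimator)


def taxon_associations(table: OtuTable, method: str = "pearson") -> AssociationMatrix:
    """Rescaled correlation of relative-abundance profiles: a = (rho + 1) / 2.

    Taxa with zero variance across samples have no defined correlation;
    their associations are set to the neutral value 0.5 (with a warning)
    rather than dropping the taxa, so the taxon set stays aligned with the
    other metrics.
    """
    if table.n_samples < 3:
        raise ValueError("need at least three samples to estimate associations")
    x = table.relative_abundances()
    if method == "spearman":
        x = rankdata(x, axis=0)
    elif method != "pearson":
        raise ValueError(f"unknown estimator {method!r}")
    sd = x.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d zero-variance taxa assigned neutral association 0.5",
                       int(degenerate.sum()))
    centred = x - x.mean(axis=0)
    denom = np.outer(sd, sd) * x.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (centred.T @ centred) / denom
    rho[degenerate, :] = 0.0
    rho[:, degenerate] = 0.0
    rho = np.clip(rho, -1.0, 1.0)
    a = (rho + 1.0) / 2.0
    np.fill_diagonal(a, 1.0)
    return AssociationMatrix(list(table.taxon_ids), a, method)


def _kernel_cosine(p: np.ndarray, kernel: np.ndarray, labels: list[str]
                   ) -> DistanceMatrix:
    cross = p @ kernel @ p.T
    self_sim = np.diagonal(cross).copy()
    if (self_sim <= 0).any():
        bad = labels[int(np.argmax(self_sim <= 0))]
        raise ValueError(f"zero self-similarity for sample {bad!r}")
    sim = cross / np.sqrt(np.outer(self_sim, self_sim))
    # Cauchy-Schwarz bounds the cosine by 1 only for positive-semidefinite
    # kernels; estimator-derived kernels ((rho+1)/2) are PSD, but arbitrary
    # [0,1] matrices may overshoot marginally, so clip to the unit interval.
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return DistanceMatrix(labels, sim, "similarity")


def tina(table: OtuTable, assoc: AssociationMatrix,
         weighted: bool = True) -> DistanceMatrix:
    """Taxa interaction-adjusted similarity under a co-occurrence kernel.

    Use ``.to_dissimilarity()`` on the result for 1 - TINA matrices.
    """
    kernel = assoc.reorder(list(table.taxon_ids)).values
    p = table.relative_abundances()
    if not weighted:
        pres = (table.counts > 0).astype(float)
        p = pres / pres.sum(axis=1, keepdims=True)
    return _kernel_cosine(p, kernel, list(table.sample_ids))


def phylogenetic_similarity(tree: skbio.TreeNode,
                            taxon_ids: list[str]) -> AssociationMatrix:
    """1 - cophenetic distance / max cophenetic distance, as a TINA kernel."""
    check_taxa_in_tree(taxon_ids, tree)
    coph = cophenetic_distances(tree).reorder(list(taxon_ids)).values
    dmax = coph.max()
    if dmax == 0:
        raise ValueError("degenerate tree: all cophenetic distances are zero")
    return AssociationMatrix(list(taxon_ids), 1.0 - coph / dmax, "phylogenetic")


def pina(table: OtuTable, tree: skbio.TreeNode,
         weighted: bool = True) -> DistanceMatrix:
    """Phylogenetic interaction-adjusted similarity (TINA with a phylo kernel)."""
    return tina(table, phylogenetic_similarity(tree, list(table.taxon_ids)),
                weighted=weighted)
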