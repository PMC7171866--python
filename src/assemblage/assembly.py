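"""Null-model quantification of selection, dispersal and drift.

The inference runs in two sequential steps over all pairs of communities:

1. *Phylogenetic turnover* — the abundance-weighted beta mean nearest taxon
   distance (betaMNTD) is compared against a null distribution obtained by
   shuffling taxon identities across the tips of the phylogeny.  The
   standardized effect size (betaNTI) flags selection: betaNTI > +2 means
   phylogenetic turnover exceeds chance (heterogeneous selection), betaNTI
   < -2 means it is constrained (homogeneous selection).

2. *Compositional turnover* — for pairs without a selection signal, the
   Raup-Crick metric on Bray-Curtis (RC_bray) compares observed turnover
   against probabilistic reassembly from the regional pool, preserving each
   community's richness (taxa drawn by occupancy) and sequencing depth
   (reads allocated by regional relative abundance).  RC_bray > +0.95 flags
   dispersal limitation, RC_bray < -0.95 homogenising dispersal, and values
   in between are indistinguishable from drift.

A prerequisite for interpreting betaNTI is phylogenetic signal in habitat
preferences, checked with a phylogenetic Mantel correlogram between
between-taxon niche distance and cophenetic distance.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import braycurtis

from .distances import DistanceMatrix
from .table import OtuTable
from .tree import check_taxa_in_tree, cophenetic_distances

logger = logging.getLogger(__name__)

PROCESSES = ("heterogeneous_selection", "homogeneous_selection",
             "dispersal_limitation", "homogenizing_dispersal", "drift")


@dataclass
class ProcessThresholds:
    """Significance cuts and null-model sizes for the two-step classification."""

    bnti_cut: float = 2.0
    rc_cut: float = 0.95
    n_null_bnti: int = 999
    n_null_rc: int = 9999

    def __post_init__(self) -> None:
        if self.bnti_cut <= 0 or self.rc_cut <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_null_bnti < 1 or self.n_null_rc < 1:
            raise ValueError("null-model sizes must be >= 1")


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------

def _presence_freqs(table: OtuTable, weighted: bool):
    """Per sample: indices of present taxa and their weights (summing to 1)."""
    rel = table.relative_abundances()
    idx, freqs = [], []
    for i in range(table.n_samples):
        present = np.flatnonzero(table.counts[i] > 0)
        if present.size == 0:
            raise ValueError(f"empty community {table.sample_ids[i]!r}")
        idx.append(present)
        if weighted:
            f = rel[i, present]
            freqs.append(f / f.sum())
        else:
            freqs.append(np.full(present.size, 1.0 / present.size))
    return idx, freqs


def _bmntd_from_parts(idx, freqs, D: np.ndarray) -> np.ndarray:
    """Pairwise betaMNTD given presence indices, weights and taxon distances."""
    n = len(idx)
    out = np.zeros((n, n))
    for k in range(n):
        for m in range(k + 1, n):
            sub = D[np.ix_(idx[k], idx[m])]
            v = 0.5 * (freqs[k] @ sub.min(axis=1) + freqs[m] @ sub.min(axis=0))
            out[k, m] = out[m, k] = v
    return out


def bmntd(table: OtuTable, tree: skbio.TreeNode | None = None,
          weighted: bool = True,
          taxon_distances: DistanceMatrix | None = None) -> DistanceMatrix:
    """Between-community mean nearest taxon distance.

    For each taxon present in one community, take the phylogenetic distance
    to its closest relative present in the other community (a shared taxon is
    its own nearest neighbour at distance zero); average with the taxon's
    relative abundance (or 1/richness when unweighted) and symmetrise.
    """
    if taxon_distances is None:
        if tree is None:
            raise ValueError("provide a tree or a precomputed taxon distance matrix")
        check_taxa_in_tree(table.taxon_ids, tree)
        taxon_distances = cophenetic_distances(tree)
    D = taxon_distances.reorder(list(table.taxon_ids)).values
    idx, freqs = _presence_freqs(table, weighted)
    return DistanceMatrix(list(table.sample_ids), _bmntd_from_parts(idx, freqs, D),
                          "dissimilarity", "branch length")


@dataclass
class BntiResult:
    """Observed betaMNTD, null moments and the standardized effect size per pair."""

    pairs: pd.DataFrame        # sample_a, sample_b, bmntd_obs, null_mean, null_sd, bnti
    matrix: pd.DataFrame       # square betaNTI (NaN where the null is degenerate)

    def bnti_values(self) -> np.ndarray:
        return self.pairs["bnti"].to_numpy()


def bnti(table: OtuTable, tree: skbio.TreeNode, n_null: int = 999,
         seed: int | None = None, weighted: bool = True,
         exhaustive: bool = False) -> BntiResult:
    """betaNTI = (betaMNTD_obs - mean_null) / sd_null under tip shuffling.

    One taxon-identity permutation per randomization is applied to the whole
    cophenetic matrix and reused for every community pair, so all pairs share
    the same null draws.  Pairs whose null has zero spread get NaN.  With
    ``exhaustive=True`` every tip permutation is enumerated instead of
    sampled (population sd; only sensible for a handful of taxa).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    check_taxa_in_tree(table.taxon_ids, tree)
    D = cophenetic_distances(tree).reorder(list(table.taxon_ids)).values
    idx, freqs = _presence_freqs(table, weighted)
    obs = _bmntd_from_parts(idx, freqs, D)
    n = table.n_samples
    iu = np.triu_indices(n, k=1)
    if exhaustive:
        if D.shape[0] > 8:
            raise ValueError("exhaustive null is limited to <= 8 taxa")
        perms = list(itertools.permutations(range(D.shape[0])))
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(D.shape[0]) for _ in range(n_null)]
    nulls = np.empty((len(perms), len(iu[0])))
    for r, perm in enumerate(perms):
        perm = np.asarray(perm)
        nulls[r] = _bmntd_from_parts(idx, freqs, D[np.ix_(perm, perm)])[iu]
        if len(perms) >= 100 and (r + 1) % max(1, len(perms) // 10) == 0:
            logger.debug("betaNTI null %d/%d", r + 1, len(perms))
    mean = nulls.mean(axis=0)
    if exhaustive:
        sd = nulls.std(axis=0, ddof=0)
    else:
        sd = nulls.std(axis=0, ddof=1) if n_null > 1 else np.zeros(mean.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = np.where(sd > 0, (obs[iu] - mean) / sd, np.nan)
    if np.isnan(ses).any():
        logger.warning("%d pairs have a degenerate betaMNTD null (sd = 0); "
                       "betaNTI recorded as NaN", int(np.isnan(ses).sum()))
    labels = list(table.sample_ids)
    pairs = pd.DataFrame({
        "sample_a": [labels[i] for i in iu[0]],
        "sample_b": [labels[j] for j in iu[1]],
        "bmntd_obs": obs[iu], "null_mean": mean, "null_sd": sd, "bnti": ses,
    })
    mat = np.full((n, n), np.nan)
    mat[iu] = ses
    mat[(iu[1], iu[0])] = ses
    np.fill_diagonal(mat, 0.0)
    return BntiResult(pairs, pd.DataFrame(mat, index=labels, columns=labels))


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------

def _null_community(rng: np.random.Generator, richness: int, depth: int,
                    occupancy_w: np.ndarray, abundance_w: np.ndarray) -> np.ndarray:
    """Assemble one null community from the regional pool.

    Draw ``richness`` distinct taxa with probability proportional to
    occupancy (Gumbel top-k, equivalent to sequential weighted sampling
    without replacement), give each one read, then allocate the remaining
    reads multinomially by regional relative abundance.
    """
    with np.errstate(divide="ignore"):
        keys = np.log(occupancy_w) + rng.gumbel(size=occupancy_w.size)
    chosen = np.argpartition(-keys, richness - 1)[:richness]
    counts = np.zeros(occupancy_w.size, dtype=np.int64)
    counts[chosen] = 1
    remaining = depth - richness
    if remaining > 0:
        w = abundance_w[chosen]
        counts[chosen] += rng.multinomial(remaining, w / w.sum())
    return counts


def raup_crick_bray(table: OtuTable, n_null: int = 9999, seed: int | None = None,
                    occupancy_weights: np.ndarray | None = None,
                    abundance_weights: np.ndarray | None = None) -> pd.DataFrame:
    """RC_bray per unordered pair, in [-1, 1].

    For each pair, ``n_null`` random pairs of communities are reassembled
    from the regional (all-sample) pool; RC_raw is the fraction of null
    Bray-Curtis values below the observed one, counting ties with weight
    0.5, and RC = 2 * (RC_raw - 0.5).  The table should be rarefied to a
    common depth so read totals are comparable.  Pool weights default to
    regional occupancy and total relative abundance but can be overridden
    (e.g. for calibration runs against a fixed pool).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    counts = table.counts
    occ = (counts > 0).sum(axis=0).astype(float) if occupancy_weights is None \
        else np.asarray(occupancy_weights, dtype=float)
    ab = counts.sum(axis=0).astype(float) if abundance_weights is None \
        else np.asarray(abundance_weights, dtype=float)
    richness = (counts > 0).sum(axis=1)
    depth = counts.sum(axis=1)
    n_pool = int((occ > 0).sum())
    if (richness > n_pool).any():
        raise ValueError("a community is richer than the regional pool")
    n = table.n_samples
    labels = list(table.sample_ids)
    rng = np.random.default_rng(seed)
    rows = []
    mat = np.zeros((n, n))
    for k, m in itertools.combinations(range(n), 2):
        obs = braycurtis(counts[k].astype(float), counts[m].astype(float))
        less = ties = 0
        for _ in range(n_null):
            a = _null_community(rng, int(richness[k]), int(depth[k]), occ, ab)
            b = _null_community(rng, int(richness[m]), int(depth[m]), occ, ab)
            d = braycurtis(a.astype(float), b.astype(float))
            if d < obs:
                less += 1
            elif d == obs:
                ties += 1
        rc = 2.0 * ((less + 0.5 * ties) / n_null - 0.5)
        rows.append({"sample_a": labels[k], "sample_b": labels[m],
                     "bray_curtis_obs": obs, "rc_bray": rc})
        mat[k, m] = mat[m, k] = rc
    out = pd.DataFrame(rows)
    out.attrs["matrix"] = pd.DataFrame(mat, index=labels, columns=labels)
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class ProcessSummary:
    """Fraction of community pairs attributed to each assembly process."""

    counts: dict[str, int]
    n_pairs: int
    n_unclassified: int = 0

    @property
    def fractions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        return {p: (self.counts.get(p, 0) / total if total else math.nan)
                for p in PROCESSES}

    @property
    def modal_process(self) -> str:
        return max(PROCESSES, key=lambda p: self.counts.get(p, 0))

    def to_series(self) -> pd.Series:
        return pd.Series(self.fractions, name="fraction")


def classify_processes(bnti_pairs: pd.DataFrame, rc_pairs: pd.DataFrame,
                       thresholds: ProcessThresholds | None = None
                       ) -> tuple[pd.DataFrame, ProcessSummary]:
    """Assign each community pair to one of the five assembly processes.

    Selection is judged first from betaNTI; only pairs without a selection
    signal are passed to RC_bray.  Pairs with an undefined betaNTI are
    excluded from the summary and counted separately.
    """
    thresholds = thresholds or ProcessThresholds()
    calls = bnti_pairs.merge(rc_pairs, on=["sample_a", "sample_b"], how="left")
    labels = []
    for _, row in calls.iterrows():
        b, rc = row["bnti"], row.get("rc_bray", np.nan)
        if np.isnan(b):
            labels.append("unclassified")
        elif b > thresholds.bnti_cut:
            labels.append("heterogeneous_selection")
        elif b < -thresholds.bnti_cut:
            labels.append("homogeneous_selection")
        elif np.isnan(rc):
            labels.append("unclassified")
        elif rc > thresholds.rc_cut:
            labels.append("dispersal_limitation")
        elif rc < -thresholds.rc_cut:
            labels.append("homogenizing_dispersal")
        else:
            labels.append("drift")
    calls["process"] = labels
    classified = calls[calls["process"] != "unclassified"]
    counts = {p: int((classified["process"] == p).sum()) for p in PROCESSES}
    summary = ProcessSummary(counts, n_pairs=len(calls),
                             n_unclassified=int((calls["process"] == "unclassified").sum()))
    return calls, summary


def quantify_processes(table: OtuTable, tree: skbio.TreeNode,
                       thresholds: ProcessThresholds | None = None,
                       seed: int | None = None, weighted: bool = True
                       ) -> tuple[pd.DataFrame, ProcessSummary]:
    """Full two-step pipeline: betaNTI, RC_bray, then the five-way call."""
    thresholds = thresholds or ProcessThresholds()
    ss = np.random.SeedSequence(seed).generate_state(2) % (2 ** 31)
    b = bnti(table, tree, n_null=thresholds.n_null_bnti, seed=int(ss[0]),
             weighted=weighted)
    rc = raup_crick_bray(table, n_null=thresholds.n_null_rc, seed=int(ss[1]))
    return classify_processes(b.pairs, rc, thresholds)


# ---------------------------------------------------------------------------
# Phylogenetic signal
# ---------------------------------------------------------------------------

def niche_values(table: OtuTable, env: pd.Series) -> pd.Series:
    """Abundance-weighted mean of an environmental variable per taxon.

    The weight of sample k for taxon i is i's relative abundance in k, so a
    taxon found in a single sample inherits that sample's value exactly.
    """
    env = env.loc[table.sample_ids].astype(float)
    rel = table.relative_abundances()
    w = rel.sum(axis=0)
    observed = w > 0
    niche = np.full(table.n_taxa, np.nan)
    niche[observed] = (rel[:, observed] * env.to_numpy()[:, None]).sum(axis=0) \
        / w[observed]
    # taxa never observed have no habitat information and are dropped
    return pd.Series(niche, index=table.taxon_ids, name="niche").dropna()


def phylo_signal_correlogram(table: OtuTable, env: pd.Series, tree: skbio.TreeNode,
                             n_classes: int = 10, n_perm: int = 999,
                             seed: int | None = None) -> pd.DataFrame:
    """Mantel correlogram of niche distance against phylogenetic distance.

    Positive correlations in the shortest distance classes indicate that
    close relatives prefer similar habitats — the phylogenetic signal that
    licenses betaNTI-based inference of selection.
    """
    from .spatial import membership_correlogram  # local import; avoids a cycle

    niche = niche_values(table, env)
    if np.ptp(niche.to_numpy()) == 0:
        raise ValueError("niche values are constant; correlation undefined")
    taxa = list(niche.index)
    coph = cophenetic_distances(tree).reorder(taxa)
    nv = niche.to_numpy()
    niche_dist = DistanceMatrix(taxa, np.abs(nv[:, None] - nv[None, :]),
                                "dissimilarity")
    breaks = np.linspace(0.0, coph.values.max(), n_classes + 1)
    return membership_correlogram(coph, niche_dist, breaks=breaks,
                                  n_perm=n_perm, seed=seed)
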