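import itertools

import numpy as np
import pandas as pd
import pytest

from assemblage import (OtuTable, bmntd, bnti, classify_processes,
                        niche_values, phylo_signal_correlogram,
                        raup_crick_bray)
from assemblage.assembly import ProcessThresholds
from assemblage.distances import DistanceMatrix
from assemblage.simulate import simulate_regime, simulate_tree
from assemblage.tree import cophenetic_distances, read_tree
from conftest import random_table


def brute_force_bmntd(table, D, weighted=True):
    """Independent oracle: literal double loop over taxa of each community."""
    rel = table.counts / table.counts.sum(axis=1, keepdims=True)
    n = table.n_samples
    out = np.zeros((n, n))
    for k in range(n):
        for m in range(n):
            if k == m:
                continue
            total = 0.0
            pres_k = [i for i in range(table.n_taxa) if table.counts[k, i] > 0]
            pres_m = [j for j in range(table.n_taxa) if table.counts[m, j] > 0]
            for i in pres_k:
                dmin = min(D[i, j] for j in pres_m)
                w = rel[k, i] if weighted else 1.0 / len(pres_k)
                total += w * dmin
            out[k, m] = total
    return 0.5 * (out + out.T)


class TestBmntd:
    def test_hand_value(self):
        # k = {A: .5, B: .5}, m = {C: 1}, D(A,C)=2, D(B,C)=4 -> 2.5
        D = DistanceMatrix(["A", "B", "C"],
                           np.array([[0., 1., 2.], [1., 0., 4.], [2., 4., 0.]]))
        t = OtuTable(["k", "m"], ["A", "B", "C"], np.array([[1, 1, 0], [0, 0, 1]]))
        res = bmntd(t, taxon_distances=D)
        assert res.loc("k", "m") == pytest.approx(2.5)

    def test_identical_communities_zero(self, toy_tree):
        t = OtuTable(["x", "y"], ["A", "B", "C", "D"],
                     np.array([[3, 1, 2, 0], [3, 1, 2, 0]]))
        assert bmntd(t, toy_tree).loc("x", "y") == pytest.approx(0.0)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force(self, rng, weighted):
        for _ in range(10):
            n_taxa = int(rng.integers(4, 10))
            tree = simulate_tree(n_taxa, seed=int(rng.integers(2**31)))
            taxa = [t.name for t in tree.tips()]
            counts = rng.integers(0, 8, size=(4, n_taxa))
            counts[:, 0] += 1
            table = OtuTable([f"s{i}" for i in range(4)], taxa, counts)
            D = cophenetic_distances(tree).reorder(taxa).values
            ours = bmntd(table, tree, weighted=weighted).values
            assert np.abs(ours - brute_force_bmntd(table, D, weighted)).max() < 1e-12


class TestBnti:
    def test_centering(self, rng):
        # betaNTI is a standardized effect size: subtracting the null mean
        # and dividing by the null sd, so its null expectation is near zero
        tree = simulate_tree(12, seed=0)
        counts = rng.integers(0, 5, size=(4, 12))
        counts[np.arange(4), np.arange(4)] += 3   # ensure non-empty, sparse
        table = OtuTable([f"s{i}" for i in range(4)],
                         [t.name for t in tree.tips()], counts)
        res = bnti(table, tree, n_null=199, seed=1)
        assert np.all(np.isfinite(res.bnti_values()))
        assert abs(np.nanmean(res.bnti_values())) < 2.0

    def test_exhaustive_enumeration_oracle(self):
        tree = read_tree("((A:1,B:1):1,C:2);")
        table = OtuTable(["s1", "s2"], ["A", "B", "C"],
                         np.array([[5, 1, 0], [0, 2, 6]]))
        res = bnti(table, tree, exhaustive=True)
        # independent enumeration of all 3! tip relabelings
        D = cophenetic_distances(tree).reorder(["A", "B", "C"]).values
        obs = brute_force_bmntd(table, D)[0, 1]
        nulls = []
        for perm in itertools.permutations(range(3)):
            Dp = D[np.ix_(perm, perm)]
            nulls.append(brute_force_bmntd(table, Dp)[0, 1])
        expected = (obs - np.mean(nulls)) / np.std(nulls)
        assert res.pairs["bnti"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_star_tree_degenerate_null_is_nan(self, caplog):
        tree = read_tree("(A:1,B:1,C:1,D:1);", midpoint_root=True)
        table = OtuTable(["s1", "s2"], ["A", "B", "C", "D"],
                         np.array([[5, 1, 0, 0], [0, 0, 2, 6]]))
        with caplog.at_level("WARNING"):
            res = bnti(table, tree, n_null=19, seed=0)
        assert np.isnan(res.pairs["bnti"].iloc[0])
        assert "degenerate" in caplog.text

    def test_deterministic_given_seed(self, rng):
        tree = simulate_tree(10, seed=2)
        counts = rng.integers(0, 5, size=(4, 10))
        counts[np.arange(4), np.arange(4)] += 3
        table = OtuTable([f"s{i}" for i in range(4)],
                         [t.name for t in tree.tips()], counts)
        a = bnti(table, tree, n_null=49, seed=5).bnti_values()
        b = bnti(table, tree, n_null=49, seed=5).bnti_values()
        assert np.array_equal(a, b)


class TestRaupCrick:
    def test_richness_one_toy_matches_enumeration(self):
        # two single-taxon samples over a 3-taxon pool; the third taxon has
        # zero occupancy and can never be drawn.  Null pairs: (A,A) or (B,B)
        # with BC 0 (prob 1/2), else BC 1 (tie with observed, weight 0.5)
        # -> RC_raw = 1/2 + 1/2 * 1/2 = 3/4, RC = 0.5
        t = OtuTable(["s1", "s2"], ["A", "B", "C"],
                     np.array([[20, 0, 0], [0, 20, 0]]))
        rc = raup_crick_bray(t, n_null=9999, seed=0)
        assert rc["rc_bray"].iloc[0] == pytest.approx(0.5, abs=0.03)

    def test_identical_samples_hit_lower_boundary(self):
        # identical compositions are more similar than (almost) any random
        # assembly -> RC at or near -1
        counts = np.array([[30, 20, 10, 5, 1, 0], [30, 20, 10, 5, 1, 0],
                           [5, 10, 20, 1, 0, 30]])
        t = OtuTable(["a", "b", "c"], [f"t{i}" for i in range(6)], counts)
        rc = raup_crick_bray(t, n_null=199, seed=0)
        pair = rc.set_index(["sample_a", "sample_b"]).loc[("a", "b"), "rc_bray"]
        assert pair == -1.0

    def test_disjoint_samples_hit_upper_boundary(self):
        counts = np.zeros((2, 12), dtype=int)
        counts[0, :6] = [30, 20, 10, 5, 2, 1]
        counts[1, 6:] = [30, 20, 10, 5, 2, 1]
        t = OtuTable(["a", "b"], [f"t{i}" for i in range(12)], counts)
        rc = raup_crick_bray(t, n_null=199, seed=0)
        assert rc["rc_bray"].iloc[0] == 1.0

    def test_range_and_determinism(self, rng):
        t = random_table(rng, n_samples=5, n_taxa=15, depth=100)
        a = raup_crick_bray(t, n_null=99, seed=3)["rc_bray"]
        b = raup_crick_bray(t, n_null=99, seed=3)["rc_bray"]
        assert np.array_equal(a.to_numpy(), b.to_numpy())
        assert ((a >= -1) & (a <= 1)).all()


class TestClassification:
    @pytest.mark.parametrize("b, rc, expected", [
        (3.0, 0.0, "heterogeneous_selection"),
        (-3.0, 0.0, "homogeneous_selection"),
        (1.0, 0.99, "dispersal_limitation"),
        (1.0, -0.99, "homogenizing_dispersal"),
        (-1.0, 0.0, "drift"),
        (2.0, 0.95, "drift"),              # both thresholds are strict
    ])
    def test_rules(self, b, rc, expected):
        bp = pd.DataFrame({"sample_a": ["x"], "sample_b": ["y"], "bnti": [b]})
        rp = pd.DataFrame({"sample_a": ["x"], "sample_b": ["y"], "rc_bray": [rc]})
        calls, summary = classify_processes(bp, rp)
        assert calls["process"].iloc[0] == expected
        assert sum(summary.fractions.values()) == pytest.approx(1.0)

    def test_nan_bnti_excluded_but_counted(self):
        bp = pd.DataFrame({"sample_a": ["x", "x"], "sample_b": ["y", "z"],
                           "bnti": [np.nan, 3.0]})
        rp = pd.DataFrame({"sample_a": ["x", "x"], "sample_b": ["y", "z"],
                           "rc_bray": [0.0, 0.0]})
        calls, summary = classify_processes(bp, rp)
        assert summary.n_unclassified == 1
        assert summary.counts["heterogeneous_selection"] == 1
        assert sum(summary.fractions.values()) == pytest.approx(1.0)


class TestPhyloSignal:
    def test_single_sample_taxon_niche(self, toy_tree):
        t = OtuTable(["s1", "s2"], ["A", "B", "C", "D"],
                     np.array([[5, 0, 1, 1], [0, 3, 1, 1]]))
        env = pd.Series({"s1": 10.0, "s2": 30.0})
        niche = niche_values(t, env)
        assert niche["A"] == pytest.approx(10.0)
        assert niche["B"] == pytest.approx(30.0)

    def test_constant_niche_errors(self, toy_tree):
        t = OtuTable(["s1", "s2"], ["A", "B", "C", "D"],
                     np.ones((2, 4), dtype=int))
        env = pd.Series({"s1": 5.0, "s2": 5.0})
        with pytest.raises(ValueError, match="constant"):
            phylo_signal_correlogram(t, env, toy_tree)

    def test_brownian_niches_show_signal_in_shortest_class(self):
        hits = 0
        for seed in range(10):
            table, tree, meta, _ = simulate_regime(
                "heterogeneous_selection", seed=seed, n_taxa=100,
                n_stations=12, community_size=4000)
            corr = phylo_signal_correlogram(table, meta.data["temperature"],
                                            tree, n_classes=8, n_perm=199,
                                            seed=seed)
            first = corr.dropna(subset=["mantel_r"]).iloc[0]
            if first["mantel_r"] > 0 and first["p_corrected"] < 0.05:
                hits += 1
        assert hits >= 8
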