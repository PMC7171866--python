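import itertools
import math

import numpy as np
import pandas as pd
import pytest
import skbio.stats.distance

from assemblage import (OtuTable, SampleMetadata, haversine_distances, lcbd,
                        mantel, mantel_correlogram, permanova,
                        variance_partition)
from assemblage.distances import DistanceMatrix
from conftest import random_table


def make_meta(n, lon_step=5.0, extra=None):
    data = {"latitude": np.zeros(n), "longitude": np.arange(n) * lon_step,
            "cruise_order": np.arange(1, n + 1)}
    data.update(extra or {})
    return SampleMetadata(pd.DataFrame(data, index=[f"s{i}" for i in range(n)]))


class TestHaversine:
    def test_closed_forms(self):
        meta = SampleMetadata(pd.DataFrame({
            "latitude": [0.0, 0.0, 90.0],
            "longitude": [0.0, 180.0, 0.0],
            "cruise_order": [1, 2, 3]}, index=["o", "anti", "pole"]))
        d = haversine_distances(meta)
        assert d.loc("o", "anti") == pytest.approx(math.pi * 6371.0, rel=1e-9)
        assert d.loc("o", "pole") == pytest.approx(math.pi * 6371.0 / 2, rel=1e-9)
        assert d.loc("o", "o") == 0.0


class TestMantel:
    def test_identity_and_anticorrelation(self, rng):
        n = 8
        m = rng.uniform(1, 5, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        d1 = DistanceMatrix([f"s{i}" for i in range(n)], m)
        r, _ = mantel(d1, d1, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        anti = m.max() - m
        np.fill_diagonal(anti, 0)
        d2 = DistanceMatrix(d1.labels, anti)
        r2, _ = mantel(d1, d2, n_perm=99, seed=0)
        assert r2 == pytest.approx(-1.0)

    def test_p_matches_exhaustive_enumeration(self, rng):
        n = 4
        m1 = rng.uniform(1, 5, size=(n, n)); m1 = (m1 + m1.T) / 2
        m2 = rng.uniform(1, 5, size=(n, n)); m2 = (m2 + m2.T) / 2
        np.fill_diagonal(m1, 0); np.fill_diagonal(m2, 0)
        labels = [f"s{i}" for i in range(n)]
        d1, d2 = DistanceMatrix(labels, m1), DistanceMatrix(labels, m2)
        iu = np.triu_indices(n, 1)
        r_obs = np.corrcoef(m1[iu], m2[iu])[0, 1]
        hits = sum(
            np.corrcoef(m1[iu], m2[np.ix_(p, p)][iu])[0, 1] >= r_obs - 1e-12
            for p in itertools.permutations(range(n)))
        exact_p = hits / math.factorial(n)
        _, p = mantel(d1, d2, n_perm=1999, seed=1)
        assert p == pytest.approx(exact_p, abs=0.05)

    def test_spearman_agrees_with_skbio(self, rng):
        n = 7
        m1 = rng.uniform(1, 5, size=(n, n)); m1 = (m1 + m1.T) / 2
        m2 = m1 ** 2 + rng.uniform(0, 1, size=(n, n))
        m2 = (m2 + m2.T) / 2
        np.fill_diagonal(m1, 0); np.fill_diagonal(m2, 0)
        labels = [f"s{i}" for i in range(n)]
        r, _ = mantel(DistanceMatrix(labels, m1), DistanceMatrix(labels, m2),
                      method="spearman", n_perm=9, seed=0)
        ref, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(m1, ids=labels),
            skbio.DistanceMatrix(m2, ids=labels),
            method="spearman", permutations=0)
        assert r == pytest.approx(ref, abs=1e-12)

    def test_constant_matrix_rejected(self):
        labels = ["a", "b", "c"]
        ones = np.ones((3, 3)); np.fill_diagonal(ones, 0)
        d = DistanceMatrix(labels, ones)
        with pytest.raises(ValueError, match="constant"):
            mantel(d, d, n_perm=9)


class TestCorrelogram:
    def test_monotone_decay_positive_short_classes(self):
        n = 20
        meta = make_meta(n, lon_step=3.0)
        geo = haversine_distances(meta)
        beta = DistanceMatrix(geo.labels, geo.values / geo.values.max() * 0.8)
        res = mantel_correlogram(geo, beta, class_width=1000.0, n_perm=199, seed=0)
        first = res.dropna(subset=["mantel_r"]).iloc[0]
        assert first["mantel_r"] > 0
        assert first["p_corrected"] < 0.05

    def test_null_calibration(self, rng):
        n = 16
        meta = make_meta(n, lon_step=3.0)
        geo = haversine_distances(meta)
        sig = 0
        total = 0
        for rep in range(15):
            m = rng.uniform(0.2, 0.9, size=(n, n)); m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            res = mantel_correlogram(geo, DistanceMatrix(geo.labels, m),
                                     class_width=1000.0, n_perm=99,
                                     seed=int(rng.integers(2**31)))
            ok = res.dropna(subset=["p_raw"])
            sig += (ok["p_raw"] < 0.05).sum()
            total += len(ok)
        assert sig / total < 0.15

    def test_classes_partition_pairs(self):
        meta = make_meta(12, lon_step=4.0)
        geo = haversine_distances(meta)
        beta = DistanceMatrix(geo.labels, geo.values / geo.values.max())
        res = mantel_correlogram(geo, beta, class_width=800.0, n_perm=9, seed=0)
        assert res["n_pairs"].sum() == 12 * 11 // 2


class TestPermanova:
    def test_perfect_two_group_separation(self):
        labels = ["a1", "a2", "b1", "b2"]
        d = np.ones((4, 4)); d[:2, :2] = 0; d[2:, 2:] = 0
        np.fill_diagonal(d, 0)
        meta = pd.DataFrame({"group": ["A", "A", "B", "B"]}, index=labels)
        res = permanova(DistanceMatrix(labels, d), meta, ["group"],
                        n_perm=99, seed=0)
        assert res.loc["group", "r2"] == pytest.approx(1.0, abs=1e-10)

    def test_single_level_group_rejected(self):
        labels = ["a", "b", "c"]
        d = np.ones((3, 3)); np.fill_diagonal(d, 0)
        meta = pd.DataFrame({"g": ["X", "X", "X"]}, index=labels)
        with pytest.raises(ValueError, match="single level"):
            permanova(DistanceMatrix(labels, d), meta, ["g"], n_perm=9)

    def test_collinear_terms_named(self, rng):
        labels = [f"s{i}" for i in range(6)]
        m = rng.uniform(1, 2, (6, 6)); m = (m + m.T) / 2; np.fill_diagonal(m, 0)
        x = rng.normal(size=6)
        meta = pd.DataFrame({"x": x, "x2": 2 * x}, index=labels)
        with pytest.raises(ValueError, match="x2"):
            permanova(DistanceMatrix(labels, m), meta, ["x", "x2"], n_perm=9)

    def test_single_factor_agrees_with_skbio(self, rng):
        # independent oracle for the pseudo-F and R2 partitioning
        for _ in range(10):
            n = 9
            m = rng.uniform(0.2, 1.0, size=(n, n)); m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            labels = [f"s{i}" for i in range(n)]
            groups = [["X", "Y", "Z"][i % 3] for i in range(n)]
            meta = pd.DataFrame({"g": groups}, index=labels)
            res = permanova(DistanceMatrix(labels, m), meta, ["g"],
                            n_perm=9, seed=0)
            ref = skbio.stats.distance.permanova(
                skbio.DistanceMatrix(m, ids=labels), groups, permutations=0)
            assert res.loc["g", "pseudo_f"] == pytest.approx(ref["test statistic"],
                                                             abs=1e-10)

    def test_sequential_ss_adds_to_total(self, rng):
        n = 12
        m = rng.uniform(0.2, 1.0, size=(n, n)); m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"s{i}" for i in range(n)]
        meta = pd.DataFrame({"x": rng.normal(size=n),
                             "g": [["A", "B"][i % 2] for i in range(n)]},
                            index=labels)
        res = permanova(DistanceMatrix(labels, m), meta, ["x", "g"],
                        n_perm=49, seed=0)
        terms = res.drop(index=["Residual", "Total"])
        assert (terms["ss"].sum() + res.loc["Residual", "ss"]
                ) == pytest.approx(res.loc["Total", "ss"], abs=1e-9)
        assert res.loc["Total", "r2"] == pytest.approx(1.0)


class TestVariancePartition:
    def _setup(self, rng, n=30):
        x = rng.normal(size=n)
        g = rng.normal(size=n)
        y = np.array([x + rng.normal(0, .4, n), g + rng.normal(0, .4, n)]).T
        d = np.sqrt(((y[:, None, :] - y[None, :, :]) ** 2).sum(-1))
        labels = [f"s{i}" for i in range(n)]
        meta = pd.DataFrame({"env": x, "geo": g,
                             "noise1": rng.normal(size=n),
                             "noise2": rng.normal(size=n)}, index=labels)
        return DistanceMatrix(labels, d), meta

    def test_fractions_sum_to_one(self, rng):
        d, meta = self._setup(rng)
        vp = variance_partition(d, meta, ["env"], ["geo"])
        total = vp.pure_env + vp.pure_geo + vp.shared + vp.unexplained
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_identical_sets_have_no_pure_fractions(self, rng):
        d, meta = self._setup(rng)
        vp = variance_partition(d, meta, ["env"], ["env"])
        assert vp.pure_env == pytest.approx(0.0, abs=1e-9)
        assert vp.pure_geo == pytest.approx(0.0, abs=1e-9)
        assert vp.shared == pytest.approx(vp.r2_env, abs=1e-9)

    def test_noise_predictors_explain_nothing(self, rng):
        d, meta = self._setup(rng, n=40)
        vp = variance_partition(d, meta, ["noise1"], ["noise2"])
        assert abs(vp.r2_both) < 0.1

    def test_informative_beats_noise(self, rng):
        d, meta = self._setup(rng)
        vp = variance_partition(d, meta, ["env"], ["noise1"])
        assert vp.pure_env > 0.3
        assert abs(vp.pure_geo) < 0.1


class TestLcbd:
    def test_sums_to_one_any_input(self, rng):
        t = random_table(rng, n_samples=7, n_taxa=12, depth=150)
        res = lcbd(t, n_perm=49, seed=0)
        assert res.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_exchangeable_design_gives_uniform_contributions(self):
        # n single-taxon samples, all distinct taxa, equal totals
        t = OtuTable([f"s{i}" for i in range(5)], [f"t{i}" for i in range(5)],
                     np.eye(5, dtype=int) * 40)
        res = lcbd(t, n_perm=49, seed=0)
        assert np.allclose(res.values, 0.2, atol=1e-12)

    def test_outlier_has_largest_contribution(self):
        counts = np.array([[30, 30, 1, 0], [31, 29, 0, 1], [30, 31, 1, 0],
                           [0, 1, 30, 30]])
        t = OtuTable(list("abcd"), ["t1", "t2", "t3", "t4"], counts)
        res = lcbd(t, n_perm=199, seed=0)
        assert res.values.idxmax() == "d"
        assert res.p_values["d"] < 0.05

    def test_identical_samples_rejected(self):
        t = OtuTable(["a", "b"], ["t1", "t2"], np.array([[5, 5], [5, 5]]))
        with pytest.raises(ValueError, match="identical"):
            lcbd(t, n_perm=9)
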