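import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from betascape.core import CommunityTable, bray_curtis, geo_distance
from betascape.simulate import SimConfig, simulate_paired_design
from betascape.spatial import (
    ddr_fit,
    forward_select,
    hellinger,
    pcnm,
    permanova,
    permanova_terms,
    variation_partition,
)


def dm_from(points, ids=None):
    ids = ids or [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestDDR:
    def test_constant_similarity_zero_slope(self):
        n = 8
        comm = DistanceMatrix(0.4 * (1 - np.eye(n)),
                              ids=[f"s{i}" for i in range(n)])
        geo = dm_from(np.arange(n, dtype=float)[:, None],
                      ids=[f"s{i}" for i in range(n)])
        fit = ddr_fit(comm, geo, ["g"] * n, n_perm=9)
        assert fit.per_group["g"]["slope"] == 0.0

    def test_slope_matches_independent_pair_regression(self):
        cfg = SimConfig(n_sites=12, n_replicates=2, n_features=150, depth=800,
                        dispersion_as=0.5, dispersion_ns=0.5, seed=5)
        table, metadata = simulate_paired_design(cfg)
        comm = bray_curtis(table)
        geo = geo_distance(metadata)
        lu = metadata.data["land_use"].to_numpy()
        fit = ddr_fit(comm, geo, lu, n_perm=9, seed=0)
        for g in ("AS", "NS"):
            idx = np.flatnonzero(lu == g)
            x, y = [], []
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    i, j = idx[a], idx[b]
                    x.append(np.asarray(geo.data)[i, j])
                    y.append(1.0 - np.asarray(comm.data)[i, j])
            oracle = stats.linregress(x, y)
            assert fit.per_group[g]["slope"] < 0
            assert fit.per_group[g]["slope"] == pytest.approx(
                oracle.slope, rel=1e-9)

    def test_order_invariance(self, rng):
        cfg = SimConfig(n_sites=5, n_replicates=2, n_features=60, depth=400,
                        seed=2)
        table, metadata = simulate_paired_design(cfg)
        comm = bray_curtis(table)
        geo = geo_distance(metadata)
        lu = metadata.data["land_use"].to_numpy()
        fit = ddr_fit(comm, geo, lu, n_perm=9, seed=0)
        perm = rng.permutation(table.n_samples)
        ids = list(comm.ids)
        comm_p = DistanceMatrix(np.asarray(comm.data)[np.ix_(perm, perm)],
                                ids=[ids[i] for i in perm])
        geo_p = DistanceMatrix(np.asarray(geo.data)[np.ix_(perm, perm)],
                               ids=[ids[i] for i in perm])
        fit_p = ddr_fit(comm_p, geo_p, lu[perm], n_perm=9, seed=0)
        for g in fit.per_group:
            assert fit.per_group[g]["slope"] == pytest.approx(
                fit_p.per_group[g]["slope"], abs=1e-12)

    def test_too_few_pairs_rejected(self):
        comm = DistanceMatrix(0.5 * (1 - np.eye(2)), ids=["a", "b"])
        geo = DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"])
        with pytest.raises(ValueError):
            ddr_fit(comm, geo, ["g", "g"])


class TestPCNM:
    def test_threshold_equals_brute_force_mst(self, rng):
        pts = rng.uniform(0, 100, size=(12, 2))
        geo = dm_from(pts)
        basis = pcnm(geo)
        # Prim's algorithm from scratch as the oracle
        d = squareform(pdist(pts))
        n = len(pts)
        in_tree = [0]
        edges = []
        while len(in_tree) < n:
            best = (np.inf, None)
            for i in in_tree:
                for j in range(n):
                    if j not in in_tree and d[i, j] < best[0]:
                        best = (d[i, j], j)
            edges.append(best[0])
            in_tree.append(best[1])
        assert basis.threshold == pytest.approx(max(edges))

    def test_orthonormal_vectors(self, rng):
        geo = dm_from(rng.uniform(0, 50, size=(10, 2)))
        basis = pcnm(geo)
        gram = basis.vectors.to_numpy().T @ basis.vectors.to_numpy()
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_transect_leading_vector_is_broad_gradient(self):
        # equally spaced collinear points: PCNM1 is the broadest-scale
        # sinusoid-like pattern, monotone over each half of the transect
        pts = np.arange(20, dtype=float)[:, None]
        basis = pcnm(dm_from(pts))
        v1 = basis.vectors["PCNM1"].to_numpy()
        sign_changes = int(np.sum(np.diff(np.sign(v1)) != 0))
        assert sign_changes <= 1
        assert basis.eigenvalues[0] == max(basis.eigenvalues)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            pcnm(DistanceMatrix(np.zeros((4, 4)), ids=list("abcd")))


class TestForwardSelect:
    def _response_from(self, x, rng, n_noise=60):
        y = np.column_stack([x + rng.normal(0, 0.4, x.size)
                             for _ in range(5)])
        return y

    def test_recovers_true_driver(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 40
            cand = pd.DataFrame(rng.normal(size=(n, 4)),
                                columns=["v1", "v2", "v3", "v4"])
            y = self._response_from(cand["v1"].to_numpy(), rng)
            sel = forward_select(y, cand, n_perm=99, seed=seed)
            hits += (sel.selected == ["v1"])
        assert hits >= 9

    def test_pure_noise_selects_nothing(self):
        empty = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            cand = pd.DataFrame(rng.normal(size=(30, 5)),
                                columns=[f"v{i}" for i in range(5)])
            y = rng.normal(size=(30, 4))
            sel = forward_select(y, cand, n_perm=99, seed=seed)
            empty += (len(sel.selected) == 0)
        assert empty >= 9

    def test_duplicated_column_never_selected_twice(self):
        rng = np.random.default_rng(0)
        n = 30
        v = rng.normal(size=n)
        cand = pd.DataFrame({"v1": v, "dup": v, "v2": rng.normal(size=n)})
        y = self._response_from(v, rng)
        sel = forward_select(y, cand, n_perm=99, seed=1)
        assert len(sel.selected) == len(set(sel.selected))
        assert not {"v1", "dup"}.issubset(sel.selected)


class TestVPA:
    def test_fractions_sum_to_one(self, rng):
        y = rng.normal(size=(30, 6))
        env = pd.DataFrame(rng.normal(size=(30, 2)), columns=["e1", "e2"])
        spa = pd.DataFrame(rng.normal(size=(30, 2)), columns=["s1", "s2"])
        res = variation_partition(y, env, spa)
        assert res.a + res.b + res.c + res.d == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_predictors_no_shared_fraction(self, rng):
        n = 200
        e = rng.normal(size=n)
        s = rng.normal(size=n)
        e -= e.mean()
        s -= s.mean()
        s -= e * (e @ s) / (e @ e)     # exactly orthogonal
        y = np.column_stack([e + rng.normal(0, 0.5, n),
                             s + rng.normal(0, 0.5, n)])
        res = variation_partition(y, pd.DataFrame({"e": e}),
                                  pd.DataFrame({"s": s}))
        assert abs(res.b) < 0.02

    def test_identical_sets_fully_shared(self, rng):
        x = pd.DataFrame(rng.normal(size=(25, 2)), columns=["a", "b"])
        y = x.to_numpy() @ rng.normal(size=(2, 3)) + rng.normal(size=(25, 3))
        res = variation_partition(y, x, x.copy())
        assert res.a == pytest.approx(0.0, abs=1e-10)
        assert res.c == pytest.approx(0.0, abs=1e-10)

    def test_empty_spatial_reduces_to_simple_adjusted_r2(self, rng):
        x = pd.DataFrame(rng.normal(size=(25, 2)), columns=["a", "b"])
        y = x.to_numpy() @ rng.normal(size=(2, 3)) + rng.normal(size=(25, 3))
        res = variation_partition(y, x, None)
        assert res.a == pytest.approx(res.adj_env)
        assert res.c == 0.0
        assert res.b == 0.0

    def test_hellinger_rows_unit_norm(self, small_table):
        h = hellinger(small_table)
        np.testing.assert_allclose((h ** 2).sum(axis=1), 1.0)


class TestPERMANOVA:
    def test_univariate_euclidean_equals_anova_f(self, rng):
        x = rng.normal(size=30)
        x[15:] += 1.0
        dm = dm_from(x[:, None])
        labels = np.array(["a"] * 15 + ["b"] * 15)
        res = permanova(dm, labels, n_perm=99, seed=0)
        f_anova = stats.f_oneway(x[:15], x[15:]).statistic
        assert res["pseudo_F"] == pytest.approx(f_anova, abs=1e-8)

    def test_matches_skbio_statistic(self, small_table):
        from skbio.stats.distance import permanova as skbio_permanova
        dm = bray_curtis(small_table)
        labels = ["a"] * 6 + ["b"] * 6
        ours = permanova(dm, labels, n_perm=99, seed=0)
        theirs = skbio_permanova(dm, grouping=labels, permutations=99)
        assert ours["pseudo_F"] == pytest.approx(theirs["test statistic"],
                                                 abs=1e-8)

    def test_separated_clusters(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, size=(10, 2)),
                         rng.normal(10, 0.1, size=(10, 2))])
        res = permanova(dm_from(pts), ["a"] * 10 + ["b"] * 10,
                        n_perm=199, seed=1)
        assert res["r2"] > 0.9
        assert res["p_value"] == pytest.approx(1 / 200)

    def test_r2_bounds_and_single_level_rejected(self, rng):
        pts = rng.normal(size=(12, 2))
        res = permanova(dm_from(pts), ["a"] * 6 + ["b"] * 6, n_perm=49)
        assert 0.0 <= res["r2"] <= 1.0
        with pytest.raises(ValueError):
            permanova(dm_from(pts), ["a"] * 12)

    def test_two_term_sequential_table(self, paired_survey):
        table, metadata = paired_survey
        dm = bray_curtis(table)
        md = metadata.data
        out = permanova_terms(
            dm,
            {"land_use": md["land_use"].to_numpy(),
             "latitude": md["latitude"].to_numpy()},
            n_perm=99, seed=0)
        assert list(out["term"]) == ["land_use", "latitude"]
        assert ((out["r2"] >= 0) & (out["r2"] <= 1)).all()
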