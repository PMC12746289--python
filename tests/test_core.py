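import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from betascape.core import (
    CommunityTable,
    SampleMetadata,
    alpha_diversity,
    bray_curtis,
    cpm_normalize,
    geo_distance,
    haversine_matrix,
    rarefy,
    read_metadata,
    read_table,
    write_table,
)


class TestTableIO:
    def test_round_trip_preserves_counts(self, tmp_path):
        df = pd.DataFrame([[1, 2], [3, 4], [5, 6]],
                          index=["f1", "f2", "f3"], columns=["s1", "s2"])
        path = tmp_path / "t.tsv"
        df.index.name = "#FeatureID"
        df.to_csv(path, sep="\t")
        table = read_table(path)
        assert table.data.shape == (2, 3)  # samples x features
        assert table.data.loc["s1", "f2"] == 3
        out = tmp_path / "out.tsv"
        write_table(table, out)
        again = read_table(out)
        pd.testing.assert_frame_equal(table.data, again.data, check_dtype=False)

    def test_negative_value_rejected_with_location(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("#FeatureID\ts1\ts2\nf1\t3\t-1\nf2\t0\t2\n")
        with pytest.raises(ValueError, match="f1"):
            read_table(path)

    def test_transposed_read_matches(self, tmp_path):
        df = pd.DataFrame([[1, 2, 0], [3, 0, 4]],
                          index=["s1", "s2"], columns=["f1", "f2", "f3"])
        p1 = tmp_path / "features_rows.tsv"
        df.T.to_csv(p1, sep="\t", index_label="#FeatureID")
        p2 = tmp_path / "samples_rows.tsv"
        df.to_csv(p2, sep="\t", index_label="sample_id")
        t1 = read_table(p1, features_as_rows=True)
        t2 = read_table(p2, features_as_rows=False)
        pd.testing.assert_frame_equal(t1.data, t2.data, check_dtype=False)

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame([[1, 2], [3, 4]], index=["a", "a"],
                          columns=["f1", "f2"])
        with pytest.raises(ValueError, match="duplicated sample"):
            CommunityTable(df)


class TestMetadata:
    def test_required_columns_enforced(self):
        with pytest.raises(ValueError, match="missing required"):
            SampleMetadata(pd.DataFrame({"sample_id": ["a"], "site_id": [1]}))

    def test_design_key_uniqueness(self, metadata_frame):
        dup = pd.concat([metadata_frame, metadata_frame.iloc[[0]].assign(
            sample_id="other")], ignore_index=True)
        with pytest.raises(ValueError, match="not unique"):
            SampleMetadata(dup)

    def test_env_columns_detected(self, metadata):
        assert metadata.env_columns == ["pH"]

    def test_read_metadata(self, tmp_path, metadata_frame):
        path = tmp_path / "md.tsv"
        metadata_frame.to_csv(path, sep="\t", index=False)
        md = read_metadata(path)
        assert len(md.sample_ids) == 12


class TestRarefy:
    def test_rows_hit_exact_depth(self, small_table):
        depth = int(small_table.data.sum(axis=1).min())
        out = rarefy(small_table, depth, seed=0)
        assert (out.data.sum(axis=1) == depth).all()
        assert out.normalization == "rarefied"

    def test_sample_at_depth_unchanged(self):
        df = pd.DataFrame([[5, 5], [20, 30]], index=["a", "b"],
                          columns=["f1", "f2"])
        out = rarefy(CommunityTable(df), 10, seed=1)
        assert out.data.loc["a"].tolist() == [5, 5]

    def test_underdepth_samples_dropped(self, small_table, caplog):
        depth = int(small_table.data.sum(axis=1).max())
        out = rarefy(small_table, depth, seed=0)
        assert out.n_samples < small_table.n_samples

    def test_reproducible_under_seed(self, small_table):
        depth = int(small_table.data.sum(axis=1).min())
        a = rarefy(small_table, depth, seed=3)
        b = rarefy(small_table, depth, seed=3)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_mean_matches_hypergeometric_oracle(self):
        # mean subsampled count of one feature vs the hypergeometric mean
        row = np.array([40, 25, 15, 10, 10])
        df = pd.DataFrame([row], index=["s"], columns=list("abcde"))
        table = CommunityTable(df)
        depth, n_rep = 30, 500
        draws = np.array([
            rarefy(table, depth, seed=k).data.iloc[0, 0] for k in range(n_rep)
        ], dtype=float)
        dist = hypergeom(row.sum(), row[0], depth)
        se = dist.std() / math.sqrt(n_rep)
        assert abs(draws.mean() - dist.mean()) < 3 * se

    def test_bad_depth_rejected(self, small_table):
        with pytest.raises(ValueError):
            rarefy(small_table, 0)


class TestCPM:
    def test_closed_form(self):
        df = pd.DataFrame([[2, 3, 5]], index=["s"], columns=list("abc"))
        out = cpm_normalize(CommunityTable(df))
        assert out.data.iloc[0].tolist() == [200000.0, 300000.0, 500000.0]

    def test_idempotent(self, small_table):
        once = cpm_normalize(small_table)
        twice = cpm_normalize(once)
        np.testing.assert_allclose(once.counts, twice.counts)

    def test_row_sums_one_million(self, small_table):
        out = cpm_normalize(small_table)
        np.testing.assert_allclose(out.data.sum(axis=1), 1e6, atol=1e-6)

    def test_zero_row_rejected(self):
        df = pd.DataFrame([[0, 0], [1, 2]], index=["bad", "ok"],
                          columns=["f1", "f2"])
        with pytest.raises(ValueError, match="bad"):
            cpm_normalize(CommunityTable(df))


class TestBrayCurtis:
    def test_hand_computed_values(self):
        df = pd.DataFrame([[1, 1, 0], [0, 1, 1], [1, 1, 0], [2, 0, 0]],
                          index=list("wxyz"), columns=list("abc"))
        dm = bray_curtis(CommunityTable(df))
        assert dm["w", "x"] == pytest.approx(0.5)     # (1+0+1)/4
        assert dm["w", "y"] == 0.0                     # identical rows
        assert dm["x", "z"] == 1.0                     # disjoint support

    def test_matches_brute_force(self, rng):
        counts = rng.integers(1, 30, size=(10, 20)).astype(float)
        df = pd.DataFrame(counts, index=[f"s{i}" for i in range(10)],
                          columns=[f"f{j}" for j in range(20)])
        dm = bray_curtis(CommunityTable(df))
        for i in range(10):
            for j in range(10):
                num = np.abs(counts[i] - counts[j]).sum()
                den = (counts[i] + counts[j]).sum()
                assert dm.data[i, j] == pytest.approx(num / den, abs=1e-12)


class TestGeoDistance:
    def test_one_degree_longitude_at_equator(self):
        d = haversine_matrix(np.array([0.0, 0.0]), np.array([0.0, 1.0]))
        assert d[0, 1] == pytest.approx(6371.0 * math.pi / 180.0, rel=1e-6)

    def test_zero_for_identical_points_and_symmetry(self, rng):
        lat = rng.uniform(-80, 80, 6)
        lon = rng.uniform(-170, 170, 6)
        d = haversine_matrix(lat, lon)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_bad_coordinates_rejected(self, metadata):
        md = SampleMetadata(metadata.data.reset_index().assign(latitude=99.0))
        with pytest.raises(ValueError, match="latitude"):
            geo_distance(md)

    def test_planar_mode_is_euclidean_degrees(self, metadata):
        d = geo_distance(metadata, planar=True)
        md = metadata.data
        expected = math.hypot(md["latitude"].iloc[0] - md["latitude"].iloc[-1],
                              md["longitude"].iloc[0] - md["longitude"].iloc[-1])
        assert d[md.index[0], md.index[-1]] == pytest.approx(expected)


class TestAlphaDiversity:
    def test_uniform_row_gives_log_richness(self):
        df = pd.DataFrame([[4, 4, 4, 4]], index=["s"], columns=list("abcd"))
        res = alpha_diversity(CommunityTable(df))
        assert res.data.loc["s", "shannon"] == pytest.approx(math.log(4))
        assert res.data.loc["s", "richness"] == 4

    def test_single_feature_row(self):
        df = pd.DataFrame([[7, 0, 0]], index=["s"], columns=list("abc"))
        res = alpha_diversity(CommunityTable(df))
        assert res.data.loc["s", "shannon"] == 0.0
        assert res.data.loc["s", "richness"] == 1

    def test_direct_evaluation(self):
        df = pd.DataFrame([[1, 1, 2]], index=["s"], columns=list("abc"))
        res = alpha_diversity(CommunityTable(df))
        expected = -(0.25 * math.log(0.25) * 2 + 0.5 * math.log(0.5))
        assert res.data.loc["s", "shannon"] == pytest.approx(expected)
        assert res.data.loc["s", "shannon"] == pytest.approx(1.0397, abs=1e-4)

    def test_bounds(self, small_table):
        res = alpha_diversity(small_table)
        assert (res.data["shannon"] >= 0).all()
        assert np.all(res.data["shannon"] <= np.log(res.data["richness"]) + 1e-12)
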