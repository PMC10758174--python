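import hypothesis.strategies as st
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from culturedist.distance import (
    MDSResult,
    cultural_distance,
    gps_centroid,
    log_and_quartile,
    nonmetric_mds,
    profile_dissimilarity,
)
from culturedist.ratings import RatingsMatrix


def _matrix(rows, group="GPS"):
    return RatingsMatrix.from_arrays(np.asarray(rows, dtype=float), group)


def _mds(coords, labels=None):
    coords = np.asarray(coords, dtype=float)
    idx = labels if labels is not None else [f"P{i}" for i in range(len(coords))]
    frame = pd.DataFrame(coords, index=idx,
                         columns=[f"dim{k+1}" for k in range(coords.shape[1])])
    return MDSResult(frame, 0.0, coords.shape[1], 0, 1)


class TestProfileDissimilarity:
    def test_identical_profiles(self):
        m = _matrix([[1, 2, 3, 4], [1, 2, 3, 4], [2, 1, 4, 3]])
        d = profile_dissimilarity(m)
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_anticorrelated_profiles(self):
        m = _matrix([[1, 2, 3, 4], [4, 3, 2, 1], [2, 1, 4, 3]])
        d = profile_dissimilarity(m)
        assert d.iloc[0, 1] == pytest.approx(2.0)

    def test_elevation_shift_ignored(self):
        m = _matrix([[1, 2, 1, 2], [2, 3, 2, 3], [2, 1, 4, 3]])
        d = profile_dissimilarity(m)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_informant_dropped(self):
        m = _matrix([[2, 2, 2, 2], [1, 2, 3, 4], [4, 3, 2, 1]])
        with pytest.warns(UserWarning, match="zero-variance"):
            d = profile_dissimilarity(m)
        assert d.shape == (2, 2)


class TestNonmetricMDS:
    def test_equilateral_triple_embeds_exactly(self):
        d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        res = nonmetric_mds(d, n_dims=2, seed=0, n_starts=8)
        assert res.stress <= 0.001

    def test_monotone_transform_invariance(self):
        # squaring all dissimilarities preserves rank order, so the
        # nonmetric solution's distance geometry should be unchanged
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 2))
        d = squareform(pdist(pts))
        labels = [f"P{i}" for i in range(12)]
        d1 = pd.DataFrame(d, index=labels, columns=labels)
        d2 = pd.DataFrame(d**2, index=labels, columns=labels)
        r1 = nonmetric_mds(d1, seed=0, n_starts=8)
        r2 = nonmetric_mds(d2, seed=0, n_starts=8)
        _, _, disparity = procrustes(r1.coordinates.to_numpy(),
                                     r2.coordinates.to_numpy())
        assert disparity < 0.05

    def test_stress_non_increasing_in_dims(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(10, 3))
        d = squareform(pdist(pts))
        labels = [f"P{i}" for i in range(10)]
        frame = pd.DataFrame(d, index=labels, columns=labels)
        stresses = [nonmetric_mds(frame, n_dims=k, seed=0, n_starts=4).stress
                    for k in (1, 2, 3)]
        assert stresses[0] >= stresses[1] - 1e-6
        assert stresses[1] >= stresses[2] - 1e-6

    def test_too_many_dims_rejected(self):
        d = pd.DataFrame(1.0 - np.eye(3))
        with pytest.raises(ValueError, match="n_dims"):
            nonmetric_mds(d, n_dims=3)


class TestCentroidAndDistance:
    def test_centroid_of_symmetric_pair(self):
        mds = _mds([[1, 0], [-1, 0], [5, 5]], ["g1", "g2", "t1"])
        groups = pd.Series(["GPS", "GPS", "TG"], index=["g1", "g2", "t1"])
        np.testing.assert_allclose(gps_centroid(mds, groups), [0, 0])

    def test_single_gps_member_is_centroid(self):
        mds = _mds([[2.5, -1], [0, 0]], ["g1", "t1"])
        groups = pd.Series(["GPS", "TG"], index=["g1", "t1"])
        np.testing.assert_allclose(gps_centroid(mds, groups), [2.5, -1])

    def test_translation_equivariance(self):
        coords = np.array([[1.0, 2.0], [3.0, -1.0], [0.0, 0.0]])
        groups = pd.Series(["GPS", "GPS", "TG"], index=["P0", "P1", "P2"])
        c0 = gps_centroid(_mds(coords), groups)
        c1 = gps_centroid(_mds(coords + [10, -3]), groups)
        np.testing.assert_allclose(c1, c0 + [10, -3])

    def test_no_gps_members_error(self):
        mds = _mds([[0, 0]], ["t1"])
        with pytest.raises(ValueError, match="no GPS"):
            gps_centroid(mds, pd.Series(["TG"], index=["t1"]))

    @pytest.mark.parametrize("point,centroid,expected", [
        ((1, 1), (0, 0), 2.0),
        ((0.5, -2), (0.5, -2), 0.0),
        ((3, -1), (1, 1), 8.0),
    ])
    def test_squared_euclidean_examples(self, point, centroid, expected):
        mds = _mds([point, (9, 9)], ["t1", "g1"])
        groups = pd.Series(["TG", "GPS"], index=["t1", "g1"])
        d = cultural_distance(mds, np.asarray(centroid, float), groups)
        assert d.loc["t1"] == pytest.approx(expected)

    def test_gps_members_excluded_from_output(self):
        mds = _mds([[1, 1], [2, 2]], ["g1", "t1"])
        groups = pd.Series(["GPS", "TG"], index=["g1", "t1"])
        d = cultural_distance(mds, np.zeros(2), groups)
        assert list(d.index) == ["t1"]

    def test_dimension_mismatch_error(self):
        mds = _mds([[1, 1]], ["t1"])
        with pytest.raises(ValueError, match="dimension"):
            cultural_distance(mds, np.zeros(3),
                              pd.Series(["TG"], index=["t1"]))

    def test_distances_invariant_to_orthogonal_transform(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(30, 2))
        groups = pd.Series(["GPS"] * 10 + ["TG"] * 20,
                           index=[f"P{i}" for i in range(30)])
        q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        m1, m2 = _mds(coords), _mds(coords @ q)
        d1 = cultural_distance(m1, gps_centroid(m1, groups), groups)
        d2 = cultural_distance(m2, gps_centroid(m2, groups), groups)
        np.testing.assert_allclose(d1, d2, atol=1e-10)


class TestEndToEndRecovery:
    def test_planted_deviation_classes_recovered_by_log_distance(self):
        # Spearman correlation between the generator's true distance class
        # and the estimated log cultural distance, median over seeds
        from scipy.stats import spearmanr

        from culturedist.distance import CulturalDistanceModel
        from culturedist.simulate import SyntheticConfig, generate_gps, generate_tg

        rhos = []
        for seed in range(10):
            cfg = SyntheticConfig(seed=seed)
            gps = generate_gps(cfg)
            tg, cls = generate_tg(cfg)
            res = CulturalDistanceModel(gps.pool(tg), seed=seed,
                                        n_starts=4).fit()
            rhos.append(spearmanr(cls, res.log_distance.reindex(cls.index))[0])
        assert np.median(rhos) >= 0.8


class TestLogAndQuartile:
    def test_log_of_e_squared(self):
        raw = pd.Series([np.e**2, 1.0, 2.0, 3.0])
        out = log_and_quartile(raw)
        assert out["log_distance"].iloc[0] == pytest.approx(2.0)

    def test_eight_values_split_evenly(self):
        raw = pd.Series([8, 1, 5, 3, 7, 2, 6, 4], dtype=float)
        out = log_and_quartile(raw)
        assert out["quartile"].value_counts().tolist() == [2, 2, 2, 2]
        # order-preserving: larger distance never in a lower quartile
        ordered = out.sort_values("log_distance")["quartile"]
        assert (ordered.diff().dropna() >= 0).all()

    def test_133_values_extra_member_in_first_quartile(self):
        rng = np.random.default_rng(0)
        raw = pd.Series(rng.exponential(size=133))
        sizes = log_and_quartile(raw)["quartile"].value_counts().sort_index()
        assert sizes.tolist() == [34, 33, 33, 33]

    def test_zero_distances_offset_before_log(self):
        raw = pd.Series([0.0, 1.0, 2.0, 4.0])
        out = log_and_quartile(raw)
        assert out["log_distance"].iloc[0] == pytest.approx(np.log(0.5))

    def test_degenerate_distances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            log_and_quartile(pd.Series([1.0, 1.0, 1.0, 1.0]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6,
                              allow_nan=False), min_size=5, max_size=60,
                    unique=True))
    def test_quartile_invariants_hold_for_any_distances(self, values):
        out = log_and_quartile(pd.Series(values))
        sizes = out["quartile"].value_counts()
        # sizes as equal as possible, labels 1..4, monotone in log distance
        assert sizes.max() - sizes.min() <= 1
        assert set(out["quartile"]) <= {1, 2, 3, 4}
        ordered = out.sort_values("log_distance")["quartile"]
        assert (ordered.diff().dropna() >= 0).all()
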