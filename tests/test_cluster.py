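"""Profile clustering: z-scores, k-means, FOM, scaled-distance assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fermstage.errors import IntegrityError
from fermstage.cluster import (ClusterModel, ZProfileMatrix,
                               drop_small_clusters, figure_of_merit,
                               form_new_clusters, kmeans, merge_clusters,
                               scaled_distance_assign, seed_clusters, zscore)
from fermstage.io_formats import STAGES


def zmat_from(values: dict) -> ZProfileMatrix:
    """Build a ZProfileMatrix directly from raw profile rows (no scaling)."""
    z = pd.DataFrame.from_dict(values, orient="index")
    idx = z.index
    return ZProfileMatrix(z=z,
                          row_mean=pd.Series(0.0, index=idx),
                          row_sd=pd.Series(1.0, index=idx),
                          constant=pd.Series(False, index=idx))


def model_with_means(means: dict, default_threshold=0.3,
                     overrides=None) -> ClusterModel:
    mp = pd.DataFrame.from_dict(means, orient="index")
    membership = pd.DataFrame(columns=["cluster", "source", "d_scaled"])
    return ClusterModel(membership=membership, mean_profiles=mp,
                        default_threshold=default_threshold,
                        threshold_overrides=dict(overrides or {}),
                        k_seed=len(means))


class TestZscore:
    def test_hand_example(self):
        sm = pd.DataFrame([[1, 2, 3, 4, 5]], index=["g"],
                          columns=list(STAGES), dtype=float)
        zm = zscore(sm)
        np.testing.assert_allclose(
            zm.z.loc["g"], [-1.2649, -0.6325, 0.0, 0.6325, 1.2649],
            atol=5e-5)
        assert zm.row_sd["g"] == pytest.approx(np.sqrt(2.5))

    def test_constant_row_flagged(self):
        sm = pd.DataFrame([[7.0] * 5], index=["g"], columns=list(STAGES))
        zm = zscore(sm)
        assert (zm.z.loc["g"] == 0).all()
        assert zm.constant["g"]

    def test_rows_standardized(self, rng):
        sm = pd.DataFrame(rng.uniform(0, 100, (30, 5)),
                          columns=list(STAGES))
        zm = zscore(sm)
        np.testing.assert_allclose(zm.z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(zm.z.std(axis=1, ddof=1), 1.0, atol=1e-9)


class TestKmeans:
    def test_two_well_separated_pairs(self):
        pts = np.array([[0, 0], [0, 1], [10, 10], [10, 11]], dtype=float)
        res = kmeans(pts, 2, seed=0)
        assert res.labels[0] == res.labels[1]
        assert res.labels[2] == res.labels[3]
        assert res.labels[0] != res.labels[2]
        got = {tuple(c) for c in np.round(res.centers, 6)}
        assert got == {(0.0, 0.5), (10.0, 10.5)}

    def test_k_equals_n_gives_zero_objective(self, rng):
        pts = rng.uniform(0, 1, (6, 3))
        res = kmeans(pts, 6, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(IntegrityError):
            kmeans(np.zeros((3, 2)), 4)

    def test_duplicates_stay_together(self):
        pts = np.array([[0, 0], [0, 0], [5, 5], [9, 9]], dtype=float)
        res = kmeans(pts, 2, seed=1, n_restarts=10)
        assert res.labels[0] == res.labels[1]

    def test_matches_exhaustive_optimum_on_small_instances(self, rng):
        """Lloyd + restarts find the globally optimal partition."""
        def exhaustive(x, k):
            best = np.inf
            n = len(x)
            for labels in itertools.product(range(k), repeat=n):
                if len(set(labels)) != k:
                    continue
                lab = np.array(labels)
                obj = 0.0
                for c in range(k):
                    pts = x[lab == c]
                    obj += ((pts - pts.mean(axis=0)) ** 2).sum()
                best = min(best, obj)
            return best

        for trial in range(5):
            n = int(rng.integers(5, 9))
            k = int(rng.integers(2, 4))
            x = rng.uniform(0, 10, (n, 2))
            res = kmeans(x, k, seed=trial, n_restarts=50)
            assert res.inertia == pytest.approx(exhaustive(x, k), rel=1e-8)


class TestFigureOfMerit:
    def test_raw_fom_zero_at_k_equals_n(self, rng):
        x = rng.uniform(-2, 2, (8, 5))
        fom = figure_of_merit(x, [2, 8], seed=0)
        raw = dict(fom.raw_curve)
        assert raw[8] == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(0, 1, (40, 5))
        f1 = figure_of_merit(x, range(2, 7), seed=5)
        f2 = figure_of_merit(x, range(2, 7), seed=5)
        assert f1.curve == f2.curve
        assert f1.k_estimate == f2.k_estimate

    def test_empty_k_range_rejected(self, rng):
        with pytest.raises(IntegrityError):
            figure_of_merit(rng.normal(0, 1, (10, 5)), [], seed=0)

    def test_recovers_planted_shape_count(self, rng):
        """Six well-separated shapes with small noise give k_estimate 6."""
        hits = 0
        for s in range(10):
            r = np.random.default_rng(900 + s)
            shapes = np.eye(6, 5)[:, :5]  # crude distinct profiles
            shapes = np.vstack([shapes[:5], -np.ones(5) / np.sqrt(5)])
            x = np.vstack([shape + r.normal(0, 0.08, (25, 5))
                           for shape in shapes])
            fom = figure_of_merit(x, range(2, 10), seed=s)
            hits += fom.k_estimate == 6
        assert hits >= 8


class TestScaledDistanceAssign:
    def test_exact_match_assigned_at_zero(self):
        zm = zmat_from({"g1": [1.0, 0.0], "far": [100.0, 100.0]})
        model = model_with_means({"A": [1.0, 0.0], "B": [0.0, 50.0]})
        model, un = scaled_distance_assign(zm, model, ["g1", "far"])
        assert model.membership.loc["g1", "cluster"] == "A"
        assert model.membership.loc["g1", "d_scaled"] == 0.0

    def test_hand_scaling_example(self):
        # gene at distance 1 and 5 from the two means; a remote gene
        # fixes d_max = 10; scaled distances (0.1, 0.5) -> cluster A
        zm = zmat_from({"g": [1.0, 0.0], "remote": [6.0, 0.0]})
        model = model_with_means({"A": [0.0, 0.0], "B": [-4.0, 0.0]})
        model, un = scaled_distance_assign(zm, model, ["g", "remote"])
        assert model.d_max == pytest.approx(10.0)
        assert model.membership.loc["g", "cluster"] == "A"
        assert model.membership.loc["g", "d_scaled"] == pytest.approx(0.1)

    def test_threshold_is_strict(self):
        # d(g, A) = 3, d_max = 10 -> d_scaled = 0.3 exactly: NOT assigned
        zm = zmat_from({"g": [3.0, 0.0], "remote": [10.0, 0.0]})
        model = model_with_means({"A": [0.0, 0.0]})
        model, un = scaled_distance_assign(zm, model, ["g", "remote"])
        assert "g" in un
        assert "g" not in model.membership.index

    def test_override_threshold(self):
        zm = zmat_from({"g": [3.0, 0.0], "remote": [10.0, 0.0]})
        model = model_with_means({"G": [0.0, 0.0]},
                                 overrides={"G": 0.6})
        model, un = scaled_distance_assign(zm, model, ["g", "remote"])
        assert model.membership.loc["g", "cluster"] == "G"

    def test_assigned_genes_respect_threshold_exactly(self, rng):
        zm_values = {f"g{i}": rng.normal(0, 1, 5) for i in range(200)}
        zm = zmat_from(zm_values)
        means = {lab: rng.normal(0, 1, 5) for lab in "ABCD"}
        model = model_with_means(means)
        model, un = scaled_distance_assign(zm, model, list(zm_values))
        for gene, row in model.membership.iterrows():
            assert row["d_scaled"] < model.threshold(row["cluster"])
        assert set(un) | set(model.membership.index) == set(zm_values)


class TestFormNewClusters:
    def test_empty_leftover_is_noop(self, rng):
        zm = zmat_from({f"g{i}": rng.normal(0, 1, 5) for i in range(10)})
        model = model_with_means({"A": np.zeros(5)})
        before = len(model.labels)
        model, un = form_new_clusters(zm, model, [], seed=0)
        assert len(model.labels) == before
        assert len(un) == 0

    def test_two_leftover_shapes_recovered(self):
        r = np.random.default_rng(3)
        s1 = np.array([2.0, -1, -1, 0, 0])
        s2 = np.array([-1.0, -1, 2, 0, 0])
        rows = {}
        truth = {}
        for i in range(30):
            rows[f"a{i}"] = s1 + r.normal(0, 0.05, 5)
            truth[f"a{i}"] = 0
            rows[f"b{i}"] = s2 + r.normal(0, 0.05, 5)
            truth[f"b{i}"] = 1
        zm = zmat_from(rows)
        model = model_with_means({"A": np.full(5, 30.0)})  # far away
        model, un = form_new_clusters(zm, model, list(rows), seed=1)
        new_labels = [l for l in model.labels if l != "A"]
        assert len(new_labels) == 2
        from sklearn.metrics import adjusted_rand_score
        members = model.membership
        got = [members.loc[g, "cluster"] for g in rows]
        want = [truth[g] for g in rows]
        assert adjusted_rand_score(want, got) >= 0.9
        assert (members["source"] == "new").all()


class TestSeedClusters:
    @pytest.fixture()
    def de_like(self, rng):
        genes = [f"g{i}" for i in range(120)]
        table = pd.DataFrame({
            "reliable": True,
            "eb_likelihood": np.where(np.arange(120) < 100, 0.995, 0.95),
        }, index=genes)
        shapes = np.array([[2, -1, -1, 0, 0], [-1, 2, -1, 0, 0],
                           [0, -1, -1, 2, 0]], dtype=float)
        z = np.vstack([shapes[i % 3] + rng.normal(0, 0.05, 5)
                       for i in range(120)])
        zm = ZProfileMatrix(
            z=pd.DataFrame(z, index=genes, columns=list(STAGES)),
            row_mean=pd.Series(0.0, index=genes),
            row_sd=pd.Series(1.0, index=genes),
            constant=pd.Series(False, index=genes))
        return table, zm

    def test_only_high_confidence_genes_seed(self, de_like):
        table, zm = de_like
        model = seed_clusters(zm, table, k=3, seed=0)
        assert set(model.membership.index) == set(table.index[:100])
        assert (model.membership["source"] == "seed").all()

    def test_labels_by_decreasing_size_and_stable(self, de_like):
        table, zm = de_like
        m1 = seed_clusters(zm, table, k=3, seed=0)
        m2 = seed_clusters(zm, table, k=3, seed=0)
        pd.testing.assert_frame_equal(m1.membership, m2.membership)
        sizes = [m1.cluster_sizes()[lab] for lab in m1.labels]
        assert sizes == sorted(sizes, reverse=True)

    def test_too_small_seed_set_rejected(self, de_like):
        table, zm = de_like
        table = table.copy()
        table["eb_likelihood"] = 0.5
        with pytest.raises(IntegrityError):
            seed_clusters(zm, table, k=3, seed=0)


class TestCuration:
    def test_merge_near_identical_means(self):
        model = model_with_means({"A": [0.0, 0], "B": [0.005, 0],
                                  "C": [5.0, 5]})
        model.membership = pd.DataFrame(
            {"cluster": ["A", "B", "C"], "source": "seed",
             "d_scaled": np.nan}, index=["g1", "g2", "g3"])
        model = merge_clusters(model, merge_tol=0.1)
        assert set(model.labels) == {"A", "C"}
        assert model.membership.loc["g2", "cluster"] == "A"

    def test_drop_small_releases_members(self):
        model = model_with_means({"A": [0.0, 0], "B": [5.0, 5]})
        model.membership = pd.DataFrame(
            {"cluster": ["A"] * 5 + ["B"], "source": "seed",
             "d_scaled": np.nan},
            index=[f"g{i}" for i in range(6)])
        model, released = drop_small_clusters(model, min_cluster_size=3)
        assert model.labels == ["A"]
        assert list(released) == ["g5"]
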