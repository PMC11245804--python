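"""Agreement metrics, dissimilarity statistics, model selection and
post-filters."""

import numpy as np
import pytest

from radnet.evaluation import (LabelVector, SweepCandidate,
                               cluster_dissimilarity, cosine_distance,
                               d_score, entropy, filter_clusters, hs,
                               metrics_report, nmi, oversample_plan, score_s,
                               select_models)


class TestNmiHs:
    Y = np.array(["A", "A", "B", "B"])
    Y_HAT = np.array([0, 0, 0, 1])

    def test_hand_computed_example(self):
        # H(y) = ln 2; H(y|y_hat) = 3/4 * H(2/3, 1/3)
        h_y = np.log(2)
        h_cond = 0.75 * (-(2 / 3) * np.log(2 / 3) - (1 / 3) * np.log(1 / 3))
        assert hs(self.Y, self.Y_HAT) == pytest.approx(1 - h_cond / h_y)
        assert hs(self.Y, self.Y_HAT) == pytest.approx(0.3113, abs=2e-4)
        h_hat = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        expected_nmi = 2 * (h_y - h_cond) / (h_y + h_hat)
        assert nmi(self.Y, self.Y_HAT) == pytest.approx(expected_nmi)

    def test_perfect_clustering_up_to_relabelling(self):
        y = np.array(["A", "B", "A", "C"])
        assert nmi(y, np.array([7, 2, 7, 5])) == pytest.approx(1.0)
        assert hs(y, np.array([7, 2, 7, 5])) == pytest.approx(1.0)

    def test_single_cluster_scores_zero(self):
        y = np.array(["A", "A", "B", "B"])
        assert nmi(y, np.zeros(4)) == pytest.approx(0.0)
        assert hs(y, np.zeros(4)) == pytest.approx(0.0)

    def test_constant_truth(self):
        with pytest.raises(ValueError):
            hs(np.array(["A", "A"]), np.array([0, 1]))
        assert nmi(np.array(["A", "A"]), np.array([0, 0])) == 0.0

    def test_oracle_equivalence_on_random_contingency_tables(self):
        """sklearn's implementations as independent oracle: |delta| < 1e-10
        over 100 random label/assignment pairs."""
        from sklearn.metrics import (homogeneity_score,
                                     normalized_mutual_info_score)

        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, int(rng.integers(2, 6)), size=n)
            if len(np.unique(y)) < 2:
                continue
            y_hat = rng.integers(0, int(rng.integers(2, 8)), size=n)
            assert abs(nmi(y, y_hat) -
                       normalized_mutual_info_score(y, y_hat)) < 1e-10
            assert abs(hs(y, y_hat) - homogeneity_score(y, y_hat)) < 1e-10

    def test_invariance_to_relabelling(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, size=40)
        y_hat = rng.integers(0, 5, size=40)
        relabelled = (y_hat * 7 + 3) % 11
        assert nmi(y, y_hat) == pytest.approx(nmi(y, relabelled))
        assert hs(y, y_hat) == pytest.approx(hs(y, relabelled))


class TestScores:
    def test_harmonic_mean_properties(self):
        assert score_s(0.4, 0.4, 0.4, 0.4) == pytest.approx(0.4)
        assert score_s(0.5, 0.5, 1.0, 1.0) == pytest.approx(2 / 3)
        assert score_s(0.0, 0.9, 0.9, 0.9) == 0.0
        # a harmonic mean sits between the min and the arithmetic mean
        s = score_s(0.2, 0.4, 0.6, 0.8)
        assert 0.2 <= s <= np.mean([0.2, 0.4, 0.6, 0.8])

    def test_d_score(self):
        assert d_score(0.02, 0.04) == pytest.approx(4 / 150)
        assert d_score(0.3, 0.3) == pytest.approx(0.3)
        assert d_score(0.0, 0.5) == 0.0
        assert d_score(0.1, 0.7) == d_score(0.7, 0.1)

    def test_metrics_report_bounds(self):
        rng = np.random.default_rng(2)
        labels = LabelVector(y_m=rng.integers(0, 3, 50),
                             y_b=rng.integers(0, 4, 50))
        report = metrics_report(labels, rng.integers(0, 5, 50))
        parts = (report.nmi_m, report.nmi_b, report.hs_m, report.hs_b)
        for v in parts:
            assert 0.0 <= v <= 1.0
        assert min(parts) - 1e-12 <= report.s <= np.mean(parts) + 1e-12


class TestCosine:
    def test_reference_angles(self):
        assert cosine_distance([1, 0], [2, 0]) == pytest.approx(0.0)
        assert cosine_distance([1, 0], [0, 3]) == pytest.approx(1.0)
        assert cosine_distance([1, 1], [-2, -2]) == pytest.approx(2.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance([0, 0], [1, 1])


class TestClusterDissimilarity:
    def test_identical_embeddings_give_zero(self):
        X = np.tile([1.0, 2.0], (5, 1))
        report = cluster_dissimilarity(X, np.zeros(5, dtype=int))
        assert report.per_cluster[0] == pytest.approx(0.0, abs=1e-12)

    def test_pair_counts(self):
        X = np.random.default_rng(3).normal(size=(4, 3)) + 2
        report = cluster_dissimilarity(X, np.zeros(4, dtype=int))
        assert report.pair_counts[0] == 6  # k(k-1)/2 with k=4

    def test_matches_exhaustive_pair_oracle(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        report = cluster_dissimilarity(X, np.zeros(3, dtype=int))
        pairs = [(0, 1), (0, 2), (1, 2)]
        oracle = np.mean([cosine_distance(X[i], X[j]) for i, j in pairs])
        assert report.mean == pytest.approx(oracle, abs=1e-12)

    def test_sampled_mode_flags_cluster_and_approximates(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(300, 5)) + 3
        y = np.zeros(300, dtype=int)
        exact = cluster_dissimilarity(X, y, max_pairs=10**9)
        sampled = cluster_dissimilarity(X, y, max_pairs=2000, seed=0)
        assert sampled.sampled_clusters == [0]
        assert sampled.mean == pytest.approx(exact.mean, rel=0.1)

    def test_singletons_excluded_and_reported(self):
        X = np.random.default_rng(5).normal(size=(5, 3)) + 2
        y = np.array([0, 0, 0, 0, 1])
        report = cluster_dissimilarity(X, y)
        assert report.skipped_clusters == [1]
        with pytest.raises(ValueError):
            cluster_dissimilarity(X[:2], np.array([0, 1]))


class TestSelectModels:
    @staticmethod
    def sweep(name, s_quality, labels, rng):
        """Candidate whose assignment at the knee matches truth at the given
        quality (fraction of records correctly grouped)."""
        kappas = [5, 10, 15, 20, 25]
        inertias = [100.0 / k for k in kappas]
        assignments = {}
        for k in kappas:
            y = labels.copy()
            flip = rng.random(len(y)) > s_quality
            y = np.where(flip, rng.integers(0, 3, len(y)), y)
            assignments[k] = y
        return SweepCandidate(name, kappas, inertias, assignments)

    def test_ranking_rules(self):
        rng = np.random.default_rng(6)
        y_m = rng.integers(0, 3, 200)
        y_b = rng.integers(0, 3, 200)
        labels = LabelVector(y_m=y_m, y_b=y_b)
        good_y = y_m * 3 + y_b  # jointly pure assignment
        image_sweeps = [self.sweep("cae", 0.95, good_y, rng),
                        self.sweep("unet", 0.40, good_y, rng)]
        text_sweeps = [self.sweep("pvdbow", 0.9, good_y, rng),
                       self.sweep("bow", 0.5, good_y, rng)]
        tag_sweeps = [self.sweep("ae", 0.9, good_y, rng),
                      self.sweep("pca", 0.2, good_y, rng)]
        rng2 = np.random.default_rng(7)
        emb = {}
        for name in ("cae", "unet", "pvdbow", "bow"):
            directions = rng2.normal(size=(9, 6))  # one direction per group
            emb[name] = 3.0 * directions[good_y] + rng2.normal(size=(200, 6))
        report = select_models(image_sweeps, text_sweeps, tag_sweeps, labels,
                               {"cae": emb["cae"], "unet": emb["unet"]},
                               {"pvdbow": emb["pvdbow"], "bow": emb["bow"]})
        assert report["image"]["winner"] == "cae"
        assert report["text"]["winner"] == "pvdbow"
        # tags ranked by D_score, lower wins: the 0.9-quality assignment
        # groups similar embeddings together => smaller within-cluster spread
        assert report["tags"]["winner"] == "ae"
        ranking = report["tags"]["ranking"]
        assert ranking[0]["D_score"] <= ranking[1]["D_score"]

    def test_single_candidate_selected_trivially(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 3, 60)
        labels = LabelVector(y_m=y, y_b=y)
        cand = self.sweep("only", 0.9, y, rng)
        emb = {"only": rng.normal(size=(60, 4)) + y[:, None]}
        report = select_models([cand], [cand], [cand], labels, emb, emb)
        for source in ("image", "text", "tags"):
            assert report[source]["winner"] == "only"

    def test_missing_sweep_rejected(self):
        with pytest.raises(ValueError):
            select_models([], [], [], LabelVector(np.zeros(2), np.zeros(2)),
                          {}, {})


class TestFilters:
    def make_labels(self, n, mixed_mask, rng):
        y_m = np.array(["CT"] * n, dtype=object)
        y_b = np.array(["HEAD"] * n, dtype=object)
        parts = np.array(["HEAD", "CHEST", "HAND", "FOOT", "ABDOMEN",
                          "KNEE", "HIP", "SPINE", "NECK", "PELVIS"])
        y_b[mixed_mask] = parts[rng.integers(0, 10, int(mixed_mask.sum()))]
        # ensure more than one level overall so entropies are defined
        y_m[-1] = "CR"
        return LabelVector(y_m=y_m, y_b=y_b)

    def test_small_and_mixed_clusters_removed(self):
        rng = np.random.default_rng(9)
        # cluster 0: 200 pure; cluster 1: 50 pure (too small);
        # cluster 2: 300 uniformly mixed over 10 body parts
        y_hat = np.array([0] * 200 + [1] * 50 + [2] * 300)
        mixed = y_hat == 2
        labels = self.make_labels(len(y_hat), mixed, rng)
        filtered, log = filter_clusters(y_hat, labels, min_size=100,
                                        entropy_cutoff=0.9)
        assert "size" in log[1]
        assert "entropy" in log[2]
        assert set(filtered[y_hat == 0]) == {0}   # survivor re-indexed densely
        assert set(filtered[y_hat != 0]) == {-1}

    def test_pure_large_cluster_kept(self):
        rng = np.random.default_rng(10)
        y_hat = np.zeros(200, dtype=int)
        labels = self.make_labels(200, np.zeros(200, dtype=bool), rng)
        filtered, log = filter_clusters(y_hat, labels)
        assert log == {} and set(filtered) == {0}

    def test_oversample_plan_matches_largest(self):
        y = np.array([0] * 10 + [1] * 4)
        assert oversample_plan(y) == {0: 0, 1: 6}
        assert oversample_plan(np.array([0] * 5)) == {0: 0}
        plan = oversample_plan(np.array([0] * 7 + [1] * 3 + [2] * 5))
        total = sum(plan.values()) + 15
        assert total == 3 * 7  # kept kappa x max cluster size

    def test_removed_records_ignored_by_plan(self):
        y = np.array([0] * 6 + [-1] * 4 + [1] * 2)
        assert oversample_plan(y) == {0: 0, 1: 4}
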