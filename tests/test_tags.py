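"""Tag preprocessing chain and tag feature extractors."""

import numpy as np
import pandas as pd
import pytest

from radnet import tags
from radnet.tags import (TagAEConfig, TagTable, encode_tags, filter_tags,
                         fit_tag_autoencoder, fit_tag_pca, impute_missing,
                         reconstruct_bpe, split_array_tags)


def table_from(frame, kinds=None):
    return TagTable(pd.DataFrame(frame), kinds or {})


# ---------------------------------------------------------------------------
# BodyPartExamined reconstruction
# ---------------------------------------------------------------------------


class TestReconstructBPE:
    RULES = [(r"(?i)ankle|foot", "StudyDescription", "FOOT"),
             (r"(?i)skull", "StudyDescription", "HEAD")]

    def test_blank_filled_from_matching_rule(self):
        t = table_from({"BodyPartExamined": ["", "HEAD"],
                        "StudyDescription": ["ankle AP/LAT", "ankle AP"]})
        out, n = reconstruct_bpe(t, self.RULES)
        assert n == 1
        assert out.frame["BodyPartExamined"].tolist() == ["FOOT", "HEAD"]

    def test_non_blank_never_overwritten(self):
        t = table_from({"BodyPartExamined": ["HEAD"],
                        "StudyDescription": ["ankle"]})
        out, n = reconstruct_bpe(t, self.RULES)
        assert n == 0 and out.frame["BodyPartExamined"].tolist() == ["HEAD"]

    def test_first_matching_rule_wins(self):
        rules = [(r"(?i)ankle", "StudyDescription", "FOOT"),
                 (r"(?i)ankle", "StudyDescription", "HEAD")]
        t = table_from({"BodyPartExamined": [""],
                        "StudyDescription": ["ankle"]})
        out, _ = reconstruct_bpe(t, rules)
        assert out.frame["BodyPartExamined"].tolist() == ["FOOT"]

    def test_no_match_stays_missing(self):
        t = table_from({"BodyPartExamined": [""],
                        "StudyDescription": ["thorax"]})
        out, n = reconstruct_bpe(t, self.RULES)
        assert n == 0 and out.frame["BodyPartExamined"].isna().all()

    def test_malformed_pattern_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            reconstruct_bpe(table_from({"BodyPartExamined": [""]}),
                            [("(unclosed", "StudyDescription", "X")])


# ---------------------------------------------------------------------------
# array splitting
# ---------------------------------------------------------------------------


class TestSplitArrayTags:
    def test_two_element_array_becomes_two_columns(self):
        t = table_from({"WindowCenter": [[40, 400], [50, 500]]})
        out = split_array_tags(t)
        assert list(out.frame.columns) == ["WindowCenter_0", "WindowCenter_1"]
        assert out.frame["WindowCenter_0"].tolist() == [40, 50]
        assert out.frame["WindowCenter_1"].tolist() == [400, 500]

    def test_scalar_columns_unchanged(self):
        t = table_from({"KVP": [60.0, 70.0], "Modality": ["CR", "CT"]})
        out = split_array_tags(t)
        pd.testing.assert_frame_equal(out.frame, t.frame)

    def test_ragged_arrays_padded_with_missing(self):
        t = table_from({"W": [[1, 2], [1, 2, 3]]})
        out = split_array_tags(t)
        assert list(out.frame.columns) == ["W_0", "W_1", "W_2"]
        assert np.isnan(out.frame["W_2"].iloc[0])
        assert out.frame["W_2"].iloc[1] == 3


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


class TestFilterTags:
    def test_fill_rate_boundary_is_inclusive(self):
        n = 100
        col34 = [float(i) for i in range(34)] + [np.nan] * 66
        col35 = [float(i) for i in range(35)] + [np.nan] * 65
        keep = [float(i % 7) for i in range(n)]
        t = table_from({"at_34": col34, "at_35": col35, "dense": keep})
        out = filter_tags(t, fill_threshold=0.35)
        assert "at_34" not in out.frame.columns
        assert "at_35" in out.frame.columns

    def test_constant_and_identifier_columns_dropped(self):
        t = table_from({
            "const": ["X"] * 10,
            "uid": [f"1.2.{i}" for i in range(10)],
            "keep": ["A", "B"] * 5,
        })
        out = filter_tags(t)
        assert list(out.frame.columns) == ["keep"]

    def test_continuous_all_distinct_not_treated_as_identifier(self):
        t = table_from({"exposure": np.linspace(0.0, 1.0, 10),
                        "keep": ["A", "B"] * 5})
        assert "exposure" in filter_tags(t).frame.columns

    def test_freetext_list_dropped_and_idempotent(self):
        t = table_from({"StudyDescription": ["ankle", "skull"] * 5,
                        "keep": ["A", "B"] * 5})
        out = filter_tags(t)
        assert list(out.frame.columns) == ["keep"]
        again = filter_tags(out)
        pd.testing.assert_frame_equal(again.frame, out.frame)

    def test_everything_dropped_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            filter_tags(table_from({"const": ["X"] * 5}))


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


class TestImputeMissing:
    def test_complete_table_is_identity(self):
        t = table_from({"a": [1.0, 2.0, 3.0], "b": ["x", "y", "x"]})
        out = impute_missing(t, n_trees=5, seed=0)
        pd.testing.assert_frame_equal(out.frame, t.frame)

    def test_constant_predictors_approach_column_mean(self):
        # with uninformative predictors each tree predicts a bootstrap mean
        # of the observed values, so the forest hovers around the column mean
        t = table_from({"target": [1.0, 3.0] * 10 + [np.nan, np.nan],
                        "flat": [1.0] * 22})
        out = impute_missing(t, n_trees=100, seed=0)
        assert out.frame["target"].iloc[20:].tolist() == pytest.approx(
            [2.0, 2.0], abs=0.25)

    def test_beats_mean_imputation_under_mcar(self):
        """RMSE of forest imputation under 20% MCAR masking is below the RMSE
        of mean imputation, on a table with predictable structure."""
        rng = np.random.default_rng(1)
        n = 300
        x = rng.uniform(0, 1, n)
        frame = pd.DataFrame({
            "x": x,
            "y": 3.0 * x + rng.normal(0, 0.05, n),
            "z": np.where(x > 0.5, "hi", "lo"),
        })
        truth = frame["y"].copy()
        mask = rng.random(n) < 0.2
        frame.loc[mask, "y"] = np.nan
        out = impute_missing(TagTable(frame), n_trees=30, max_iter=5, seed=0)
        rmse = np.sqrt(np.mean((out.frame.loc[mask, "y"] - truth[mask]) ** 2))
        rmse_mean = np.sqrt(np.mean((truth[~mask].mean() - truth[mask]) ** 2))
        assert rmse < rmse_mean

    def test_all_missing_column_is_an_error(self):
        t = table_from({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="all-missing"):
            impute_missing(t, n_trees=5)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


class TestEncodeTags:
    def test_one_hot_blocks_sum_to_one(self):
        t = table_from({"cat": ["a", "b", "c", "a"]})
        m, enc = encode_tags(t)
        assert m.shape == (4, 3)
        assert np.allclose(m.sum(axis=1), 1.0)

    def test_min_max_scaling(self):
        t = table_from({"x": [0.0, 5.0, 10.0]})
        m, _ = encode_tags(t)
        assert m[:, 0] == pytest.approx([0.0, 0.5, 1.0])

    def test_training_ranges_applied_with_clipping(self):
        t = table_from({"x": [0.0, 5.0, 10.0, 20.0]})
        m, enc = encode_tags(t, train_index=t.frame.index[:3])
        assert m[:, 0] == pytest.approx([0.0, 0.5, 1.0, 1.0])  # 20 clipped
        assert (m >= 0).all() and (m <= 1).all()

    def test_unseen_category_gives_zero_block(self):
        t = table_from({"cat": ["a", "b", "a", "NEW"]})
        m, enc = encode_tags(t, train_index=t.frame.index[:3])
        assert m.shape[1] == 2
        assert m[3].sum() == 0.0

    def test_missing_cells_rejected(self):
        t = table_from({"x": [1.0, np.nan]})
        with pytest.raises(ValueError, match="imputed"):
            encode_tags(t)


# ---------------------------------------------------------------------------
# extractors
# ---------------------------------------------------------------------------


class TestTagExtractors:
    def test_autoencoder_embedding_length_and_loss_curve(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 1, size=(200, 5))
        X = np.clip(base @ rng.uniform(-1, 1, size=(5, 40)) * 0.2 + 0.5, 0, 1)
        cfg = TagAEConfig(layer_sizes=(64, 48, 40), bottleneck=32,
                          max_epochs=30, seed=0)
        ae = fit_tag_autoencoder(X, cfg)
        assert ae.transform(X).shape == (200, 32)
        # accepted checkpoints never increase the monitored loss
        accepted = np.minimum.accumulate(ae.history_)
        assert (np.diff(accepted) <= 1e-12).all()
        # rank-5 data through a 32-wide bottleneck: beats the mean predictor
        assert ae.reconstruction_mse(X) < X.var()

    def test_autoencoder_config_validation(self):
        with pytest.raises(ValueError):
            TagAEConfig(layer_sizes=(64, 64, 32)).validate()
        with pytest.raises(ValueError):
            TagAEConfig(layer_sizes=(64, 48, 32), bottleneck=32).validate()

    @pytest.mark.parametrize("solver", ["lapack", "arpack", "randomised"])
    def test_pca_matches_eigendecomposition_oracle(self, solver):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 8)) @ np.diag([5, 3, 2, 1, .5, .3, .2, .1])
        pca = fit_tag_pca(X, n_components=3, solver=solver, seed=0)
        scores = pca.transform(X)
        # independent oracle: eigendecomposition of the covariance matrix
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (len(X) - 1))
        top = evecs[:, np.argsort(evals)[::-1][:3]]
        oracle = Xc @ top
        for j in range(3):
            sign = np.sign(oracle[0, j] * scores[0, j]) or 1.0
            assert np.allclose(scores[:, j], sign * oracle[:, j], atol=1e-8)
        assert pca.explained_variance_ratio_.sum() <= 1.0 + 1e-12

    def test_pca_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_tag_pca(np.eye(4), n_components=5)
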