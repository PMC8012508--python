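import numpy as np
import pandas as pd
import pytest

from electrome.descriptive import dispersion
from electrome.io import segment
from electrome.ml import (
    COMPARISONS,
    FeatureMatrix,
    accuracy_summary,
    compare_conditions,
    evaluate_models,
    extract_window_features,
    pca_features,
    scatter_plot,
    sensitivity_precision,
)
from electrome.spectral import fft_spectrum


def make_fm(X, y, groups=None):
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df["label"] = y
    df["group_id"] = groups if groups is not None else np.arange(len(y)).astype(str)
    return FeatureMatrix(df=df, feature_columns=list(df.columns[: X.shape[1]]))


class TestFeatureExtraction:
    def test_shape_and_columns(self, pink_rec):
        fm = extract_window_features(segment(pink_rec))
        assert len(fm.df) == 10
        assert len(fm.feature_columns) == 19  # 3 representations × 6 stats + entropy
        assert not fm.df[fm.feature_columns].isna().any().any()

    def test_identical_windows_give_identical_rows(self, pink_rec):
        fm1 = extract_window_features(segment(pink_rec))
        fm2 = extract_window_features(segment(pink_rec))
        pd.testing.assert_frame_equal(fm1.df, fm2.df)

    def test_summary_statistics_match_descriptive_oracle(self, pink_rec):
        ws = segment(pink_rec)
        fm = extract_window_features(ws)
        x = ws.arrays()[0]
        from electrome.io import Recording

        spec = fft_spectrum(Recording(samples=x, fs=pink_rec.fs))
        d = dispersion(spec.values)
        row = fm.df.iloc[0]
        assert row["fft_mean"] == pytest.approx(d.mean, rel=1e-9)
        assert row["fft_var"] == pytest.approx(d.sd**2, rel=1e-9)
        assert row["fft_skew"] == pytest.approx(d.skewness, rel=1e-9)
        assert row["fft_kurt"] == pytest.approx(d.kurtosis, rel=1e-9)
        assert row["fft_max"] == pytest.approx(spec.values.max())
        assert row["fft_min"] == pytest.approx(spec.values.min())


class TestPCA:
    def test_rank_three_data_fully_explained(self, rng):
        basis = rng.standard_normal((3, 18))
        scores = rng.standard_normal((40, 3))
        X = scores @ basis
        raw = make_fm(np.column_stack([X, rng.standard_normal(40)]), ["a"] * 20 + ["b"] * 20)
        raw.feature_columns = [f"f{i}" for i in range(18)] + ["entropy"]
        raw.df = raw.df.rename(columns={"f18": "entropy"})
        fm = pca_features(raw)
        assert fm.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scores_orthogonal_and_variance_ordered(self, rng):
        X = rng.standard_normal((60, 18))
        raw = make_fm(np.column_stack([X, rng.standard_normal(60)]), ["a"] * 30 + ["b"] * 30)
        raw.feature_columns = [f"f{i}" for i in range(18)] + ["entropy"]
        raw.df = raw.df.rename(columns={"f18": "entropy"})
        fm = pca_features(raw)
        S = fm.df[["PCA1", "PCA2", "PCA3"]].to_numpy()
        S = S - S.mean(axis=0)
        assert abs(S[:, 0] @ S[:, 1]) < 1e-8
        assert abs(S[:, 0] @ S[:, 2]) < 1e-8
        evr = fm.explained_variance_ratio
        assert evr[0] >= evr[1] >= evr[2]

    def test_too_few_rows_rejected(self, rng):
        raw = make_fm(rng.standard_normal((3, 19)), ["a", "b", "a"])
        raw.df = raw.df.rename(columns={"f18": "entropy"})
        raw.feature_columns = [f"f{i}" for i in range(18)] + ["entropy"]
        with pytest.raises(ValueError):
            pca_features(raw)


class TestEvaluateModels:
    def test_separable_clusters_score_high(self, rng):
        X = np.vstack([
            rng.standard_normal((30, 4)) + 8.0,
            rng.standard_normal((30, 4)) - 8.0,
        ])
        y = np.array(["hi"] * 30 + ["lo"] * 30)
        reports = evaluate_models(make_fm(X, y), n_repeats=5, seed=1)
        for r in reports:
            if r.model != "dummy_stratified":
                assert r.accuracy_mean >= 95.0, r.model

    def test_permuted_labels_score_at_chance(self, rng):
        X = rng.standard_normal((60, 4))
        y = rng.permutation(np.array(["a"] * 30 + ["b"] * 30))
        reports = evaluate_models(make_fm(X, y), n_repeats=20, seed=2)
        for r in reports:
            assert 40.0 <= r.accuracy_mean <= 60.0, (r.model, r.accuracy_mean)

    def test_stratified_dummy_matches_sum_of_squared_proportions(self, rng):
        X = rng.standard_normal((100, 4))
        y = np.array(["maj"] * 60 + ["min"] * 40)
        reports = evaluate_models(make_fm(X, y), n_repeats=50, seed=3)
        dummy = next(r for r in reports if r.model == "dummy_stratified")
        assert dummy.accuracy_mean == pytest.approx(52.0, abs=5.0)

    def test_reproducible_given_seed(self, rng):
        X = rng.standard_normal((40, 4))
        y = np.array(["a", "b"] * 20)
        fm = make_fm(X, y)
        r1 = evaluate_models(fm, n_repeats=3, seed=9)
        r2 = evaluate_models(fm, n_repeats=3, seed=9)
        assert [(r.model, r.accuracy_mean, r.accuracy_sd) for r in r1] == [
            (r.model, r.accuracy_mean, r.accuracy_sd) for r in r2
        ]

    def test_small_class_rejected_by_name(self, rng):
        X = rng.standard_normal((23, 4))
        y = np.array(["big"] * 20 + ["tiny"] * 3)
        with pytest.raises(ValueError, match="tiny"):
            evaluate_models(make_fm(X, y), k_folds=5)


class TestSensitivityPrecision:
    def test_perfect_classifier_scores_100(self, rng):
        from sklearn.neighbors import KNeighborsClassifier

        X = np.vstack([
            rng.standard_normal((20, 2)) + 10.0,
            rng.standard_normal((20, 2)) - 10.0,
        ])
        y = np.array(["a"] * 20 + ["b"] * 20)
        sens, prec = sensitivity_precision(KNeighborsClassifier(), make_fm(X, y))
        assert sens == {"a": 100.0, "b": 100.0}
        assert prec == {"a": 100.0, "b": 100.0}

    def test_constant_predictor_confusion_arithmetic(self, rng):
        from sklearn.dummy import DummyClassifier

        X = rng.standard_normal((40, 2))
        y = np.array(["a"] * 20 + ["b"] * 20)
        sens, prec = sensitivity_precision(
            DummyClassifier(strategy="constant", constant="a"), make_fm(X, y)
        )
        assert sens["a"] == 100.0 and sens["b"] == 0.0
        assert prec["a"] == pytest.approx(50.0)
        assert np.isnan(prec["b"])  # never predicted: precision undefined

    def test_rates_match_hand_confusion_matrix(self):
        from electrome.ml import _rates_from_confusion

        y_true = np.array(list("aaaaabbbbb"))
        y_pred = np.array(list("aaabbbbbba"))
        sens, prec = _rates_from_confusion(y_true, y_pred, np.array(["a", "b"]))
        # a: TP=3 FN=2 FP=1; b: TP=4 FN=1 FP=2
        assert sens["a"] == pytest.approx(60.0)
        assert prec["a"] == pytest.approx(75.0)
        assert sens["b"] == pytest.approx(80.0)
        assert prec["b"] == pytest.approx(4 / 6 * 100)


class TestScatterPlot:
    def test_two_class_figure_has_two_legend_entries(self, rng, tmp_path):
        X = rng.standard_normal((20, 4))
        fm = make_fm(X, ["a"] * 10 + ["b"] * 10)
        fm.df = fm.df.rename(columns={"f0": "PCA1", "f1": "entropy"})
        fig = scatter_plot(fm, path=tmp_path / "sc.png")
        assert (tmp_path / "sc.png").exists()
        assert len(fig.axes[0].get_legend().get_texts()) == 2

    def test_empty_matrix_rejected(self):
        fm = FeatureMatrix(df=pd.DataFrame(columns=["PCA1", "entropy", "label",
                                                    "group_id"]),
                           feature_columns=["PCA1", "entropy"])
        with pytest.raises(ValueError):
            scatter_plot(fm)

    def test_unknown_feature_rejected(self, rng):
        fm = make_fm(rng.standard_normal((10, 4)), ["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError, match="unknown"):
            scatter_plot(fm, coords=("nope", "f1"))

    def test_output_deterministic(self, rng, tmp_path):
        X = rng.standard_normal((20, 4))
        fm = make_fm(X, ["a"] * 10 + ["b"] * 10)
        fm.df = fm.df.rename(columns={"f0": "PCA1", "f1": "entropy"})
        scatter_plot(fm, path=tmp_path / "a.png")
        scatter_plot(fm, path=tmp_path / "b.png")
        assert (tmp_path / "a.png").read_bytes() == (tmp_path / "b.png").read_bytes()


class TestCompareConditions:
    def test_five_comparisons_produce_five_reports(self, small_experiment):
        res = compare_conditions(small_experiment, n_repeats=2, seed=0)
        assert set(res) == {c[0] for c in COMPARISONS}
        assert all(len(reports) == 8 for reports in res.values())
        summary = accuracy_summary(res)
        assert summary.shape == (5, 8)

    def test_missing_group_rejected(self, small_experiment):
        partial = {k: v for k, v in small_experiment.items() if k != "CW-after"}
        with pytest.raises(ValueError, match="CW-after"):
            compare_conditions(partial, n_repeats=1, seed=0)
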