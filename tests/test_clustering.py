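"""Mobility-state clustering: training sets, GMM/Ward+SVM, fold changes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.mixture import GaussianMixture

from burstkin.clustering import (
    FEATURE_COLUMNS,
    build_training_set,
    classify_tracks,
    classify_tracks_array,
    cluster_fold_changes,
    fit_gmm,
    fit_ward_svm,
    model_selection_report,
)
from burstkin.clustering import _transform


CENTERS = np.array([
    [0.5, 1.0, 0.6, 0.5, 0.02, 0.05],
    [0.05, 0.7, 0.25, 0.05, 0.004, 0.3],
    [0.005, 0.4, 0.08, 0.005, 0.0008, 1.5],
])


def three_population_features(n_per=300, scatter=0.08, seed=0):
    """Well-separated lognormal populations (>5 sigma in log space)."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for c in range(3):
        rows.append(CENTERS[c] * np.exp(rng.normal(0, scatter, (n_per, 6))))
        labels += [c] * n_per
    df = pd.DataFrame(np.vstack(rows), columns=list(FEATURE_COLUMNS))
    df["condition"] = np.tile(["minus", "acute", "chronic"],
                              len(df) // 3 + 1)[: len(df)]
    return df, np.array(labels)


def matched_accuracy(pred, truth, k=3):
    """Accuracy under the best one-to-one label matching (Hungarian)."""
    from scipy.optimize import linear_sum_assignment

    confusion = np.zeros((k, k))
    for t, p in zip(truth, pred):
        confusion[t, p] += 1
    rows, cols = linear_sum_assignment(-confusion)
    return confusion[rows, cols].sum() / len(truth)


class TestTrainingSet:
    def test_balanced_counts_and_shape(self):
        df, _ = three_population_features()
        train = build_training_set(df, ["minus", "acute", "chronic"], 200,
                                   seed=1)
        assert train.X.shape == (600, 6)
        assert train.balancing == {"minus": 200, "acute": 200, "chronic": 200}
        assert all((train.conditions == c).sum() == 200
                   for c in ("minus", "acute", "chronic"))

    def test_same_seed_reproduces_selection(self):
        df, _ = three_population_features()
        a = build_training_set(df, ["minus", "acute"], 150, seed=7)
        b = build_training_set(df, ["minus", "acute"], 150, seed=7)
        assert np.array_equal(a.index, b.index)

    def test_different_seeds_differ(self):
        df, _ = three_population_features()
        a = build_training_set(df, ["minus", "acute"], 150, seed=7)
        b = build_training_set(df, ["minus", "acute"], 150, seed=8)
        assert not np.array_equal(a.index, b.index)

    def test_insufficient_tracks_names_condition(self):
        df, _ = three_population_features(n_per=50)
        with pytest.raises(ValueError, match="acute"):
            build_training_set(df, ["acute"], 500, seed=0)

    def test_incomplete_rows_excluded(self):
        df, _ = three_population_features()
        df.loc[df.index[:100], "alpha"] = np.nan
        train = build_training_set(df, ["minus"], 100, seed=0)
        assert np.isfinite(train.X).all()


class TestGMM:
    def test_three_population_accuracy(self):
        df, truth = three_population_features()
        train = build_training_set(df, ["minus", "acute", "chronic"], 250,
                                   seed=1)
        model = fit_gmm(train, k=3, seed=2)
        pred = classify_tracks_array(model, train.X)
        assert matched_accuracy(pred, truth[train.index]) >= 0.98

    def test_k1_recovers_sample_moments(self):
        df, _ = three_population_features(n_per=200)
        train = build_training_set(df, ["minus"], 150, seed=3)
        model = fit_gmm(train, k=1, seed=0)
        Xt = _transform(train.X, train.feature_names, model.log_features)
        assert np.allclose(model.means[0], Xt.mean(axis=0), atol=1e-8)
        assert np.allclose(model.covariances[0],
                           np.cov(Xt.T, bias=True), atol=1e-4)

    def test_em_loglik_nondecreasing(self):
        df, _ = three_population_features()
        train = build_training_set(df, ["minus", "acute", "chronic"], 200,
                                   seed=4)
        Xt = _transform(train.X, train.feature_names,
                        ("D_um2_s", "Rc_um", "msd_dt1_um2"))
        gm = GaussianMixture(n_components=3, covariance_type="full",
                             max_iter=1, warm_start=True, random_state=0,
                             reg_covar=1e-6, tol=0.0)
        lls = []
        import warnings

        for _ in range(15):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(Xt)
            lls.append(gm.score(Xt))
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_components_ordered_slowest_last(self):
        df, truth = three_population_features()
        train = build_training_set(df, ["minus", "acute", "chronic"], 250,
                                   seed=1)
        model = fit_gmm(train, k=3, seed=2)
        d_col = model.feature_names.index("D_um2_s")
        assert np.all(np.diff(model.means[:, d_col]) < 0)

    def test_fixed_seed_bit_identical_model(self):
        df, _ = three_population_features()
        train = build_training_set(df, ["minus", "acute", "chronic"], 250,
                                   seed=1)
        a = fit_gmm(train, k=3, seed=5)
        b = fit_gmm(train, k=3, seed=5)
        assert a.to_bytes() == b.to_bytes()


class TestWardSVM:
    def test_three_population_accuracy_and_self_consistency(self):
        df, truth = three_population_features()
        train = build_training_set(df, ["minus", "acute", "chronic"], 250,
                                   seed=1)
        model = fit_ward_svm(train, k=3, seed=2)
        assert matched_accuracy(model.train_labels, truth[train.index]) >= 0.98
        pred = classify_tracks_array(model, train.X)
        assert (pred == model.train_labels).mean() >= 0.95

    def test_fixed_seed_bit_identical_model(self):
        df, _ = three_population_features()
        train = build_training_set(df, ["minus", "acute", "chronic"], 200,
                                   seed=1)
        a = fit_ward_svm(train, k=3, seed=9)
        b = fit_ward_svm(train, k=3, seed=9)
        assert a.to_bytes() == b.to_bytes()


class TestClassification:
    def test_point_at_component_mean_assigned_to_it(self):
        df, _ = three_population_features()
        train = build_training_set(df, ["minus", "acute", "chronic"], 250,
                                   seed=1)
        model = fit_gmm(train, k=3, seed=2)
        for c in range(3):
            x = np.exp(model.means[c]).copy()
            # undo log transform for the log features only
            row = []
            for j, name in enumerate(model.feature_names):
                row.append(np.exp(model.means[c, j])
                           if name in model.log_features
                           else model.means[c, j])
            pred = classify_tracks_array(model, np.array([row]))
            assert pred[0] == c

    def test_training_rows_reclassified_identically(self):
        df, _ = three_population_features()
        train = build_training_set(df, ["minus", "acute", "chronic"], 250,
                                   seed=1)
        model = fit_gmm(train, k=3, seed=2)
        again = classify_tracks_array(model, train.X)
        assert np.array_equal(again, model.train_labels)

    def test_dataframe_interface_flags_incomplete_rows(self):
        df, _ = three_population_features(n_per=120)
        train = build_training_set(df, ["minus", "acute", "chronic"], 100,
                                   seed=1)
        model = fit_gmm(train, k=3, seed=2)
        df.loc[df.index[0], "alpha"] = np.nan
        labels = classify_tracks(model, df)
        assert labels.iloc[0] == -1
        assert (labels.iloc[1:] >= 0).all()


class TestFoldChanges:
    def test_identical_assignments_fold_one(self):
        lab = np.repeat(np.arange(4), 100)
        out = cluster_fold_changes({"a": lab, "b": lab.copy()}, "a", "b", k=4,
                                   n_boot=50, seed=0)
        assert np.allclose(out["fold_change"], 1.0)
        assert np.allclose(out["fraction_a"].sum(), 1.0, atol=1e-12)

    def test_constructed_halving_gives_half(self):
        la = np.repeat(np.arange(5), [400, 150, 150, 150, 150])
        lb = np.repeat(np.arange(5), [200, 200, 200, 200, 200])
        out = cluster_fold_changes({"a": la, "b": lb}, "a", "b", k=5,
                                   n_boot=50, seed=0)
        assert out["fold_change"][0] == pytest.approx(0.5, abs=1e-12)

    def test_empty_denominator_reported_missing(self):
        la = np.repeat([0, 1], [100, 100])
        lb = np.repeat([0, 1, 2], [80, 80, 40])
        out = cluster_fold_changes({"a": la, "b": lb}, "a", "b", k=3,
                                   n_boot=20, seed=0)
        assert np.isnan(out["fold_change"][2])

    def test_bootstrap_ci_covers_constructed_truth(self):
        rng = np.random.default_rng(12)
        true_fold = 0.5
        cover = 0
        reps = 60
        for _ in range(reps):
            la = rng.choice(3, p=[0.4, 0.3, 0.3], size=800)
            lb = rng.choice(3, p=[0.2, 0.4, 0.4], size=800)
            out = cluster_fold_changes({"a": la, "b": lb}, "a", "b", k=3,
                                       n_boot=200,
                                       seed=int(rng.integers(2**31)))
            if out["ci_low"][0] <= true_fold <= out["ci_high"][0]:
                cover += 1
        assert cover / reps >= 0.90

    def test_depleted_low_mobility_population_flagged(self):
        # a slow/confined population present at 8% in condition a and absent
        # in b: the slowest canonical cluster shows the strongest depletion
        rng = np.random.default_rng(3)

        def pop(center, n):
            return center * np.exp(rng.normal(0, 0.08, (n, 6)))

        a = np.vstack([pop(CENTERS[0], 420), pop(CENTERS[1], 420),
                       pop(CENTERS[2], 73)])  # ~8% slow
        b = np.vstack([pop(CENTERS[0], 450), pop(CENTERS[1], 450)])
        df = pd.DataFrame(np.vstack([a, b]), columns=list(FEATURE_COLUMNS))
        df["condition"] = ["a"] * len(a) + ["b"] * len(b)
        train = build_training_set(df, ["a", "b"], 400, seed=4)
        model = fit_gmm(train, k=3, seed=4)
        la = classify_tracks(model, df[df["condition"] == "a"]).to_numpy()
        lb = classify_tracks(model, df[df["condition"] == "b"]).to_numpy()
        out = cluster_fold_changes({"a": la, "b": lb}, "a", "b", k=3,
                                   n_boot=50, seed=0)
        folds = out["fold_change"].fillna(0.0)
        assert folds.idxmin() == 2  # slowest cluster is canonically last


def test_model_selection_report_emits_candidates():
    df, _ = three_population_features()
    train = build_training_set(df, ["minus", "acute", "chronic"], 250, seed=1)
    rep = model_selection_report(train, k_values=range(2, 5), seed=0,
                                 compare=("acute", "chronic"))
    assert set(rep["k"]) == {2, 3, 4}
    assert rep["silhouette"].notna().all()
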