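import numpy as np
import pandas as pd
import pytest

from neowave import evaluate, make_observations, per_contact_auc, scatter_clusters
from neowave.errors import DataError


def _feature_table(rng, n_subjects=12, channels=("C4-P4", "Cz-Pz"),
                   features=("envelope", "sharpness", "don"),
                   effect=2.0, n_epochs=6):
    """Labeled epoch table with a class shift on every feature."""
    rows = []
    for s in range(n_subjects):
        for ch in channels:
            for feat in features:
                for label in ("nonseizure", "S1", "S2", "S3"):
                    shift = 0.0 if label == "nonseizure" else effect
                    if label == "S3":
                        shift += effect  # stages separable too
                    for ep in range(n_epochs):
                        rows.append({
                            "subject": f"s{s}", "channel": ch,
                            "feature": feat, "label": label, "epoch": ep,
                            "value": rng.normal(shift, 1.0)})
    return pd.DataFrame(rows)


def _separable_obs(n_per_class=10):
    vals = np.r_[-np.abs(np.random.default_rng(0).normal(2, 0.5, n_per_class)),
                 np.abs(np.random.default_rng(1).normal(2, 0.5, n_per_class))]
    return pd.DataFrame({
        "subject": [f"s{i}" for i in range(2 * n_per_class)],
        "y": [0] * n_per_class + [1] * n_per_class,
        "value": vals})


class TestMakeObservations:
    def test_median_per_subject(self):
        table = pd.DataFrame({
            "subject": ["a"] * 3 + ["a"] * 3,
            "channel": ["C4-P4"] * 6,
            "feature": ["envelope"] * 6,
            "label": ["S1"] * 3 + ["nonseizure"] * 3,
            "value": [1.0, 2.0, 9.0, 0.0, 0.5, 1.0]})
        table2 = pd.concat([table, table.assign(subject="b")])
        obs = make_observations(table2, "envelope", scheme=2)
        a_pos = obs[(obs["subject"] == "a") & (obs["y"] == 1)]["value"]
        assert a_pos.iloc[0] == 2.0

    def test_scheme_three_ignores_nonseizure(self):
        rng = np.random.default_rng(0)
        table = _feature_table(rng)
        obs = make_observations(table, "envelope", scheme=3)
        # only S3 (positive) and S1 (negative) medians contribute
        sub = table[(table["subject"] == "s0") & (table["channel"] == "C4-P4")
                    & (table["feature"] == "envelope")]
        want = sub[sub["label"] == "S3"]["value"].median()
        got = obs[(obs["subject"] == "s0") & (obs["y"] == 1)]["value"].iloc[0]
        assert got == pytest.approx(want)

    def test_empty_class_rejected(self):
        rng = np.random.default_rng(1)
        table = _feature_table(rng)
        with pytest.raises(DataError):
            make_observations(table[table["label"] == "nonseizure"],
                              "envelope", scheme=1)


class TestEvaluate:
    @pytest.mark.parametrize("clf", ["svm", "knn", "lr", "nb"])
    def test_separable_feature_is_perfect(self, clf):
        rep = evaluate(_separable_obs(), classifier=clf, seed=0)
        assert rep.auc == 1.0
        assert rep.accuracy == 1.0

    def test_report_internal_consistency(self):
        rep = evaluate(_separable_obs(), classifier="lr", seed=1)
        # AUC equals trapezoidal area under its own ROC
        assert rep.auc == pytest.approx(
            np.trapezoid(rep.roc["tpr"], rep.roc["fpr"]), abs=1e-9)
        assert (np.diff(rep.roc["tpr"]) >= 0).all()
        for rate in (rep.accuracy, rep.sensitivity, rep.specificity):
            assert 0.0 <= rate <= 1.0

    def test_too_few_observations_rejected(self):
        with pytest.raises(DataError):
            evaluate(_separable_obs(n_per_class=4), classifier="lr")

    def test_unknown_classifier_rejected(self):
        with pytest.raises(DataError):
            evaluate(_separable_obs(), classifier="forest")


class TestRankAucProperties:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        table = _feature_table(rng, effect=1.0)
        base = per_contact_auc(table, "envelope", scheme=1)
        warped = table.copy()
        warped["value"] = np.exp(warped["value"] / 2)  # strictly monotone
        after = per_contact_auc(warped, "envelope", scheme=1)
        np.testing.assert_allclose(base["auc"], after["auc"])

    def test_label_swap_reflects_auc(self):
        rng = np.random.default_rng(3)
        table = _feature_table(rng, effect=1.0)
        obs = make_observations(table, "envelope", scheme=1)
        from sklearn.metrics import roc_auc_score
        auc = roc_auc_score(obs["y"], obs["value"])
        swapped = roc_auc_score(1 - obs["y"], obs["value"])
        assert swapped == pytest.approx(1 - auc, abs=1e-12)


class TestScatterClusters:
    def test_identical_classes_have_coincident_centroids(self):
        rng = np.random.default_rng(4)
        table = _feature_table(rng, effect=0.0, n_subjects=16)
        clusters = scatter_clusters(table, scheme=1)
        c0 = clusters[0][["envelope", "sharpness", "don"]].mean()
        c1 = clusters[1][["envelope", "sharpness", "don"]].mean()
        assert np.linalg.norm(c1 - c0) < 0.5

    def test_shifted_classes_separate_in_all_coordinates(self):
        rng = np.random.default_rng(5)
        table = _feature_table(rng, effect=2.0)
        clusters = scatter_clusters(table, scheme=1)
        for feat in ("envelope", "sharpness", "don"):
            assert clusters[1][feat].mean() > clusters[0][feat].mean()

    def test_single_subject_yields_single_points(self):
        rng = np.random.default_rng(6)
        table = _feature_table(rng, n_subjects=1)
        clusters = scatter_clusters(table, scheme=1)
        assert len(clusters[0]) == 1 and len(clusters[1]) == 1
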