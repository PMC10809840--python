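"""Single-feature classification of seizure periods and stages.

Three schemes mirror the clinical questions: (1) seizure vs nonseizure,
(2) starting stage S1 vs nonseizure (onset detection), and (3) end stage S3
vs starting stage S1 (termination).  Observations are per-subject medians of
a feature's epochs in each class, by default at the C4-P4 contact.  Four
classifiers (RBF-SVM, kNN, logistic regression, Gaussian naive Bayes) are
tuned by 5-fold cross-validation on a stratified 80% training split and
scored on the held-out 20%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DataError

__all__ = ["ClassifierReport", "SCHEMES", "make_observations", "evaluate",
           "per_contact_auc", "scatter_clusters"]

log = logging.getLogger(__name__)

#: scheme id -> (positive-class labels, negative-class labels)
SCHEMES: dict[int, tuple[tuple[str, ...], tuple[str, ...]]] = {
    1: (("S1", "S2", "S3", "seizure"), ("nonseizure",)),
    2: (("S1",), ("nonseizure",)),
    3: (("S3",), ("S1",)),
}

DEFAULT_CONTACT = "C4-P4"


def make_observations(table: pd.DataFrame, feature: str, scheme: int,
                      channel: str | None = DEFAULT_CONTACT) -> pd.DataFrame:
    """Per-subject, per-class observations: median of the feature's epochs.

    ``table`` must carry columns subject, channel, feature, value, label.
    ``channel=None`` pools all contacts.  Subjects missing either class are
    excluded (logged).  Returns columns ``subject, y, value`` with y in
    {0, 1} (1 = positive class of the scheme).
    """
    if scheme not in SCHEMES:
        raise DataError(f"unknown scheme {scheme}")
    pos, neg = SCHEMES[scheme]
    sub = table[table["feature"] == feature]
    if channel is not None:
        sub = sub[sub["channel"] == channel]
    if sub.empty:
        raise DataError(f"no rows for feature {feature!r}"
                        + (f" at {channel}" if channel else ""))
    sub = sub.dropna(subset=["value"])
    rows = []
    for subject, grp in sub.groupby("subject"):
        pos_vals = grp.loc[grp["label"].isin(pos), "value"]
        neg_vals = grp.loc[grp["label"].isin(neg), "value"]
        if pos_vals.empty or neg_vals.empty:
            log.info("subject %s missing a class for scheme %d; excluded",
                     subject, scheme)
            continue
        rows.append({"subject": subject, "y": 1,
                     "value": float(pos_vals.median())})
        rows.append({"subject": subject, "y": 0,
                     "value": float(neg_vals.median())})
    obs = pd.DataFrame(rows)
    if obs.empty or obs["y"].nunique() < 2:
        raise DataError(f"scheme {scheme}: a class is empty")
    return obs


@dataclass
class ClassifierReport:
    """Held-out-set performance of one feature x classifier x scheme."""

    classifier: str
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc: pd.DataFrame                      # fpr, tpr, threshold
    calibration: pd.DataFrame              # predicted vs observed rate per bin
    best_params: dict = field(default_factory=dict)
    seed: int = 0
    n_train: int = 0
    n_test: int = 0

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "best_params": {k: (v if isinstance(v, (int, float, str)) else str(v))
                            for k, v in self.best_params.items()},
            "seed": self.seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "roc": self.roc.to_dict(orient="list"),
            "calibration": self.calibration.to_dict(orient="list"),
        }


def _estimator(name: str, seed: int):
    if name == "svm":
        est = SVC(kernel="rbf", probability=True, random_state=seed)
        grid = {"clf__C": [0.1, 1.0, 10.0, 100.0],
                "clf__gamma": ["scale", 0.1, 1.0]}
    elif name == "knn":
        est = KNeighborsClassifier()
        grid = {"clf__n_neighbors": [3, 5, 7]}
    elif name == "lr":
        est = LogisticRegression(max_iter=1000, random_state=seed)
        grid = {"clf__C": [0.01, 0.1, 1.0, 10.0]}
    elif name == "nb":
        est = GaussianNB()
        grid = {}
    else:
        raise DataError(f"unknown classifier {name!r}; use svm/knn/lr/nb")
    return Pipeline([("scale", StandardScaler()), ("clf", est)]), grid


def _scores(model, X: np.ndarray) -> np.ndarray:
    clf = model.named_steps["clf"] if isinstance(model, Pipeline) else model
    if hasattr(clf, "decision_function"):
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


def evaluate(obs: pd.DataFrame, classifier: str = "svm", seed: int = 0,
             test_size: float = 0.2, cv: int = 5,
             feature_cols: tuple[str, ...] = ("value",)) -> ClassifierReport:
    """Train/tune/evaluate one classifier on labeled observations.

    Stratified 80/20 split (seeded); hyperparameters by stratified k-fold
    cross-validation on the training part (folds reduced when a class has
    fewer members than ``cv``); accuracy/sensitivity/specificity and the
    ROC/AUC are computed on the held-out test part from decision scores;
    calibration from predicted probabilities in quantile bins.
    """
    if len(obs) < 10:
        raise DataError("need at least 10 observations")
    X = obs[list(feature_cols)].to_numpy(dtype=float)
    y = obs["y"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise DataError("both classes must be present")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed)

    pipe, grid = _estimator(classifier, seed)
    min_class = int(np.bincount(y_tr).min())
    folds = min(cv, min_class)
    if folds < 2:
        raise DataError("too few training members of a class for CV")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        if grid:
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=seed)
            search = GridSearchCV(pipe, grid, cv=skf, scoring="roc_auc")
            search.fit(X_tr, y_tr)
            model = search.best_estimator_
            best = search.best_params_
        else:
            model = pipe.fit(X_tr, y_tr)
            best = {}

    y_pred = model.predict(X_te)
    tp = int(np.sum((y_pred == 1) & (y_te == 1)))
    tn = int(np.sum((y_pred == 0) & (y_te == 0)))
    fp = int(np.sum((y_pred == 1) & (y_te == 0)))
    fn = int(np.sum((y_pred == 0) & (y_te == 1)))
    scores = _scores(model, X_te)
    fpr, tpr, thr = roc_curve(y_te, scores)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    probs = model.predict_proba(X_te)[:, 1]
    n_bins = max(min(5, len(probs) // 2), 1)
    order = np.argsort(probs)
    bins = np.array_split(order, n_bins)
    calibration = pd.DataFrame([
        {"predicted": float(np.mean(probs[b])),
         "observed": float(np.mean(y_te[b])),
         "n": len(b)}
        for b in bins if len(b)])

    return ClassifierReport(
        classifier=classifier,
        accuracy=(tp + tn) / len(y_te),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        auc=float(auc(fpr, tpr)),
        roc=roc, calibration=calibration, best_params=best,
        seed=seed, n_train=len(y_tr), n_test=len(y_te))


def per_contact_auc(table: pd.DataFrame, feature: str,
                    scheme: int) -> pd.DataFrame:
    """Rank (threshold-free) AUC of the raw feature per contact."""
    from sklearn.metrics import roc_auc_score

    out = []
    for ch in sorted(table["channel"].unique()):
        try:
            obs = make_observations(table, feature, scheme, channel=ch)
        except DataError:
            continue
        out.append({"channel": ch,
                    "auc": float(roc_auc_score(obs["y"], obs["value"]))})
    return pd.DataFrame(out)


def scatter_clusters(table: pd.DataFrame, scheme: int,
                     features: tuple[str, ...] = ("envelope", "sharpness", "don")
                     ) -> dict[int, pd.DataFrame]:
    """Per-subject 3-feature points from the two most discriminative contacts.

    Contacts are ranked by the summed standardized between-class mean
    difference across the three features; each subject's point is the sum of
    its per-contact medians over the top two contacts.  Returns
    ``{0: negative-class frame, 1: positive-class frame}`` with one column
    per feature.
    """
    per_contact: dict[str, float] = {}
    per_obs: dict[tuple[str, str], pd.DataFrame] = {}
    for ch in sorted(table["channel"].unique()):
        score = 0.0
        ok = True
        for feat in features:
            try:
                obs = make_observations(table, feat, scheme, channel=ch)
            except DataError:
                ok = False
                break
            per_obs[(ch, feat)] = obs
            a = obs.loc[obs["y"] == 1, "value"]
            b = obs.loc[obs["y"] == 0, "value"]
            pooled = np.std(np.concatenate([a, b])) or 1.0
            score += abs(a.mean() - b.mean()) / pooled
        if ok:
            per_contact[ch] = score
    if len(per_contact) < 1:
        raise DataError("no contact has complete observations")
    top = sorted(per_contact, key=per_contact.get, reverse=True)[:2]

    out: dict[int, pd.DataFrame] = {}
    for cls in (0, 1):
        frames = []
        for feat in features:
            parts = [per_obs[(ch, feat)].loc[lambda d, c=cls: d["y"] == c]
                     .set_index("subject")["value"] for ch in top]
            summed = sum(parts[1:], parts[0].copy())
            frames.append(summed.rename(feat))
        df = pd.concat(frames, axis=1).dropna()
        out[cls] = df.reset_index()
    return out
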