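"""Model training, evaluation and hyperparameter search on tricluster features.

The evaluation protocol is 5x10-fold cross-validation, stratified on the
Evolution label and grouped by patient (all of a patient's examples fall in
the same fold).  Class imbalance is handled inside each training fold only:
when the majority class exceeds 2/3 of the fold it is randomly undersampled
to exactly twice the minority, then SMOTE oversamples the minority to parity
(SMOTE runs in the transformed similarity space, after the tricluster
feature transformation).  Test folds are never touched.

Plug-in classifiers: Gaussian Naive Bayes, RBF-kernel SVM, Random Forest,
XGBoost — off-the-shelf implementations with fixed seeds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold, StratifiedGroupKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .mining import MiningParams, tc_tricluster
from .patterns import build_feature_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "CVScheme",
    "EvalReport",
    "smote",
    "rebalance",
    "grouped_stratified_cv",
    "evaluate",
    "train_predict",
    "make_classifier",
    "run_cv",
    "hyperparameter_search",
    "rank_patterns",
]


@dataclass(frozen=True)
class CVScheme:
    """Repeated patient-grouped stratified cross-validation settings."""

    repeats: int = 5
    folds: int = 10


@dataclass
class EvalReport:
    """AUC / sensitivity / specificity per fold and aggregated, in percent."""

    fold_auc: list = field(default_factory=list)
    fold_sensitivity: list = field(default_factory=list)
    fold_specificity: list = field(default_factory=list)

    def _agg(self, xs):
        arr = np.asarray(xs, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            return float("nan"), float("nan")
        return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0

    @property
    def auc(self):
        return self._agg(self.fold_auc)

    @property
    def sensitivity(self):
        return self._agg(self.fold_sensitivity)

    @property
    def specificity(self):
        return self._agg(self.fold_specificity)

    def summary(self) -> dict:
        a, s, p = self.auc, self.sensitivity, self.specificity
        return {
            "auc": {"mean": a[0], "sd": a[1]},
            "sensitivity": {"mean": s[0], "sd": s[1]},
            "specificity": {"mean": p[0], "sd": p[1]},
            "n_folds": len(self.fold_auc),
        }


def smote(X_minority: np.ndarray, n_new: int, rng: np.random.Generator, k: int = 5) -> np.ndarray:
    """Synthetic minority oversampling: interpolate towards k-NN neighbours.

    Each synthetic example is ``x + lam * (x_nn - x)`` for a random minority
    sample ``x``, one of its ``k`` nearest minority neighbours ``x_nn`` and
    ``lam ~ U(0, 1)``.
    """
    X = np.asarray(X_minority, dtype=float)
    if len(X) < 2:
        raise ValueError("SMOTE needs at least 2 minority examples")
    k_eff = min(k, len(X) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X)
    _, neigh = nn.kneighbors(X)
    base = rng.integers(0, len(X), size=n_new)
    pick = rng.integers(1, k_eff + 1, size=n_new)  # skip self at column 0
    lam = rng.random(n_new)[:, None]
    x = X[base]
    x_nn = X[neigh[base, pick]]
    return x + lam * (x_nn - x)


def rebalance(X, y, seed: int, k_neighbors: int = 5):
    """Random-undersample-to-2/3 then SMOTE-to-parity on a training fold.

    If the majority class holds more than 2/3 of the examples, majority
    examples are randomly dropped (seeded) until the majority is exactly
    twice the minority; SMOTE then raises the minority to exact parity.
    When the majority is already at or under 2/3, only SMOTE runs.  The
    output always has equal class counts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("rebalance expects exactly two classes")
    maj, mino = classes[np.argmax(counts)], classes[np.argmin(counts)]
    if maj == mino:  # equal counts: np.unique order; nothing to do
        return X.copy(), y.copy()
    n_maj, n_min = counts.max(), counts.min()
    if n_min < 2:
        raise ValueError("minority class has fewer than 2 examples; SMOTE undefined")
    if n_maj == n_min:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    maj_idx = np.nonzero(y == maj)[0]
    min_idx = np.nonzero(y == mino)[0]
    if n_maj / (n_maj + n_min) > 2 / 3:
        keep = rng.choice(maj_idx, size=2 * n_min, replace=False)
        maj_idx = np.sort(keep)
        n_maj = 2 * n_min
    X_kept = np.vstack([X[maj_idx], X[min_idx]])
    y_kept = np.concatenate([np.full(n_maj, maj), np.full(n_min, mino)])
    X_new = smote(X[min_idx], n_maj - n_min, rng, k=k_neighbors)
    X_out = np.vstack([X_kept, X_new])
    y_out = np.concatenate([y_kept, np.full(n_maj - n_min, mino)])
    return X_out, y_out


def grouped_stratified_cv(y, groups, scheme: CVScheme = CVScheme(), seed: int = 0):
    """Fold assignments for repeated patient-grouped stratified CV.

    Returns a list of ``scheme.repeats`` partitions, each a list of
    ``scheme.folds`` (train_idx, test_idx) pairs.  Patients are atomic
    (never split across folds); stratification is greedy on per-patient
    label counts (scikit-learn's StratifiedGroupKFold).
    """
    y = np.asarray(y)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < scheme.folds:
        raise ValueError(
            f"need at least {scheme.folds} distinct patients, got {len(np.unique(groups))}"
        )
    _, class_counts = np.unique(y, return_counts=True)
    stratify = class_counts.min() >= scheme.folds
    if not stratify:
        logger.warning(
            "a class has fewer members than folds; falling back to plain group folds"
        )
    out = []
    for r in range(scheme.repeats):
        if stratify:
            cv = StratifiedGroupKFold(
                n_splits=scheme.folds, shuffle=True, random_state=seed + r
            )
        else:
            cv = GroupKFold(n_splits=scheme.folds, shuffle=True, random_state=seed + r)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn warns on unbalanced groups
            out.append([(tr, te) for tr, te in cv.split(np.zeros(len(y)), y, groups)])
    return out


def evaluate(scores, labels, positive="Y", threshold: float = 0.5):
    """AUC, sensitivity, specificity of one fold, in percent.

    AUC is the rank statistic (probability a positive outranks a negative);
    sensitivity and specificity threshold the scores at 0.5.  Returns NaN
    AUC (with a log entry) for a single-class fold.
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == positive).astype(int)
    if y.min() == y.max():
        logger.warning("single-class fold: AUC undefined, excluded")
        auc = float("nan")
    else:
        auc = 100.0 * roc_auc_score(y, scores)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return auc, sens, spec


def make_classifier(classifier_id: str, seed: int):
    """Off-the-shelf classifier with a fixed seed: NB, SVM, RF or XGB."""
    cid = classifier_id.upper()
    if cid == "NB":
        return GaussianNB()
    if cid == "SVM":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if cid == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if cid == "XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=100, random_state=seed, eval_metric="logloss", verbosity=0
        )
    raise ValueError(f"unknown classifier id {classifier_id!r} (use NB, SVM, RF or XGB)")


def train_predict(X_train, y_train, X_test, classifier_id: str, seed: int):
    """Fit a plug-in classifier and return (model, positive-class scores)."""
    model = make_classifier(classifier_id, seed)
    y = (np.asarray(y_train) == "Y").astype(int) if np.asarray(y_train).dtype.kind in "UO" else np.asarray(y_train)
    model.fit(np.asarray(X_train, float), y)
    scores = model.predict_proba(np.asarray(X_test, float))[:, 1]
    return model, scores


def run_cv(
    X,
    y,
    groups,
    classifier_id: str = "RF",
    scheme: CVScheme = CVScheme(),
    seed: int = 0,
    do_rebalance: bool = True,
) -> EvalReport:
    """Full repeated grouped stratified CV with in-fold rebalancing."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    report = EvalReport()
    for r, folds in enumerate(grouped_stratified_cv(y, groups, scheme, seed)):
        for f, (tr, te) in enumerate(folds):
            Xtr, ytr = X[tr], y[tr]
            if do_rebalance and len(np.unique(ytr)) == 2:
                Xtr, ytr = rebalance(Xtr, ytr, seed=seed * 1000 + r * 100 + f)
            _, scores = train_predict(Xtr, ytr, X[te], classifier_id, seed)
            auc, sens, spec = evaluate(scores, y[te])
            report.fold_auc.append(auc)
            report.fold_sensitivity.append(sens)
            report.fold_specificity.append(spec)
    return report


def _params_sort_key(p: MiningParams):
    d = asdict(p)
    return tuple((k, repr(v)) for k, v in sorted(d.items()))


def hyperparameter_search(
    data,
    grid,
    y,
    groups,
    classifier_id: str = "RF",
    mode: str = "distance",
    scheme: CVScheme = CVScheme(),
    seed: int = 0,
    example_arrays=None,
):
    """Choose the mining parameters that maximise CV mean AUC.

    ``grid`` is either a list of :class:`MiningParams` or a dict of
    per-field value lists expanded as a product.  For each candidate the
    pipeline runs mine -> transform -> CV-evaluate; ties are broken by fewer
    triclusters, then lexicographic parameters.  A candidate yielding zero
    triclusters scores AUC 50 with a warning.  A final mining pass with the
    winner produces the returned triclusters.

    ``example_arrays`` optionally supplies the per-example (contexts x
    features) sub-arrays used by the transformation; by default each object's
    full slice stack in ``data`` is used.
    """
    if isinstance(grid, dict):
        keys = sorted(grid)
        candidates = [MiningParams(**dict(zip(keys, vals))) for vals in product(*(grid[k] for k in keys))]
    else:
        candidates = list(grid)
    if not candidates:
        raise ValueError("empty hyperparameter grid")

    if example_arrays is None:
        example_arrays = [data.values[i].T for i in range(len(data.objects))]

    results = []
    for params in candidates:
        tris = tc_tricluster(data, params)
        if not tris:
            logger.warning("candidate %s yielded zero triclusters; scored AUC 50", params)
            results.append((50.0, 0, params, [], None))
            continue
        fm = build_feature_matrix(example_arrays, tris, data, mode=mode)
        report = run_cv(fm.data.values, y, groups, classifier_id, scheme, seed)
        results.append((report.auc[0], len(tris), params, tris, report))

    degenerate = all(r[1] == 0 for r in results)
    if degenerate:
        logger.warning("degenerate search: every candidate yielded zero triclusters")
    best = sorted(results, key=lambda r: (-r[0], r[1], _params_sort_key(r[2])))[0]
    best_params = best[2]
    final_tris = tc_tricluster(data, best_params)  # the additional final pass
    return {
        "best_params": best_params,
        "triclusters": final_tris,
        "best_auc": best[0],
        "report": best[4],
        "degenerate": degenerate,
        "all_candidates": [
            {"params": asdict(r[2]), "mean_auc": r[0], "n_triclusters": r[1]} for r in results
        ],
    }


def rank_patterns(model, feature_matrix, y, seed: int = 0, n_repeats: int = 20) -> pd.DataFrame:
    """Permutation importance of each pattern column, ranked descending.

    Importance is the mean AUC drop over ``n_repeats`` seeded shuffles of
    the column; output keeps the ``Tric_<id>_<pos>`` names.
    """
    df = feature_matrix.data if hasattr(feature_matrix, "data") else pd.DataFrame(feature_matrix)
    ybin = (np.asarray(y) == "Y").astype(int) if np.asarray(y).dtype.kind in "UO" else np.asarray(y)
    res = permutation_importance(
        model,
        df.values,
        ybin,
        scoring="roc_auc",
        n_repeats=n_repeats,
        random_state=seed,
    )
    out = pd.DataFrame(
        {
            "pattern": df.columns,
            "importance": res.importances_mean,
            "importance_sd": res.importances_std,
        }
    ).sort_values("importance", ascending=False, kind="stable")
    return out.reset_index(drop=True)
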