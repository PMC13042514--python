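"""Per-cell-type, per-readout gradient-boosted classifiers ("Reading-m6A").

Each task pairs one readout category (HL_down, TE_down, TE_up, PSI_down,
PSI_up — half-life up-regulation is excluded for lack of cases) with one cell
type. Models are XGBoost classifiers with fixed default hyperparameters
(performance is insensitive to tuning on this problem), evaluated by
stratified 10-fold cross-validation with out-of-fold ROC/AUC, sensitivity at
80% specificity, a greedy feature-set AUC-gain search, and per-RBP importance
aggregated from tree gain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

READOUT_CATEGORIES = ("HL_down", "TE_down", "TE_up", "PSI_down", "PSI_up")

DEFAULT_HYPERPARAMS = dict(
    max_depth=6,
    n_estimators=300,
    learning_rate=0.1,
    subsample=0.8,
)

MIN_CLASS_SIZE = 20
N_FOLDS = 10


class InsufficientDataError(ValueError):
    pass


@dataclass
class ModelTask:
    readout: str
    cell_type: str
    positives: list[str]
    negatives: list[str]
    seed: int
    hyperparams: dict = field(default_factory=lambda: dict(DEFAULT_HYPERPARAMS))

    def __post_init__(self) -> None:
        if self.readout not in READOUT_CATEGORIES:
            raise ValueError(f"readout must be one of {READOUT_CATEGORIES}")
        if set(self.positives) & set(self.negatives):
            raise ValueError("positives and negatives must be disjoint")


@dataclass
class CVResult:
    unit_ids: list[str]
    labels: np.ndarray
    scores: np.ndarray       # out-of-fold predicted probabilities
    folds: np.ndarray
    roc: pd.DataFrame        # fpr, tpr, threshold
    auc: float
    sens_at_80spec: float
    models: list = field(default_factory=list, repr=False)


def _new_model(hyperparams: dict, seed: int) -> XGBClassifier:
    return XGBClassifier(
        **hyperparams,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points and AUC in the Mann-Whitney form (ties count half).

    AUC is the probability that a random positive outscores a random negative.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    # rank-based AUC: midranks handle ties exactly
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty_like(s)
    sorted_s = s[order]
    i = 0
    r = np.arange(1, len(s) + 1, dtype=float)
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        r[i:j + 1] = (i + 1 + j + 1) / 2.0
        i = j + 1
    ranks[order] = r
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # stepwise ROC over unique score thresholds, descending
    thresholds = np.unique(s)[::-1]
    rows = [(0.0, 0.0, math.inf)]
    for t in thresholds:
        pred = s >= t
        tpr = float((pred & (y == 1)).sum()) / n_pos
        fpr = float((pred & (y == 0)).sum()) / n_neg
        rows.append((fpr, tpr, float(t)))
    roc = pd.DataFrame(rows, columns=["fpr", "tpr", "threshold"])
    return roc, float(auc)


def sensitivity_at_specificity(roc: pd.DataFrame, spec: float = 0.80) -> float:
    """Max sensitivity among thresholds with specificity >= ``spec`` (no interpolation)."""
    eligible = roc[roc["fpr"] <= 1.0 - spec + 1e-12]
    if eligible.empty:
        return 0.0
    return float(eligible["tpr"].max())


def train_cv(
    task: ModelTask,
    features: pd.DataFrame,
    n_folds: int = N_FOLDS,
    columns: list[str] | None = None,
) -> CVResult:
    """Stratified k-fold out-of-fold scoring for one task.

    ``features`` is indexed by unit id; NaN entries are native missing values
    for the trees. Deterministic under a fixed task seed.
    """
    units = list(task.positives) + list(task.negatives)
    if len(task.positives) < MIN_CLASS_SIZE or len(task.negatives) < MIN_CLASS_SIZE:
        raise InsufficientDataError(
            f"need >= {MIN_CLASS_SIZE} units per class, got "
            f"{len(task.positives)}/{len(task.negatives)}"
        )
    missing = [u for u in units if u not in features.index]
    if missing:
        raise KeyError(f"units without features: {missing[:5]}...")
    X_all = features.loc[units]
    if columns is not None:
        X_all = X_all[columns]
    X = X_all.to_numpy(dtype=float)
    y = np.array([1] * len(task.positives) + [0] * len(task.negatives))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=task.seed)
    scores = np.empty(len(y), dtype=float)
    folds = np.empty(len(y), dtype=int)
    models = []
    feature_names = list(X_all.columns)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = _new_model(task.hyperparams, task.seed + fold)
        model.fit(X[tr], y[tr])
        scores[te] = model.predict_proba(X[te])[:, 1]
        folds[te] = fold
        models.append((model, feature_names))
    roc, auc = roc_auc(scores, y)
    return CVResult(
        unit_ids=units, labels=y, scores=scores, folds=folds,
        roc=roc, auc=auc,
        sens_at_80spec=sensitivity_at_specificity(roc, 0.80),
        models=models,
    )


def _cv_auc(task, features, columns, n_folds) -> float:
    return train_cv(task, features, n_folds=n_folds, columns=columns).auc


def featureset_auc_gain(
    task: ModelTask,
    features: pd.DataFrame,
    partition: dict[str, list[str]],
    n_folds: int = 5,
) -> pd.DataFrame:
    """Greedy forward selection over feature sets, measuring each set's AUC gain.

    Starting from the empty set (baseline AUC 0.5), repeatedly add the set
    maximizing CV-AUC; a set's gain is the AUC after its addition minus the
    AUC before. Selection stops when no candidate improves the AUC; sets never
    picked are reported with their marginal gain at termination. Returns a
    frame with columns set, order (-1 if unpicked), gain, cumulative_auc.
    """
    all_cols = [c for cols in partition.values() for c in cols]
    extra = set(all_cols) - set(features.columns)
    if extra:
        raise ValueError(f"partition names unknown columns: {sorted(extra)[:5]}")
    remaining = dict(partition)
    selected_cols: list[str] = []
    current_auc = 0.5
    rows = []
    order = 0
    while remaining:
        aucs = {
            name: _cv_auc(task, features, selected_cols + cols, n_folds)
            for name, cols in sorted(remaining.items())
        }
        best = max(aucs, key=lambda n: (aucs[n], n))
        if aucs[best] <= current_auc:
            break
        rows.append({"set": best, "order": order, "gain": aucs[best] - current_auc,
                     "cumulative_auc": aucs[best]})
        selected_cols += remaining.pop(best)
        current_auc = aucs[best]
        order += 1
    for name, cols in sorted(remaining.items()):
        marginal = _cv_auc(task, features, selected_cols + cols, n_folds) - current_auc
        rows.append({"set": name, "order": -1, "gain": marginal,
                     "cumulative_auc": math.nan})
    return pd.DataFrame(rows)


def rbp_importance(cv: CVResult) -> pd.DataFrame:
    """Per-RBP importance: mean tree gain per feature over folds, max over the RBP's features.

    Returns a frame indexed by RBP, sorted descending; RBPs whose features
    were never split on get importance 0.
    """
    feature_names = cv.models[0][1]
    totals = pd.Series(0.0, index=feature_names)
    for model, names in cv.models:
        booster = model.get_booster()
        gain = booster.get_score(importance_type="total_gain")
        for key, val in gain.items():
            idx = int(key[1:]) if key.startswith("f") and key[1:].isdigit() else None
            name = names[idx] if idx is not None else key
            totals[name] += val
    totals /= len(cv.models)
    rbp_cols = totals[totals.index.str.startswith("rbp:")]
    rbps = sorted({c.split(":")[1] for c in rbp_cols.index})
    per_rbp = {
        rbp: float(rbp_cols[rbp_cols.index.str.startswith(f"rbp:{rbp}:")].max())
        for rbp in rbps
    }
    out = pd.DataFrame({"importance": pd.Series(per_rbp)})
    out.index.name = "rbp"
    return out.sort_values("importance", ascending=False)


def feature_importance(cv: CVResult) -> pd.Series:
    """Mean total-gain importance per feature over the fold models."""
    feature_names = cv.models[0][1]
    totals = pd.Series(0.0, index=feature_names)
    for model, names in cv.models:
        gain = model.get_booster().get_score(importance_type="total_gain")
        for key, val in gain.items():
            idx = int(key[1:]) if key.startswith("f") and key[1:].isdigit() else None
            totals[names[idx] if idx is not None else key] += val
    return totals / len(cv.models)
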