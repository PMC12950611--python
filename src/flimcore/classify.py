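"""Tissue classification under patient-aware validation.

Binary and three-class malignancy classifiers are evaluated exactly under
the study protocol:

* RBF-kernel SVM with a fixed box constraint C = 0.1 and per-class
  misclassification costs inversely proportional to training-class
  frequency;
* leave-one-patient-out (LOPO) cross-validation, pooling out-of-fold class
  scores across all patients;
* patient-weighted pooled ROC: each point is weighted by the inverse of
  its patient's point count so every patient contributes equally to the
  curve and the AUC;
* three-class prediction through a one-vs-one error-correcting output code
  (ECOC) decomposition of SVM learners;
* patient-level (cluster) bootstrap confidence intervals;
* a deliberately naive point-level 10-fold cross-validation that ignores
  patient boundaries, kept as the data-leakage comparison;
* LDA / QDA / logistic-regression / decision-tree comparison classifiers.

Measurements along a core are spatially correlated well beyond the point
spacing (the probe's lateral resolution spans ~18 points), so by default
training folds are decimated to one point per resolution element
(``train_stride``); scoring always uses every point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import InvalidParameterError, UndefinedAUCError

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "ValidationResult",
    "prepare_dataset",
    "make_lopo_folds",
    "class_costs",
    "train_predict_fold",
    "weighted_roc_auc",
    "run_binary_task",
    "run_three_class",
    "bootstrap_ci",
    "naive_kfold_auc",
    "compare_classifiers",
]

FAMILIES = ("svm_rbf", "lda", "qda", "logistic", "tree")

#: binary task -> (positive label set, positive name)
BINARY_TASKS = {
    "two_class": ({"GP3", "GP4+", "GP4", "GP5"}, "PCa"),
    "gp4_vs_rest": ({"GP4+", "GP4", "GP5"}, "GP4+"),
}
THREE_CLASSES = ("benign", "GP3", "GP4+")


@dataclass(frozen=True)
class ClassifierSpec:
    """Model family and protocol hyperparameters."""

    family: str = "svm_rbf"
    box_constraint: float = 0.1
    kernel_scale: str = "median"       # median pairwise-distance heuristic
    feature_subset: str = "four_lifetimes"  # or "all_52"
    train_stride: int = 18             # training decimation, points
    min_leaf: int = 20                 # decision-tree regularization

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise InvalidParameterError(f"unknown model family {self.family!r}")
        if self.box_constraint <= 0:
            raise InvalidParameterError("box_constraint must be > 0")
        if self.feature_subset not in ("four_lifetimes", "all_52"):
            raise InvalidParameterError(
                f"unknown feature subset {self.feature_subset!r}"
            )


@dataclass
class ClassMetrics:
    auc_weighted: float
    auc_unweighted: float
    sensitivity: float
    specificity: float
    threshold: float
    fpr: np.ndarray
    tpr: np.ndarray
    ci: Optional[Tuple[float, float]] = None


@dataclass
class ValidationResult:
    task: str
    classes: List[str]
    scores: pd.DataFrame        # one row per point, score_<class> columns
    per_class: Dict[str, Optional[ClassMetrics]]
    fold_manifest: Dict[str, List[str]]  # test patient -> train patients
    spec: ClassifierSpec = field(default_factory=ClassifierSpec)

    def to_dict(self) -> dict:
        out = {
            "task": self.task,
            "classes": self.classes,
            "spec": vars(self.spec) | {},
            "fold_manifest": self.fold_manifest,
            "per_class": {},
        }
        for cls, m in self.per_class.items():
            if m is None:
                out["per_class"][cls] = None
                continue
            out["per_class"][cls] = {
                "auc_weighted": m.auc_weighted,
                "auc_unweighted": m.auc_unweighted,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "threshold": m.threshold,
                "fpr": np.asarray(m.fpr).tolist(),
                "tpr": np.asarray(m.tpr).tolist(),
                "ci": list(m.ci) if m.ci is not None else None,
            }
        return out


# ---------------------------------------------------------------------------
# dataset preparation
# ---------------------------------------------------------------------------

def feature_names(df: pd.DataFrame, subset: str) -> List[str]:
    """Feature columns for a subset: the four average lifetimes, or the
    52-parameter set (lifetimes + normalized Laguerre coefficients,
    intensities excluded)."""
    lt = sorted(c for c in df.columns if c.endswith("_lt"))
    if subset == "four_lifetimes":
        return lt
    lag = sorted(c for c in df.columns if "_lag" in c)
    return lt + lag


def prepare_dataset(
    labeled: pd.DataFrame,
    pass_index: Optional[int] = 0,
    merge_gp5: bool = True,
) -> pd.DataFrame:
    """Classification view of a labeled feature table.

    Keeps labeled, non-excluded, successfully fitted points of one pass
    (pass 0 by default; pass 1 is reserved for QC) and merges GP5 into the
    GP4+ class used by every task.
    """
    df = labeled
    keep = df["label"].notna()
    if "excluded" in df:
        keep &= ~df["excluded"].astype(bool)
    if "fit_ok" in df:
        keep &= df["fit_ok"].astype(bool)
    if pass_index is not None and "pass_index" in df:
        keep &= df["pass_index"] == pass_index
    out = df[keep].copy().reset_index(drop=True)
    if merge_gp5:
        out["label"] = out["label"].replace({"GP4": "GP4+", "GP5": "GP4+"})
    return out


def _decimate_training(df: pd.DataFrame, stride: int) -> pd.DataFrame:
    """One training point per ``stride`` along each core (scoring is never
    decimated)."""
    if stride <= 1:
        return df
    parts = []
    cols = [c for c in ("core_id", "pass_index") if c in df.columns]
    for _, grp in df.groupby(cols, sort=False):
        parts.append(grp.sort_values("position_mm").iloc[::stride])
    return pd.concat(parts) if parts else df


# ---------------------------------------------------------------------------
# folds, costs, weights
# ---------------------------------------------------------------------------

def make_lopo_folds(patient_ids: Sequence[str]) -> Dict[str, List[str]]:
    """Leave-one-patient-out fold manifest: test patient -> training
    patients.  Invariant to record order (patients are sorted)."""
    patients = sorted(set(patient_ids))
    if len(patients) < 2:
        raise InvalidParameterError("LOPO needs at least 2 distinct patients")
    return {p: [q for q in patients if q != p] for p in patients}


def class_costs(labels: Sequence) -> Dict[str, float]:
    """Per-class misclassification costs inversely proportional to class
    frequency, normalized to mean 1 over the classes present."""
    counts = pd.Series(list(labels)).value_counts()
    if len(counts) < 2:
        raise InvalidParameterError("need at least 2 classes for costs")
    freq = counts / counts.sum()
    inv = 1.0 / freq
    costs = inv / inv.mean()
    return {str(k): float(v) for k, v in costs.items()}


def patient_weights(patient_ids: Sequence[str]) -> np.ndarray:
    """Per-point weights 1 / (points of the point's patient)."""
    s = pd.Series(list(patient_ids))
    counts = s.map(s.value_counts())
    return (1.0 / counts).to_numpy(float)


# ---------------------------------------------------------------------------
# weighted ROC
# ---------------------------------------------------------------------------

def weighted_roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    patient_ids: Optional[Sequence[str]] = None,
) -> Dict[str, object]:
    """Pooled ROC with patient-level weighting.

    ``labels`` are binary (bool or 0/1).  Each point is weighted by the
    inverse of its patient's point count, equalizing patient influence;
    the unweighted AUC is reported alongside.  Tied scores integrate with
    the trapezoidal midpoint convention.
    """
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, float)
    if y.all() or not y.any():
        raise UndefinedAUCError("both classes must be present for an ROC")
    if patient_ids is None:
        w = np.ones_like(s)
    else:
        w = patient_weights(patient_ids)

    def _auc(sample_weight):
        fpr, tpr, thr = roc_curve(
            y, s, sample_weight=sample_weight, drop_intermediate=False
        )
        return float(np.trapezoid(tpr, fpr)), fpr, tpr, thr

    auc_w, fpr, tpr, thr = _auc(w)
    auc_u, _, _, _ = _auc(None)
    return {
        "auc": auc_w,
        "auc_unweighted": auc_u,
        "fpr": fpr,
        "tpr": tpr,
        "thresholds": thr,
    }


def youden_operating_point(fpr, tpr, thresholds) -> Tuple[float, float, float]:
    """(sensitivity, specificity, threshold) at the maximum of Youden's J."""
    j = np.asarray(tpr) - np.asarray(fpr)
    i = int(np.argmax(j))
    return float(tpr[i]), float(1.0 - fpr[i]), float(thresholds[i])


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _median_gamma(X: np.ndarray, rng: np.random.Generator) -> float:
    n = X.shape[0]
    if n > 500:
        X = X[rng.choice(n, size=500, replace=False)]
    d = pdist(X)
    # zero distances (duplicate rows) are excluded, so duplicating the
    # training data does not move the median
    med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return 1.0 / (2.0 * med**2)


class _Standardizer:
    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.keep = sd > 0
        if not self.keep.all():
            logger.warning("dropping %d zero-variance features", (~self.keep).sum())
        self.sd = np.where(self.keep, sd, 1.0)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return ((X - self.mean) / self.sd)[:, self.keep]


#: reference total sample weight: per-point weights are scaled by
#: REF_WEIGHT_SUM / n_train, so the box constraint controls a fixed total
#: slack budget and results are invariant to duplicating the training set
#: (inverse-frequency costs already cancel the class-frequency part).
REF_WEIGHT_SUM = 1000.0


class _PlattSVM:
    """Binary RBF SVM with inverse-frequency costs and a monotone
    (Platt-type) probability calibration fit on the training fold."""

    def __init__(self, X, y01, box_constraint, rng):
        costs = class_costs(y01)
        scale = REF_WEIGHT_SUM / len(y01)
        self.svc = SVC(
            C=box_constraint,
            kernel="rbf",
            gamma=_median_gamma(X, rng),
            class_weight={int(k): v * scale for k, v in costs.items()},
        )
        self.svc.fit(X, y01)
        d = self.svc.decision_function(X).reshape(-1, 1)
        self.platt = LogisticRegression(C=1e6, max_iter=1000)
        self.platt.fit(d, y01)

    def predict_score(self, X) -> np.ndarray:
        d = self.svc.decision_function(X).reshape(-1, 1)
        return self.platt.predict_proba(d)[:, 1]


def _fit_multiclass_family(X, y, spec: ClassifierSpec, rng):
    """Native multiclass fit for the comparison families; returns a model
    exposing classes_ and predict_proba."""
    costs = class_costs(y)
    counts = pd.Series(y).value_counts()
    freq = (counts / counts.sum()).to_dict()
    if spec.family == "lda":
        priors_map = {c: freq[c] * costs[c] for c in costs}
        z = sum(priors_map.values())
        model = LinearDiscriminantAnalysis(
            priors=[priors_map[c] / z for c in sorted(costs)]
        )
    elif spec.family == "qda":
        priors_map = {c: freq[c] * costs[c] for c in costs}
        z = sum(priors_map.values())
        model = QuadraticDiscriminantAnalysis(
            priors=[priors_map[c] / z for c in sorted(costs)], reg_param=1e-3
        )
    elif spec.family == "logistic":
        model = LogisticRegression(class_weight=costs, max_iter=2000)
    elif spec.family == "tree":
        model = DecisionTreeClassifier(
            class_weight=costs, min_samples_leaf=spec.min_leaf, random_state=0
        )
    else:
        raise InvalidParameterError(f"family {spec.family!r} has no native multiclass fit")
    ysort = pd.Series(y, dtype=object)
    model.fit(X, ysort)
    return model


def train_predict_fold(
    train: pd.DataFrame,
    test: pd.DataFrame,
    spec: ClassifierSpec,
    classes: Sequence[str],
    rng_seed: int = 0,
    label_col: str = "label",
) -> np.ndarray:
    """Fit on one training fold and score the test fold.

    Features are standardized by training-fold statistics (zero-variance
    features dropped).  Returns an (n_test, n_classes) score matrix in the
    order of ``classes``; for the SVM family scores come from one-vs-one
    ECOC learners decoded to per-class values, for the other families from
    the native multiclass posterior.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(rng_seed)
    cols = feature_names(train, spec.feature_subset)
    std = _Standardizer(train[cols].to_numpy(float))
    Xtr = std(train[cols].to_numpy(float))
    Xte = std(test[cols].to_numpy(float))
    ytr = train[label_col].to_numpy(object)

    present = [c for c in classes if (ytr == c).any()]
    for c in classes:
        if c not in present:
            logger.warning("class %r absent from training fold", c)

    scores = np.zeros((len(test), len(classes)))
    if spec.family == "svm_rbf":
        votes = np.zeros(len(classes))
        for i, a in enumerate(classes):
            for jb in range(i + 1, len(classes)):
                b = classes[jb]
                if a not in present or b not in present:
                    continue
                mask = (ytr == a) | (ytr == b)
                y01 = (ytr[mask] == a).astype(int)
                model = _PlattSVM(Xtr[mask], y01, spec.box_constraint, rng)
                p = model.predict_score(Xte)
                scores[:, i] += p
                scores[:, jb] += 1.0 - p
                votes[i] += 1
                votes[jb] += 1
        votes[votes == 0] = 1.0
        scores = scores / votes[None, :]
    else:
        model = _fit_multiclass_family(Xtr, ytr, spec, rng)
        proba = model.predict_proba(Xte)
        order = {c: k for k, c in enumerate(model.classes_)}
        for i, c in enumerate(classes):
            if c in order:
                scores[:, i] = proba[:, order[c]]
    return scores


# ---------------------------------------------------------------------------
# validation drivers
# ---------------------------------------------------------------------------

def _lopo_scores(
    df: pd.DataFrame,
    classes: Sequence[str],
    spec: ClassifierSpec,
    rng_seed: int,
    fold_patients: Optional[Dict[str, List[str]]] = None,
    fold_ids: Optional[pd.Series] = None,
) -> Tuple[pd.DataFrame, Dict[str, List[str]]]:
    """Pool out-of-fold scores over LOPO folds.

    ``fold_ids`` allows bootstrap patient copies: folds follow the copy id
    while training data keeps all other copies.
    """
    ids = fold_ids if fold_ids is not None else df["patient_id"]
    manifest = fold_patients or make_lopo_folds(ids)
    score_cols = [f"score_{c}" for c in classes]
    pooled = df.copy()
    for c in score_cols:
        pooled[c] = np.nan
    for test_patient in manifest:
        test_mask = (ids == test_patient).to_numpy()
        train = df[~test_mask]
        train = _decimate_training(train, spec.train_stride)
        s = train_predict_fold(train, df[test_mask], spec, classes, rng_seed)
        pooled.loc[test_mask, score_cols] = s
    return pooled, {p: manifest[p] for p in sorted(manifest)}


def _metrics_for_class(
    pooled: pd.DataFrame, cls: str, classes: Sequence[str]
) -> Optional[ClassMetrics]:
    y = (pooled["label"] == cls).to_numpy()
    patients_with = pooled.loc[y, "patient_id"].nunique()
    if patients_with < 2:
        logger.warning("class %r present in <2 patients; AUC undefined", cls)
        return None
    try:
        roc = weighted_roc_auc(
            pooled[f"score_{cls}"].to_numpy(float), y, pooled["patient_id"]
        )
    except UndefinedAUCError:
        return None
    sens, spe, thr = youden_operating_point(
        roc["fpr"], roc["tpr"], roc["thresholds"]
    )
    return ClassMetrics(
        auc_weighted=roc["auc"],
        auc_unweighted=roc["auc_unweighted"],
        sensitivity=sens,
        specificity=spe,
        threshold=thr,
        fpr=roc["fpr"],
        tpr=roc["tpr"],
    )


def run_binary_task(
    dataset: pd.DataFrame,
    task: str,
    spec: Optional[ClassifierSpec] = None,
    rng_seed: int = 0,
) -> ValidationResult:
    """LOPO evaluation of one binary task ('two_class': PCa vs benign;
    'gp4_vs_rest': GP4+GP5 vs benign+GP3)."""
    if task not in BINARY_TASKS:
        raise InvalidParameterError(f"unknown binary task {task!r}")
    spec = spec or ClassifierSpec()
    pos_set, pos_name = BINARY_TASKS[task]
    df = dataset.copy()
    df["label"] = np.where(df["label"].isin(pos_set), pos_name, "rest")
    classes = [pos_name, "rest"]
    pooled, manifest = _lopo_scores(df, classes, spec, rng_seed)
    pooled["label_orig"] = dataset["label"].to_numpy()
    metrics = {pos_name: _metrics_for_class(pooled, pos_name, classes)}
    return ValidationResult(task, classes, pooled, metrics, manifest, spec)


def run_three_class(
    dataset: pd.DataFrame,
    spec: Optional[ClassifierSpec] = None,
    rng_seed: int = 0,
) -> ValidationResult:
    """LOPO evaluation of the three-class task (benign / GP3 / GP4+) with
    one-vs-one ECOC SVM (or a native multiclass comparison family)."""
    spec = spec or ClassifierSpec()
    classes = list(THREE_CLASSES)
    pooled, manifest = _lopo_scores(dataset, classes, spec, rng_seed)
    metrics = {c: _metrics_for_class(pooled, c, classes) for c in classes}
    return ValidationResult("three_class", classes, pooled, metrics, manifest, spec)


def naive_kfold_auc(
    dataset: pd.DataFrame,
    task: str = "gp4_vs_rest",
    spec: Optional[ClassifierSpec] = None,
    k: int = 10,
    rng_seed: int = 0,
) -> Dict[str, object]:
    """Point-level k-fold cross-validation ignoring patient boundaries.

    Folds are random over points, so spatially adjacent (nearly duplicate)
    measurements of one patient land in train and test simultaneously --
    the data-leakage comparison to LOPO.
    """
    if task not in BINARY_TASKS:
        raise InvalidParameterError(f"unknown binary task {task!r}")
    spec = spec or ClassifierSpec()
    pos_set, pos_name = BINARY_TASKS[task]
    df = dataset.copy().reset_index(drop=True)
    df["label"] = np.where(df["label"].isin(pos_set), pos_name, "rest")
    classes = [pos_name, "rest"]
    k = min(k, len(df))
    kf = KFold(n_splits=k, shuffle=True, random_state=rng_seed)
    score = np.full(len(df), np.nan)
    for tr_idx, te_idx in kf.split(df):
        train = _decimate_training(df.iloc[tr_idx], spec.train_stride)
        s = train_predict_fold(train, df.iloc[te_idx], spec, classes, rng_seed)
        score[te_idx] = s[:, 0]
    y = (df["label"] == pos_name).to_numpy()
    roc = weighted_roc_auc(score, y, df["patient_id"])
    return {"auc": roc["auc"], "auc_unweighted": roc["auc_unweighted"], "k": k}


def bootstrap_ci(
    dataset: pd.DataFrame,
    spec: Optional[ClassifierSpec] = None,
    B: int = 100,
    rng_seed: int = 0,
    mode: str = "resample_scores",
    base_result: Optional[ValidationResult] = None,
) -> Dict[str, object]:
    """Patient-level bootstrap CI (2.5th/97.5th percentiles) of the
    three-class per-class weighted AUCs.

    Patients are resampled with replacement.  ``mode="resample_scores"``
    (default) resamples patients' pooled out-of-fold scores and recomputes
    the weighted AUC per replicate -- the classical cluster bootstrap of
    the pooled ROC.  ``mode="refit"`` reruns the full LOPO per replicate
    (duplicated patients appear in the training of other copies' folds and
    are tested once per copy); it is exact to the protocol but far more
    expensive.  Replicates that lose a class are dropped and counted.
    """
    spec = spec or ClassifierSpec()
    patients = sorted(dataset["patient_id"].unique())
    if len(patients) < 5:
        raise InvalidParameterError("bootstrap needs at least 5 patients")
    rng = np.random.default_rng(rng_seed)
    classes = list(THREE_CLASSES)

    if mode == "resample_scores":
        if base_result is None:
            base_result = run_three_class(dataset, spec, rng_seed)
        pooled = base_result.scores
        by_patient = {p: g for p, g in pooled.groupby("patient_id")}
    elif mode != "refit":
        raise InvalidParameterError(f"unknown bootstrap mode {mode!r}")

    reps: Dict[str, List[float]] = {c: [] for c in classes}
    dropped = 0
    for b in range(B):
        draw = rng.choice(patients, size=len(patients), replace=True)
        if mode == "resample_scores":
            parts = []
            for j, p in enumerate(draw):
                g = by_patient[p].copy()
                g["patient_id"] = f"{p}#{j}"
                parts.append(g)
            rep = pd.concat(parts, ignore_index=True)
        else:
            parts = []
            for j, p in enumerate(draw):
                g = dataset[dataset["patient_id"] == p].copy()
                g["fold_id"] = f"{p}#{j}"
                parts.append(g)
            rep = pd.concat(parts, ignore_index=True)
            try:
                rep, _ = _lopo_scores(
                    rep, classes, spec, rng_seed, fold_ids=rep["fold_id"]
                )
            except InvalidParameterError:
                dropped += 1
                continue
            # each resampled copy is its own cluster for the weighting
            rep["patient_id"] = rep["fold_id"]
        ok = True
        vals = {}
        for c in classes:
            y = (rep["label"] == c).to_numpy()
            try:
                roc = weighted_roc_auc(
                    rep[f"score_{c}"].to_numpy(float), y, rep["patient_id"]
                )
            except UndefinedAUCError:
                ok = False
                break
            vals[c] = roc["auc"]
        if not ok:
            dropped += 1
            continue
        for c in classes:
            reps[c].append(vals[c])
    if dropped:
        logger.info("bootstrap: dropped %d/%d replicates missing a class", dropped, B)

    ci = {}
    for c in classes:
        arr = np.array(reps[c])
        if arr.size == 0:
            ci[c] = None
        else:
            ci[c] = (
                float(np.percentile(arr, 2.5)),
                float(np.percentile(arr, 97.5)),
            )
    return {
        "ci": ci,
        "replicates": {c: list(map(float, reps[c])) for c in classes},
        "n_dropped": dropped,
        "B": B,
        "mode": mode,
    }


def compare_classifiers(
    dataset: pd.DataFrame,
    families: Sequence[str] = FAMILIES,
    spec: Optional[ClassifierSpec] = None,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Three-class LOPO AUC table across model families on the
    four-lifetime feature set; all families share the fold manifest.
    Per-family failures are isolated as NaN rows."""
    spec = spec or ClassifierSpec()
    rows = {}
    for fam in families:
        fam_spec = replace(spec, family=fam, feature_subset="four_lifetimes")
        try:
            res = run_three_class(dataset, fam_spec, rng_seed)
            rows[fam] = {
                c: (m.auc_weighted if m is not None else np.nan)
                for c, m in res.per_class.items()
            }
        except Exception as exc:  # noqa: BLE001 - isolate per-family failures
            logger.warning("family %s failed: %s", fam, exc)
            rows[fam] = {c: np.nan for c in THREE_CLASSES}
    return pd.DataFrame(rows).T[list(THREE_CLASSES)]
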