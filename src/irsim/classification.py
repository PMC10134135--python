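"""Penalized linear classification and cross-validated ROC-AUC evaluation.

The evaluation pipeline mirrors standard chemometric practice for binary
phenotype classification from spectra: per-training-fold z-score
standardization of each wavenumber feature, an L2-regularized logistic
regression, and the ROC-AUC as the summary metric, reported as mean and
standard deviation over all folds of a repeated stratified k-fold
cross-validation. The ridge penalty is fixed (inverse strength ``C``, default
1.0) rather than tuned — the point of the L2 model here is robustness to
noise, and sensitivity to ``C`` can be probed through the argument.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .calibration import NoiseModel, calibrate_descriptive
from .cohort import SpectralCohort
from .errors import (
    DegenerateLabelsError,
    LeakageError,
    UnsplittableError,
    ValidationError,
)
from .rng import child_seed

__all__ = [
    "LinearScorer",
    "ClassificationResult",
    "fit_l2_logistic",
    "roc_auc",
    "repeated_kfold_cv",
    "train_sim_test_exp",
    "labels_to_binary",
    "assert_no_leakage",
]

CASE_LABEL = "case"
CONTROL_LABEL = "control"
_FPR_GRID = np.linspace(0.0, 1.0, 101)


def labels_to_binary(labels) -> np.ndarray:
    """Map control/case string labels to 0/1."""
    labels = np.asarray(labels).astype(str)
    known = {CONTROL_LABEL: 0, CASE_LABEL: 1}
    bad = set(labels) - set(known)
    if bad:
        raise ValidationError(f"labels {sorted(bad)} are not case/control")
    return np.array([known[l] for l in labels], dtype=int)


@dataclass
class LinearScorer:
    """A fitted linear decision function ``score(x) = x @ weights + intercept``.

    Standardization parameters fitted on the training data are folded in so
    the scorer applies directly to raw features.
    """

    weights: np.ndarray
    intercept: float

    def score(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features, dtype=float) @ self.weights + self.intercept


@dataclass
class ClassificationResult:
    """Cross-validated performance summary."""

    fold_aucs: np.ndarray
    mean_auc: float
    std_auc: float
    roc_points: np.ndarray  # (k, 2) averaged (FPR, TPR) polyline
    config_digest: str
    settings: dict

    @staticmethod
    def from_folds(
        fold_aucs: Sequence[float], rocs: Sequence[np.ndarray], settings: dict
    ) -> "ClassificationResult":
        fold_aucs = np.asarray(fold_aucs, dtype=float)
        mean_tpr = np.mean(np.stack(rocs), axis=0)
        mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
        digest = hashlib.sha256(
            json.dumps(settings, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        # std over folds uses ddof=1 (dispersion across CV splits)
        std = float(fold_aucs.std(ddof=1)) if fold_aucs.size > 1 else 0.0
        return ClassificationResult(
            fold_aucs=fold_aucs,
            mean_auc=float(fold_aucs.mean()),
            std_auc=std,
            roc_points=np.column_stack([_FPR_GRID, mean_tpr]),
            config_digest=digest,
            settings=settings,
        )


def _validate_features(features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    if not np.all(np.isfinite(features)):
        raise ValidationError("features must be finite")
    return features


def fit_l2_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    penalty_strength: float = 1.0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> LinearScorer:
    """Fit an L2-regularized logistic regression and return its linear scorer.

    ``penalty_strength`` follows the inverse-regularization convention
    (scikit-learn's ``C``): larger values mean weaker shrinkage. Features are
    expected to be standardized by the caller (the CV pipeline standardizes
    per training fold); the returned scorer operates on features as given.
    """
    features = _validate_features(features)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise DegenerateLabelsError("both classes must be present to fit a classifier")
    if penalty_strength <= 0:
        raise ValidationError("penalty_strength must be > 0")
    # L2 (ridge) penalty is LogisticRegression's default; C is its inverse strength
    clf = LogisticRegression(C=penalty_strength, solver="lbfgs", max_iter=max_iter, tol=tol)
    clf.fit(features, labels)
    return LinearScorer(weights=clf.coef_.ravel().copy(), intercept=float(clf.intercept_[0]))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC-AUC as the Mann-Whitney concordance probability, ties counted 1/2.

    Computed from mid-ranks: ``AUC = (R1 - n1(n1+1)/2) / (n1 * n0)`` with
    ``R1`` the rank sum of the positive class. Exactly equal to the average
    over all case-control pairs of ``[s_case > s_ctrl] + 1/2 [s_case = s_ctrl]``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise DegenerateLabelsError("AUC is undefined with a single class")
    ranks = rankdata(scores)  # mid-ranks
    r1 = float(np.sum(ranks[labels == 1]))
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _fold_roc(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """TPR on the common FPR grid for one fold (step-function interpolation)."""
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    tpr = np.concatenate([[0.0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0.0], fps / max(fps[-1], 1)])
    return np.interp(_FPR_GRID, fpr, tpr)


def _check_splittable(y: np.ndarray, k: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DegenerateLabelsError("both classes must be present")
    if counts.min() < k:
        raise UnsplittableError(
            f"smallest class has {counts.min()} members, cannot form {k} stratified folds"
        )


def assert_no_leakage(held_out_ids, calibration_ids) -> None:
    """Abort if any held-out sample id appears in a calibration/training set."""
    overlap = set(map(str, held_out_ids)) & set(map(str, calibration_ids))
    if overlap:
        raise LeakageError(
            f"held-out sample ids leaked into the calibration set: {sorted(overlap)[:5]}"
        )


def _standardized_fit_score(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    penalty_strength: float,
) -> np.ndarray:
    scaler = StandardScaler().fit(X_train)
    scorer = fit_l2_logistic(scaler.transform(X_train), y_train, penalty_strength)
    return scorer.score(scaler.transform(X_test))


def repeated_kfold_cv(
    cohort: SpectralCohort,
    k: int = 10,
    repeats: int = 10,
    penalty_strength: float = 1.0,
    seed: int = 0,
) -> ClassificationResult:
    """Repeated stratified k-fold cross-validation of the case-control task.

    Per fold: standardize on the training fold, fit, score the test fold and
    compute its ROC-AUC. Returns the mean and standard deviation over all
    ``k * repeats`` folds. Deterministic for a fixed seed.
    """
    X = cohort.absorbance
    y = labels_to_binary(cohort.labels)
    _check_splittable(y, k)
    fold_aucs, rocs = [], []
    for rep in range(repeats):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=child_seed(seed, rep))
        for train_idx, test_idx in splitter.split(X, y):
            scores = _standardized_fit_score(
                X[train_idx], y[train_idx], X[test_idx], penalty_strength
            )
            fold_aucs.append(roc_auc(scores, y[test_idx]))
            rocs.append(_fold_roc(scores, y[test_idx]))
    settings = {
        "evaluation": "repeated_kfold_cv",
        "k": k,
        "repeats": repeats,
        "penalty_strength": penalty_strength,
        "seed": int(seed),
        "n": int(cohort.n),
        "p": int(cohort.p),
    }
    return ClassificationResult.from_folds(fold_aucs, rocs, settings)


def train_sim_test_exp(
    reference: SpectralCohort,
    noise: Optional[NoiseModel],
    folds: int = 10,
    sim_repeats: int = 10,
    sim_sizes: Optional[Tuple[int, int]] = None,
    beta_scale: float = 1.0,
    eps_scale: float = 1.0,
    penalty_strength: float = 1.0,
    seed: int = 0,
) -> ClassificationResult:
    """Train on simulated spectra only, test on held-out reference spectra.

    The reference cohort is split into stratified folds. For each fold the
    descriptive models (control and case) are calibrated on the *remaining*
    reference spectra only, a training cohort of ``sim_sizes`` is simulated
    from them, a classifier is fitted on the simulated cohort and evaluated on
    the held-out fold. A leakage guard asserts that no held-out sample id ever
    enters calibration. ``sim_sizes`` defaults to the reference class sizes.
    """
    from .generator import SimulationConfig, simulate_case_control  # local: avoid cycle

    if folds < 2:
        raise ValidationError("folds must be >= 2")
    y = labels_to_binary(reference.labels)
    _check_splittable(y, folds)
    X = reference.absorbance
    counts = reference.label_counts()
    if sim_sizes is None:
        sim_sizes = (counts[CONTROL_LABEL], counts[CASE_LABEL])
    n_controls, n_cases = sim_sizes

    fold_aucs, rocs = [], []
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=child_seed(seed, 0))
    for fold_i, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        calib = reference.select(train_idx)
        assert_no_leakage(reference.sample_ids[test_idx], calib.sample_ids)
        control_model = calibrate_descriptive(calib.with_label(CONTROL_LABEL))
        case_model = calibrate_descriptive(calib.with_label(CASE_LABEL))
        for rep in range(sim_repeats):
            config = SimulationConfig(
                n_controls=n_controls,
                n_cases=n_cases,
                beta_scale=beta_scale,
                eps_scale=eps_scale,
                seed=child_seed(seed, 1, fold_i, rep),
            )
            sim = simulate_case_control(control_model, case_model, noise, config)
            scores = _standardized_fit_score(
                sim.absorbance, labels_to_binary(sim.labels), X[test_idx], penalty_strength
            )
            fold_aucs.append(roc_auc(scores, y[test_idx]))
            rocs.append(_fold_roc(scores, y[test_idx]))
    settings = {
        "evaluation": "train_sim_test_exp",
        "folds": folds,
        "sim_repeats": sim_repeats,
        "sim_sizes": list(sim_sizes),
        "beta_scale": beta_scale,
        "eps_scale": eps_scale,
        "penalty_strength": penalty_strength,
        "seed": int(seed),
    }
    return ClassificationResult.from_folds(fold_aucs, rocs, settings)
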