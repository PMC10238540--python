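"""Linear discriminant classification and the conditional attention cascade.

The motor-imagery paradigm uses a single two-class LDA (relax 0 vs MI 1) on
the alpha/beta CSP features.  The attention paradigm uses two LDAs on the
gamma CSP features, consulted per epoch according to the motor-imagery
output: when the MI decoder says the epoch is imagery, attention is scored
by the Count-vs-MI discriminant; otherwise by the (Relax+Count)-vs-MI one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, PredictionError, TrainingError


@dataclass
class LDAModel:
    """Closed-form two-class linear discriminant.

    Decision rule: ``w . x + b > 0`` predicts class 1; exact ties resolve
    to class 0 so the low-activity class is the conservative outcome.
    Class means and the pooled covariance are retained for audit.
    """

    weights: np.ndarray
    bias: float
    class_means: np.ndarray      # (2, n_features)
    pooled_cov: np.ndarray
    ridge: float


def fit_lda(features: np.ndarray, targets: np.ndarray, ridge: float = 1e-6) -> LDAModel:
    """Fit LDA from class means and a ridge-regularized pooled covariance.

    ``ridge`` scales the mean diagonal of the pooled covariance, so tiny
    training folds (even fewer rows than features) never fail.
    Deterministic given its inputs.
    """
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets)
    if features.ndim != 2:
        raise TrainingError(f"features must be 2-D, got shape {features.shape}")
    mask0, mask1 = targets == 0, targets == 1
    if not (mask0.any() and mask1.any()):
        raise TrainingError("fit_lda needs rows of both classes (targets 0 and 1)")

    x0, x1 = features[mask0], features[mask1]
    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
    scatter = np.zeros((features.shape[1],) * 2)
    for x, m in ((x0, m0), (x1, m1)):
        centered = x - m
        scatter += centered.T @ centered
    denom = max(len(x0) + len(x1) - 2, 1)
    pooled = scatter / denom
    mean_diag = float(np.mean(np.diag(pooled)))
    pooled_reg = pooled + ridge * (mean_diag if mean_diag > 0 else 1.0) * np.eye(len(m0))

    weights = np.linalg.solve(pooled_reg, m1 - m0)
    bias = -0.5 * float(weights @ (m0 + m1))
    return LDAModel(
        weights=weights,
        bias=bias,
        class_means=np.stack([m0, m1]),
        pooled_cov=pooled_reg,
        ridge=ridge,
    )


def decision_values(model: LDAModel, features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.shape[-1] != len(model.weights):
        raise AlignmentError(
            f"features have {features.shape[-1]} columns, model expects {len(model.weights)}"
        )
    return features @ model.weights + model.bias


def predict_binary(model: LDAModel, features: np.ndarray) -> np.ndarray:
    """Per-epoch 0/1 decisions; NaN features raise naming the epoch."""
    features = np.asarray(features, dtype=float)
    bad = np.flatnonzero(np.isnan(features).any(axis=-1))
    if bad.size:
        raise PredictionError(f"NaN feature value in epoch {int(bad[0])}")
    return (decision_values(model, features) > 0).astype(np.int64)


@dataclass
class CascadeModel:
    """Gated pair of attention discriminants sharing one feature space.

    ``count_vs_mi`` (classifier A) is trained on count-vs-MI rows only;
    ``rest_vs_mi`` (classifier B) on all rows with relax and count pooled
    as class 0.  When no relax rows exist (ramp trials without labeled
    rests) B is fitted on the same rows as A and the cascade degenerates
    to a single classifier.
    """

    count_vs_mi: LDAModel
    rest_vs_mi: LDAModel
    gating: str = "mi_output"


def fit_cascade(features: np.ndarray, tasks: np.ndarray) -> CascadeModel:
    """Fit both attention discriminants from task-labeled feature rows."""
    features = np.asarray(features, dtype=float)
    tasks = np.asarray(tasks, dtype=object)
    known = {"relax", "mi", "count"}
    unknown = set(tasks.tolist()) - known
    if unknown:
        raise TrainingError(f"unknown task name(s) {sorted(map(str, unknown))}; expected {sorted(known)}")
    if not (tasks == "mi").any():
        raise TrainingError("cascade training requires MI rows")

    mask_a = (tasks == "mi") | (tasks == "count")
    clf_a = fit_lda(features[mask_a], (tasks[mask_a] == "mi").astype(int))
    clf_b = fit_lda(features, (tasks == "mi").astype(int))
    return CascadeModel(count_vs_mi=clf_a, rest_vs_mi=clf_b)


def predict_cascade(
    model: CascadeModel, features: np.ndarray, mi_gate: np.ndarray
) -> np.ndarray:
    """Binary attention decision per epoch, gated by the MI-paradigm output.

    Epochs the MI decoder flagged as imagery (gate 1) are scored by the
    Count-vs-MI discriminant, the rest by (Relax+Count)-vs-MI.
    """
    features = np.asarray(features, dtype=float)
    mi_gate = np.asarray(mi_gate)
    if len(mi_gate) != len(features):
        raise AlignmentError(
            f"gate has {len(mi_gate)} entries but features have {len(features)} rows"
        )
    pred_a = predict_binary(model.count_vs_mi, features)
    pred_b = predict_binary(model.rest_vs_mi, features)
    return np.where(mi_gate == 1, pred_a, pred_b).astype(np.int64)
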