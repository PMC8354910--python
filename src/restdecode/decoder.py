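"""Wrist-vs-finger decoding: trial patterns, L2-regularised logistic
regression, leave-one-session-out cross-validation, weight maps.

Trial construction mirrors the block design: within each task block the
first two scans are discarded (haemodynamic lag carries the previous state),
the remaining scans are scaled to unit Euclidean norm, and their mean is one
trial pattern.  The decoder models P(y = Finger | x) = sigmoid(x.w + b) with
an L2 penalty on w (the bias is unpenalised); Finger is the positive class,
so positive decision values are finger-like and negative ones wrist-like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import wilcoxon

from .core import FINGER, REST, WRIST, Run

__all__ = [
    "TrialSet",
    "DecoderModel",
    "normalize_scan",
    "extract_trials",
    "train_decoder",
    "predict",
    "loo_cv_accuracy",
    "threshold_weight_map",
    "compare_to_control",
]


@dataclass
class TrialSet:
    """Per-trial averaged patterns with class labels and session ids.

    ``patterns[i]`` is the mean of the unit-normalised scans of one task
    block; ``labels[i]`` is ``"Wrist"`` or ``"Finger"``; ``session_ids[i]``
    identifies the session the block came from.
    """

    patterns: np.ndarray
    labels: np.ndarray
    session_ids: np.ndarray

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.session_ids = np.asarray(self.session_ids, dtype=int)
        n = self.patterns.shape[0]
        if not (len(self.labels) == n == len(self.session_ids)):
            raise ValueError("patterns, labels and session_ids must align")

    @property
    def n_trials(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    def concat(self, other: "TrialSet") -> "TrialSet":
        return TrialSet(
            patterns=np.vstack([self.patterns, other.patterns]),
            labels=np.concatenate([self.labels, other.labels]),
            session_ids=np.concatenate([self.session_ids, other.session_ids]),
        )

    def subset(self, mask: np.ndarray) -> "TrialSet":
        return TrialSet(
            patterns=self.patterns[mask],
            labels=self.labels[mask],
            session_ids=self.session_ids[mask],
        )


@dataclass
class DecoderModel:
    """Trained linear decoder: weights ``w`` over voxels, bias ``b``,
    L2 strength ``lam``, and the number of training trials."""

    w: np.ndarray
    b: float
    lam: float
    n_train: int

    def decision_values(self, patterns: np.ndarray) -> np.ndarray:
        patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
        if patterns.shape[1] != self.w.shape[0]:
            raise ValueError(
                f"pattern has {patterns.shape[1]} voxels, decoder expects {self.w.shape[0]}"
            )
        return patterns @ self.w + self.b


def normalize_scan(x: np.ndarray) -> np.ndarray:
    """Scale a voxel vector to unit Euclidean norm (direction preserved)."""
    x = np.asarray(x, dtype=float)
    norm = np.linalg.norm(x)
    if norm == 0:
        raise ValueError("cannot normalise an all-zero scan")
    return x / norm


def _contiguous_blocks(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """(label, start, stop) for each maximal run of identical labels."""
    blocks = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            blocks.append((labels[start], start, i))
            start = i
    return blocks


def extract_trials(run: Run, schedule: np.ndarray, drop_initial: int = 2) -> TrialSet:
    """Build one trial pattern per task block.

    For each contiguous Wrist/Finger block in the schedule: drop the first
    ``drop_initial`` scans, unit-normalise each remaining scan, and average
    them into a single pattern row.
    """
    schedule = np.asarray(schedule, dtype=object)
    if len(schedule) != run.n_scans:
        raise ValueError("schedule must label every scan of the run")
    session = run.session_id if run.session_id is not None else 0

    rows, labels = [], []
    for label, start, stop in _contiguous_blocks(schedule):
        if label == REST:
            continue
        if label not in (WRIST, FINGER):
            raise ValueError(f"unknown schedule label {label!r}")
        if stop - start <= drop_initial:
            raise ValueError(
                f"block of {stop - start} scans too short to drop {drop_initial}"
            )
        scans = run.data[start + drop_initial : stop]
        rows.append(np.mean([normalize_scan(s) for s in scans], axis=0))
        labels.append(label)
    return TrialSet(
        patterns=np.array(rows),
        labels=np.array(labels, dtype=object),
        session_ids=np.full(len(rows), session, dtype=int),
    )


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    """Finger -> +1, Wrist -> -1."""
    y = np.where(labels == FINGER, 1.0, -1.0)
    bad = set(labels) - {WRIST, FINGER}
    if bad:
        raise ValueError(f"unknown class labels: {bad}")
    return y


def train_decoder(trials: TrialSet, lam: float = 1.0) -> DecoderModel:
    """Fit the L2-penalised logistic decoder.

    Minimises ``sum_i log(1 + exp(-y_i (x_i.w + b))) + (lam/2) ||w||^2``
    (bias unpenalised) by L-BFGS with an analytic gradient; converges to
    gradient norm <= 1e-6.
    """
    classes = set(trials.labels)
    if classes != {WRIST, FINGER}:
        raise ValueError(f"training needs both classes, got {sorted(map(str, classes))}")
    for cls in (WRIST, FINGER):
        if np.sum(trials.labels == cls) < 2:
            raise ValueError(f"need >= 2 trials of class {cls}")
    if lam < 0:
        raise ValueError("lam must be >= 0")

    X = trials.patterns
    y = _encode_labels(trials.labels)
    n, p = X.shape

    def objective(theta: np.ndarray):
        w, b = theta[:p], theta[p]
        margins = y * (X @ w + b)
        # log(1 + exp(-m)) computed stably
        loss = np.sum(np.logaddexp(0.0, -margins))
        sig = 1.0 / (1.0 + np.exp(np.clip(margins, -500, 500)))
        grad_w = -(X.T @ (y * sig)) + lam * w
        grad_b = -np.sum(y * sig)
        return loss + 0.5 * lam * w @ w, np.append(grad_w, grad_b)

    theta0 = np.zeros(p + 1)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "gtol": 1e-9, "ftol": 1e-15},
    )
    grad_norm = np.max(np.abs(res.jac))
    if grad_norm > 1e-6:
        # polish with a few Newton-ish restarts from the L-BFGS solution
        res = minimize(objective, res.x, jac=True, method="L-BFGS-B",
                       options={"maxiter": 5000, "gtol": 1e-12, "ftol": 1e-18})
    return DecoderModel(w=res.x[:p], b=float(res.x[p]), lam=lam, n_train=n)


def predict(model: DecoderModel, patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Probability of Finger and hard label per pattern.

    Label is Finger iff P(Finger) > 0.5; an exact tie goes to Wrist.
    """
    z = model.decision_values(patterns)
    prob = 1.0 / (1.0 + np.exp(-z))
    labels = np.where(prob > 0.5, FINGER, WRIST).astype(object)
    return prob, labels


def loo_cv_accuracy(trials: TrialSet, lam: float = 1.0) -> tuple[float, list[dict]]:
    """Leave-one-session-out cross-validation.

    For each session: train on every other session, classify the held-out
    trials.  Returns overall accuracy (correct / total held-out trials) and a
    per-fold record.
    """
    sessions = np.unique(trials.session_ids)
    if len(sessions) < 2:
        raise ValueError("leave-one-session-out CV requires >= 2 sessions")

    correct = 0
    total = 0
    folds = []
    for s in sessions:
        test_mask = trials.session_ids == s
        train = trials.subset(~test_mask)
        test = trials.subset(test_mask)
        assert not set(train.session_ids) & set(test.session_ids)
        model = train_decoder(train, lam)
        _, pred = predict(model, test.patterns)
        n_ok = int(np.sum(pred == test.labels))
        correct += n_ok
        total += test.n_trials
        folds.append({"session": int(s), "n_test": test.n_trials, "n_correct": n_ok})
    return correct / total, folds


def threshold_weight_map(
    avg_w: np.ndarray, fraction: float = 0.10
) -> tuple[np.ndarray, np.ndarray]:
    """Select the top ``fraction`` of voxels by |weight|.

    Returns ``(finger_voxels, wrist_voxels)``: indices of selected voxels
    with positive weights (finger-related) and negative weights
    (wrist-related).  ``ceil(fraction * n)`` voxels are selected; ties in
    |weight| break towards the lower voxel index.
    """
    avg_w = np.asarray(avg_w, dtype=float)
    if avg_w.size == 0:
        raise ValueError("empty weight map")
    k = int(np.ceil(fraction * avg_w.size))
    order = np.lexsort((np.arange(avg_w.size), -np.abs(avg_w)))
    selected = np.sort(order[:k])
    finger_voxels = selected[avg_w[selected] > 0]
    wrist_voxels = selected[avg_w[selected] < 0]
    return finger_voxels, wrist_voxels


def compare_to_control(
    roi_accuracies: np.ndarray,
    control_accuracies: np.ndarray,
    n_rois: int = 8,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Paired Wilcoxon signed-rank test of an ROI's accuracies against the
    control ROI, Bonferroni-corrected across ``n_rois`` regions.

    Returns the adjusted two-sided p-value (capped at 1) and whether it is
    below ``alpha``.
    """
    roi = np.asarray(roi_accuracies, dtype=float)
    ctl = np.asarray(control_accuracies, dtype=float)
    if roi.shape != ctl.shape:
        raise ValueError("paired samples must have equal length")
    if roi.size < 5:
        raise ValueError("need >= 5 pairs for a meaningful signed-rank test")
    diffs = roi - ctl
    if np.all(diffs == 0):
        p_raw = 1.0
    else:
        p_raw = float(wilcoxon(roi, ctl, alternative="two-sided").pvalue)
    p_adj = min(1.0, p_raw * n_rois)
    return p_adj, p_adj < alpha
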