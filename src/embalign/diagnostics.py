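"""Decoupled confidence scoring of label assignments.

A random forest (200 trees, depth 10 by default) predicts per-cell
assignment correctness from five alignment features: the Sinkhorn row
entropy of the cell's soft correspondence, its Mahalanobis distance to
the assigned template Gaussian, the frame's cell count, the frame's
inferred canonical time (the winning slice's t_med), and the assigned
cell's life progress (t_med - t_birth)/(t_division - t_birth) clipped to
[0, 1]. Cell probabilities average into a frame-level confidence.

Because correct assignments vastly outnumber errors, the layer is
evaluated by the area under the precision-recall curve for the *error*
class, with step-wise interpolated precision. The leave-one-out harness
fits the atlas, slice database, growth curve and the confidence model on
the training embryos of each fold before scoring the withheld embryo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .atlas import CellTrajectoryModel, EmbryoAtlas
from .config import RunConfig
from .io import ObservedFrame
from .registration import FrameResult, NoTemplateError, align_frame

log = logging.getLogger("embalign")

FEATURE_NAMES = ("sinkhorn_entropy", "mahalanobis", "frame_cell_count",
                 "frame_inferred_time", "division_delta")


def division_delta(model: CellTrajectoryModel, t_med: float) -> float:
    """Life progress of a cell at t_med, clipped to [0, 1]."""
    span = model.t_division - model.t_birth
    if span <= 0:
        return 0.0
    return float(np.clip((t_med - model.t_birth) / span, 0.0, 1.0))


def features_for_assignment(result: FrameResult,
                            trajectories: Mapping[str, CellTrajectoryModel],
                            assigned_names: Sequence[str] | None = None) -> np.ndarray:
    """Feature matrix (N, 5) for an arbitrary assignment of a frame result.

    ``assigned_names`` defaults to the winning assignment; passing an
    alternative permutation of the slice's names recomputes the
    Mahalanobis and division-delta features for that assignment (used
    when injecting label corruptions during evaluation).
    """
    names = list(assigned_names if assigned_names is not None else result.assigned_names)
    n = result.frame.n_cells
    if len(names) != n:
        raise ValueError("one assigned name per observed cell is required")
    col = {name: j for j, name in enumerate(result.slice.cell_names)}
    rows = np.empty((n, 5))
    for i, name in enumerate(names):
        if name not in trajectories:
            raise KeyError(f"assigned cell {name!r} has no atlas trajectory")
        if name not in col:
            raise KeyError(f"assigned cell {name!r} is not in the winning slice")
        rows[i] = (result.entropies[i],
                   result.cost_matrix[i, col[name]],
                   n,
                   result.slice.t_med,
                   division_delta(trajectories[name], result.slice.t_med))
    return rows


def extract_cell_features(result: FrameResult,
                          trajectories: Mapping[str, CellTrajectoryModel]) -> np.ndarray:
    """Per-cell diagnostic features of the winning assignment, shape (N, 5)."""
    return features_for_assignment(result, trajectories)


class ConfidenceScorer(BaseEstimator, ClassifierMixin):
    """Random-forest classifier of per-cell assignment correctness.

    ``predict_proba``'s positive column is the probability that an
    assignment is *correct*; :meth:`score_frame` averages it into the
    frame-level confidence.
    """

    def __init__(self, n_estimators: int = 200, max_depth: int = 10,
                 class_weight=None, random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"X must have {len(FEATURE_NAMES)} columns {FEATURE_NAMES}")
        if len(np.unique(y)) < 2:
            raise ValueError(
                "training labels contain a single class; the confidence model "
                "needs both correct and incorrect assignments")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            class_weight=self.class_weight, random_state=self.random_state)
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        self.feature_order_ = FEATURE_NAMES
        return self

    def _validate(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_order_):
            raise ValueError(
                f"feature matrix must have columns {self.feature_order_} in order")
        return X

    def predict_proba(self, X):
        return self.forest_.predict_proba(self._validate(X))

    def predict(self, X):
        return self.forest_.predict(self._validate(X))

    def confidence(self, X) -> np.ndarray:
        """P(correct) per cell."""
        proba = self.predict_proba(X)
        return proba[:, int(np.flatnonzero(self.classes_ == 1)[0])]

    def score_frame(self, X) -> tuple[np.ndarray, float]:
        """(per-cell confidences, their arithmetic mean)."""
        conf = self.confidence(X)
        return conf, float(conf.mean())


# ---------------------------------------------------------------------------
# precision-recall with interpolated precision


def pr_curve_interpolated(is_error: np.ndarray, error_score: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated PR curve for detecting errors by descending score.

    Returns (recall, precision) step points where precision at recall r
    is the maximum achievable precision at any recall >= r.
    """
    is_error = np.asarray(is_error).astype(bool)
    error_score = np.asarray(error_score, dtype=float)
    n_pos = int(is_error.sum())
    if n_pos == 0:
        raise ValueError("no positive (error) examples; PR curve undefined")
    order = np.argsort(-error_score, kind="stable")
    tp = np.cumsum(is_error[order])
    k = np.arange(1, len(order) + 1)
    recall = tp / n_pos
    precision = tp / k
    # best precision at each distinct recall level = its first occurrence
    keep = np.r_[True, recall[1:] != recall[:-1]]
    keep &= np.r_[recall[0] > 0, np.ones(len(recall) - 1, dtype=bool)]
    r = recall[keep]
    p = precision[keep]
    p_interp = np.maximum.accumulate(p[::-1])[::-1]
    return r, p_interp


def auprc(is_error: np.ndarray, error_score: np.ndarray) -> float:
    """Area under the interpolated precision-recall curve."""
    r, p = pr_curve_interpolated(is_error, error_score)
    r = np.r_[0.0, r]
    return float(np.sum((r[1:] - r[:-1]) * p))


# ---------------------------------------------------------------------------
# leave-one-out cross-validation harness


@dataclass
class CellRecordOut:
    embryo_id: str
    frame_index: int
    true_name: str
    assigned_name: str
    correct: bool
    confidence: float | None
    features: np.ndarray


@dataclass
class EvaluationReport:
    """Aggregated LOOCV outcome across folds."""

    frame_accuracies: list[tuple[str, int, float]]   # (embryo, frame, accuracy)
    mean_frame_accuracy: float
    per_cell_type_accuracy: dict[str, float]
    cells: list[CellRecordOut]
    pr_recall: np.ndarray | None = None
    pr_precision: np.ndarray | None = None
    auprc: float | None = None
    error_prevalence: float | None = None
    error_recall: float | None = None
    success_recall: float | None = None
    confidence_threshold: float = 0.5
    n_skipped_frames: int = 0
    fold_embryos: list[str] = field(default_factory=list)


def _inject_swaps(names: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    """Corrupt ~rate of a frame's assignments by swapping random pairs."""
    n = len(names)
    if n < 2 or rate <= 0:
        return names
    n_swaps = int(round(rate * n / 2.0))
    # keep at least an expected-rate chance of one swap in small frames
    if n_swaps == 0 and rng.random() < rate * n / 2.0:
        n_swaps = 1
    out = list(names)
    for _ in range(n_swaps):
        i, j = rng.choice(n, size=2, replace=False)
        out[i], out[j] = out[j], out[i]
    return out


def _fold_cell_records(frames: Sequence[ObservedFrame], atlas: EmbryoAtlas,
                       config: RunConfig, inject_rate: float,
                       rng: np.random.Generator
                       ) -> tuple[list[CellRecordOut], list[tuple[str, int, float]], int]:
    records: list[CellRecordOut] = []
    frame_acc: list[tuple[str, int, float]] = []
    skipped = 0
    for f in frames:
        truth = f.cell_names
        try:
            res = align_frame(f.unlabeled(), atlas.slice_db_, config)
        except NoTemplateError:
            skipped += 1
            continue
        correct = [a == t for a, t in zip(res.assigned_names, truth)]
        frame_acc.append((f.embryo_id, f.frame_index, float(np.mean(correct))))
        names = _inject_swaps(list(res.assigned_names), inject_rate, rng)
        feats = features_for_assignment(res, atlas.trajectories_, names)
        for i, name in enumerate(names):
            records.append(CellRecordOut(
                f.embryo_id, f.frame_index, truth[i], name,
                name == truth[i], None, feats[i]))
    return records, frame_acc, skipped


def loocv_evaluate(cohort: Mapping[str, Sequence[ObservedFrame]],
                   config: RunConfig | None = None,
                   with_diagnostics: bool = True,
                   inject_error_rate: float = 0.0) -> EvaluationReport:
    """Leave-one-embryo-out evaluation of the full pipeline.

    Per fold the atlas (GP trajectories, slice database, growth curve)
    and, when enabled, the confidence model are fitted on the training
    embryos only; the withheld embryo's frames are stripped of labels,
    aligned and scored. ``inject_error_rate`` corrupts that fraction of
    assignments (random pairwise swaps, features recomputed) on both the
    training and test sides so the diagnostic layer sees both classes
    even when the aligner itself is near-perfect.
    """
    config = config or RunConfig()
    embryos = sorted(cohort)
    if len(embryos) < 2:
        raise ValueError("LOOCV needs at least 2 embryos")
    rng = np.random.default_rng(config.random_seed)

    all_cells: list[CellRecordOut] = []
    frame_acc: list[tuple[str, int, float]] = []
    n_skipped = 0
    for test_id in embryos:
        train_ids = [e for e in embryos if e != test_id]
        train_frames = [f for e in train_ids for f in cohort[e]]
        assert all(f.embryo_id != test_id for f in train_frames)
        atlas = EmbryoAtlas(time_bin_width=config.time_bin_width,
                            covariance_jitter=config.covariance_jitter,
                            gp_restarts=config.gp_restarts,
                            random_state=config.random_seed).fit(train_frames)

        model = None
        if with_diagnostics:
            train_records, _, _ = _fold_cell_records(
                train_frames, atlas, config, inject_error_rate, rng)
            X = np.stack([r.features for r in train_records])
            y = np.array([r.correct for r in train_records], dtype=int)
            if len(np.unique(y)) == 2:
                model = ConfidenceScorer(
                    n_estimators=config.rf_n_estimators,
                    max_depth=config.rf_max_depth,
                    class_weight="balanced" if config.rf_balanced else None,
                    random_state=config.random_seed).fit(X, y)
            else:
                log.warning("fold %s: single-class training labels; "
                            "confidence model skipped", test_id)

        test_records, acc, skipped = _fold_cell_records(
            list(cohort[test_id]), atlas, config, inject_error_rate, rng)
        if model is not None and test_records:
            conf = model.confidence(np.stack([r.features for r in test_records]))
            for r, c in zip(test_records, conf):
                r.confidence = float(c)
        all_cells.extend(test_records)
        frame_acc.extend(acc)
        n_skipped += skipped

    by_type: dict[str, list[bool]] = {}
    for r in all_cells:
        by_type.setdefault(r.true_name, []).append(r.correct)
    per_type = {k: float(np.mean(v)) for k, v in sorted(by_type.items())}

    report = EvaluationReport(
        frame_accuracies=frame_acc,
        mean_frame_accuracy=float(np.mean([a for _, _, a in frame_acc])),
        per_cell_type_accuracy=per_type,
        cells=all_cells,
        confidence_threshold=config.confidence_threshold,
        n_skipped_frames=n_skipped,
        fold_embryos=embryos)

    scored = [r for r in all_cells if r.confidence is not None]
    if scored:
        is_error = np.array([not r.correct for r in scored])
        err_score = np.array([1.0 - r.confidence for r in scored])
        if is_error.any():
            report.pr_recall, report.pr_precision = pr_curve_interpolated(is_error, err_score)
            report.auprc = auprc(is_error, err_score)
            report.error_prevalence = float(is_error.mean())
            thr = config.confidence_threshold
            flagged = np.array([r.confidence < thr for r in scored])
            report.error_recall = float(flagged[is_error].mean())
            report.success_recall = float((~flagged)[~is_error].mean()) if (~is_error).any() else None
    return report
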