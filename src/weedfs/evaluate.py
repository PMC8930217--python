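"""Classification metrics, ROC analysis and the repeated hold-out protocol.

Metrics follow the usual two-class definitions: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), precision TP/(TP+FP), accuracy (TP+TN)/total and the
F-score as the harmonic mean of precision and sensitivity. All are reported
as percentages; exports round to 2 decimals, internal values keep full
precision.

The repeated-iteration protocol draws seeded stratified 70/30 train/test
splits; on each split feature selection (optional) and classifier training
see only the training samples, and the test split is scored once. The
report holds one metrics row per iteration plus their arithmetic mean, and
an ROC over the pooled test-split scores.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from . import ciwo, dnn
from .matrix import ExpressionMatrix
from .preprocess import PreprocessConfig, run_preprocess


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_label: object = "tumor"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass
class MetricsRow:
    """Percentages in [0, 100]."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f_score: float

    def rounded(self) -> "MetricsRow":
        return MetricsRow(*(round(v, 2) for v in dataclasses.astuple(self)))

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray


@dataclasses.dataclass
class IterationArtifacts:
    """What one pipeline iteration produced before seeing test labels."""

    iteration: int
    seed: int
    selected_mask: np.ndarray | None
    model_params: dnn.NetworkParams
    test_sample_ids: list[str]
    test_scores: np.ndarray  # positive-class probabilities
    test_labels: np.ndarray


@dataclasses.dataclass
class EvaluationReport:
    rows: list[MetricsRow]
    average: MetricsRow
    roc: ROCCurve
    auc: float  # percentage
    artifacts: list[IterationArtifacts] = dataclasses.field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        data = [r.rounded().as_dict() for r in self.rows]
        data.append(self.average.rounded().as_dict())
        index = [f"Iteration {i + 1}" for i in range(len(self.rows))] + ["Average"]
        df = pd.DataFrame(data, index=index)
        df.columns = ["Sensitivity", "Specificity", "Precision", "Accuracy", "F-score"]
        return df

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "rows": [r.as_dict() for r in self.rows],
            "average": self.average.as_dict(),
            "auc": self.auc,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def confusion(y_true, y_pred, positive_label) -> ConfusionCounts:
    """Exact confusion counts; labels must come from the two observed classes."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = set(np.unique(y_true).tolist())
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} absent from y_true")
    if len(classes) > 2:
        raise ValueError("more than two classes in y_true")
    unknown = set(np.unique(y_pred).tolist()) - classes
    if unknown:
        raise ValueError(f"unknown predicted label(s): {sorted(map(str, unknown))}")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionCounts(
        tp=int((pos_t & pos_p).sum()),
        fp=int((~pos_t & pos_p).sum()),
        tn=int((~pos_t & ~pos_p).sum()),
        fn=int((pos_t & ~pos_p).sum()),
        positive_label=positive_label,
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} has a 0/0 denominator; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricsRow:
    """Sensitivity/specificity/precision/accuracy/F-score as percentages."""
    sens = _safe_div(c.tp, c.tp + c.fn, "sensitivity")
    spec = _safe_div(c.tn, c.tn + c.fp, "specificity")
    prec = _safe_div(c.tp, c.tp + c.fp, "precision")
    acc = _safe_div(c.tp + c.tn, c.total, "accuracy")
    f = _safe_div(2.0 * prec * sens, prec + sens, "f_score")
    return MetricsRow(
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        precision=100.0 * prec,
        accuracy=100.0 * acc,
        f_score=100.0 * f,
    )


def roc_auc(y_true, scores, positive_label) -> tuple[ROCCurve, float]:
    """ROC by threshold sweep over the unique scores (ties grouped), AUC by
    the trapezoid rule; AUC returned as a percentage."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    pos = y_true == positive_label
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes to be present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = pos[order]
    # group ties: cumulative counts at the last index of each distinct score
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    cum_tp = np.cumsum(sorted_pos)[distinct]
    cum_fp = np.cumsum(~sorted_pos)[distinct]
    tpr = np.r_[0.0, cum_tp / n_pos]
    fpr = np.r_[0.0, cum_fp / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, tpr=tpr, fpr=fpr), 100.0 * auc


# ---------------------------------------------------------------------------
# repeated hold-out pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """End-to-end settings: preprocessing, optional selection, classifier."""

    preprocess: PreprocessConfig | None = dataclasses.field(default_factory=PreprocessConfig)
    select: bool = True
    ciwo_params: ciwo.CIWOParams = dataclasses.field(default_factory=ciwo.CIWOParams)
    fitness: ciwo.FitnessConfig = dataclasses.field(default_factory=ciwo.FitnessConfig)
    hidden_sizes: tuple[int, int] = (64, 32)
    training: dnn.TrainingOptions = dataclasses.field(default_factory=dnn.TrainingOptions)
    rms_alpha: float = 1e-3
    rms_beta: float = 0.9
    rms_epsilon: float = 1e-8
    test_fraction: float = 0.3
    positive_label: object = "tumor"


def fit_pipeline(
    train_matrix: ExpressionMatrix, cfg: PipelineConfig, seed: int
) -> tuple[np.ndarray | None, dnn.NetworkParams]:
    """Select features (optional) and train the classifier on training data
    only. Deterministic given ``seed``."""
    mask = None
    Xtr = train_matrix.sample_matrix()
    ytr = train_matrix.label_codes(cfg.positive_label)
    if cfg.select:
        params = dataclasses.replace(cfg.ciwo_params, rng_seed=seed)
        fit_cfg = dataclasses.replace(cfg.fitness, cv_seed=seed)
        result = ciwo.run_ciwo(train_matrix, params, fit_cfg)
        mask = result.best_mask
        if not mask.any():  # degenerate: fall back to all genes
            mask = np.ones(train_matrix.n_genes, dtype=bool)
        Xtr = Xtr[:, mask]
    spec = dnn.NetworkSpec(
        layer_sizes=(Xtr.shape[1], *cfg.hidden_sizes, 2), init_seed=seed
    )
    opts = dataclasses.replace(cfg.training, shuffle_seed=seed + 1)
    params0 = dnn.init_params(spec)
    rms = dnn.RMSpropState.for_params(
        params0, alpha=cfg.rms_alpha, beta=cfg.rms_beta, epsilon=cfg.rms_epsilon
    )
    model, _ = dnn.train(spec, Xtr, ytr, opts, rms)
    return mask, model


def score_split(
    artifacts_mask: np.ndarray | None,
    model: dnn.NetworkParams,
    test_matrix: ExpressionMatrix,
    cfg: PipelineConfig,
) -> tuple[MetricsRow, np.ndarray]:
    """Apply a fitted mask+model to a test split; returns the metrics row and
    the positive-class probabilities."""
    Xte = test_matrix.sample_matrix()
    if artifacts_mask is not None:
        Xte = Xte[:, artifacts_mask]
    yte = test_matrix.label_codes(cfg.positive_label)
    pred, probs = dnn.predict(model, Xte)
    names = test_matrix.class_names
    neg = [n for n in names if n != cfg.positive_label][0]
    pred_labels = np.where(pred == 1, cfg.positive_label, neg)
    row = metrics(confusion(test_matrix.labels, pred_labels, cfg.positive_label))
    # column index 1 is the positive class by label_codes construction
    return row, probs[:, 1]


def repeated_evaluation(
    dataset: ExpressionMatrix,
    pipeline_cfg: PipelineConfig | None = None,
    n_iterations: int = 10,
    base_seed: int = 0,
) -> EvaluationReport:
    """Seeded stratified hold-out repeated ``n_iterations`` times.

    Preprocessing (label-free) is applied once to the full matrix; selection
    and training then see only each iteration's training split.
    """
    cfg = pipeline_cfg or PipelineConfig()
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if cfg.preprocess is not None:
        dataset = run_preprocess(dataset, cfg.preprocess).matrix
    y = dataset.label_codes(cfg.positive_label)
    rows: list[MetricsRow] = []
    artifacts: list[IterationArtifacts] = []
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for i in range(n_iterations):
        seed = base_seed + i
        for attempt in range(10):
            splitter = StratifiedShuffleSplit(
                n_splits=1, test_size=cfg.test_fraction, random_state=seed + 1000 * attempt
            )
            train_idx, test_idx = next(splitter.split(np.zeros_like(y), y))
            if len(set(y[train_idx])) == 2 and len(set(y[test_idx])) == 2:
                break
        else:  # pragma: no cover - stratified splits always contain both classes
            raise RuntimeError("could not draw a split containing both classes")
        train_m = dataset.subset_samples(train_idx)
        test_m = dataset.subset_samples(test_idx)
        mask, model = fit_pipeline(train_m, cfg, seed)
        row, scores = score_split(mask, model, test_m, cfg)
        rows.append(row)
        artifacts.append(
            IterationArtifacts(
                iteration=i,
                seed=seed,
                selected_mask=mask,
                model_params=model,
                test_sample_ids=list(test_m.sample_ids),
                test_scores=scores,
                test_labels=test_m.labels.copy(),
            )
        )
        all_scores.append(scores)
        all_labels.append(test_m.labels)
    avg = MetricsRow(
        *(float(np.mean(col)) for col in zip(*(dataclasses.astuple(r) for r in rows)))
    )
    pooled_scores = np.concatenate(all_scores)
    pooled_labels = np.concatenate(all_labels)
    roc, auc = roc_auc(pooled_labels, pooled_scores, cfg.positive_label)
    return EvaluationReport(rows=rows, average=avg, roc=roc, auc=auc, artifacts=artifacts)
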