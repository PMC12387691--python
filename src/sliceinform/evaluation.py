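"""Dataset splitting, cross-validation, metrics, and the accuracy grid.

The evaluation protocol mirrors the study design: an 80/10/10
train/validation/test split convention, stratified 5-fold cross-validation
with a per-fold stratified 10% test holdout, six metrics per experiment
(accuracy, precision, sensitivity, specificity, F1, trapezoidal ROC AUC),
attention-weight interpretation per feature level, and a 3-orientation ×
9-segment accuracy grid per binary task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import (StratifiedKFold, StratifiedShuffleSplit,
                                     train_test_split)

from .classifier import (AttentionFusionNet, AttentionWeights, ModelConfig,
                         build_model, train)
from .slice_selection import SelectionResult

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "SplitCounts",
    "SplitAssignment",
    "TrainHyper",
    "CellResult",
    "ExperimentGrid",
    "split_dataset",
    "stratified_cv",
    "confusion",
    "compute_metrics",
    "mean_attention",
    "attention_report",
    "stack_cell_inputs",
    "accuracy_grid",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The six evaluation metrics on [0, 1]; undefined ratios are NaN."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        d = {k: getattr(self, k) for k in
             ("accuracy", "precision", "sensitivity", "specificity",
              "f1", "auc")}
        if percent:
            d = {k: v * 100.0 for k, v in d.items()}
        return d


@dataclass(frozen=True)
class SplitCounts:
    train: int
    val: int
    test: int

    @property
    def total(self) -> int:
        return self.train + self.val + self.test


@dataclass(frozen=True)
class SplitAssignment:
    counts: SplitCounts
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


def split_counts(n: int, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                 ) -> SplitCounts:
    """Rounding convention: train = floor, test = ceil, val = remainder."""
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_train = int(np.floor(f_train * n))
    n_test = min(int(np.ceil(f_test * n)), n - n_train)
    n_val = n - n_train - n_test
    return SplitCounts(train=n_train, val=n_val, test=n_test)


def split_dataset(n: int,
                  fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0,
                  labels: np.ndarray | None = None) -> SplitAssignment:
    """Seeded three-way split; stratified when ``labels`` are supplied.

    With the default fractions, ``n = 1125`` yields 900/112/113 items in
    train/validation/test.
    """
    if n < 3:
        raise ValueError("need n >= 3 to populate all three parts")
    counts = split_counts(n, fractions)
    idx = np.arange(n)
    strat = None if labels is None else np.asarray(labels)
    rest, test = train_test_split(idx, test_size=counts.test,
                                  random_state=seed, stratify=strat)
    strat_rest = None if strat is None else strat[rest]
    if counts.val > 0:
        tr, val = train_test_split(rest, test_size=counts.val,
                                   random_state=seed + 1,
                                   stratify=strat_rest)
    else:
        tr, val = rest, np.array([], dtype=int)
    return SplitAssignment(counts, np.sort(tr), np.sort(val), np.sort(test))


def stratified_cv(labels: np.ndarray, k: int = 5, test_fraction: float = 0.1,
                  seed: int = 0, mode: str = "holdout",
                  ) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """K folds of ``(train_idx, val_idx, test_idx)``, stratified and seeded.

    ``mode="holdout"`` (default): each fold draws its own stratified
    ``test_fraction`` holdout, then a stratified k-fold on the remainder
    supplies that fold's validation part, with the rest as training.
    ``mode="plain"``: ordinary stratified k-fold where the k-th part is
    used as the test part and no validation part is drawn.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(
            f"every class needs >= k={k} members, got {counts.min()}")
    n = len(labels)
    idx = np.arange(n)
    folds = []
    if mode == "plain":
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for tr, te in skf.split(idx, labels):
            folds.append((np.sort(tr), np.array([], dtype=int), np.sort(te)))
        return folds
    if mode != "holdout":
        raise ValueError(f"unknown cv mode {mode!r}")
    n_test = max(int(np.ceil(test_fraction * n)), 2)
    for f in range(k):
        sss = StratifiedShuffleSplit(n_splits=1, test_size=n_test,
                                     random_state=seed * k + f)
        rest, test = next(sss.split(idx, labels))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        inner = list(skf.split(rest, labels[rest]))
        tr_rel, val_rel = inner[f]
        folds.append((np.sort(idx[rest][tr_rel]), np.sort(idx[rest][val_rel]),
                      np.sort(idx[test])))
    return folds


def confusion(y_pred: np.ndarray, y_true: np.ndarray,
              positive_class=1) -> ConfusionCounts:
    """Confusion counts with an explicit positive class (e.g. the diseased
    group of the task at hand)."""
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    if y_pred.shape != y_true.shape:
        raise ValueError(
            f"length mismatch: {y_pred.shape} vs {y_true.shape}")
    pos = (np.asarray(y_true) == positive_class)
    pred_pos = (np.asarray(y_pred) == positive_class)
    cm = confusion_matrix(pos, pred_pos, labels=[False, True])
    tn, fp, fn, tp = cm.ravel()
    return ConfusionCounts(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def trapezoidal_auc(y_true: np.ndarray, scores: np.ndarray,
                    positive_class=1) -> float:
    """Area under the ROC curve by the trapezoidal rule."""
    pos = np.asarray(y_true) == positive_class
    if pos.all() or (~pos).all():
        warnings.warn("AUC undefined with a single class; reporting NaN",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    fpr, tpr, _ = roc_curve(pos, scores)
    return float(np.trapezoid(tpr, fpr))


def compute_metrics(c: ConfusionCounts, y_true: np.ndarray | None = None,
                    scores: np.ndarray | None = None,
                    positive_class=1) -> MetricsReport:
    """The six metrics from confusion counts plus continuous scores.

    accuracy = (TP+TN)/all, precision = TP/(TP+FP), sensitivity =
    TP/(TP+FN), specificity = TN/(TN+FP), F1 = harmonic mean of precision
    and sensitivity, AUC = trapezoidal area under the ROC. Ratios with a
    zero denominator are flagged with a warning and reported as NaN,
    never silently as 0.
    """
    if c.total == 0:
        raise ValueError("no evaluated items")
    acc = (c.tp + c.tn) / c.total
    prec = _ratio(c.tp, c.tp + c.fp, "precision")
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = _ratio(c.tn, c.tn + c.fp, "specificity")
    if np.isnan(prec) or np.isnan(sens) or (prec + sens) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    if scores is not None and y_true is not None:
        auc = trapezoidal_auc(y_true, scores, positive_class)
    else:
        auc = float("nan")
    return MetricsReport(accuracy=acc, precision=prec, sensitivity=sens,
                         specificity=spec, f1=f1, auc=auc)


def mean_attention(weights: np.ndarray) -> AttentionWeights:
    """Arithmetic mean of per-item attention triples (stays on the simplex)."""
    w = np.asarray(weights, dtype=float)
    if w.ndim == 1:
        w = w[None, :]
    if w.size == 0:
        raise ValueError("no attention weights to average")
    m = w.mean(axis=0)
    return AttentionWeights(low=float(m[0]), mid=float(m[1]),
                            high=float(m[2]))


def attention_report(per_item_weights: dict[tuple, np.ndarray]) -> pd.DataFrame:
    """Mean attention per key (e.g. (task, orientation, segment)).

    Returns one row per key with the averaged low/mid/high weights; the
    triples sum to one because averaging preserves the simplex.
    """
    if not per_item_weights:
        raise ValueError("empty evaluation set")
    rows = []
    for key, w in per_item_weights.items():
        mw = mean_attention(w)
        key = key if isinstance(key, tuple) else (key,)
        rows.append({**{f"key{i}": k for i, k in enumerate(key)},
                     "w_low": mw.low, "w_mid": mw.mid, "w_high": mw.high})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the orientation × segment accuracy grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainHyper:
    """Optimization hyperparameters (study defaults)."""

    lr: float = 1e-3
    epochs: int = 20
    batch_size: int = 32
    cv_folds: int = 5
    test_fraction: float = 0.1
    cv_mode: str = "holdout"
    dtype: str = "float64"


@dataclass
class CellResult:
    metrics: MetricsReport            # fold-averaged
    attention: AttentionWeights       # mean over test items and folds
    fold_metrics: list[MetricsReport] = field(default_factory=list)


@dataclass
class ExperimentGrid:
    """Per-(orientation, segment) results for one binary task."""

    task: str
    cells: dict[tuple[str, int], CellResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (orientation, seg), cell in sorted(self.cells.items()):
            rows.append({"task": self.task, "orientation": orientation,
                         "segment": seg,
                         **cell.metrics.as_dict(),
                         "w_low": cell.attention.low,
                         "w_mid": cell.attention.mid,
                         "w_high": cell.attention.high})
        return pd.DataFrame(rows)

    def orientation_averages(self) -> pd.DataFrame:
        """Mean of each orientation's nine segment rows ('Average of all
        slices')."""
        df = self.to_frame()
        metric_cols = [c for c in df.columns
                       if c not in ("task", "orientation", "segment")]
        return (df.groupby("orientation", sort=True)[metric_cols]
                .mean().reset_index())

    def argmax_accuracy(self) -> tuple[str, int]:
        """The (orientation, segment) cell with the highest mean accuracy.

        Ties resolve to the first cell in sorted (orientation, segment)
        order, deterministically.
        """
        best, best_acc = None, -np.inf
        for key in sorted(self.cells):
            acc = self.cells[key].metrics.accuracy
            if np.isfinite(acc) and acc > best_acc:
                best, best_acc = key, acc
        if best is None:
            raise ValueError("no finite accuracy in the grid")
        return best


def stack_cell_inputs(selections: list[dict[tuple[str, int], SelectionResult]],
                      input_size: tuple[int, int, int],
                      ) -> dict[tuple[str, int], np.ndarray]:
    """Resize each subject's winning slice per cell into a model batch.

    ``selections`` holds one ``select_all`` result per subject (in cohort
    order); output maps each (orientation, segment) to an array of shape
    ``(n_subjects, H, W, C)``.
    """
    h, w, c = input_size
    out: dict[tuple[str, int], np.ndarray] = {}
    for key in selections[0]:
        batch = []
        for sel in selections:
            img = sel[key].winner.pixels
            if img.shape != (h, w):
                img = resize(img, (h, w), order=1, mode="reflect",
                             anti_aliasing=False, preserve_range=True)
            batch.append(np.repeat(img[:, :, None], c, axis=2))
        out[key] = np.stack(batch)
    return out


def _cell_seed(seed: int, cell_idx: int, fold: int) -> int:
    ss = np.random.SeedSequence([seed, cell_idx, fold])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def accuracy_grid(cell_inputs: dict[tuple[str, int], np.ndarray],
                  labels: np.ndarray,
                  model_cfg: ModelConfig,
                  hyper: TrainHyper = TrainHyper(),
                  seed: int = 0,
                  task: str = "positive_vs_negative",
                  positive_class=1) -> ExperimentGrid:
    """Train and evaluate one model per (orientation, segment) cell.

    For each cell: stratified CV folds per the protocol, a freshly
    initialized model trained per fold on that cell's selected slices,
    metrics on the fold's held-out test part, then unweighted averaging
    across folds (NaN-aware, so an undefined ratio in one fold does not
    erase the others). Every model and fold seed derives deterministically
    from ``seed`` and the cell's position, so evaluation order cannot
    change any number.
    """
    labels = np.asarray(labels)
    y = (labels == positive_class).astype(int)
    grid = ExperimentGrid(task=task)
    for cell_idx, key in enumerate(sorted(cell_inputs)):
        x = cell_inputs[key]
        folds = stratified_cv(y, k=hyper.cv_folds,
                              test_fraction=hyper.test_fraction,
                              seed=_cell_seed(seed, cell_idx, 10 ** 6),
                              mode=hyper.cv_mode)
        fold_metrics: list[MetricsReport] = []
        fold_weights: list[np.ndarray] = []
        for fold, (tr, _val, te) in enumerate(folds):
            mseed = _cell_seed(seed, cell_idx, fold)
            cfg = ModelConfig(**{**model_cfg.__dict__, "seed": mseed})
            model = build_model(cfg, dtype=hyper.dtype)
            train(model, x[tr], y[tr], lr=hyper.lr, epochs=hyper.epochs,
                  batch_size=hyper.batch_size, seed=mseed + 1)
            probs, wts = model.forward(x[te])
            preds = (probs >= 0.5).astype(int)
            c = confusion(preds, y[te], positive_class=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fold_metrics.append(compute_metrics(c, y_true=y[te],
                                                    scores=probs,
                                                    positive_class=1))
            fold_weights.append(wts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_report = MetricsReport(**{
                k: float(np.nanmean([getattr(fm, k) for fm in fold_metrics]))
                for k in ("accuracy", "precision", "sensitivity",
                          "specificity", "f1", "auc")})
        grid.cells[key] = CellResult(
            metrics=mean_report,
            attention=mean_attention(np.vstack(fold_weights)),
            fold_metrics=fold_metrics)
    return grid
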