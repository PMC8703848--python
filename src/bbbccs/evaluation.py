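"""Accuracy evaluation, Z-score normalization and random-forest
descriptor importance.

The importance metric is mean decrease accuracy realised as out-of-bag
permutation importance: for every tree, the accuracy on its out-of-bag
samples is compared with the accuracy after permuting one descriptor
column, and the drops are averaged over trees.  Stepwise reduction refits
after discarding the lowest-ranked descriptors (8 -> 6 -> 4 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .bbb_classifier import CombinedRule, ThresholdRule, classify_dataset
from .compound_model import BBBLabel, CompoundDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationReport",
    "ImportanceReport",
    "ValidationConfig",
    "confusion_and_accuracy",
    "zscore_normalize",
    "rf_importance",
    "stepwise_reduction",
    "split_and_validate",
]


class DegenerateInputError(ValueError):
    pass


class UndefinedMetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ClassificationReport:
    """2x2 confusion counts plus the derived accuracy and class errors.

    Rows are true classes, columns predictions; ``tp`` counts true-BBB+
    records predicted BBB+.  Class error is the misclassified fraction
    within each true class.  Unclassifiable records are excluded from the
    confusion matrix but counted in ``n_unclassifiable``.
    """

    tp: int
    fn: int
    fp: int
    tn: int
    n_unclassifiable: int = 0

    @property
    def n_classified(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_classified

    @property
    def class_error_plus(self) -> float:
        n_plus = self.tp + self.fn
        return self.fn / n_plus if n_plus else float("nan")

    @property
    def class_error_minus(self) -> float:
        n_minus = self.tn + self.fp
        return self.fp / n_minus if n_minus else float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "n_classified": self.n_classified,
            "n_unclassifiable": self.n_unclassifiable,
            "accuracy": self.accuracy,
            "class_error_plus": self.class_error_plus,
            "class_error_minus": self.class_error_minus,
        }


@dataclass(frozen=True)
class ImportanceReport:
    """Permutation importances (mean decrease accuracy) for one RF fit."""

    descriptor_names: tuple[str, ...]
    importance_scores: tuple[float, ...]
    n_trees: int
    seed: int

    @property
    def ranking(self) -> tuple[str, ...]:
        order = np.argsort(-np.asarray(self.importance_scores), kind="stable")
        return tuple(self.descriptor_names[i] for i in order)

    @property
    def descriptor_subset_size(self) -> int:
        return len(self.descriptor_names)


@dataclass(frozen=True)
class ValidationConfig:
    """Split / cross-validation / random-forest settings.

    Defaults follow common practice for this analysis: a 0.3 test
    fraction with split seed 42, 100-fold cross validation, 1000 trees
    and RF seed 123456.
    """

    test_fraction: float = 0.3
    split_seed: int = 42
    n_folds: int = 100
    rf_trees: int = 1000
    rf_seed: int = 123456

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be >= 1")


def confusion_and_accuracy(predictions, labels, *, n_unclassifiable: int | None = None):
    """Build a :class:`ClassificationReport` from aligned prediction/label
    sequences.

    Predictions may contain ``None`` (unclassifiable); records whose true
    label is unknown are ignored.
    """
    if len(predictions) != len(labels):
        raise ValueError(f"{len(predictions)} predictions vs {len(labels)} labels")
    tp = fn = fp = tn = 0
    n_uncls = 0
    for pred, true in zip(predictions, labels):
        if true not in (BBBLabel.BBB_plus, BBBLabel.BBB_minus):
            continue
        if pred is None or pred is BBBLabel.unknown:
            n_uncls += 1
            continue
        if true is BBBLabel.BBB_plus:
            if pred is BBBLabel.BBB_plus:
                tp += 1
            else:
                fn += 1
        else:
            if pred is BBBLabel.BBB_minus:
                tn += 1
            else:
                fp += 1
    if tp + fn + fp + tn == 0:
        raise UndefinedMetricsError("no classified records with known labels")
    if n_unclassifiable is not None:
        n_uncls = n_unclassifiable
    return ClassificationReport(tp=tp, fn=fn, fp=fp, tn=tn, n_unclassifiable=n_uncls)


def zscore_normalize(values) -> np.ndarray:
    """Standardize a vector to mean 0 and population SD 1.

    The Z score is the difference between a raw value and the population
    mean, divided by the population standard deviation.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DegenerateInputError("need a 1-D vector with >= 2 values")
    sd = x.std()  # population SD (ddof=0)
    if sd == 0:
        raise DegenerateInputError("constant vector has no Z scores")
    return (x - x.mean()) / sd


def _design_matrix(ds: CompoundDataset, descriptor_subset):
    """Dense matrix + 0/1 labels; records with any gap or unknown label
    are dropped (and logged)."""
    rows, y, kept_ids = [], [], []
    dropped = 0
    for record in ds:
        if record.bbb_label not in (BBBLabel.BBB_plus, BBBLabel.BBB_minus):
            dropped += 1
            continue
        values = [record.descriptor(name) for name in descriptor_subset]
        if any(v is None for v in values):
            dropped += 1
            continue
        rows.append(values)
        y.append(1 if record.bbb_label is BBBLabel.BBB_plus else 0)
        kept_ids.append(record.id)
    if dropped:
        logger.info("design matrix: dropped %d records with gaps/unknown labels", dropped)
    return np.asarray(rows, dtype=float), np.asarray(y, dtype=int), kept_ids


def rf_importance(
    ds: CompoundDataset,
    descriptor_subset,
    cfg: ValidationConfig = ValidationConfig(),
) -> tuple[ImportanceReport, ClassificationReport]:
    """Fit a random forest and compute OOB permutation importances.

    Returns the importance report and the out-of-bag classification
    report (OOB error = 1 - accuracy of the report).
    """
    descriptor_subset = tuple(descriptor_subset)
    X, y, _ = _design_matrix(ds, descriptor_subset)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("dataset contains a single class")

    rf = RandomForestClassifier(
        n_estimators=cfg.rf_trees,
        oob_score=True,
        random_state=cfg.rf_seed,
        n_jobs=1,
    )
    rf.fit(X, y)

    # OOB confusion from the aggregated out-of-bag votes
    oob_votes = rf.oob_decision_function_
    voted = ~np.isnan(oob_votes[:, 0])
    oob_pred = (oob_votes[voted, 1] > 0.5).astype(int)
    y_oob = y[voted]
    report = ClassificationReport(
        tp=int(np.sum((y_oob == 1) & (oob_pred == 1))),
        fn=int(np.sum((y_oob == 1) & (oob_pred == 0))),
        fp=int(np.sum((y_oob == 0) & (oob_pred == 1))),
        tn=int(np.sum((y_oob == 0) & (oob_pred == 0))),
        n_unclassifiable=int(np.sum(~voted)),
    )

    rng = np.random.default_rng(cfg.rf_seed)
    n = X.shape[0]
    drops = np.zeros(len(descriptor_subset))
    n_trees_used = 0
    for tree, sample_idx in zip(rf.estimators_, rf.estimators_samples_):
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[sample_idx] = False
        if not oob_mask.any():
            continue
        X_oob, y_tree = X[oob_mask], y[oob_mask]
        base_acc = np.mean(tree.predict(X_oob) == y_tree)
        for j in range(len(descriptor_subset)):
            X_perm = X_oob.copy()
            X_perm[:, j] = rng.permutation(X_perm[:, j])
            drops[j] += base_acc - np.mean(tree.predict(X_perm) == y_tree)
        n_trees_used += 1
    importances = drops / max(n_trees_used, 1)

    return (
        ImportanceReport(
            descriptor_names=descriptor_subset,
            importance_scores=tuple(float(v) for v in importances),
            n_trees=cfg.rf_trees,
            seed=cfg.rf_seed,
        ),
        report,
    )


def stepwise_reduction(
    ds: CompoundDataset,
    full_subset,
    cfg: ValidationConfig = ValidationConfig(),
    sizes: tuple[int, ...] = (8, 6, 4),
) -> list[tuple[ImportanceReport, ClassificationReport]]:
    """Refit the forest on shrinking descriptor subsets.

    At each step the lowest-ranked descriptors are dropped to reach the
    next size in ``sizes`` (default ladder 8 -> 6 -> 4).
    """
    full_subset = tuple(full_subset)
    if len(full_subset) != sizes[0]:
        raise ValueError(f"expected {sizes[0]} descriptors, got {len(full_subset)}")
    if any(b >= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError(f"sizes must strictly decrease, got {sizes}")

    reports = []
    subset = full_subset
    for i, _size in enumerate(sizes):
        imp, cls = rf_importance(ds, subset, cfg)
        reports.append((imp, cls))
        if i + 1 < len(sizes):
            subset = imp.ranking[: sizes[i + 1]]  # drop lowest-ranked
    return reports


def split_and_validate(
    ds: CompoundDataset,
    rule_or_model,
    cfg: ValidationConfig = ValidationConfig(),
):
    """Hold-out evaluation plus k-fold cross validation.

    ``rule_or_model`` is either a threshold/combined rule (no fitting) or
    an sklearn-style estimator with ``fit``/``predict`` over the default
    descriptor matrix.  The split is stratified; when ``n_folds`` equals
    the dataset size a plain leave-one-out split is used instead (a
    stratified one is impossible there).

    Returns ``(test_report, fold_accuracies)``.
    """
    is_rule = isinstance(rule_or_model, (ThresholdRule, CombinedRule))
    if is_rule:
        pred_by_id = classify_dataset(ds, rule_or_model).by_id()
        labelled = [
            r for r in ds
            if r.bbb_label in (BBBLabel.BBB_plus, BBBLabel.BBB_minus)
        ]
        ids = [r.id for r in labelled]
        y = np.array(
            [1 if r.bbb_label is BBBLabel.BBB_plus else 0 for r in labelled]
        )

        def accuracy_on(idx) -> float:
            preds = [pred_by_id[ids[i]] for i in idx]
            labels = [labelled[i].bbb_label for i in idx]
            return confusion_and_accuracy(preds, labels).accuracy

        def report_on(idx) -> ClassificationReport:
            preds = [pred_by_id[ids[i]] for i in idx]
            labels = [labelled[i].bbb_label for i in idx]
            return confusion_and_accuracy(preds, labels)
    else:
        from .compound_model import DESCRIPTOR_NAMES

        X, y, ids = _design_matrix(ds, DESCRIPTOR_NAMES)

    n = len(y)
    class_min = int(min(np.sum(y == 0), np.sum(y == 1)))
    if class_min == 0:
        raise DegenerateInputError("dataset contains a single known class")

    indices = np.arange(n)
    train_idx, test_idx = train_test_split(
        indices,
        test_size=cfg.test_fraction,
        random_state=cfg.split_seed,
        stratify=y,
    )

    if cfg.n_folds > n:
        raise ValueError(f"n_folds={cfg.n_folds} exceeds dataset size {n}")
    if cfg.n_folds == n:
        splitter = KFold(n_splits=cfg.n_folds)  # leave-one-out
    elif cfg.n_folds > class_min:
        raise ValueError(
            f"n_folds={cfg.n_folds} exceeds the minority class count {class_min}"
        )
    else:
        splitter = StratifiedKFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=cfg.split_seed
        )

    if is_rule:
        test_report = report_on(test_idx)
        fold_acc = []
        for _, fold_test in splitter.split(indices, y):
            try:
                fold_acc.append(accuracy_on(fold_test))
            except UndefinedMetricsError:
                continue  # fold of all-unclassifiable records
        return test_report, np.asarray(fold_acc)

    # estimator path: fit on train indices, evaluate on test indices
    model = rule_or_model
    model.fit(X[train_idx], y[train_idx])
    pred = model.predict(X[test_idx])
    y_test = y[test_idx]
    test_report = ClassificationReport(
        tp=int(np.sum((y_test == 1) & (pred == 1))),
        fn=int(np.sum((y_test == 1) & (pred == 0))),
        fp=int(np.sum((y_test == 0) & (pred == 1))),
        tn=int(np.sum((y_test == 0) & (pred == 0))),
    )
    fold_acc = []
    for fold_train, fold_test in splitter.split(indices, y):
        model.fit(X[fold_train], y[fold_train])
        fold_acc.append(float(np.mean(model.predict(X[fold_test]) == y[fold_test])))
    return test_report, np.asarray(fold_acc)


def plot_importances(report: ImportanceReport, path) -> None:
    """Horizontal bar chart of descriptor importances (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(report.ranking)
    scores = dict(zip(report.descriptor_names, report.importance_scores))
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(names) + 1))
    ax.barh(names[::-1], [scores[n] for n in names[::-1]])
    ax.set_xlabel("mean decrease accuracy")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
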