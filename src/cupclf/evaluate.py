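"""Cohort splitting, stratified cross-validation, and the reported metrics.

Metrics follow the usual multiclass conventions: accuracy is the fraction of
correct argmax calls; top-2 accuracy counts a sample as correct when the
true class is among the two largest probabilities (ties at the rank-2
boundary resolve by class-order position, so results are deterministic);
F1 is macro-averaged — the unweighted mean over classes of 2PR/(P+R), with
a class contributing 0 when it has neither predictions nor truths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score as _sk_f1

from .features import FeatureSelectionConfig, restrict_to_mqtl, select_top_variable
from .io import (
    BetaMatrix,
    CLASSES,
    MQTLCatalog,
    PredictionReport,
    SampleSheet,
    ValidationError,
)
from .network import NetworkConfig, TrainingHistory, build_network, predict_probabilities, train_network
from .preprocess import impute_probe_means


@dataclass
class SplitSpec:
    """Train/validation/test fractions with an explicit rounding convention:
    train = floor(f_train*n), test = ceil(f_test*n), validation = remainder."""

    train: float = 0.70
    validation: float = 0.15
    test: float = 0.15
    seed: int = 0
    stratify_by_label: bool = True

    def __post_init__(self) -> None:
        total = self.train + self.validation + self.test
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"split fractions sum to {total}, expected 1")

    def sizes(self, n: int) -> tuple[int, int, int]:
        n_train = int(np.floor(self.train * n))
        n_test = int(np.ceil(self.test * n))
        return n_train, n - n_train - n_test, n_test


def _largest_remainder_allocation(
    class_counts: dict[str, int], set_sizes: Sequence[int]
) -> dict[str, list[int]]:
    """Round per-class x per-set quotas to integers matching both margins.

    Floors of the proportional quotas first; the leftover units are then
    handed out by largest fractional remainder, respecting class totals and
    set totals, which keeps every class within ~1 sample of proportionality.
    """
    classes = list(class_counts)
    n = sum(class_counts.values())
    quota = {
        c: [class_counts[c] * t / n for t in set_sizes] for c in classes
    }
    alloc = {c: [int(np.floor(q)) for q in quota[c]] for c in classes}
    set_deficit = [t - sum(alloc[c][s] for c in classes) for s, t in enumerate(set_sizes)]
    class_left = {c: class_counts[c] - sum(alloc[c]) for c in classes}
    cells = sorted(
        ((c, s) for c in classes for s in range(len(set_sizes))),
        key=lambda cs: (-(quota[cs[0]][cs[1]] - np.floor(quota[cs[0]][cs[1]])), cs[0], cs[1]),
    )
    for c, s in cells:
        if class_left[c] > 0 and set_deficit[s] > 0:
            alloc[c][s] += 1
            class_left[c] -= 1
            set_deficit[s] -= 1
    # mop up any remaining units (rare, degenerate remainders)
    for c in classes:
        while class_left[c] > 0:
            s = int(np.argmax(set_deficit))
            alloc[c][s] += 1
            class_left[c] -= 1
            set_deficit[s] -= 1
    return alloc


def split_cohort(
    sheet: SampleSheet, spec: SplitSpec
) -> tuple[list[str], list[str], list[str]]:
    """Split sample ids into disjoint train/validation/test sets.

    Global sizes follow the floor/ceil/remainder convention exactly; with
    stratification, class proportions are preserved to within one sample per
    class per set. The shuffle is seeded.
    """
    n = sheet.n_samples
    if n < 3:
        raise ValidationError("need at least 3 samples to split")
    sizes = spec.sizes(n)
    rng = np.random.default_rng(spec.seed)
    if not spec.stratify_by_label or sheet.labels is None:
        perm = rng.permutation(n)
        ids = [sheet.sample_ids[i] for i in perm]
        a, b = sizes[0], sizes[0] + sizes[1]
        return ids[:a], ids[a:b], ids[b:]

    by_class: dict[str, list[str]] = {}
    for sid, lab in zip(sheet.sample_ids, sheet.labels):
        by_class.setdefault(lab, []).append(sid)
    counts = {c: len(v) for c, v in by_class.items()}
    alloc = _largest_remainder_allocation(counts, sizes)
    sets: tuple[list[str], list[str], list[str]] = ([], [], [])
    for c in sorted(by_class):
        members = list(by_class[c])
        rng.shuffle(members)
        start = 0
        for s in range(3):
            take = alloc[c][s]
            sets[s].extend(members[start : start + take])
            start += take
    return sets


def make_stratified_folds(labels: Sequence[str], k: int, seed: int = 0) -> np.ndarray:
    """Assign each sample to one of k folds, stratified by label.

    Returns an integer fold index per sample. Per class, members are dealt
    round-robin over the folds ordered by current occupancy, so per-fold
    class counts differ by at most one and overall fold sizes stay balanced.
    A class with fewer than k samples triggers a warning and its samples
    land in distinct folds (degenerate stratification).
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    labels = list(labels)
    if k > len(labels):
        raise ValidationError(f"k={k} exceeds the number of samples")
    counts = pd.Series(labels).value_counts()
    if (counts < k).any():
        small = sorted(counts[counts < k].index)
        warnings.warn(
            f"classes with fewer than {k} samples: {small}; their samples are "
            f"spread across distinct folds", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    totals = np.zeros(k, dtype=int)
    assignment = np.empty(len(labels), dtype=int)
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    for lab in sorted(by_class):
        members = np.array(by_class[lab])
        rng.shuffle(members)
        fold_order = np.argsort(totals, kind="stable")
        for pos, sample in enumerate(members):
            fold = int(fold_order[pos % k])
            assignment[sample] = fold
            totals[fold] += 1
    return assignment


def compute_metrics(
    probs: PredictionReport | np.ndarray,
    truth: Sequence[str],
    class_order: Sequence[str] = CLASSES,
) -> dict:
    """Accuracy, top-2 accuracy, macro-F1 and the confusion matrix.

    Confusion rows are true classes, columns predicted, in ``class_order``.
    """
    if isinstance(probs, PredictionReport):
        class_order = probs.class_order
        p = probs.probabilities
    else:
        p = np.asarray(probs, dtype=np.float64)
    class_order = list(class_order)
    truth = list(truth)
    if len(truth) != p.shape[0]:
        raise ValidationError("truth length does not match predictions")
    bad = sorted(set(truth) - set(class_order))
    if bad:
        raise ValidationError(f"truth labels outside class_order: {bad}")
    idx_of = {c: i for i, c in enumerate(class_order)}
    y_true = np.array([idx_of[t] for t in truth])
    y_pred = p.argmax(axis=1)

    order = np.argsort(-p, axis=1, kind="stable")  # ties -> class_order position
    top2 = (order[:, :2] == y_true[:, None]).any(axis=1)

    labels = np.arange(len(class_order))
    confusion = _sk_confusion(y_true, y_pred, labels=labels)
    macro_f1 = float(
        _sk_f1(y_true, y_pred, labels=labels, average="macro", zero_division=0)
    )
    return {
        "accuracy": float((y_pred == y_true).mean()),
        "top2_accuracy": float(top2.mean()),
        "macro_f1": macro_f1,
        "confusion": confusion,
    }


@dataclass
class CVReport:
    """Everything a k-fold run produces: per-fold metrics and their means."""

    class_order: list[str]
    fold_assignment: dict[str, int]
    fold_metrics: list[dict]
    histories: list[TrainingHistory]
    warnings: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.fold_metrics)

    def _mean(self, key: str) -> float:
        return float(np.mean([m[key] for m in self.fold_metrics]))

    @property
    def mean_accuracy(self) -> float:
        return self._mean("accuracy")

    @property
    def mean_top2_accuracy(self) -> float:
        return self._mean("top2_accuracy")

    @property
    def mean_macro_f1(self) -> float:
        return self._mean("macro_f1")

    @property
    def pooled_confusion(self) -> np.ndarray:
        return np.sum([m["confusion"] for m in self.fold_metrics], axis=0)

    @property
    def best_fold(self) -> int:
        """Fold with the lowest final validation loss."""
        finals = [h.val_loss[-1] for h in self.histories]
        return int(np.argmin(finals))

    def to_dict(self) -> dict:
        return {
            "class_order": self.class_order,
            "k": self.k,
            "mean_accuracy": self.mean_accuracy,
            "mean_top2_accuracy": self.mean_top2_accuracy,
            "mean_macro_f1": self.mean_macro_f1,
            "best_fold": self.best_fold,
            "fold_assignment": self.fold_assignment,
            "folds": [
                {
                    "accuracy": m["accuracy"],
                    "top2_accuracy": m["top2_accuracy"],
                    "macro_f1": m["macro_f1"],
                    "confusion": np.asarray(m["confusion"]).tolist(),
                    "final_train_loss": h.train_loss[-1],
                    "final_val_loss": h.val_loss[-1],
                }
                for m, h in zip(self.fold_metrics, self.histories)
            ],
            "warnings": self.warnings,
        }


def cross_validate(
    bm: BetaMatrix,
    sheet: SampleSheet,
    catalog: MQTLCatalog,
    fs_cfg: FeatureSelectionConfig | None = None,
    net_cfg: NetworkConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation of the full modelling chain.

    Per fold: mQTL restriction, top-K variance selection (on training
    samples only under the default ``variance_scope``), probe-mean
    imputation frozen from the training fold, network training with the
    held-out fold as the validation series, metrics on the held-out fold.
    """
    fs_cfg = fs_cfg or FeatureSelectionConfig()
    net_cfg = net_cfg or NetworkConfig()
    if sheet.labels is None:
        raise ValidationError("cross-validation requires labelled samples")
    label_of = sheet.label_of()
    sample_ids = list(bm.sample_ids)
    labels = [label_of[s] for s in sample_ids]
    folds = make_stratified_folds(labels, k, seed)

    restricted = restrict_to_mqtl(bm, catalog, fs_cfg.organs)
    class_order = list(CLASSES)
    notes: list[str] = []
    fold_metrics: list[dict] = []
    histories: list[TrainingHistory] = []

    for fold in range(k):
        test_mask = folds == fold
        train_ids = [s for s, t in zip(sample_ids, test_mask) if not t]
        test_ids = [s for s, t in zip(sample_ids, test_mask) if t]
        train_bm = restricted.subset_samples(train_ids)
        test_bm = restricted.subset_samples(test_ids)
        missing_classes = sorted(set(class_order) - {label_of[s] for s in train_ids})
        if missing_classes:
            notes.append(f"fold {fold}: classes absent from training data: {missing_classes}")

        scope_bm = restricted if fs_cfg.variance_scope == "full-cohort" else train_bm
        probes = select_top_variable(scope_bm, fs_cfg.top_k)

        train_sel = train_bm.subset_probes(probes)
        x_train, means = impute_probe_means(train_sel.values)
        x_train = x_train.T  # samples x features
        y_train = [label_of[s] for s in train_ids]

        cfg = NetworkConfig(
            layer_dims=(len(probes), *net_cfg.layer_dims[1:]),
            dropout_rate=net_cfg.dropout_rate,
            batch_size=net_cfg.batch_size,
            epochs=net_cfg.epochs,
            learning_rate=net_cfg.learning_rate,
            seed=net_cfg.seed + fold,
            class_weighting=net_cfg.class_weighting,
            checkpoint_best=net_cfg.checkpoint_best,
        )
        spec = build_network(cfg)

        test_sel = test_bm.subset_probes(probes)
        x_test = np.where(
            np.isnan(test_sel.values), means[:, None], test_sel.values
        ).T
        y_test = [label_of[s] for s in test_ids]

        model, history = train_network(
            spec, x_train, y_train, cfg,
            x_val=x_test, y_val=y_test,
            class_order=class_order,
            selected_probes=probes,
            preprocessing_state={"impute_means": means},
        )
        report = predict_probabilities(model, test_sel, impute_missing_probes=False)
        fold_metrics.append(compute_metrics(report, y_test))
        histories.append(history)

    return CVReport(
        class_order=class_order,
        fold_assignment={s: int(f) for s, f in zip(sample_ids, folds)},
        fold_metrics=fold_metrics,
        histories=histories,
        warnings=notes,
    )


def _round_half_up(x: float) -> int:
    return int(Decimal(x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def cohort_report(sheet: SampleSheet) -> dict:
    """Per-class counts with integer percentages (round half-up), totals,
    and the metastasis fraction."""
    if sheet.n_samples == 0:
        raise ValidationError("empty sample sheet")
    if sheet.labels is None:
        raise ValidationError("cohort report requires labels")
    total = sheet.n_samples
    counts = pd.Series(sheet.labels).value_counts().to_dict()
    classes = {
        c: {"count": int(n), "percent": _round_half_up(100.0 * n / total)}
        for c, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }
    n_met = int(sum(sheet.is_metastasis))
    return {
        "total": total,
        "classes": classes,
        "metastasis_count": n_met,
        "metastasis_percent": _round_half_up(100.0 * n_met / total),
    }
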