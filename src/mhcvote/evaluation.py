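"""Confusion counts, SE/SP/ACC/MCC, cross-validation and hold-out protocols.

Metrics follow the standard confusion-matrix definitions:

    SE  = TP / (TP + FN)                    (sensitivity / recall on positives)
    SP  = TN / (TN + FP)                    (specificity)
    ACC = (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Zero-denominator policy: SE or SP with an empty class is reported as NaN
with a flag; an MCC zero denominator yields 0 with a flag — never a silent
NaN.

Cross-validation pools the per-fold confusion counts into a single primary
report (well-defined for MCC) and also retains the per-fold reports, whose
fold mean and SD are available for inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .descriptors import EncoderConfig, PropertyTables, default_tables, encode_dataset
from .ensemble import BaseLearnerSpec, default_specs, fit_ensemble
from .errors import DataError
from .seqio import LabeledDataset, stratified_kfold


@dataclass(frozen=True)
class ConfusionCounts:
    """TP / FP / TN / FN counts of one binary evaluation."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.FP + other.FP,
            self.TN + other.TN,
            self.FN + other.FN,
        )


def counts_from_pairs(y_true, y_pred) -> ConfusionCounts:
    """Tally confusion counts from aligned label/prediction vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise DataError("y_true and y_pred must be aligned")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


@dataclass
class MetricsReport:
    """Confusion counts plus the four derived metrics for one evaluation."""

    counts: ConfusionCounts
    SE: float
    SP: float
    ACC: float
    MCC: float
    flags: list[str] = field(default_factory=list)
    per_fold: list["MetricsReport"] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "counts": {
                "TP": self.counts.TP,
                "FP": self.counts.FP,
                "TN": self.counts.TN,
                "FN": self.counts.FN,
            },
            "SE": None if math.isnan(self.SE) else self.SE,
            "SP": None if math.isnan(self.SP) else self.SP,
            "ACC": self.ACC,
            "MCC": self.MCC,
            "flags": list(self.flags),
        }
        if self.per_fold:
            d["per_fold"] = [f.to_dict() for f in self.per_fold]
        return d

    def table(self) -> str:
        """Plain-text one-row table, columns ordered ACC, MCC, SE, SP."""
        fmt = lambda x: "  nan " if math.isnan(x) else f"{x:.4f}"
        return (
            "ACC\tMCC\tSE\tSP\n"
            f"{fmt(self.ACC)}\t{fmt(self.MCC)}\t{fmt(self.SE)}\t{fmt(self.SP)}"
        )


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Derive SE, SP, ACC and MCC from confusion counts."""
    if counts.total == 0:
        raise DataError("cannot compute metrics over zero examples")
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    flags: list[str] = []
    if tp + fn > 0:
        se = tp / (tp + fn)
    else:
        se = float("nan")
        flags.append("SE undefined: no positive examples")
    if tn + fp > 0:
        sp = tn / (tn + fp)
    else:
        sp = float("nan")
        flags.append("SP undefined: no negative examples")
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom > 0:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    else:
        mcc = 0.0
        flags.append("MCC denominator zero: reported as 0")
    return MetricsReport(counts=counts, SE=se, SP=sp, ACC=acc, MCC=mcc, flags=flags)


def evaluate_predictions(y_true, y_pred) -> MetricsReport:
    """Convenience wrapper: pairs -> counts -> metrics."""
    return compute_metrics(counts_from_pairs(y_true, y_pred))


def cross_validate(
    ds: LabeledDataset,
    cfg: EncoderConfig | None = None,
    specs: list[BaseLearnerSpec] | None = None,
    n_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    tables: PropertyTables | None = None,
) -> MetricsReport:
    """Stratified k-fold cross-validation of the full pipeline.

    Sequences are encoded once; for each fold the ensemble (and its
    standardizer) is fitted on the out-of-fold rows and evaluated on the
    held-out rows.  The primary report pools the per-fold confusion counts;
    per-fold reports are retained in ``per_fold``.
    """
    cfg = cfg or EncoderConfig()
    tables = tables or default_tables()
    ds.require_two_classes()
    folds = stratified_kfold(ds, n_folds=n_folds, seed=seed)
    X, y, _, feature_labels = encode_dataset(ds, cfg, tables)
    specs = specs if specs is not None else default_specs(seed)
    pooled = ConfusionCounts(0, 0, 0, 0)
    per_fold: list[MetricsReport] = []
    for k in range(n_folds):
        test_idx = folds.indices(k)
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        try:
            model = fit_ensemble(
                X[train_mask],
                y[train_mask],
                specs=specs,
                standardize=standardize,
                encoder_config=cfg,
                feature_labels=feature_labels,
            )
            y_pred = model.predict(X[test_idx])
        except Exception as e:
            raise type(e)(f"fold {k}: {e}") from e
        fold_counts = counts_from_pairs(y[test_idx], y_pred)
        per_fold.append(compute_metrics(fold_counts))
        pooled = pooled + fold_counts
    report = compute_metrics(pooled)
    report.per_fold = per_fold
    return report


def evaluate_holdout(
    train: LabeledDataset,
    test: LabeledDataset,
    cfg: EncoderConfig | None = None,
    specs: list[BaseLearnerSpec] | None = None,
    seed: int = 0,
    standardize: bool = True,
    tables: PropertyTables | None = None,
    allow_overlap: bool = False,
) -> MetricsReport:
    """Train once on ``train`` and evaluate once on ``test``.

    The standardizer is fitted on the training set only.  Overlapping IDs
    between the two sets are an error unless ``allow_overlap`` is set (a
    deliberate leakage override, e.g. resubstitution checks).
    """
    cfg = cfg or EncoderConfig()
    tables = tables or default_tables()
    if len(test) == 0:
        raise DataError("empty test set")
    overlap = set(train.ids) & set(test.ids)
    if overlap and not allow_overlap:
        raise DataError(f"train/test ID overlap: {sorted(overlap)[:10]}")
    train.require_two_classes()
    X_tr, y_tr, _, feature_labels = encode_dataset(train, cfg, tables)
    X_te, y_te, _, _ = encode_dataset(test, cfg, tables)
    specs = specs if specs is not None else default_specs(seed)
    model = fit_ensemble(
        X_tr,
        y_tr,
        specs=specs,
        standardize=standardize,
        encoder_config=cfg,
        feature_labels=feature_labels,
    )
    return evaluate_predictions(y_te, model.predict(X_te))
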