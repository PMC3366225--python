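"""Stratified cross-validation and confusion-matrix diagnostics.

The identification modes are judged by sensitivity TP/(TP+FN), specificity
TN/(TN+FP) and accuracy (TP+TN)/total, displayed as percentages rounded
half-up to one decimal place. Cross-validation is stratified 10-fold by
default; the pooled out-of-fold confusion matrix is the headline result,
with resubstitution (classify the training data with the full-data tree)
available as an alternative reading.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import chaid
from .cohort import Cohort

logger = logging.getLogger(__name__)


class UndefinedMetricError(ZeroDivisionError):
    """A requested rate has a zero denominator."""


def _round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total < 1:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def correct(self) -> int:
        return self.TP + self.TN

    def sensitivity(self) -> float:
        if self.TP + self.FN == 0:
            raise UndefinedMetricError("no positive cases: sensitivity undefined")
        return self.TP / (self.TP + self.FN)

    def specificity(self) -> float:
        if self.TN + self.FP == 0:
            raise UndefinedMetricError("no negative cases: specificity undefined")
        return self.TN / (self.TN + self.FP)

    def accuracy(self) -> float:
        return self.correct / self.total


def metrics(cm: ConfusionMatrix, decimals: int = 1) -> dict[str, float]:
    """Sensitivity/specificity/accuracy as percentages, half-up rounded."""
    return {
        "sensitivity": _round_half_up(100 * cm.sensitivity(), decimals),
        "specificity": _round_half_up(100 * cm.specificity(), decimals),
        "accuracy": _round_half_up(100 * cm.accuracy(), decimals),
    }


@dataclass(frozen=True)
class ValidationConfig:
    n_folds: int = 10
    stratified: bool = True
    random_seed: int = 0
    pooling: str = "pooled-out-of-fold"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.pooling not in ("pooled-out-of-fold", "resubstitution"):
            raise ValueError(f"unknown pooling mode {self.pooling!r}")


def stratified_folds(labels, config: ValidationConfig) -> np.ndarray:
    """Fold index (0..n_folds-1) per case; sizes and per-class counts per
    fold balanced within one, deterministic under the seed."""
    y = np.asarray(labels)
    if config.n_folds > y.size:
        raise ValueError(f"n_folds {config.n_folds} exceeds n {y.size}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for stratification")
    assignment = np.empty(y.size, dtype=int)
    rng = np.random.default_rng(config.random_seed)
    if config.stratified:
        # shuffle within each class, then deal fold slots round-robin;
        # carrying the slot offset across classes keeps total sizes within 1
        offset = 0
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            assignment[idx] = (np.arange(idx.size) + offset) % config.n_folds
            offset += idx.size
    else:
        perm = rng.permutation(y.size)
        for fold, chunk in enumerate(np.array_split(perm, config.n_folds)):
            assignment[chunk] = fold
    return assignment


@dataclass
class CrossValidationReport:
    target: str
    pooled: ConfusionMatrix
    resubstitution: ConfusionMatrix
    fold_assignment: np.ndarray
    fold_trees: list[chaid.ChaidTree]
    final_tree: chaid.ChaidTree
    skipped_folds: list[int] = field(default_factory=list)
    seed: int = 0

    def metrics(self, mode: str = "pooled-out-of-fold") -> dict[str, float]:
        cm = self.pooled if mode == "pooled-out-of-fold" else self.resubstitution
        return metrics(cm)

    def to_json_dict(self) -> dict:
        return {
            "target": self.target,
            "seed": self.seed,
            "n": int(self.fold_assignment.size),
            "n_folds": int(self.fold_assignment.max()) + 1,
            "skipped_folds": self.skipped_folds,
            "pooled": vars(self.pooled)
            | {"metrics": metrics(self.pooled)},
            "resubstitution": vars(self.resubstitution)
            | {"metrics": metrics(self.resubstitution)},
            "tree": {
                "n_nodes": self.final_tree.n_nodes,
                "n_terminal": self.final_tree.n_terminal,
                "depth": self.final_tree.depth,
            },
        }

    def render_text(self) -> str:
        """Plain-text table in the reference layout (TN FP / FN TP plus the
        three percentages)."""
        lines = [f"CHAID identification mode: {self.target}", ""]
        for label, cm in (
            ("pooled out-of-fold", self.pooled),
            ("resubstitution", self.resubstitution),
        ):
            m = metrics(cm)
            lines += [
                f"[{label}]",
                f"  TN={cm.TN:>4}  FP={cm.FP:>4}   "
                f"sensitivity {m['sensitivity']}%",
                f"  FN={cm.FN:>4}  TP={cm.TP:>4}   "
                f"specificity {m['specificity']}%",
                f"  correct {cm.correct}/{cm.total}   "
                f"accuracy {m['accuracy']}%",
                "",
            ]
        return "\n".join(lines)


def confusion_from_calls(actual, predicted) -> ConfusionMatrix:
    a = np.asarray(actual).astype(int)
    p = np.asarray(predicted).astype(int)
    return ConfusionMatrix(
        TP=int(np.sum((a == 1) & (p == 1))),
        FP=int(np.sum((a == 0) & (p == 1))),
        TN=int(np.sum((a == 0) & (p == 0))),
        FN=int(np.sum((a == 1) & (p == 0))),
    )


def cross_validate(
    cohort: Cohort,
    target: str,
    chaid_config: chaid.ChaidConfig | None = None,
    validation_config: ValidationConfig | None = None,
    predictors: list[str] | None = None,
) -> CrossValidationReport:
    """Fit and cross-validate a CHAID identification mode for one syndrome.

    Biomarkers are the predictors and the named syndrome label the binary
    response. Out-of-fold predictions are pooled into a single confusion
    matrix; the tree refit on all data is the reportable mode. Folds whose
    training complement loses a class are skipped with a warning.
    """
    chaid_config = chaid_config or chaid.ChaidConfig()
    validation_config = validation_config or ValidationConfig()
    if target not in cohort.labels.columns:
        raise KeyError(f"target syndrome {target!r} not in cohort labels")
    y = cohort.labels[target].reset_index(drop=True)
    if y.nunique() < 2:
        raise ValueError(f"target {target!r} has a single class")
    x = cohort.biomarkers.reset_index(drop=True)
    if predictors is not None:
        x = x[predictors]

    assignment = stratified_folds(y.to_numpy(), validation_config)
    predicted = pd.Series(index=y.index, dtype=float)
    fold_trees: list[chaid.ChaidTree] = []
    skipped: list[int] = []
    for fold in range(validation_config.n_folds):
        test_mask = assignment == fold
        y_train = y[~test_mask]
        if y_train.nunique() < 2:
            logger.warning("fold %d: training data lost a class; skipped", fold)
            skipped.append(fold)
            continue
        tree = chaid.fit_chaid(x[~test_mask], y_train, chaid_config)
        fold_trees.append(tree)
        calls, _ = chaid.predict(tree, x[test_mask])
        predicted[test_mask] = calls.to_numpy()

    final_tree = chaid.fit_chaid(x, y, chaid_config)
    resub_calls, _ = chaid.predict(final_tree, x)

    scored = predicted.notna()
    pooled = confusion_from_calls(y[scored], predicted[scored])
    resubstitution = confusion_from_calls(y, resub_calls)
    return CrossValidationReport(
        target=target,
        pooled=pooled,
        resubstitution=resubstitution,
        fold_assignment=assignment,
        fold_trees=fold_trees,
        final_tree=final_tree,
        skipped_folds=skipped,
        seed=validation_config.random_seed,
    )


# ------------------------------------------------- published fixtures ----

def load_reference_confusions() -> dict:
    ref = importlib.resources.files("zhengmine.fixtures").joinpath(
        "confusion_matrices.json"
    )
    with importlib.resources.as_file(ref) as path:
        with open(path, encoding="utf-8") as f:
            return json.load(f)


def reproduce_paper_tables(fixtures: dict | None = None) -> dict:
    """Recompute every printed percentage and correct-prediction count from
    the packaged confusion-matrix counts; flag any mismatch.

    Returns {cohort: {syndrome: {counts, computed, printed, mismatches}}}.
    """
    if fixtures is None:
        fixtures = load_reference_confusions()
    report: dict = {}
    for cohort_name, entries in fixtures.items():
        report[cohort_name] = {}
        for syndrome, entry in entries.items():
            if not isinstance(entry, dict) or "TP" not in entry:
                continue
            cm = ConfusionMatrix(
                TP=entry["TP"], FP=entry["FP"], TN=entry["TN"], FN=entry["FN"]
            )
            computed = metrics(cm) | {"correct": cm.correct, "total": cm.total}
            printed = entry.get("printed", {})
            mismatches = [
                key for key, want in printed.items()
                if computed.get(key) != want
            ]
            report[cohort_name][syndrome] = {
                "counts": {k: entry[k] for k in ("TP", "FP", "TN", "FN")},
                "computed": computed,
                "printed": printed,
                "mismatches": mismatches,
            }
    return report
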