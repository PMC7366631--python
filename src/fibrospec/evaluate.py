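"""Figures of merit, the nine-combination benchmark, and score export.

Figures of merit are computed on the external test set only: accuracy
(fraction of all test samples correctly classified), sensitivity
(fraction of true positives recovered) and specificity (fraction of true
negatives recovered), with "case" the positive class by clinical
convention.  The benchmark crosses the three variable-engineering
engines (PCA, SPA, GA) with the three classifiers (LDA, QDA, SVM) and
scores each pairing once on the test set, which no selection or tuning
step ever touches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    discriminant_scores,
    fit_discriminant,
    fit_svm,
    predict_discriminant,
    predict_svm,
    svm_decision_value,
    DiscriminantModel,
    SvmModel,
)
from .dataset import CASE, CONTROL, SpectrumSet
from .features import GAConfig, choose_n_components, ga_select, pca_decompose, spa_select
from .partition import SplitResult

logger = logging.getLogger(__name__)

SELECTORS = ("PCA", "SPA", "GA")
CLASSIFIERS = ("LDA", "QDA", "SVM")

#: Fixed column order of the benchmark report.
REPORT_COLUMNS = ("method", "accuracy", "sensitivity", "specificity", "n_features", "seed")


@dataclass(frozen=True)
class FiguresOfMerit:
    """Confusion counts and the derived percentages (full precision)."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def accuracy(self) -> float:
        n = self.tp + self.tn + self.fp + self.fn
        return 100.0 * (self.tp + self.tn) / n if n else float("nan")

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else float("nan")

    def rounded(self) -> tuple:
        """(accuracy, sensitivity, specificity) rounded to 1 decimal for reporting."""
        return tuple(round(v, 1) for v in (self.accuracy, self.sensitivity, self.specificity))


def figures_of_merit(truth, predicted, positive: str = CASE) -> FiguresOfMerit:
    """Confusion counts and accuracy/sensitivity/specificity percentages.

    If the truth vector lacks one class the corresponding metric is NaN
    and a warning flags it (never silently zero).
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.size == 0:
        raise ValueError("empty truth/prediction vectors")
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction lengths differ")
    if positive not in truth:
        raise ValueError(f"positive label {positive!r} absent from truth")
    is_pos = truth == positive
    pred_pos = predicted == positive
    fom = FiguresOfMerit(
        tp=int(np.sum(is_pos & pred_pos)),
        fn=int(np.sum(is_pos & ~pred_pos)),
        tn=int(np.sum(~is_pos & ~pred_pos)),
        fp=int(np.sum(~is_pos & pred_pos)),
    )
    if fom.tn + fom.fp == 0:
        warnings.warn("no negative samples in truth; specificity undefined", RuntimeWarning)
    return fom


@dataclass
class BenchmarkConfig:
    """Knobs of the nine-combination benchmark."""

    pca_threshold: float = 0.95
    pca_cap: int = 10
    spa_max_vars: int = 20
    ga: GAConfig = field(default_factory=GAConfig)
    svm_kernel: str = "linear"
    svm_c_grid: tuple = (1.0, 10.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        # one stream of reproducibility: the GA inherits the benchmark seed
        self.ga = GAConfig(**{**self.ga.__dict__, "seed": self.seed})


@dataclass
class ReportTable:
    """One row per (selector x classifier) pairing."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(REPORT_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"report missing columns {sorted(missing)}")


def _svm_labels(labels: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(labels) == CASE, 1, -1)


def _fit_and_score_classifier(
    name: str,
    feats: dict,
    labels: dict,
    config: BenchmarkConfig,
):
    """Fit one classifier on train features, tune on validation, score test."""
    if name in ("LDA", "QDA"):
        model = fit_discriminant(feats["train"], labels["train"])
        pred = predict_discriminant(feats["test"], model, rule=name.lower())
        return figures_of_merit(labels["test"], pred), model
    # SVM: case -> +1, control -> -1; box constraint tuned on validation
    ytr = _svm_labels(labels["train"])
    yval = _svm_labels(labels["val"])
    best = None
    for C in config.svm_c_grid:
        m = fit_svm(feats["train"], ytr, kernel=config.svm_kernel, C=C)
        err = float(np.mean(predict_svm(feats["val"], m) != yval))
        if best is None or err < best[0]:
            best = (err, m)
    model = best[1]
    pred_pm = predict_svm(feats["test"], model)
    pred = np.where(pred_pm == 1, CASE, CONTROL)
    return figures_of_merit(labels["test"], pred), model


def run_benchmark(
    spectra: SpectrumSet,
    split: SplitResult,
    config: BenchmarkConfig | None = None,
    return_details: bool = False,
):
    """Run all nine selector x classifier pairings and report figures of merit.

    Each selector is fitted once on the training set (using the validation
    set where its cost requires it) and its variables are reused by all
    three classifiers; the test rows enter only the final scoring.  A
    failing pairing is recorded in its row's ``error`` column and the
    remaining pairings still run.
    """
    config = config or BenchmarkConfig()
    train = spectra.take(split.train_idx)
    val = spectra.take(split.val_idx)
    test = spectra.take(split.test_idx)
    # leakage guard: the three sets must be a true partition of the input
    assert (
        len(
            set(split.train_idx.tolist())
            | set(split.val_idx.tolist())
            | set(split.test_idx.tolist())
        )
        == split.train_idx.size + split.val_idx.size + split.test_idx.size
    ), "split sets overlap"

    labels = {"train": train.label, "val": val.label, "test": test.label}
    rows = []
    details = {}
    for selector in SELECTORS:
        try:
            feats, n_features, sel_result = _run_selector(selector, train, val, test, config)
        except Exception as exc:  # selector failure poisons its three rows
            logger.exception("selector %s failed", selector)
            for clf in CLASSIFIERS:
                rows.append(_error_row(f"{selector}-{clf}", config.seed, exc))
            continue
        details[selector] = sel_result
        for clf in CLASSIFIERS:
            method = f"{selector}-{clf}"
            try:
                fom, model = _fit_and_score_classifier(clf, feats, labels, config)
            except Exception as exc:
                logger.exception("pairing %s failed", method)
                rows.append(_error_row(method, config.seed, exc))
                continue
            details[method] = {"fom": fom, "model": model, "features": feats}
            rows.append(
                {
                    "method": method,
                    "accuracy": fom.accuracy,
                    "sensitivity": fom.sensitivity,
                    "specificity": fom.specificity,
                    "n_features": n_features,
                    "seed": config.seed,
                    "error": "",
                }
            )
    report = ReportTable(frame=pd.DataFrame(rows, columns=[*REPORT_COLUMNS, "error"]))
    return (report, details) if return_details else report


def _error_row(method: str, seed: int, exc: Exception) -> dict:
    return {
        "method": method,
        "accuracy": np.nan,
        "sensitivity": np.nan,
        "specificity": np.nan,
        "n_features": 0,
        "seed": seed,
        "error": f"{type(exc).__name__}: {exc}",
    }


def _run_selector(selector: str, train, val, test, config: BenchmarkConfig):
    """Fit one selector on train(+val) and produce feature matrices for all sets."""
    if selector == "PCA":
        max_k = min(train.n_rows - 1, train.n_points, config.pca_cap)
        pca = pca_decompose(train.absorbance, max_k)
        k = choose_n_components(pca, config.pca_threshold, cap=config.pca_cap)
        feats = {
            "train": pca.scores[:, :k],
            "val": pca.transform(val.absorbance)[:, :k],
            "test": pca.transform(test.absorbance)[:, :k],
        }
        return feats, k, pca
    if selector == "SPA":
        result = spa_select(train, val, max_vars=config.spa_max_vars)
    elif selector == "GA":
        result = ga_select(train, val, config=config.ga)
    else:
        raise ValueError(f"unknown selector {selector!r}")
    cols = result.selected_indices
    feats = {
        "train": train.absorbance[:, cols],
        "val": val.absorbance[:, cols],
        "test": test.absorbance[:, cols],
    }
    return feats, cols.size, result


def export_discriminant_scores(model, spectra: SpectrumSet, split: SplitResult) -> pd.DataFrame:
    """Per-sample scalar discriminant value for plotting.

    For an LDA/QDA model the value is L(case) - L(control): negative
    means the sample falls on the case side.  For an SVM model it is the
    pre-sign kernel sum (positive = case side).  The sign of each exported
    value reproduces the model's own prediction exactly.
    """
    subset = np.full(spectra.n_rows, "", dtype=object)
    for name, idx in (("train", split.train_idx), ("validation", split.val_idx), ("test", split.test_idx)):
        subset[idx] = name
    if isinstance(model, DiscriminantModel):
        scores = discriminant_scores(spectra.absorbance, model, rule="lda")
        i_case = model.class_index(CASE)
        i_ctrl = model.class_index(CONTROL)
        value = scores[:, i_case] - scores[:, i_ctrl]
    elif isinstance(model, SvmModel):
        value = svm_decision_value(spectra.absorbance, model)
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    return pd.DataFrame(
        {
            "sample_id": spectra.sample_id,
            "set": subset,
            "class": spectra.label,
            "score": value,
        }
    )
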