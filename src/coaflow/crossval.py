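"""Stratified k-fold cross-validation of the diagnosis models.

The cohort is split into k non-overlapping folds of (near-)equal size,
stratified exactly on the CoA label (per-fold positive counts differ by at
most one) and approximately on sex and age by a sort-and-deal scheme.  Each
fold in turn is held out, the logistic models (combined, f-only, s-only)
are fit on the remaining folds, and the operating threshold is chosen by
the Youden index on the training set.  The ESC narrowing-rate comparator is
evaluated on the same test folds at its fixed 50% threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnosis import (
    DiagnosticModel,
    InvalidLabelsError,
    classification_metrics,
    esc_classifier,
    fit_logistic_model,
    roc_auc,
    youden_threshold,
)

__all__ = ["FoldAssignment", "FoldReport", "CrossValResult",
           "stratified_partition", "cross_validate"]


@dataclass(frozen=True)
class FoldAssignment:
    fold_index: np.ndarray   # 0..k-1 per patient, aligned with the cohort order
    k: int
    seed: int

    def fold_members(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)


def stratified_partition(
    cohort: pd.DataFrame, k: int = 5, seed: int = 0,
    label_col: str = "coa_label", sex_col: str = "sex", age_col: str = "age_months",
    id_col: str = "patient_id",
) -> FoldAssignment:
    """Label-exact, covariate-approximate stratified fold assignment.

    Within each label class, patients are ordered by (sex, age rank) and
    partitioned into consecutive blocks of k; each complete block is dealt
    across all k folds in a seeded random order, so neighbours in the
    covariate ordering land in different folds (approximate sex/age
    balance) while every fold receives the same per-class count up to one.
    Remainder patients continue a running round-robin offset across the
    classes, which keeps total fold sizes within one of each other
    (exactly equal when n is divisible by k).

    Sort ties are broken on patient id, so the assignment is a function of
    patient identity and the seed — invariant to the row order of the
    cohort table.
    """
    n = len(cohort)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} patients")
    if k < 2:
        raise ValueError("k must be at least 2")
    y = cohort[label_col].to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise InvalidLabelsError("both classes must be present")
    rng = np.random.default_rng(seed)

    if id_col in cohort.columns:
        ids = cohort[id_col].astype(str).to_numpy()
    else:
        ids = cohort.index.astype(str).to_numpy()
    fold = np.full(n, -1, dtype=int)
    offset = 0
    for cls in (1, 0):
        idx = np.flatnonzero(y == cls)
        sex = cohort[sex_col].to_numpy()[idx]
        age = cohort[age_col].to_numpy()[idx]
        order = idx[np.lexsort((ids[idx], age, sex))]
        n_full = (len(order) // k) * k
        for start in range(0, n_full, k):
            perm = rng.permutation(k)
            for j, i in enumerate(order[start:start + k]):
                fold[i] = perm[j]
        for j, i in enumerate(order[n_full:]):
            fold[i] = (offset + j) % k
        offset = (offset + len(order) - n_full) % k
    return FoldAssignment(fold_index=fold, k=k, seed=seed)


# ---------------------------------------------------------------------------

@dataclass
class FoldReport:
    fold: int
    split: str                     # "train" or "test"
    model: str                     # "combined", "f_only", "s_only", "esc"
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    n: int
    degenerate: bool = False


@dataclass
class CrossValResult:
    folds: FoldAssignment
    reports: list[FoldReport]
    models: dict[int, dict[str, DiagnosticModel]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.reports])

    def average(self, split: str, model: str, metric: str) -> float:
        vals = [getattr(r, metric) for r in self.reports
                if r.split == split and r.model == model and not r.degenerate]
        return float(np.mean(vals)) if vals else float("nan")

    def averages(self) -> pd.DataFrame:
        rows = []
        df = self.to_frame()
        for (split, model), grp in df.groupby(["split", "model"]):
            ok = grp[~grp.degenerate]
            rows.append({
                "split": split, "model": model,
                "auc": ok.auc.mean(), "sensitivity": ok.sensitivity.mean(),
                "specificity": ok.specificity.mean(),
                "accuracy": ok.accuracy.mean(),
                "n_folds": len(ok),
            })
        return pd.DataFrame(rows)


def _evaluate(scores, labels, threshold, fold, split, model, degenerate=False):
    if degenerate:
        return FoldReport(fold, split, model, float("nan"), float("nan"),
                          float("nan"), float("nan"), float("nan"),
                          float("nan"), threshold, len(labels), True)
    roc = roc_auc(scores, labels)
    rep = classification_metrics(scores, labels, threshold)
    return FoldReport(fold, split, model, roc.auc, roc.ci_low, roc.ci_high,
                      rep.sensitivity, rep.specificity, rep.accuracy,
                      threshold, len(labels))


def cross_validate(
    features: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    threshold_rule: str = "youden",
    fixed_threshold: float = 0.5,
) -> CrossValResult:
    """k-fold evaluation of the combined, f-only, s-only and ESC models.

    ``features`` needs columns f, s, narrowing_rate, coa_label, sex,
    age_months.  A test fold containing a single class is reported as
    degenerate and excluded from averages (with a warning).
    """
    folds = stratified_partition(features, k=k, seed=seed)
    f = features["f"].to_numpy(float)
    s = features["s"].to_numpy(float)
    nar = features["narrowing_rate"].to_numpy(float)
    y = features["coa_label"].to_numpy(int)

    reports: list[FoldReport] = []
    models: dict[int, dict[str, DiagnosticModel]] = {}
    for fold in range(k):
        test = folds.fold_members(fold)
        train = np.flatnonzero(folds.fold_index != fold)
        assert len(np.intersect1d(train, test)) == 0
        fold_models: dict[str, DiagnosticModel] = {}
        for name, feats in (
            ("combined", np.column_stack([f, s])),
            ("f_only", f[:, None]),
            ("s_only", s[:, None]),
        ):
            model = fit_logistic_model(feats[train], y[train])
            fold_models[name] = model
            if name == "combined":
                scores_tr = model.predict(f[train], s[train])
                scores_te = model.predict(f[test], s[test])
            else:  # single-feature model: slope lives in a, b is zero
                scores_tr = model.predict(feats[train][:, 0], 0.0)
                scores_te = model.predict(feats[test][:, 0], 0.0)
            if threshold_rule == "youden":
                thr = youden_threshold(scores_tr, y[train])
            elif threshold_rule == "fixed":
                thr = fixed_threshold
            else:
                raise ValueError(f"unknown threshold rule {threshold_rule!r}")
            model.decision_threshold = min(max(thr, 1e-9), 1 - 1e-9)
            reports.append(_evaluate(scores_tr, y[train], thr, fold, "train", name))
            degenerate = len(np.unique(y[test])) < 2
            if degenerate:
                warnings.warn(f"fold {fold}: test set has a single class; "
                              "excluded from averages")
            reports.append(_evaluate(scores_te, y[test], thr, fold, "test",
                                     name, degenerate))
        # ESC comparator at its fixed anatomical threshold
        esc_scores = nar
        reports.append(_evaluate(esc_scores[train], y[train],
                                 0.5, fold, "train", "esc"))
        degenerate = len(np.unique(y[test])) < 2
        reports.append(_evaluate(esc_scores[test], y[test], 0.5, fold,
                                 "test", "esc", degenerate))
        models[fold] = fold_models
    return CrossValResult(folds=folds, reports=reports, models=models)
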