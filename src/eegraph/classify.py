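"""Stepwise linear discriminant classification with leave-one-out evaluation.

Feature selection is stepwise in the SPSS tradition: at each step the
candidate that minimises Wilks' lambda enters if its partial F-to-enter
reaches ``f_in``; previously entered features whose F-to-remove falls below
``f_out`` are removed again.  For two groups the partial F of a change from
lambda_p (p features) to lambda_{p+1} is

    F = (lambda_p / lambda_{p+1} - 1) * (n - g - p) / (g - 1).

Performance of the selected model is estimated by leave-one-out
cross-validation: each subject is predicted by an LDA trained on all the
others, and accuracy, sensitivity (correct patients / all patients) and
specificity (correct controls / all controls) summarise the predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "FeatureTable",
    "StepwiseResult",
    "ClassificationReport",
    "stepwise_lda_select",
    "loocv_evaluate",
    "confusion_metrics",
]

F_IN_DEFAULT = 3.84
F_OUT_DEFAULT = 2.71


@dataclass
class FeatureTable:
    """Subjects x features with binary group labels (complete cases only)."""

    features: pd.DataFrame  # index: subject ids
    labels: pd.Series  # aligned to features.index, two classes

    def __post_init__(self) -> None:
        self.labels = self.labels.loc[self.features.index]
        if self.features.isna().any().any():
            bad = self.features.columns[self.features.isna().any()].tolist()
            raise ValueError(f"feature table has missing cells in {bad}")
        if self.labels.nunique() != 2:
            raise ValueError("labels must contain exactly two classes")

    @property
    def classes(self) -> tuple[str, str]:
        return tuple(sorted(self.labels.unique()))


@dataclass
class StepwiseResult:
    selected: list[str]
    wilks_lambda: float
    chi_square: float
    df: int
    p_value: float
    history: list[tuple[str, str, float]] = field(default_factory=list)


@dataclass
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    predictions: pd.Series | None = None
    scores: pd.Series | None = None
    selected: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)


def _wilks_lambda(x: np.ndarray, y: np.ndarray) -> float:
    """det(W)/det(T) for the given feature block; inf if T is singular."""
    n, p = x.shape
    xc = x - x.mean(axis=0)
    total = xc.T @ xc
    within = np.zeros((p, p))
    for cls in np.unique(y):
        xg = x[y == cls]
        xg = xg - xg.mean(axis=0)
        within += xg.T @ xg
    sign_t, logdet_t = np.linalg.slogdet(total)
    sign_w, logdet_w = np.linalg.slogdet(within)
    if sign_t <= 0 or sign_w <= 0:
        return float("inf")
    lam = np.exp(logdet_w - logdet_t)
    return float(min(lam, 1.0))


def stepwise_lda_select(
    table: FeatureTable,
    f_in: float = F_IN_DEFAULT,
    f_out: float = F_OUT_DEFAULT,
    max_steps: int = 100,
) -> StepwiseResult:
    """Forward selection with backward removal, minimising Wilks' lambda.

    Features whose inclusion makes the total scatter matrix numerically
    singular (e.g. exact collinearity) are skipped with a warning.  The
    final lambda is converted to a chi-square via Bartlett's approximation
    with df equal to the number of selected features (two groups).
    """
    x_all = table.features.to_numpy(dtype=float)
    y = table.labels.to_numpy()
    names = list(table.features.columns)
    n, g = len(y), 2
    selected: list[int] = []
    lam_current = 1.0
    history: list[tuple[str, str, float]] = []

    for _ in range(max_steps):
        changed = False
        # entry step
        best_j, best_lam = None, lam_current
        p = len(selected)
        for j in range(len(names)):
            if j in selected:
                continue
            lam_new = _wilks_lambda(x_all[:, selected + [j]], y)
            if not np.isfinite(lam_new):
                continue
            if lam_new >= lam_current - 1e-12:
                continue
            f_enter = (lam_current / lam_new - 1.0) * (n - g - p) / (g - 1)
            if f_enter >= f_in and lam_new < best_lam:
                best_j, best_lam = j, lam_new
        if best_j is not None:
            selected.append(best_j)
            lam_current = best_lam
            history.append((names[best_j], "enter", lam_current))
            changed = True
        # removal step
        if len(selected) > 1:
            p = len(selected)
            worst_j, worst_f = None, np.inf
            for j in selected:
                rest = [k for k in selected if k != j]
                lam_without = _wilks_lambda(x_all[:, rest], y)
                f_remove = (
                    (lam_without / lam_current - 1.0) * (n - g - (p - 1)) / (g - 1)
                )
                if f_remove < worst_f:
                    worst_j, worst_f = j, f_remove
            if worst_j is not None and worst_f < f_out:
                selected.remove(worst_j)
                lam_current = _wilks_lambda(x_all[:, selected], y)
                history.append((names[worst_j], "remove", lam_current))
                changed = True
        if not changed:
            break

    p = len(selected)
    if p:
        chi2 = -(n - 1 - (p + g) / 2.0) * np.log(max(lam_current, 1e-300))
        p_value = float(spstats.chi2.sf(chi2, df=p))
    else:
        chi2, p_value, lam_current = 0.0, 1.0, 1.0
    skipped = [
        names[j]
        for j in range(len(names))
        if j not in selected
        and not np.isfinite(_wilks_lambda(x_all[:, selected + [j]], y))
    ]
    if skipped:
        warnings.warn(
            f"features skipped due to singular scatter matrices: {skipped}",
            stacklevel=2,
        )
    return StepwiseResult(
        selected=[names[j] for j in selected],
        wilks_lambda=float(lam_current),
        chi_square=float(chi2),
        df=p,
        p_value=p_value,
        history=history,
    )


def _metrics_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, positive: str
) -> dict[str, float | int]:
    pos = y_true == positive
    tp = int(((y_pred == positive) & pos).sum())
    fn = int(((y_pred != positive) & pos).sum())
    tn = int(((y_pred != positive) & ~pos).sum())
    fp = int(((y_pred == positive) & ~pos).sum())
    total = tp + fn + tn + fp
    return dict(
        tp=tp, fn=fn, tn=tn, fp=fp,
        accuracy=(tp + tn) / total if total else float("nan"),
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
    )


def loocv_evaluate(
    table: FeatureTable,
    selection: Sequence[str] | StepwiseResult,
    positive: str = "patient",
    priors: str = "proportional",
    nested: bool = False,
    f_in: float = F_IN_DEFAULT,
    f_out: float = F_OUT_DEFAULT,
) -> ClassificationReport:
    """Leave-one-out evaluation of an LDA on the selected features.

    By default the selection is fixed (chosen once on the full table, the
    classical reporting convention); ``nested=True`` redoes the stepwise
    selection inside every training fold, the unbiased variant.
    ``priors`` is ``"proportional"`` (class frequencies) or ``"equal"``.
    """
    if isinstance(selection, StepwiseResult):
        selection = selection.selected
    selection = list(selection)
    if not selection and not nested:
        raise ValueError("selection is empty")
    y = table.labels.to_numpy()
    ids = table.features.index
    classes = np.unique(y)
    prior_vec = [0.5, 0.5] if priors == "equal" else None

    preds = []
    for i in range(len(ids)):
        mask = np.ones(len(ids), dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if len(np.unique(y_train)) < 2:
            raise ValueError("a class is absent from a training fold")
        if nested:
            sub = FeatureTable(
                table.features.iloc[mask], table.labels.iloc[mask]
            )
            fold_sel = stepwise_lda_select(sub, f_in, f_out).selected
        else:
            fold_sel = selection
        if not fold_sel:
            # null model: predict the training majority class
            vals, counts = np.unique(y_train, return_counts=True)
            preds.append(vals[np.argmax(counts)])
            continue
        x = table.features[fold_sel].to_numpy(dtype=float)
        lda = LinearDiscriminantAnalysis(priors=prior_vec)
        lda.fit(x[mask], y_train)
        preds.append(lda.predict(x[i : i + 1])[0])
    preds = np.asarray(preds)
    m = _metrics_from_predictions(y, preds, positive)

    scores = None
    if selection:
        lda_full = LinearDiscriminantAnalysis(priors=prior_vec)
        x = table.features[selection].to_numpy(dtype=float)
        lda_full.fit(x, y)
        scores = pd.Series(
            lda_full.transform(x)[:, 0], index=ids, name="discriminant_score"
        )
    return ClassificationReport(
        accuracy=float(m["accuracy"]),
        sensitivity=float(m["sensitivity"]),
        specificity=float(m["specificity"]),
        predictions=pd.Series(preds, index=ids, name="loocv_prediction"),
        scores=scores,
        selected=selection,
        counts={k: int(m[k]) for k in ("tp", "fn", "tn", "fp")},
    )


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> ClassificationReport:
    """Accuracy, sensitivity and specificity from raw confusion counts.

    Sensitivity (resp. specificity) is NaN when there are no positives
    (resp. negatives) -- flagged rather than raised, except that an
    all-zero table is rejected.
    """
    for name, v in dict(tp=tp, fn=fn, tn=tn, fp=fp).items():
        if v < 0:
            raise ValueError(f"count {name} must be nonnegative")
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("confusion table is empty")
    return ClassificationReport(
        accuracy=(tp + tn) / total,
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        counts=dict(tp=tp, fn=fn, tn=tn, fp=fp),
    )
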