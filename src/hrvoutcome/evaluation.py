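"""Cross-validated discrimination metrics and model comparison reports.

For each feature set, every (repeat, fold) cell of the shared CV scheme
yields train and test AUC, sensitivity and specificity at the fixed 0.5
probability cutoff (the positive class is non-survival, and "positive"
means predicted probability strictly above the cutoff).  Aggregates are
the mean over cells with a normal-approximation 95% confidence interval
(mean ± 1.96·SE).  All compared feature sets reuse identical fold
assignments so that differences between rows of the report are not due
to different splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .model_selection import (
    CohortDataset,
    CVScheme,
    Fold,
    build_design_matrix,
    fit_logistic,
    make_folds,
    predict_prob,
    training_rows,
)

__all__ = [
    "auc",
    "sens_spec",
    "EvaluationResult",
    "evaluate_feature_set",
    "compare_models",
    "format_report_markdown",
]

METRICS = ("auc", "sens", "spec")


def auc(labels, probabilities) -> float:
    """Mann–Whitney AUC: probability a random positive outranks a random
    negative, ties counted one half; equals the trapezoidal ROC area."""
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(y, p))


def sens_spec(labels, probabilities, cutoff: float = 0.5) -> tuple[float, float]:
    """Sensitivity and specificity at a probability cutoff.

    A row is classified positive (non-survivor) when its probability is
    strictly greater than the cutoff; a probability exactly at the cutoff
    is negative.
    """
    y = np.asarray(labels)
    pred = np.asarray(probabilities, dtype=float) > cutoff
    pos = y == 1
    neg = ~pos
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    sens = float(np.sum(pred & pos)) / n_pos if n_pos else np.nan
    spec = float(np.sum(~pred & neg)) / n_neg if n_neg else np.nan
    return sens, spec


@dataclass
class EvaluationResult:
    """Per-cell metrics and aggregates for one feature set."""

    name: str
    features: tuple[str, ...]
    cells: pd.DataFrame  # repeat, fold, train_auc..test_spec
    aggregates: dict[str, dict[str, float]]  # metric -> mean/ci_low/ci_high/n
    fold_fingerprint: int


def _aggregate(values: np.ndarray) -> dict[str, float]:
    v = values[np.isfinite(values)]
    n = v.size
    if n == 0:
        return {"mean": np.nan, "ci_low": np.nan, "ci_high": np.nan, "n": 0}
    mean = float(np.mean(v))
    se = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return {"mean": mean, "ci_low": mean - 1.96 * se, "ci_high": mean + 1.96 * se, "n": n}


def evaluate_feature_set(
    features,
    dataset: CohortDataset,
    folds: list[Fold],
    name: str | None = None,
    cutoff: float = 0.5,
    paper_literal: bool = False,
    standardize: bool = False,
    ridge: float = 1e-4,
) -> EvaluationResult:
    """Fit and score one feature set over prebuilt folds.

    Each fold is fitted on its training rows and scored on both sides;
    degenerate folds (single-class training data) propagate as missing
    cells and reduce the aggregate n.
    """
    features = tuple(features)
    if not features:
        raise ValueError("feature set must be non-empty")
    records = []
    for fold in folds:
        rec: dict[str, float] = {"repeat": fold.repeat, "fold": fold.index}
        tr = training_rows(dataset, fold, paper_literal=paper_literal)
        X_tr, y_tr, _ = build_design_matrix(dataset, features, tr)
        X_te, y_te, _ = build_design_matrix(dataset, features, fold.test_rows)
        try:
            model = fit_logistic(X_tr, y_tr, feature_names=features, ridge=ridge,
                                 standardize=standardize,
                                 meta={"repeat": fold.repeat, "fold": fold.index})
        except ValueError:
            for side in ("train", "test"):
                for m in METRICS:
                    rec[f"{side}_{m}"] = np.nan
            records.append(rec)
            continue
        for side, (Xs, ys) in {"train": (X_tr, y_tr), "test": (X_te, y_te)}.items():
            probs = predict_prob(model, Xs)
            try:
                rec[f"{side}_auc"] = auc(ys, probs)
            except ValueError:
                rec[f"{side}_auc"] = np.nan
            s, c = sens_spec(ys, probs, cutoff=cutoff)
            rec[f"{side}_sens"] = s
            rec[f"{side}_spec"] = c
        records.append(rec)
    cells = pd.DataFrame.from_records(records)
    aggregates = {
        f"{side}_{m}": _aggregate(cells[f"{side}_{m}"].to_numpy(dtype=float))
        for side in ("train", "test") for m in METRICS
    }
    fingerprint = hash(tuple(f.fingerprint() for f in folds))
    return EvaluationResult(
        name=name or "+".join(features),
        features=features,
        cells=cells,
        aggregates=aggregates,
        fold_fingerprint=fingerprint,
    )


def compare_models(
    feature_sets: dict[str, list[str]],
    dataset: CohortDataset,
    scheme: CVScheme | None = None,
    folds: list[Fold] | None = None,
    **eval_kwargs,
) -> tuple[pd.DataFrame, dict[str, EvaluationResult]]:
    """Evaluate several feature sets on identical folds.

    Returns a report table (one row per set; mean and 95% CI bounds for
    train/test AUC, sensitivity and specificity) and the underlying
    per-set :class:`EvaluationResult` objects.
    """
    if not feature_sets:
        raise ValueError("need at least one feature set")
    for nm, members in feature_sets.items():
        if not members:
            raise ValueError(f"feature set {nm!r} has no members")
    if folds is None:
        if scheme is None:
            raise ValueError("provide either folds or a scheme")
        folds = make_folds(dataset, scheme)
    results: dict[str, EvaluationResult] = {}
    rows = []
    for nm, members in feature_sets.items():
        res = evaluate_feature_set(members, dataset, folds, name=nm, **eval_kwargs)
        results[nm] = res
        row: dict[str, object] = {"set": nm, "features": " ".join(members)}
        for key, agg in res.aggregates.items():
            row[f"{key}_mean"] = agg["mean"]
            row[f"{key}_ci_low"] = agg["ci_low"]
            row[f"{key}_ci_high"] = agg["ci_high"]
        rows.append(row)
    return pd.DataFrame(rows), results


def format_report_markdown(report: pd.DataFrame, digits: int = 2) -> str:
    """Render the comparison report as a compact Markdown table."""
    cols = ["set", "features"]
    metric_cols = [
        ("train_auc", "Train AUC"), ("train_sens", "Train Sens"), ("train_spec", "Train Spec"),
        ("test_auc", "Test AUC"), ("test_sens", "Test Sens"), ("test_spec", "Test Spec"),
    ]
    header = "| Set | Features | " + " | ".join(h for _, h in metric_cols) + " |"
    sep = "|" + "---|" * (2 + len(metric_cols))
    lines = [header, sep]
    for _, row in report.iterrows():
        cells = [str(row["set"]), str(row["features"])]
        for key, _ in metric_cols:
            m, lo, hi = (row[f"{key}_mean"], row[f"{key}_ci_low"], row[f"{key}_ci_high"])
            cells.append(f"{m:.{digits}f} [{lo:.{digits}f}, {hi:.{digits}f}]")
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
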