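"""Supervised validation: sparse logistic regression under grouped CV.

An L1-penalized (lasso) logistic regression is fit on the 27 stationary
probabilities — lasso both classifies and selects features, keeping the
model sparse and interpretable. Evaluation uses stratified 5-fold
cross-validation in which every transcript of a participant is confined to
a single fold, so no subject contributes to both training and testing.
Reported per model variant: AUC, F1, precision, recall (sensitivity),
specificity and accuracy as mean +/- SD across folds; Brier score and
expected calibration error (ECE); and thresholds optimized for Youden's J
and maximal F1 alongside the default 0.5.

Model variants (feature representations):

=============  ==========================================================
charmark       order-1 stationary vectors (27 features)
freq_only      raw character relative frequencies (27 features)
space_only     single feature: space count / sequence length
second_order   order-2 bigram-state stationary vectors (729 features)
=============  ==========================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .markov import (
    DEFAULT_ALPHA,
    ALPHA_GRID,
    FeatureMatrix,
    MarkovError,
    build_feature_matrix,
)
from .preprocess import CharSequence

logger = logging.getLogger(__name__)

MODEL_VARIANTS = ("charmark", "freq_only", "space_only", "second_order")

#: Inverse regularization strength of the lasso logistic model.
DEFAULT_C = 1.0
DEFAULT_N_FOLDS = 5
DEFAULT_ECE_BINS = 10


class ClassifyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Fold construction


@dataclass
class FoldPlan:
    """Participant-grouped, class-stratified fold assignment."""

    n_folds: int
    assignment: np.ndarray  # fold index per row
    participant_map: dict[str, int]

    def splits(self):
        for f in range(self.n_folds):
            test = self.assignment == f
            yield ~test, test


def make_folds(
    fm,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    *,
    positive_label: str = "case",
) -> FoldPlan:
    """Greedy grouped-stratified fold assignment.

    ``fm`` may be a :class:`FeatureMatrix` or a list of
    :class:`CharSequence`. Participants are sorted by transcript count
    descending (seeded shuffle breaks ties) and each is placed into the fold
    currently lightest in its own class, tie-broken by total size — all of a
    participant's transcripts land in one fold while per-fold class
    proportions stay close to the global proportion. Deterministic given
    the seed.
    """
    participants, labels = _row_metadata(fm)
    per_part: dict[str, dict] = {}
    for p, lab in zip(participants, labels):
        rec = per_part.setdefault(p, {"n": 0, "label": lab})
        rec["n"] += 1
        if rec["label"] != lab:
            raise ClassifyError(f"participant {p!r} has transcripts in both groups")
    for lab in set(labels):
        n_part = sum(1 for r in per_part.values() if r["label"] == lab)
        if n_part < n_folds:
            raise ClassifyError(
                f"class {lab!r} has {n_part} participants; need >= {n_folds}"
            )
    rng = np.random.default_rng(seed)
    order = list(per_part)
    rng.shuffle(order)
    order.sort(key=lambda p: -per_part[p]["n"])  # stable: keeps shuffled ties

    class_load = {lab: np.zeros(n_folds) for lab in set(labels)}
    total_load = np.zeros(n_folds)
    participant_map: dict[str, int] = {}
    for p in order:
        lab, n = per_part[p]["label"], per_part[p]["n"]
        cost = list(zip(class_load[lab], total_load, range(n_folds)))
        f = min(cost)[2]
        participant_map[p] = f
        class_load[lab][f] += n
        total_load[f] += n
    assignment = np.asarray([participant_map[p] for p in participants])
    return FoldPlan(n_folds=n_folds, assignment=assignment, participant_map=participant_map)


def _row_metadata(fm) -> tuple[list[str], list[str]]:
    if isinstance(fm, FeatureMatrix):
        return fm.row_participants, fm.row_groups
    return [s.participant_id for s in fm], [s.group_label for s in fm]


# ---------------------------------------------------------------------------
# Feature representations


def feature_representation(
    corpus: list[CharSequence],
    variant: str,
    alpha: float = DEFAULT_ALPHA,
) -> FeatureMatrix:
    """Build the feature matrix for a model variant (see module docstring)."""
    if variant == "charmark":
        return build_feature_matrix(corpus, alpha=alpha, order=1)
    if variant == "second_order":
        return build_feature_matrix(corpus, alpha=alpha, order=2)
    if variant not in MODEL_VARIANTS:
        raise ClassifyError(f"unknown model variant {variant!r}")
    alphabet = corpus[0].alphabet
    k = alphabet.size
    rows = []
    for seq in corpus:
        if variant == "freq_only":
            rows.append(np.bincount(seq.indices, minlength=k) / len(seq))
        else:  # space_only
            rows.append([seq.space_fraction])
    col_names = alphabet.display_names() if variant == "freq_only" else ["space_fraction"]
    return FeatureMatrix(
        values=np.asarray(rows, dtype=float),
        row_ids=[s.transcript_id for s in corpus],
        row_groups=[s.group_label for s in corpus],
        row_participants=[s.participant_id for s in corpus],
        col_names=list(col_names),
    )


# ---------------------------------------------------------------------------
# Model fitting


def fit_predict_lasso(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    C: float = DEFAULT_C,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit L1 logistic regression (class-balanced) and predict P(case).

    Returns (test probabilities, coefficient vector). Features enter on
    their native probability scale.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ClassifyError("training fold contains a single class")
    model = LogisticRegression(
        l1_ratio=1.0,  # pure lasso penalty
        C=C,
        solver="liblinear",
        class_weight="balanced",
        max_iter=1000,
        random_state=seed,
    )
    model.fit(X_train, y_train)
    return model.predict_proba(X_test)[:, 1], model.coef_.ravel()


# ---------------------------------------------------------------------------
# Metrics


def confusion_matrix(probs, labels, threshold: float = 0.5):
    """2x2 counts (tn, fp, fn, tp) and row-normalized proportions at a
    threshold (predicted positive iff p >= threshold)."""
    if not 0 <= threshold <= 1:
        raise ClassifyError(f"threshold {threshold} outside [0, 1]")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    pred = probs >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    counts = np.array([[tn, fp], [fn, tp]])
    with np.errstate(invalid="ignore"):
        proportions = counts / counts.sum(axis=1, keepdims=True)
    return counts, proportions


def threshold_metrics(probs, labels, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy / precision / recall (sensitivity) / specificity / F1 at a
    threshold. Undefined ratios (empty denominators) are reported as 0."""
    (tn, fp), (fn, tp) = confusion_matrix(probs, labels, threshold)[0]
    n = tn + fp + fn + tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "accuracy": (tp + tn) / n,
        "precision": precision,
        "recall_sensitivity": recall,
        "specificity": specificity,
        "f1": f1,
    }


def calibration_metrics(
    probs, labels, n_bins: int = DEFAULT_ECE_BINS
) -> tuple[float, float, pd.DataFrame]:
    """Brier score, expected calibration error, and reliability bins.

    Brier is the mean squared error of predicted probabilities against 0/1
    labels. ECE partitions [0, 1] into ``n_bins`` equal-width bins and
    weights, by occupancy, the absolute gap between mean confidence and
    observed positive fraction; empty bins are skipped.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.shape != labels.shape:
        raise ClassifyError("probs and labels length mismatch")
    if n_bins < 2:
        raise ClassifyError("n_bins must be >= 2")
    brier = float(np.mean((probs - labels) ** 2))
    edges = np.linspace(0, 1, n_bins + 1)
    which = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    records = []
    ece = 0.0
    for b in range(n_bins):
        mask = which == b
        count = int(mask.sum())
        if count == 0:
            continue
        conf = float(probs[mask].mean())
        frac = float(labels[mask].mean())
        ece += count / probs.size * abs(conf - frac)
        records.append(
            {"bin": b, "mean_confidence": conf, "observed_frequency": frac, "count": count}
        )
    return brier, float(ece), pd.DataFrame(records)


def optimize_threshold(probs, labels, criterion: str = "youden_j"):
    """Scan thresholds (midpoints of sorted unique probs, plus 0 and 1) for
    the one maximizing Youden's J = sensitivity + specificity - 1, or F1.
    Ties go to the lower threshold."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ClassifyError("threshold optimization needs both classes")
    uniq = np.unique(probs)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2, [1.0]])
    best_t, best_score, best_metrics = 0.0, -np.inf, None
    for t in candidates:
        m = threshold_metrics(probs, labels, t)
        if criterion == "youden_j":
            score = m["recall_sensitivity"] + m["specificity"] - 1
        elif criterion == "f1_max":
            score = m["f1"]
        else:
            raise ClassifyError(f"unknown criterion {criterion!r}")
        if score > best_score + 1e-12:
            best_t, best_score, best_metrics = float(t), score, m
    best_metrics = dict(best_metrics)
    best_metrics["youden_j"] = (
        best_metrics["recall_sensitivity"] + best_metrics["specificity"] - 1
    )
    return best_t, best_metrics


# ---------------------------------------------------------------------------
# Cross-validated evaluation


@dataclass
class CVReport:
    """Per-fold and aggregate results for one model variant."""

    variant: str
    per_fold: pd.DataFrame
    mean: dict[str, float]
    sd: dict[str, float]
    pooled: dict[str, float]
    brier: float
    ece: float
    reliability_bins: pd.DataFrame
    thresholds: dict[str, dict]
    selected_features: list[list[str]]
    oof_probs: np.ndarray
    oof_labels: np.ndarray
    config: dict = field(default_factory=dict)

    def summary_row(self) -> dict[str, str]:
        """One formatted 'mean ± SD' row, shaped like a comparison table."""
        keys = ["auc", "f1", "precision", "recall_sensitivity", "specificity", "accuracy"]
        row = {"model": self.variant}
        row.update({k: f"{self.mean[k]:.3f} ± {self.sd[k]:.3f}" for k in keys})
        return row


def _encode_labels(groups: list[str], positive_label: str) -> np.ndarray:
    y = np.asarray([1 if g == positive_label else 0 for g in groups])
    if len(np.unique(y)) < 2:
        raise ClassifyError(
            f"corpus must contain both {positive_label!r} and another group"
        )
    return y


def evaluate_feature_matrix(
    fm: FeatureMatrix,
    plan: FoldPlan,
    *,
    variant: str = "charmark",
    C: float = DEFAULT_C,
    ece_bins: int = DEFAULT_ECE_BINS,
    seed: int = 0,
    positive_label: str = "case",
    config: dict | None = None,
) -> CVReport:
    """Cross-validate a lasso logistic model on a prebuilt feature matrix."""
    if plan.assignment.shape[0] != fm.n_rows:
        raise ClassifyError("fold plan does not cover the feature matrix rows")
    y = _encode_labels(fm.row_groups, positive_label)
    X = fm.values
    oof = np.full(fm.n_rows, np.nan)
    fold_rows, selected = [], []
    for f, (train, test) in enumerate(plan.splits()):
        probs, coefs = fit_predict_lasso(X[train], y[train], X[test], C=C, seed=seed)
        oof[test] = probs
        names = [fm.col_names[j] for j in np.flatnonzero(coefs)]
        selected.append(names)
        row = {"fold": f, "auc": _safe_auc(y[test], probs)}
        row.update(threshold_metrics(probs, y[test], 0.5))
        b, e, _ = calibration_metrics(probs, y[test], ece_bins)
        row.update({"brier": b, "ece": e, "n_selected": len(names)})
        fold_rows.append(row)
    assert not np.isnan(oof).any(), "out-of-fold predictions must cover every row"
    per_fold = pd.DataFrame(fold_rows).set_index("fold")
    metric_cols = [c for c in per_fold.columns if c != "n_selected"]
    mean = per_fold[metric_cols].mean().to_dict()
    sd = per_fold[metric_cols].std(ddof=1).to_dict()

    pooled = {"auc": _safe_auc(y, oof)}
    pooled.update(threshold_metrics(oof, y, 0.5))
    brier, ece, bins = calibration_metrics(oof, y, ece_bins)
    pooled.update({"brier": brier, "ece": ece})

    thresholds = {"default_0.5": {"threshold": 0.5, **threshold_metrics(oof, y, 0.5)}}
    for crit in ("youden_j", "f1_max"):
        t, m = optimize_threshold(oof, y, crit)
        thresholds[crit] = {"threshold": t, **m}

    cfg = {"variant": variant, "C": C, "ece_bins": ece_bins, "seed": seed,
           "n_folds": plan.n_folds}
    cfg.update(config or {})
    return CVReport(
        variant=variant,
        per_fold=per_fold,
        mean=mean,
        sd=sd,
        pooled=pooled,
        brier=brier,
        ece=ece,
        reliability_bins=bins,
        thresholds=thresholds,
        selected_features=selected,
        oof_probs=oof,
        oof_labels=y,
        config=cfg,
    )


def _safe_auc(y_true, probs) -> float:
    if len(np.unique(y_true)) < 2:
        return float("nan")
    return float(roc_auc_score(y_true, probs))


def evaluate_cv(
    corpus: list[CharSequence],
    plan: FoldPlan,
    variant: str = "charmark",
    *,
    alpha: float = DEFAULT_ALPHA,
    C: float = DEFAULT_C,
    ece_bins: int = DEFAULT_ECE_BINS,
    seed: int = 0,
    positive_label: str = "case",
) -> CVReport:
    """Build the variant's feature representation and cross-validate it."""
    fm = feature_representation(corpus, variant, alpha=alpha)
    if fm.n_rows != len(corpus):
        raise ClassifyError(
            "some transcripts were excluded during feature building; "
            "rebuild the fold plan on the surviving rows"
        )
    return evaluate_feature_matrix(
        fm, plan, variant=variant, C=C, ece_bins=ece_bins, seed=seed,
        positive_label=positive_label, config={"alpha": alpha},
    )


def alpha_sensitivity(
    corpus: list[CharSequence],
    plan: FoldPlan,
    grid=ALPHA_GRID,
    **kwargs,
) -> tuple[dict[float, CVReport], dict[str, float]]:
    """Re-run the charmark evaluation across a smoothing grid with the folds
    held fixed; report per-alpha CVReports plus the max-minus-min spread of
    mean AUC and F1 across the grid."""
    grid = list(grid)
    if not grid:
        raise ClassifyError("alpha grid must be nonempty")
    reports = {
        a: evaluate_cv(corpus, plan, "charmark", alpha=a, **kwargs) for a in grid
    }
    aucs = [r.mean["auc"] for r in reports.values()]
    f1s = [r.mean["f1"] for r in reports.values()]
    spread = {
        "auc_spread": max(aucs) - min(aucs),
        "f1_spread": max(f1s) - min(f1s),
    }
    return reports, spread


def sensitivity_table(reports: dict[float, CVReport]) -> pd.DataFrame:
    """Grid-by-metric table of 'mean ± SD' strings, one row per alpha."""
    rows = []
    for a, rep in sorted(reports.items()):
        row = rep.summary_row()
        row["model"] = f"{a:g}"
        rows.append(row)
    df = pd.DataFrame(rows).rename(columns={"model": "alpha"})
    return df
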