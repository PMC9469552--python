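"""Cross-validation, metrics, ablations, and hyper-parameter sweeps.

Known associations are the positive class.  In the ``balanced`` regime an
equal number of negative pairs is sampled once, uniformly without
replacement, from the unobserved cells (a dataset-level decision fixed
before training); the ``all_pairs`` regime folds every cell.  Each
cross-validation round trains the estimator on the training folds' pairs
and scores the held-out fold.

Threshold metrics are computed on scores min-max scaled within each
validation fold (raw inner-product scores are unbounded, so some explicit
normalization is unavoidable) with a default threshold of 0.5; the ROC AUC
uses the rank statistic with ties averaged and the PR area uses step-wise
integration (precision held constant between recall points).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import ConfigError
from .estimator import GCMM
from .hetnet import AssociationMatrix, HeterogeneousNetwork

METRIC_NAMES = ("AUC", "AUPR", "F1", "ACC", "Recall", "Precision", "Specificity")


# ---------------------------------------------------------------------------
# cross-validation plan
# ---------------------------------------------------------------------------


@dataclass
class CvPlan:
    """Fold assignment of positive and sampled negative pairs."""

    k: int
    regime: str
    seed: int
    positive_folds: list[np.ndarray]  # each (m_i, 2) of (drug, disease) indices
    negative_folds: list[np.ndarray]

    def train_pairs(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(pairs, labels) over all folds except ``fold``."""
        self._check_fold(fold)
        pos = [p for f, p in enumerate(self.positive_folds) if f != fold]
        neg = [p for f, p in enumerate(self.negative_folds) if f != fold]
        return _stack_pairs(pos, neg)

    def validation_pairs(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        self._check_fold(fold)
        return _stack_pairs(
            [self.positive_folds[fold]], [self.negative_folds[fold]]
        )

    def _check_fold(self, fold: int):
        if not 0 <= fold < self.k:
            raise IndexError(f"fold {fold} out of range for k={self.k}")


def _stack_pairs(pos_list, neg_list):
    pos = np.vstack([p for p in pos_list if len(p)]) if any(len(p) for p in pos_list) else np.empty((0, 2), int)
    neg = np.vstack([p for p in neg_list if len(p)]) if any(len(p) for p in neg_list) else np.empty((0, 2), int)
    pairs = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    return pairs, labels


def make_cv_plan(
    assoc: AssociationMatrix,
    k: int = 5,
    regime: str = "balanced",
    seed: int = 0,
) -> CvPlan:
    """Deterministically split pairs into ``k`` folds.

    ``balanced``: positives are shuffled and partitioned; an equal number
    of negatives is sampled without replacement from the zero cells and
    partitioned likewise.  ``all_pairs``: every cell is folded.
    """
    if regime not in ("balanced", "all_pairs"):
        raise ConfigError(f"unknown regime {regime!r}")
    values = assoc.values
    positives = np.argwhere(values == 1)
    negatives_all = np.argwhere(values == 0)
    if len(positives) < k:
        raise ValueError(f"need at least k={k} positives, have {len(positives)}")
    rng = np.random.default_rng(seed)
    pos = positives[rng.permutation(len(positives))]
    if regime == "balanced":
        n_neg = min(len(positives), len(negatives_all))
        neg = negatives_all[rng.choice(len(negatives_all), size=n_neg, replace=False)]
    else:
        neg = negatives_all[rng.permutation(len(negatives_all))]
    return CvPlan(
        k=k,
        regime=regime,
        seed=seed,
        positive_folds=[a.copy() for a in np.array_split(pos, k)],
        negative_folds=[a.copy() for a in np.array_split(neg, k)],
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int
    threshold: float

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Precision, Recall, ACC, F1, Specificity from confusion counts."""
    p = _safe_div(counts.TP, counts.TP + counts.FP)
    r = _safe_div(counts.TP, counts.TP + counts.FN)
    return {
        "Precision": p,
        "Recall": r,
        "ACC": _safe_div(counts.TP + counts.TN, counts.total),
        "F1": _safe_div(2 * p * r, p + r),
        "Specificity": _safe_div(counts.TN, counts.TN + counts.FP),
    }


def minmax_scale(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    lo, hi = scores.min(), scores.max()
    if hi > lo:
        return (scores - lo) / (hi - lo)
    return np.full_like(scores, 0.5)


def score_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    scale: bool = True,
) -> tuple[dict[str, float], ConfusionCounts]:
    """All six threshold metrics plus AUC and AUPR for one fold.

    Scores are min-max scaled before thresholding unless ``scale=False``
    (pass pre-scaled scores, e.g. probabilities, with ``scale=False``).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: labels contain a single class")
    scaled = minmax_scale(scores) if scale else scores
    predicted = scaled >= threshold
    counts = ConfusionCounts(
        TP=int(np.sum(predicted & (labels == 1))),
        TN=int(np.sum(~predicted & (labels == 0))),
        FP=int(np.sum(predicted & (labels == 0))),
        FN=int(np.sum(~predicted & (labels == 1))),
        threshold=threshold,
    )
    metrics = confusion_metrics(counts)
    metrics["AUC"] = float(roc_auc_score(labels, scores))
    metrics["AUPR"] = float(average_precision_score(labels, scores))
    return metrics, counts


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-fold and mean metrics with the confusion counts behind them."""

    per_fold: list[dict[str, float]]
    counts: list[ConfusionCounts]
    loss_curves: list[np.ndarray] = field(default_factory=list)

    @property
    def mean(self) -> dict[str, float]:
        return {
            name: float(np.mean([f[name] for f in self.per_fold]))
            for name in self.per_fold[0]
        }

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"fold": f"Fold {i + 1}", **fold} for i, fold in enumerate(self.per_fold)
        ]
        rows.append({"fold": "Mean", **self.mean})
        return pd.DataFrame(rows).set_index("fold")[list(METRIC_NAMES)]


def train_fold(
    net: HeterogeneousNetwork,
    plan: CvPlan,
    fold: int,
    estimator: GCMM | None = None,
) -> GCMM:
    """Fit a fresh clone of the estimator on one fold's training pairs."""
    est = clone(estimator) if estimator is not None else GCMM()
    pairs, _ = plan.train_pairs(fold)
    return est.fit(net, mask=pairs)


def evaluate_fold(
    est: GCMM, plan: CvPlan, fold: int, threshold: float = 0.5
) -> tuple[dict[str, float], ConfusionCounts]:
    pairs, labels = plan.validation_pairs(fold)
    return score_metrics(est.decision_function(pairs), labels, threshold)


def run_cv(
    net: HeterogeneousNetwork,
    plan: CvPlan,
    estimator: GCMM | None = None,
    threshold: float = 0.5,
) -> EvalReport:
    """Train and score every fold; aggregate per-fold and mean metrics."""
    per_fold, counts, curves = [], [], []
    for fold in range(plan.k):
        est = train_fold(net, plan, fold, estimator)
        metrics, cc = evaluate_fold(est, plan, fold, threshold)
        per_fold.append(metrics)
        counts.append(cc)
        curves.append(est.loss_curve_)
    return EvalReport(per_fold, counts, curves)


def run_cv_repeated(
    net: HeterogeneousNetwork,
    assoc_seed_base: int,
    n_repeats: int = 1,
    k: int = 5,
    regime: str = "balanced",
    estimator: GCMM | None = None,
) -> pd.DataFrame:
    """Repeat run_cv with distinct plan seeds; report mean and sd per metric."""
    means = []
    for rep in range(n_repeats):
        plan = make_cv_plan(net.assoc, k=k, regime=regime, seed=assoc_seed_base + rep)
        means.append(run_cv(net, plan, estimator).mean)
    frame = pd.DataFrame(means)
    return pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=0)})


# ---------------------------------------------------------------------------
# ablation and sweeps
# ---------------------------------------------------------------------------

_VIEW_FAMILY = {"C": "drug", "T": "drug", "M": "disease", "A": "disease"}


def ablation_estimator(variant, base: GCMM | None = None) -> GCMM:
    """Estimator configured for an ablation variant.

    ``variant`` is ``"full"``, ``"no_att"``, ``"no_lin"``, or a view subset
    given as an iterable or a string like ``"C+M"``.
    """
    est = clone(base) if base is not None else GCMM()
    if variant == "full":
        return est
    if variant == "no_att":
        return est.set_params(attention=False)
    if variant == "no_lin":
        return est.set_params(extractor=False)
    views = variant.split("+") if isinstance(variant, str) else list(variant)
    bad = [v for v in views if v not in _VIEW_FAMILY]
    if bad:
        raise ConfigError(f"unknown view(s) {bad} in ablation variant")
    drug = tuple(v for v in ("C", "T") if v in views)
    disease = tuple(v for v in ("M", "A") if v in views)
    if not drug or not disease:
        raise ConfigError(
            f"variant {variant!r} must keep at least one view per node family"
        )
    return est.set_params(drug_views=drug, disease_views=disease)


def run_ablation(
    net: HeterogeneousNetwork,
    variant,
    plan: CvPlan,
    estimator: GCMM | None = None,
    threshold: float = 0.5,
) -> EvalReport:
    """run_cv under an ablation variant (``"full"`` reduces to run_cv)."""
    return run_cv(net, plan, ablation_estimator(variant, estimator), threshold)


_SWEEP_PARAMS = {
    "layers": "n_layers",
    "embedding": "embedding_dim",
    "channels": "n_out_channels",
    "lr": "learning_rate",
}


def sweep(
    net: HeterogeneousNetwork,
    param: str,
    values: Sequence,
    plan: CvPlan,
    estimator: GCMM | None = None,
) -> pd.DataFrame:
    """One run_cv per hyper-parameter value; mean metrics tabulated."""
    if len(values) < 2:
        raise ConfigError("a sweep needs at least 2 values")
    name = _SWEEP_PARAMS.get(param, param)
    base = estimator if estimator is not None else GCMM()
    rows = {}
    for value in values:
        est = clone(base).set_params(**{name: value})
        rows[value] = run_cv(net, plan, est).mean
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = name
    return frame[list(METRIC_NAMES)]


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict_top_k(
    est: GCMM, net: HeterogeneousNetwork, disease_id: str, k: int = 5
) -> list[tuple[str, float]]:
    """Top-k candidate drugs for a disease, excluding known associations.

    Ties are broken by drug registry order (stable sort on descending
    score).
    """
    if disease_id not in net.disease_ids:
        raise KeyError(f"unknown disease {disease_id!r}")
    j = net.disease_ids.index(disease_id)
    scores = est.decision_function()[:, j]
    known = net.assoc.values[:, j] == 1
    candidates = [
        (net.drug_ids[i], float(scores[i])) for i in range(len(scores)) if not known[i]
    ]
    candidates.sort(key=lambda t: -t[1])  # stable: registry order breaks ties
    return candidates[:k]
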