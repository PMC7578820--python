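"""Evaluation utilities: exact-match entity scoring, interrater reliability
(two-way random, absolute agreement, average measures ICC with an
F-distribution 95% CI), and Likert score summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import f as f_dist

from .types import Mention

__all__ = [
    "EvalReport",
    "ner_metrics",
    "ICCResult",
    "icc",
    "icc_category",
    "likert_summary",
]


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


@dataclass
class EvalReport:
    micro_precision: float
    micro_recall: float
    micro_f1: float
    per_type: dict[str, tuple[float, float, float, int]] = field(default_factory=dict)
    support: int = 0


def ner_metrics(gold: Sequence[Mention], predicted: Sequence[Mention]) -> EvalReport:
    """Exact-match scoring: a prediction is a true positive iff its
    (doc_id, start, end, sem_type) tuple occurs among the gold mentions."""

    def keys(mentions: Sequence[Mention]) -> set[tuple]:
        return {(m.doc_id, m.start, m.end, m.sem_type) for m in mentions}

    gset, pset = keys(gold), keys(predicted)
    tp = len(gset & pset)
    fp = len(pset - gset)
    fn = len(gset - pset)
    p, r, f1 = _prf(tp, fp, fn)
    per_type: dict[str, tuple[float, float, float, int]] = {}
    types = {m.sem_type for m in gold} | {m.sem_type for m in predicted}
    for t in sorted(types):
        gt = {k for k in gset if k[3] == t}
        pt = {k for k in pset if k[3] == t}
        tpt = len(gt & pt)
        pp, rr, ff = _prf(tpt, len(pt - gt), len(gt - pt))
        per_type[t] = (pp, rr, ff, len(gt))
    return EvalReport(p, r, f1, per_type, support=len(gset))


# -- intraclass correlation ------------------------------------------------

#: verbal reliability bands: 1.0 perfect; >0.81 excellent; 0.61-0.80
#: substantial; 0.41-0.60 moderate; 0.21-0.40 fair; <0.20 slight.  The
#: printed bands leave (0.80, 0.81) and (0.20, 0.21) open; values there are
#: assigned to the lower band.
_CATEGORIES = (
    (0.81, "excellent"),
    (0.61, "substantial"),
    (0.41, "moderate"),
    (0.21, "fair"),
)


def icc_category(value: float) -> str:
    if value >= 1.0:
        return "perfect"
    if value > 0.81:
        return "excellent"
    for lo, name in _CATEGORIES[1:]:
        if value >= lo:
            return name
    return "slight"


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    category: str


def icc(ratings: np.ndarray, confidence: float = 0.95) -> ICCResult:
    """Two-way random-effects, absolute-agreement, average-measures ICC.

    ``ratings`` is a raters x items matrix with no missing cells.  The CI is
    the F-distribution interval for the single-rater coefficient mapped to
    average measures through the Spearman-Brown relation.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2-D raters x items matrix")
    k, n = ratings.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 raters and 2 items")
    if not np.all(np.isfinite(ratings)):
        raise ValueError("missing cells are not supported")
    data = ratings.T  # items x raters

    grand = data.mean()
    item_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_items = k * ((item_means - grand) ** 2).sum()
    ss_raters = n * ((rater_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_items - ss_raters
    msr = ss_items / (n - 1)  # between items
    msc = ss_raters / (k - 1)  # between raters
    mse = ss_err / ((n - 1) * (k - 1))
    if msr == 0 and msc == 0 and mse == 0:
        raise ValueError("degenerate ratings: no variance anywhere")

    denom_k = msr + (msc - mse) / n
    value = (msr - mse) / denom_k if denom_k != 0 else 1.0

    # single-measures ICC(A,1) and its F-based CI (McGraw & Wong), then
    # Spearman-Brown up to average measures
    denom_1 = msr + (k - 1) * mse + k * (msc - mse) / n
    icc1 = (msr - mse) / denom_1 if denom_1 != 0 else 1.0
    alpha = 1.0 - confidence
    if mse == 0:
        lo1 = hi1 = icc1
    else:
        a = k * icc1 / (n * (1 - icc1)) if icc1 < 1 else np.inf
        b = 1 + k * icc1 * (n - 1) / (n * (1 - icc1)) if icc1 < 1 else np.inf
        if np.isfinite(a) and np.isfinite(b):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_lo = f_dist.ppf(1 - alpha / 2, n - 1, v)
            f_hi = f_dist.ppf(1 - alpha / 2, v, n - 1)
            lo1 = n * (msr - f_lo * mse) / (
                f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi1 = n * (f_hi * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_hi * msr
            )
        else:
            lo1 = hi1 = icc1

    def sb(x: float) -> float:
        return k * x / (1 + (k - 1) * x)

    lo, hi = sb(lo1), sb(hi1)
    lo, hi = min(lo, hi), max(lo, hi)
    return ICCResult(
        icc=float(value),
        ci_low=float(min(lo, 1.0)),
        ci_high=float(min(hi, 1.0)),
        category=icc_category(float(value)),
    )


def likert_summary(
    scores: np.ndarray, metric_names: Sequence[str] | None = None
) -> dict:
    """Per-metric and overall arithmetic means of a raters x metrics matrix
    of 1-5 scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a 2-D raters x metrics matrix")
    if np.any((scores < 1) | (scores > 5)):
        raise ValueError("Likert scores must lie in 1..5")
    n_metrics = scores.shape[1]
    names = list(metric_names) if metric_names else [
        f"metric_{i + 1}" for i in range(n_metrics)
    ]
    if len(names) != n_metrics:
        raise ValueError("metric_names length mismatch")
    per_metric = {name: float(scores[:, j].mean()) for j, name in enumerate(names)}
    return {"per_metric": per_metric, "overall": float(scores.mean())}
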