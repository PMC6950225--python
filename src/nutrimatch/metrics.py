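"""Evaluation suite for nutrient prediction and database matching.

Regression quality is summarized by R², Pearson and Spearman correlation,
and mean absolute error.  Match quality is summarized by diagnostics that
need no reference lookup (the median coefficient of variation of the
lactose carried by a query's top-5 matches — similar foods should carry
similar lactose), by recovery of known query-target links at rank 1 and
within the top 5, and by the accuracy of returning a lactose-free food as
the first match for a lactose-free query.  A manual-lookup confidence rule
rates a query/match pair "high" when the description was judged a high-
confidence match and at least 5 of 7 key nutrients agree within cutoffs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mean_absolute_error, r2_score

from .data import FoodDatabase, FoodRecord, GroundTruthLink, MatchResult

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionMetrics",
    "regression_metrics",
    "MatchDiagnostics",
    "match_diagnostics",
    "ConfidenceConfig",
    "confidence_rating",
    "stratified_report",
]


@dataclass
class RegressionMetrics:
    """R², Pearson r, Spearman rho, and MAE on n pairs.

    Correlations and R² are NaN (undefined) when the true values are
    constant.
    """

    r2: float
    pcc: float
    src: float
    mae: float
    n: int

    def as_dict(self) -> dict:
        return {"r2": self.r2, "pcc": self.pcc, "src": self.src,
                "mae": self.mae, "n": self.n}


def regression_metrics(y_true, y_pred) -> RegressionMetrics:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    n = y_true.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    mae = float(mean_absolute_error(y_true, y_pred))
    if np.ptp(y_true) == 0:
        logger.warning("constant y_true: r2/pcc/src undefined")
        return RegressionMetrics(math.nan, math.nan, math.nan, mae, n)
    r2 = float(r2_score(y_true, y_pred))
    if np.ptp(y_pred) == 0:
        pcc = src = math.nan
    else:
        pcc = float(stats.pearsonr(y_true, y_pred).statistic)
        src = float(stats.spearmanr(y_true, y_pred).statistic)
    return RegressionMetrics(r2, pcc, src, mae, n)


# ---------------------------------------------------------------------------
# match diagnostics


@dataclass
class MatchDiagnostics:
    median_cv_top5: float
    foodlink_first_hits: int
    foodlink_top5_hits: int
    foodlink_queries: int
    zero_first_match_accuracy: float
    per_query_cv: dict[str, float] = field(default_factory=dict)


def _lactose_cv(values: np.ndarray) -> float:
    """Population std / mean; all-zero lists have CV 0 by convention."""
    if values.size == 0:
        return math.nan
    mean = values.mean()
    if mean == 0:
        return 0.0  # lactose >= 0, so mean 0 means all zero
    return float(values.std(ddof=0) / mean)


def match_diagnostics(
    results: list[MatchResult],
    links: list[GroundTruthLink] | None = None,
    reference_lactose: dict[str, float] | None = None,
    top_n: int = 5,
) -> MatchDiagnostics:
    """Match-quality diagnostics over a batch of ranked match results.

    * median CV of the lactose among each query's top-``top_n`` matches;
    * link recovery: queries whose rank-1 match (or any of the top
      ``top_n``) is one of its known linked targets — any linked target
      counts for multi-link queries;
    * fraction of truly lactose-free queries (reference 0 g) whose first
      match is lactose-free.  Queries absent from the reference are
      excluded with a warning.
    """
    if not results:
        raise ValueError("results must be non-empty")
    per_query_cv: dict[str, float] = {}
    for res in results:
        vals = np.asarray(
            [e.lactose_g for e in res.ranked[:top_n] if not math.isnan(e.lactose_g)]
        )
        cv = _lactose_cv(vals)
        if not math.isnan(cv):
            per_query_cv[res.query_id] = cv
    median_cv = float(np.median(list(per_query_cv.values()))) if per_query_cv else math.nan

    first_hits = top5_hits = link_queries = 0
    if links:
        linked: dict[str, set[str]] = {}
        for ln in links:
            linked.setdefault(ln.query_id, set()).add(ln.target_id)
        for res in results:
            targets = linked.get(res.query_id)
            if not targets or not res.ranked:
                continue
            link_queries += 1
            if res.ranked[0].target_id in targets:
                first_hits += 1
            if any(e.target_id in targets for e in res.ranked[:top_n]):
                top5_hits += 1

    zero_acc = math.nan
    if reference_lactose is not None:
        zero_total = zero_correct = 0
        for res in results:
            if res.query_id not in reference_lactose:
                logger.warning(
                    "query %s missing from reference; excluded", res.query_id
                )
                continue
            if reference_lactose[res.query_id] == 0 and res.ranked:
                zero_total += 1
                if res.ranked[0].lactose_g == 0:
                    zero_correct += 1
        zero_acc = zero_correct / zero_total if zero_total else math.nan

    return MatchDiagnostics(
        median_cv_top5=median_cv,
        foodlink_first_hits=first_hits,
        foodlink_top5_hits=top5_hits,
        foodlink_queries=link_queries,
        zero_first_match_accuracy=zero_acc,
        per_query_cv=per_query_cv,
    )


# ---------------------------------------------------------------------------
# manual-lookup confidence rule


DEFAULT_QC_NUTRIENTS = ("KCAL", "CARB", "TFAT", "PROT", "SODI", "CALC", "PHOS")


@dataclass
class ConfidenceConfig:
    """Cutoffs for the 7-nutrient match-confidence rule.

    ``cutoffs`` maps each QC nutrient (energy, carbohydrate, fat, protein,
    sodium, calcium, phosphorus) to a (high, medium) pair of absolute-
    difference thresholds, high < medium.  There are no shipped default
    cutoff values; they are study-specific configuration.
    """

    cutoffs: dict[str, tuple[float, float]]
    qc_nutrients: tuple[str, ...] = DEFAULT_QC_NUTRIENTS
    min_high_nutrients: int = 5

    def __post_init__(self) -> None:
        for name in self.qc_nutrients:
            if name not in self.cutoffs:
                raise ValueError(f"missing cutoff for QC nutrient {name!r}")
            high, medium = self.cutoffs[name]
            if not high < medium:
                raise ValueError(
                    f"{name}: high cutoff must be smaller than medium cutoff"
                )


def confidence_rating(
    query: FoodRecord,
    match: FoodRecord,
    cfg: ConfidenceConfig,
    description_rating: str,
    schema=None,
) -> str:
    """Overall match confidence: "high" or "not_high".

    A nutrient rates "high" when |query - match| is within its high cutoff.
    The overall rating is "high" iff the (human-judged) description rating
    is "high" and at least ``min_high_nutrients`` of the QC nutrients rate
    high.
    """
    from .data import default_schema

    if schema is None:
        schema = default_schema()
    high_count = 0
    for name in cfg.qc_nutrients:
        j = schema.index(name)
        diff = abs(float(query.nutrients[j]) - float(match.nutrients[j]))
        if diff <= cfg.cutoffs[name][0]:
            high_count += 1
    if description_rating == "high" and high_count >= cfg.min_high_nutrients:
        return "high"
    return "not_high"


# ---------------------------------------------------------------------------
# stratified reporting


def stratified_report(
    y_true,
    y_pred,
    ids: list[str],
    subsets: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Regression metrics per subset of the evaluation foods.

    ``subsets`` maps a row label to ``{"exclude": [ids...]}`` or
    ``{"include": [ids...]}``; an "all" row is always present.  Empty
    subsets yield a flagged (all-NaN) row rather than being dropped, and
    exclusions are echoed in the table.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ids = list(ids)
    if not (len(ids) == y_true.size == y_pred.size):
        raise ValueError("ids, y_true, y_pred must have equal length")
    subsets = {"all": {}, **(subsets or {})}
    rows = []
    for label, spec in subsets.items():
        mask = np.ones(len(ids), dtype=bool)
        if "include" in spec:
            keep = set(spec["include"])
            mask &= np.array([i in keep for i in ids])
        if "exclude" in spec:
            drop = set(spec["exclude"])
            mask &= np.array([i not in drop for i in ids])
        excluded = sorted(spec.get("exclude", []))
        if mask.sum() < 2:
            logger.warning("subset %r has fewer than 2 foods; flagged empty", label)
            rows.append(
                {"subset": label, "r2": math.nan, "pcc": math.nan, "src": math.nan,
                 "mae": math.nan, "n": int(mask.sum()), "is_empty": True,
                 "excluded_ids": ";".join(excluded)}
            )
            continue
        m = regression_metrics(y_true[mask], y_pred[mask])
        rows.append(
            {"subset": label, **m.as_dict(), "is_empty": False,
             "excluded_ids": ";".join(excluded)}
        )
    return pd.DataFrame(rows)
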