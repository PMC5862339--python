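"""Rank normalization methods by AUC and pool mean ranks across datasets.

Within each two-group comparison, methods are ranked by descending AUC
(rank 1 = best; ties share the average of their rank span). Per-dataset
mean ranks carry a standard error over comparisons; a comparison-count-
weighted pooled mean rank across datasets gets its standard error from the
Satterthwaite combination of the per-dataset variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ProtNormError

__all__ = [
    "RankTable",
    "rank_by_auc",
    "summarize_ranks",
    "pool_ranks_satterthwaite",
]


@dataclass
class RankTable:
    """Method × comparison ranks with per-dataset and pooled summaries."""

    ranks: pd.DataFrame                     # methods × comparisons
    per_dataset: pd.DataFrame               # columns: mean, se, n
    pooled: pd.DataFrame | None = None      # columns: mean, se, df
    test: str = "t"
    flags: dict[str, list[str]] = field(default_factory=dict)


def rank_by_auc(aucs: Mapping[str, float]) -> tuple[dict[str, float], list[str]]:
    """Rank methods by AUC (1 = highest); tied AUCs share average ranks.

    A missing AUC ranks the method last; such methods are returned in the
    flag list.
    """
    if len(aucs) < 2:
        raise ProtNormError("need at least 2 methods to rank")
    methods = list(aucs)
    values = np.array([aucs[m] for m in methods], dtype=float)
    flagged = [m for m, v in zip(methods, values) if np.isnan(v)]
    filled = np.where(np.isnan(values), -np.inf, values)
    ranks = stats.rankdata(-filled, method="average")
    return dict(zip(methods, ranks.astype(float))), flagged


def summarize_ranks(ranks: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Mean rank and SE = SD/sqrt(n) over comparisons, per method.

    With a single comparison the SE is undefined and reported missing.
    """
    rows = {}
    for method, r in ranks.items():
        r = np.asarray(r, dtype=float)
        n = r.size
        if n == 0:
            raise ProtNormError(f"method {method!r} has no ranks")
        se = float(r.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        rows[method] = {"mean": float(r.mean()), "se": se, "n": n}
    return pd.DataFrame.from_dict(rows, orient="index")


def pool_ranks_satterthwaite(
    per_dataset: Sequence[tuple[float, float, int]],
) -> tuple[float, float, float]:
    """Pool per-dataset (mean rank, SE, n_comparisons) across datasets.

    The pooled mean weights dataset means by their comparison counts; the
    pooled variance is the Satterthwaite combination of the weighted
    per-dataset variances, with effective degrees of freedom

        ν = (Σ wᵢ² seᵢ²)² / Σ (wᵢ² seᵢ²)² / (nᵢ − 1).

    Returns (pooled mean, pooled SE, ν).
    """
    if len(per_dataset) < 2:
        raise ProtNormError("pooling needs at least 2 datasets")
    means = np.array([d[0] for d in per_dataset], dtype=float)
    ses = np.array([d[1] for d in per_dataset], dtype=float)
    ns = np.array([d[2] for d in per_dataset], dtype=float)
    if np.any(ns < 1):
        raise ProtNormError("a dataset has zero comparisons")
    w = ns / ns.sum()
    pooled_mean = float(np.sum(w * means))
    terms = w**2 * ses**2
    pooled_var = float(terms.sum())
    denom_terms = terms**2 / np.maximum(ns - 1, 1)
    if terms.sum() == 0:
        nu = float("inf")
    else:
        denom = denom_terms.sum()
        nu = float(terms.sum() ** 2 / denom) if denom > 0 else float("inf")
    return pooled_mean, float(np.sqrt(pooled_var)), nu


def build_rank_table(auc_table: pd.DataFrame, test: str = "t") -> RankTable:
    """Build a RankTable from a methods × comparisons AUC grid."""
    ranks = {}
    flags: dict[str, list[str]] = {}
    for comp in auc_table.columns:
        r, flagged = rank_by_auc(auc_table[comp].to_dict())
        ranks[comp] = r
        if flagged:
            flags[comp] = flagged
    rank_frame = pd.DataFrame(ranks)
    per_dataset = summarize_ranks({m: rank_frame.loc[m].to_numpy()
                                   for m in rank_frame.index})
    return RankTable(ranks=rank_frame, per_dataset=per_dataset,
                     test=test, flags=flags)


def pool_rank_tables(tables: Sequence[RankTable]) -> pd.DataFrame:
    """Pool per-dataset mean ranks of several RankTables (same methods)."""
    if len(tables) < 2:
        raise ProtNormError("pooling needs at least 2 datasets")
    methods = list(tables[0].per_dataset.index)
    rows = {}
    for m in methods:
        per = [(t.per_dataset.loc[m, "mean"], t.per_dataset.loc[m, "se"],
                int(t.per_dataset.loc[m, "n"])) for t in tables]
        mean, se, nu = pool_ranks_satterthwaite(per)
        rows[m] = {"mean": mean, "se": se, "df": nu}
    return pd.DataFrame.from_dict(rows, orient="index")
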