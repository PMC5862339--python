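"""Intragroup variation and similarity metrics, plus MA/intensity diagnostics.

Technical replicates measure the same sample, so any spread among them is
nonbiological. Three pooled per-protein measures quantify it:

* PMAD — mean over groups of the scaled median absolute deviation
  (consistency constant 1.4826), in log2 units;
* PCV  — mean over groups of the coefficient of variation SD/mean,
  dimensionless (computed on the analysis scale as given);
* PEV  — the (n_g − 1)-weighted pooled variance across groups, in squared
  log2 units.

Replicate similarity is summarized by within-group pairwise Pearson
correlations; method contrasts on per-protein metric vectors use the
two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._loess import LoessSmoother
from .io_model import AbundanceMatrix, ProtNormError, StudyDesign
from .normalization import MAData, ma_transform

__all__ = [
    "IntragroupResult",
    "SimilarityResult",
    "intragroup_variation",
    "intragroup_similarity",
    "paired_metric_test",
    "ma_plot_data",
    "sample_summaries",
]

MAD_CONSTANT = 1.4826


@dataclass
class IntragroupResult:
    metric: str
    per_protein: pd.Series
    summary: dict[str, float]
    dropped_proteins: tuple[str, ...] = ()
    flagged_near_zero_mean: tuple[str, ...] = ()


@dataclass
class SimilarityResult:
    coefficients: list[tuple[str, tuple[str, str], float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g, a, b, r) for g, (a, b), r in self.coefficients],
            columns=["group", "sample_1", "sample_2", "pearson_r"],
        )


def _group_columns(m: AbundanceMatrix, design: StudyDesign) -> dict[str, np.ndarray]:
    design.validate_against(m)
    cols: dict[str, list[int]] = {}
    for j, s in enumerate(m.sample_ids):
        cols.setdefault(design.groups[s], []).append(j)
    return {g: np.asarray(idx) for g, idx in cols.items()}


def intragroup_variation(m: AbundanceMatrix, design: StudyDesign,
                         metric: str = "PMAD") -> IntragroupResult:
    """Pooled per-protein replicate variation (PMAD, PCV or PEV).

    Proteins lacking two non-missing observations in any group are dropped
    and reported in ``dropped_proteins``.
    """
    metric = metric.upper()
    if metric not in ("PMAD", "PCV", "PEV"):
        raise ProtNormError(f"unknown metric {metric!r}")
    cols = _group_columns(m, design)
    for g, idx in cols.items():
        if idx.size < 2:
            raise ProtNormError(f"group {g!r} has a single sample")

    V = m.values
    per_group_stats = []
    counts = []
    for g, idx in cols.items():
        block = V[:, idx]
        n_obs = np.sum(~np.isnan(block), axis=1)
        counts.append(n_obs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if metric == "PMAD":
                med = np.nanmedian(block, axis=1, keepdims=True)
                stat = MAD_CONSTANT * np.nanmedian(np.abs(block - med), axis=1)
            elif metric == "PCV":
                stat = np.nanstd(block, axis=1, ddof=1) / np.nanmean(block, axis=1)
            else:  # PEV: per-group (n-1)-weighted variance, pooled later
                stat = np.nanvar(block, axis=1, ddof=1)
        per_group_stats.append(stat)
    counts = np.column_stack(counts)
    stats_arr = np.column_stack(per_group_stats)

    keep = np.all(counts >= 2, axis=1)
    flagged: list[str] = []
    if metric == "PEV":
        w = counts - 1
        per_protein = np.sum(w * stats_arr, axis=1) / np.sum(w, axis=1)
    else:
        per_protein = np.mean(stats_arr, axis=1)
        if metric == "PCV":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                group_means = [np.nanmean(V[:, idx], axis=1)
                               for idx in cols.values()]
            near_zero = np.any(np.abs(np.column_stack(group_means)) < 1e-6, axis=1)
            flagged = [p for p, nz, k in zip(m.protein_ids, near_zero, keep) if nz and k]

    series = pd.Series(per_protein[keep],
                       index=[p for p, k in zip(m.protein_ids, keep) if k],
                       name=metric)
    if metric != "PCV":
        series = series.abs()  # numerically tiny negatives from nanvar
    summary = {
        "median": float(series.median()),
        "q1": float(series.quantile(0.25)),
        "q3": float(series.quantile(0.75)),
        "n_proteins": int(series.size),
    }
    dropped = tuple(p for p, k in zip(m.protein_ids, keep) if not k)
    return IntragroupResult(metric=metric, per_protein=series, summary=summary,
                            dropped_proteins=dropped,
                            flagged_near_zero_mean=tuple(flagged))


def intragroup_similarity(m: AbundanceMatrix, design: StudyDesign) -> SimilarityResult:
    """Pearson correlation for every within-group replicate pair."""
    cols = _group_columns(m, design)
    result = SimilarityResult()
    for g, idx in cols.items():
        if idx.size < 2:
            raise ProtNormError(f"group {g!r} has a single sample")
        for ai in range(idx.size):
            for bi in range(ai + 1, idx.size):
                x = m.values[:, idx[ai]]
                y = m.values[:, idx[bi]]
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 3:
                    raise ProtNormError(
                        f"pair ({m.sample_ids[idx[ai]]}, {m.sample_ids[idx[bi]]}) "
                        "shares fewer than 3 proteins")
                r = float(stats.pearsonr(x[ok], y[ok]).statistic)
                result.coefficients.append(
                    (g, (m.sample_ids[idx[ai]], m.sample_ids[idx[bi]]), r))
    return result


def paired_metric_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired metric vectors.

    Zero differences are dropped. If every difference is zero the test is
    uninformative: returns statistic 0 and p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ProtNormError("paired vectors must have equal length")
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size == 0:
        raise ProtNormError("no paired observations")
    diffs = a - b
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; test is uninformative")
        return 0.0, 1.0
    method = "exact" if np.count_nonzero(diffs) <= 25 else "auto"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(a, b, zero_method="wilcox",
                             alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class MAPlotData:
    ma: MAData
    curve_a: np.ndarray
    curve_m: np.ndarray
    labels: np.ndarray | None = None


def ma_plot_data(x: np.ndarray, y: np.ndarray,
                 labels: np.ndarray | None = None,
                 grid_size: int = 200, frac: float = 0.75) -> MAPlotData:
    """MA scatter of two log2 samples plus a loess trend curve on an A-grid."""
    ma = ma_transform(x, y, pairwise=True)
    ok = ~np.isnan(ma.A) & ~np.isnan(ma.M)
    if ok.sum() < 20:
        raise ProtNormError("need at least 20 shared points for an MA plot")
    smoother = LoessSmoother(frac=frac).fit(ma.A[ok], ma.M[ok])
    grid = np.linspace(np.nanmin(ma.A), np.nanmax(ma.A), grid_size)
    return MAPlotData(ma=ma, curve_a=grid, curve_m=smoother.predict(grid),
                      labels=None if labels is None else np.asarray(labels))


def sample_summaries(m: AbundanceMatrix) -> pd.DataFrame:
    """Per-sample total, median and non-missing count (any scale)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        totals = np.nansum(m.values, axis=0)
        medians = np.nanmedian(m.values, axis=0)
    counts = np.sum(~np.isnan(m.values), axis=0)
    return pd.DataFrame(
        {"total": totals, "median": medians, "n_observed": counts},
        index=list(m.sample_ids),
    )
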