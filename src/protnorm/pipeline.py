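"""Benchmark orchestration: normalize, evaluate, rank, report.

Two workflow variants are supported. In *global* normalization the whole
multi-group matrix is normalized at once and the compared groups are then
subset; in *pairwise* normalization the two groups under comparison are
first extracted from the unnormalized data and preprocessed and normalized
on their own. All methods receive log2 input except ``vsn``, which always
receives raw intensities.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import eigenms, vsn  # noqa: F401  (populate the method registry)
from .diffexpr import ComparisonResult, RocResult, roc_auc, rots_test, t_test_two_group
from .io_model import (
    AbundanceMatrix,
    ProtNormError,
    StudyDesign,
    log2_transform,
    preprocess_zeros,
    write_abundance_table,
)
from .logfc import LogFCSummary, compute_logfc, logfc_summary, theoretical_logfc
from .metrics import intragroup_variation
from .normalization import METHOD_REGISTRY, NormalizationResult, normalize
from .ranking import RankTable, build_rank_table

logger = logging.getLogger("protnorm")

__all__ = ["BenchmarkConfig", "BenchmarkResult", "run_normalization",
           "run_benchmark", "generate_report"]

ALL_METHODS = ("log2", "median", "quantile", "rlr", "rlr_ma", "rlr_ma_cyclic",
               "loess_f", "loess_cyc", "vsn", "progenesis", "eigenms")


@dataclass
class BenchmarkConfig:
    methods: tuple[str, ...] = ALL_METHODS
    comparisons: tuple[tuple[str, str], ...] | None = None  # None = all pairs
    mode: str = "global"
    test: str = "t"
    seed: int = 17
    rots_B: int = 100
    variation_metrics: tuple[str, ...] = ("PMAD", "PCV", "PEV")

    def __post_init__(self) -> None:
        if not self.methods:
            raise ProtNormError("methods must be nonempty")
        if self.mode not in ("global", "pairwise"):
            raise ProtNormError("mode must be 'global' or 'pairwise'")
        if self.test not in ("t", "rots"):
            raise ProtNormError("test must be 't' or 'rots'")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ProtNormError(f"unknown methods: {sorted(unknown)}")


def _prepare(m_raw: AbundanceMatrix, method: str) -> AbundanceMatrix:
    """Preprocess raw input for one method: zeros → NA, then log2 except vsn."""
    cleaned = preprocess_zeros(m_raw)
    return cleaned if method == "vsn" else log2_transform(cleaned)


def run_normalization(m_raw: AbundanceMatrix, design: StudyDesign, method: str,
                      mode: str = "global",
                      comparison: tuple[str, str] | None = None,
                      seed: int = 17) -> NormalizationResult:
    """Normalize raw input with one method in global or pairwise mode.

    Global mode normalizes all samples, then subsets to the comparison (if
    one is given); pairwise mode subsets the two comparison groups from the
    raw data first, then preprocesses and normalizes the subset.
    """
    if m_raw.scale != "raw":
        raise ProtNormError("run_normalization expects raw-scale input")
    if mode == "pairwise":
        if comparison is None:
            raise ProtNormError("pairwise mode requires a comparison")
        samples = [s for s in m_raw.sample_ids
                   if design.groups.get(s) in comparison]
        m_sub = m_raw.subset_samples(samples)
        design_sub = design.subset(comparison)
        prepared = _prepare(m_sub, method)
        kwargs = {"random_state": seed} if method == "eigenms" else {}
        result = normalize(prepared, method, design=design_sub, **kwargs)
        result.mode = "pairwise"
        return result
    prepared = _prepare(m_raw, method)
    kwargs = {"random_state": seed} if method == "eigenms" else {}
    result = normalize(prepared, method, design=design, **kwargs)
    if comparison is not None:
        samples = [s for s in result.matrix.sample_ids
                   if design.groups.get(s) in comparison]
        result.matrix = result.matrix.subset_samples(samples)
    result.mode = "global"
    return result


@dataclass
class BenchmarkResult:
    config: BenchmarkConfig
    normalized: dict[str, NormalizationResult] = field(default_factory=dict)
    variation: dict[tuple[str, str], pd.Series] = field(default_factory=dict)
    variation_summary: dict[tuple[str, str], dict] = field(default_factory=dict)
    comparisons: dict[tuple[str, tuple[str, str]], ComparisonResult] = field(default_factory=dict)
    rocs: dict[tuple[str, tuple[str, str]], RocResult] = field(default_factory=dict)
    logfc: dict[tuple[str, tuple[str, str]], LogFCSummary] = field(default_factory=dict)
    auc_table: pd.DataFrame | None = None
    rank_table: RankTable | None = None
    errors: dict[str, str] = field(default_factory=dict)
    has_truth: bool = True


def run_benchmark(m_raw: AbundanceMatrix, design: StudyDesign,
                  config: BenchmarkConfig) -> BenchmarkResult:
    """Run the full method × comparison benchmark on one dataset.

    Without spike truth the differential-expression and logFC stages are
    skipped with a notice and only variation metrics are computed. Stage
    errors are recorded per (method, comparison) and the benchmark
    continues.
    """
    design.validate_against(m_raw, require_groups_of=2)
    groups = design.group_labels
    comparisons = (config.comparisons if config.comparisons is not None
                   else tuple(combinations(groups, 2)))
    for g1, g2 in comparisons:
        if g1 not in groups or g2 not in groups:
            raise ProtNormError(f"comparison ({g1}, {g2}) references unknown groups")
    has_truth = bool(design.spike_truth) and any(design.spike_truth.values())
    result = BenchmarkResult(config=config, has_truth=has_truth)
    if not has_truth:
        logger.info("no spike-in truth: differential expression and logFC "
                    "stages skipped; variation metrics only")

    auc: dict[str, dict[str, float]] = {}
    for method in config.methods:
        t0 = time.perf_counter()
        # global normalization once per method; pairwise inside the loop
        norm_full: NormalizationResult | None = None
        if config.mode == "global":
            try:
                norm_full = run_normalization(m_raw, design, method,
                                              mode="global", seed=config.seed)
                result.normalized[method] = norm_full
            except Exception as exc:  # noqa: BLE001 - isolate per method
                result.errors[f"{method}/normalize"] = repr(exc)
                continue
            for metric in config.variation_metrics:
                try:
                    ig = intragroup_variation(norm_full.matrix, design, metric)
                    result.variation[(method, metric)] = ig.per_protein
                    result.variation_summary[(method, metric)] = ig.summary
                except Exception as exc:  # noqa: BLE001
                    result.errors[f"{method}/variation/{metric}"] = repr(exc)

        auc[method] = {}
        for comp in comparisons:
            key = (method, comp)
            try:
                if config.mode == "pairwise":
                    norm = run_normalization(m_raw, design, method,
                                             mode="pairwise", comparison=comp,
                                             seed=config.seed)
                else:
                    norm = NormalizationResult(
                        matrix=norm_full.matrix.subset_samples(
                            [s for s in norm_full.matrix.sample_ids
                             if design.groups[s] in comp]),
                        method=method, mode="global",
                        diagnostics=norm_full.diagnostics)
                if config.mode == "pairwise":
                    result.normalized.setdefault(method, norm)
                if not has_truth:
                    continue
                sub_design = design.subset(comp)
                if config.test == "rots":
                    cmp_res = rots_test(norm.matrix, sub_design, comp[0], comp[1],
                                        B=config.rots_B, seed=config.seed,
                                        method=method)
                else:
                    cmp_res = t_test_two_group(norm.matrix, sub_design,
                                               comp[0], comp[1], method=method)
                result.comparisons[key] = cmp_res
                truth = np.array([design.spike_truth[p]
                                  for p in norm.matrix.protein_ids])
                roc = roc_auc(cmp_res.scores.to_numpy(), truth)
                result.rocs[key] = roc
                auc[method]["_vs_".join(comp)] = roc.auc
                lfc = compute_logfc(norm.matrix, sub_design, comp[0], comp[1])
                theo = None
                try:
                    theo = theoretical_logfc(design, comp[0], comp[1])
                except ProtNormError:
                    pass
                result.logfc[key] = logfc_summary(
                    lfc, dict(design.spike_truth), theoretical=theo)
            except Exception as exc:  # noqa: BLE001 - isolate per combination
                result.errors[f"{method}/{'_vs_'.join(comp)}"] = repr(exc)
        logger.info("method %s done in %.2fs", method, time.perf_counter() - t0)

    if has_truth:
        auc_table = pd.DataFrame(auc).T  # methods × comparisons
        auc_table = auc_table.reindex(index=list(config.methods))
        result.auc_table = auc_table
        if auc_table.shape[1] >= 1 and auc_table.shape[0] >= 2:
            result.rank_table = build_rank_table(auc_table, test=config.test)
    return result


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _frame_to_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


def generate_report(result: BenchmarkResult, outdir: str | Path,
                    matrices: bool = False) -> Path:
    """Write tidy TSVs plus a JSON summary; deterministic given seeds."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ProtNormError(f"cannot create output directory {outdir}: {exc}")

    cfg = result.config
    summary: dict[str, Any] = {
        "config": {
            "methods": list(cfg.methods),
            "comparisons": (None if cfg.comparisons is None
                            else ["_vs_".join(c) for c in cfg.comparisons]),
            "mode": cfg.mode,
            "test": cfg.test,
            "seed": cfg.seed,
            "rots_B": cfg.rots_B,
            "variation_metrics": list(cfg.variation_metrics),
        },
        "has_truth": result.has_truth,
        "errors": dict(sorted(result.errors.items())),
    }

    rows = []
    for (method, metric), series in sorted(result.variation.items()):
        for pid, value in series.items():
            rows.append((pid, method, metric, value))
    variation = pd.DataFrame(rows, columns=["protein_id", "method", "metric", "value"])
    _frame_to_tsv(variation.set_index("protein_id"), outdir / "variation.tsv")
    summary["variation_summary"] = {
        f"{m}/{k}": v for (m, k), v in sorted(result.variation_summary.items())
    }

    de_rows = []
    for (method, comp), cmp_res in sorted(result.comparisons.items()):
        for pid, row in cmp_res.table.iterrows():
            de_rows.append((pid, "_vs_".join(comp), method, cmp_res.test,
                            row["statistic"], row["p_or_fdr"], row["logfc"]))
    de = pd.DataFrame(de_rows, columns=["protein_id", "comparison", "method",
                                        "test", "statistic", "p_or_fdr", "logfc"])
    _frame_to_tsv(de.set_index("protein_id"), outdir / "differential_expression.tsv")

    auc_rows = [("_vs_".join(comp), method, roc.auc, roc.n_pos, roc.n_neg,
                 roc.n_missing_excluded)
                for (method, comp), roc in sorted(result.rocs.items())]
    aucs = pd.DataFrame(auc_rows, columns=["comparison", "method", "auc",
                                           "n_pos", "n_neg", "n_missing"])
    _frame_to_tsv(aucs.set_index("comparison"), outdir / "auc.tsv")

    if result.rank_table is not None:
        rt = result.rank_table
        _frame_to_tsv(rt.ranks, outdir / f"ranks_{cfg.test}.tsv")
        _frame_to_tsv(rt.per_dataset, outdir / f"rank_summary_{cfg.test}.tsv")

    lfc_rows = []
    for (method, comp), s in sorted(result.logfc.items()):
        lfc_rows.append(("_vs_".join(comp), method, s.background_center,
                         s.background_iqr,
                         np.nan if s.spike_center is None else s.spike_center,
                         np.nan if s.theoretical is None else s.theoretical,
                         np.nan if s.deviation_from_theoretical is None
                         else s.deviation_from_theoretical))
    lfc = pd.DataFrame(lfc_rows, columns=["comparison", "method",
                                          "background_median", "background_iqr",
                                          "spike_median", "theoretical",
                                          "deviation"])
    _frame_to_tsv(lfc.set_index("comparison"), outdir / "logfc_summary.tsv")

    if matrices:
        for method, norm in sorted(result.normalized.items()):
            write_abundance_table(norm.matrix, outdir / f"normalized_{method}.tsv")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return outdir
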