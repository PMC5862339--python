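"""Log fold changes of spike-in and background proteins.

In a spike-in design only the spiked proteins change between groups, with
an expected log2 fold change of log2(c₂/c₁) from the nominal
concentrations; background proteins should sit at logFC 0. Comparing the
observed logFC distributions against these expectations diagnoses both
normalization bias (a shifted background) and effect-size attenuation
(spike logFCs smaller in magnitude than theoretical, a known feature of
label-free spike-in data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import AbundanceMatrix, ProtNormError, StudyDesign

__all__ = [
    "LogFCSummary",
    "compute_logfc",
    "theoretical_logfc",
    "logfc_summary",
    "logfc_density",
]


@dataclass
class LogFCSummary:
    background: pd.Series
    spike: pd.Series
    background_center: float
    background_iqr: float
    spike_center: float | None
    theoretical: float | None
    deviation_from_theoretical: float | None


def compute_logfc(m: AbundanceMatrix, design: StudyDesign,
                  g1: str, g2: str) -> pd.Series:
    """Per-protein logFC = mean(group2) − mean(group1) on the analysis scale.

    Proteins with no observation in either group get a missing logFC.
    """
    design.validate_against(m)
    for g in (g1, g2):
        if g not in design.group_labels:
            raise ProtNormError(f"unknown group label {g!r}")
    idx1 = [j for j, s in enumerate(m.sample_ids) if design.groups[s] == g1]
    idx2 = [j for j, s in enumerate(m.sample_ids) if design.groups[s] == g2]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean1 = np.nanmean(m.values[:, idx1], axis=1)
        mean2 = np.nanmean(m.values[:, idx2], axis=1)
    return pd.Series(mean2 - mean1, index=list(m.protein_ids), name="logfc")


def theoretical_logfc(design: StudyDesign, g1: str, g2: str) -> float:
    """Expected spike logFC, log2(c₂/c₁), from nominal concentrations."""
    for g in (g1, g2):
        if g not in design.concentrations:
            raise ProtNormError(f"no nominal concentration for group {g!r}")
    c1, c2 = design.concentrations[g1], design.concentrations[g2]
    if c1 <= 0 or c2 <= 0:
        raise ProtNormError("concentrations must be positive")
    return float(np.log2(c2 / c1))


def logfc_summary(logfc: pd.Series, truth: dict[str, bool],
                  theoretical: float | None = None) -> LogFCSummary:
    """Split logFCs by spike truth and summarize centers and spread."""
    missing = [p for p in logfc.index if p not in truth]
    if missing:
        raise ProtNormError(f"truth labels missing for proteins: {missing[:5]}")
    observed = logfc.dropna()
    is_spike = np.array([truth[p] for p in observed.index], dtype=bool)
    background = observed[~is_spike]
    spike = observed[is_spike]
    if background.empty:
        raise ProtNormError("no background proteins with a logFC")
    b_center = float(background.median())
    b_iqr = float(background.quantile(0.75) - background.quantile(0.25))
    s_center = float(spike.median()) if not spike.empty else None
    deviation = None
    if theoretical is not None and s_center is not None:
        deviation = s_center - theoretical
    return LogFCSummary(
        background=background, spike=spike,
        background_center=b_center, background_iqr=b_iqr,
        spike_center=s_center, theoretical=theoretical,
        deviation_from_theoretical=deviation)


def logfc_density(values: np.ndarray | pd.Series,
                  grid_size: int = 256) -> pd.DataFrame:
    """Plot-ready kernel density of a logFC vector (Silverman bandwidth)."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 3:
        raise ProtNormError("need at least 3 values for a density")
    if np.ptp(values) == 0:
        grid = np.array([values[0]])
        return pd.DataFrame({"logfc": grid, "density": [np.inf]})
    kde = stats.gaussian_kde(values, bw_method="silverman")
    lo, hi = values.min(), values.max()
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    return pd.DataFrame({"logfc": grid, "density": kde(grid)})
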