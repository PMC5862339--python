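"""Normalization methods for label-free proteomics intensity matrices.

Ten methods plus a plain-log2 baseline, addressable through a uniform
registry::

    log2, median, quantile, rlr, rlr_ma, rlr_ma_cyclic,
    loess_f, loess_cyc, vsn, progenesis, eigenms

All methods except ``vsn`` consume log2-scale matrices and return log2
output; ``vsn`` consumes raw intensities and returns a glog2 matrix.
Methods are implemented as scikit-learn-style transformers operating on
``(n_samples, n_proteins)`` arrays with ``NaN`` for missing values; the
module-level ``normalize_*`` functions are thin wrappers that accept an
:class:`~protnorm.io_model.AbundanceMatrix` and return a
:class:`NormalizationResult`.

Most of these methods share one core idea: express a sample against a
reference through the MA transform (A = average intensity, M = difference),
model the M-vs-A trend — a constant, a robust line or a loess curve — and
subtract it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Any, Callable

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin

from ._loess import LoessSmoother
from .io_model import AbundanceMatrix, ProtNormError, ScaleError, StudyDesign

__all__ = [
    "MAData",
    "NormalizationResult",
    "ma_transform",
    "MedianNormalizer",
    "QuantileNormalizer",
    "RlrNormalizer",
    "LoessNormalizer",
    "ProgenesisNormalizer",
    "normalize_median",
    "normalize_quantile",
    "normalize_linreg",
    "normalize_loess",
    "normalize_progenesis",
    "METHOD_REGISTRY",
    "normalize",
]


# ---------------------------------------------------------------------------
# MA transform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MAData:
    """MA reparameterization of a sample against a reference.

    ``A`` is the per-protein reference/mean intensity and ``M`` the
    difference to it, both in log2 units. Intensity-dependent bias appears
    as a trend of M against A.
    """

    A: np.ndarray
    M: np.ndarray
    pairing: tuple[str, str] = ("sample", "reference")

    def __post_init__(self) -> None:
        if self.A.shape != self.M.shape:
            raise ProtNormError("A and M must have equal length")


def ma_transform(x: np.ndarray, ref: np.ndarray, pairwise: bool = True,
                 pairing: tuple[str, str] = ("sample", "reference")) -> MAData:
    """MA-transform ``x`` against ``ref`` (both log2 vectors).

    pairwise: ``A = (x + ref)/2``, ``M = x - ref`` (two peer samples).
    global: ``A = ref`` (a median/mean reference sample), ``M = x - ref``.
    Positions missing in either input are missing in both A and M.
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ProtNormError(f"length mismatch: {x.shape} vs {ref.shape}")
    miss = np.isnan(x) | np.isnan(ref)
    A = (x + ref) / 2.0 if pairwise else ref.copy()
    M = x - ref
    A = np.where(miss, np.nan, A)
    M = np.where(miss, np.nan, M)
    return MAData(A=A, M=M, pairing=pairing)


@dataclass
class NormalizationResult:
    """A normalized matrix plus the fitted bias parameters that produced it."""

    matrix: AbundanceMatrix
    method: str
    mode: str = "global"
    diagnostics: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# robust line fit (shared by the Rlr variants)
# ---------------------------------------------------------------------------

def _robust_line(x: np.ndarray, y: np.ndarray, max_iter: int = 50,
                 tol: float = 1e-8) -> tuple[float, float]:
    """IRLS Huber line fit (tuning constant 1.345); returns (intercept, slope)."""
    if x.size < 3:
        raise ProtNormError("need at least 3 complete proteins for a line fit")
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    scale = np.median(np.abs(resid - np.median(resid)))
    if scale < 1e-12:
        # noiseless data: least squares is exact, IRLS scale is degenerate
        return float(coef[0]), float(coef[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(
            maxiter=max_iter, tol=tol)
    return float(fit.params[0]), float(fit.params[1])


# ---------------------------------------------------------------------------
# estimator base
# ---------------------------------------------------------------------------

class _MatrixNormalizer(TransformerMixin, BaseEstimator):
    """Base class: fit runs the normalization on X, caching output.

    ``X`` is ``(n_samples, n_proteins)`` with ``NaN`` missing. Several of
    these methods (quantile, the cyclic schemes) are defined on a dataset
    as a whole rather than as a per-sample parametric map, so ``transform``
    re-runs the procedure when handed a matrix other than the fitted one.
    """

    def fit(self, X, y=None):
        V = self._validate(X)
        out, diag = self._normalize(V, y)
        self.n_features_in_ = V.shape[0]
        self.output_ = out.T
        self.diagnostics_ = diag
        self._fitted_input = V
        return self

    def transform(self, X):
        V = self._validate(X)
        cached = getattr(self, "_fitted_input", None)
        if cached is not None and V.shape == cached.shape and \
                np.array_equal(V, cached, equal_nan=True):
            return self.output_.copy()
        out, _ = self._normalize(V, None)
        return out.T

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ProtNormError("X must be 2-D (n_samples, n_proteins)")
        # internal orientation: proteins × samples
        V = X.T.copy()
        if np.all(np.isnan(V), axis=0).any():
            raise ProtNormError("a sample has all values missing")
        return V

    def _normalize(self, V: np.ndarray, y) -> tuple[np.ndarray, dict]:
        raise NotImplementedError


class MedianNormalizer(_MatrixNormalizer):
    """Shift every sample so all medians equal the mean of sample medians."""

    def _normalize(self, V, y):
        medians = np.nanmedian(V, axis=0)
        target = medians.mean()
        shift = target - medians
        return V + shift[None, :], {"shift": shift, "target": float(target),
                                    "medians": medians}


class QuantileNormalizer(_MatrixNormalizer):
    """Force identical intensity distributions across samples.

    Each value is replaced by the across-sample mean of the corresponding
    order statistic; samples with missing values are mapped through rank
    interpolation, and ties within a sample receive the mean of their
    reference values.
    """

    def _normalize(self, V, y):
        n, S = V.shape
        grid = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
        curves = np.empty((S, grid.size))
        for j in range(S):
            vals = np.sort(V[~np.isnan(V[:, j]), j])
            if vals.size == 1:
                curves[j] = vals[0]
            else:
                p = np.arange(vals.size) / (vals.size - 1)
                curves[j] = np.interp(grid, p, vals)
        ref = curves.mean(axis=0)

        out = np.full_like(V, np.nan)
        for j in range(S):
            obs = ~np.isnan(V[:, j])
            vals = V[obs, j]
            nj = vals.size
            order = np.argsort(vals, kind="stable")
            p = np.arange(nj) / (nj - 1) if nj > 1 else np.array([0.5])
            assigned = np.interp(p, grid, ref)
            vs = vals[order]
            uniq, inverse = np.unique(vs, return_inverse=True)
            if uniq.size < nj:  # average reference values over ties
                sums = np.bincount(inverse, weights=assigned)
                counts = np.bincount(inverse)
                assigned = (sums / counts)[inverse]
            col = np.empty(nj)
            col[order] = assigned
            out[obs, j] = col
        return out, {"reference_distribution": ref}


class RlrNormalizer(_MatrixNormalizer):
    """Robust linear regression normalization (Rlr / RlrMA / RlrMACyc).

    The bias is assumed linear in intensity. ``rlr`` robust-fits each
    sample against the per-protein median reference sample and inverts the
    line; ``rlr_ma`` fits M against A (A = median sample) and subtracts the
    fitted line; ``rlr_ma_cyclic`` normalizes every unordered sample pair
    on its own MA transform, moving each sample by half the fitted bias,
    sweeping all pairs for ``n_cycles`` full cycles.
    """

    def __init__(self, variant: str = "rlr", n_cycles: int = 3):
        self.variant = variant
        self.n_cycles = n_cycles

    def _normalize(self, V, y):
        if self.variant not in ("rlr", "rlr_ma", "rlr_ma_cyclic"):
            raise ProtNormError(f"unknown rlr variant {self.variant!r}")
        if V.shape[1] < 2:
            raise ProtNormError("rlr normalization needs at least 2 samples")
        if self.variant == "rlr_ma_cyclic":
            return self._cyclic(V)
        ref = np.nanmedian(V, axis=1)
        out = np.full_like(V, np.nan)
        coefs = np.empty((V.shape[1], 2))
        for j in range(V.shape[1]):
            xj = V[:, j]
            ok = ~np.isnan(xj) & ~np.isnan(ref)
            if ok.sum() < 3:
                raise ProtNormError(f"sample {j}: fewer than 3 complete proteins")
            if self.variant == "rlr":
                a, b = _robust_line(ref[ok], xj[ok])
                if abs(b) < 1e-8:
                    raise ProtNormError(f"sample {j}: estimated slope is zero")
                out[:, j] = (xj - a) / b
            else:  # rlr_ma
                ma = ma_transform(xj, ref, pairwise=False)
                a, b = _robust_line(ma.A[ok], ma.M[ok])
                out[:, j] = xj - (a + b * ref)
            coefs[j] = (a, b)
        return out, {"reference": ref, "coefficients": coefs}

    def _cyclic(self, V):
        out = V.copy()
        S = out.shape[1]
        history = []
        for _ in range(self.n_cycles):
            for i, j in combinations(range(S), 2):
                xi, xj = out[:, i], out[:, j]
                ok = ~np.isnan(xi) & ~np.isnan(xj)
                if ok.sum() < 3:
                    raise ProtNormError(
                        f"pair ({i},{j}): fewer than 3 complete proteins")
                A = (xi + xj) / 2.0
                M = xi - xj
                a, b = _robust_line(A[ok], M[ok])
                fitted = a + b * A
                fitted = np.where(np.isnan(fitted), 0.0, fitted)
                out[:, i] = xi - fitted / 2.0
                out[:, j] = xj + fitted / 2.0
                history.append((i, j, a, b))
        return out, {"pair_fits": history, "n_cycles": self.n_cycles}


class LoessNormalizer(_MatrixNormalizer):
    """Local regression (loess) normalization of the M-vs-A trend.

    ``fast_ref`` smooths each sample's M against the per-protein mean
    reference sample and subtracts the curve, iterating ``n_cycles`` times
    against the recomputed reference; ``cyclic`` smooths and half-corrects
    every sample pair, sweeping all pairs ``n_cycles`` times.
    """

    def __init__(self, variant: str = "fast_ref", frac: float = 0.75,
                 degree: int = 2, robust_iters: int = 3, n_cycles: int = 3,
                 min_points: int = 20):
        self.variant = variant
        self.frac = frac
        self.degree = degree
        self.robust_iters = robust_iters
        self.n_cycles = n_cycles
        self.min_points = min_points

    def _smoother(self):
        return LoessSmoother(frac=self.frac, degree=self.degree,
                             robust_iters=self.robust_iters)

    def _normalize(self, V, y):
        if self.variant not in ("fast_ref", "cyclic"):
            raise ProtNormError(f"unknown loess variant {self.variant!r}")
        out = V.copy()
        trends = []
        if self.variant == "fast_ref":
            for _ in range(self.n_cycles):
                ref = np.nanmean(out, axis=1)
                for j in range(out.shape[1]):
                    xj = out[:, j]
                    ok = ~np.isnan(xj) & ~np.isnan(ref)
                    if ok.sum() < self.min_points:
                        raise ProtNormError(
                            f"sample {j}: fewer than {self.min_points} points")
                    smoother = self._smoother().fit(ref[ok], (xj - ref)[ok])
                    fitted = smoother.predict(ref)
                    fitted = np.where(np.isnan(fitted), 0.0, fitted)
                    out[:, j] = xj - fitted
                    trends.append((j, smoother.grid_x_, smoother.grid_y_))
        else:
            S = out.shape[1]
            for _ in range(self.n_cycles):
                for i, j in combinations(range(S), 2):
                    xi, xj = out[:, i], out[:, j]
                    ok = ~np.isnan(xi) & ~np.isnan(xj)
                    if ok.sum() < self.min_points:
                        raise ProtNormError(
                            f"pair ({i},{j}): fewer than {self.min_points} points")
                    A = (xi + xj) / 2.0
                    M = xi - xj
                    smoother = self._smoother().fit(A[ok], M[ok])
                    fitted = smoother.predict(A)
                    fitted = np.where(np.isnan(fitted), 0.0, fitted)
                    out[:, i] = xi - fitted / 2.0
                    out[:, j] = xj + fitted / 2.0
                    trends.append(((i, j), smoother.grid_x_, smoother.grid_y_))
        return out, {"trends": trends, "n_cycles": self.n_cycles}


class ProgenesisNormalizer(_MatrixNormalizer):
    """Reference-sample scaling normalization (Progenesis-style).

    On the log2 scale the vendor's global scaling factor becomes a
    per-sample shift: the robust location (median) of the per-protein
    differences to a selected reference sample. ``reference="auto"``
    selects the sample with the highest mean pairwise Pearson correlation.
    """

    def __init__(self, reference: int | str = "auto"):
        self.reference = reference

    def _normalize(self, V, y):
        S = V.shape[1]
        if self.reference == "auto":
            import pandas as pd
            corr = pd.DataFrame(V).corr(min_periods=3).to_numpy()
            np.fill_diagonal(corr, np.nan)
            mean_corr = np.nanmean(corr, axis=1)
            ref_idx = int(np.nanargmax(mean_corr))
        else:
            ref_idx = int(self.reference)
        ref = V[:, ref_idx]
        shifts = np.empty(S)
        for j in range(S):
            ok = ~np.isnan(ref) & ~np.isnan(V[:, j])
            if not ok.any():
                raise ProtNormError(
                    f"sample {j} shares no proteins with the reference")
            shifts[j] = np.median(ref[ok] - V[ok, j])
        shifts[ref_idx] = 0.0
        return V + shifts[None, :], {"reference_index": ref_idx, "shift": shifts}


# ---------------------------------------------------------------------------
# AbundanceMatrix wrappers
# ---------------------------------------------------------------------------

def _require_log2(m: AbundanceMatrix, op: str) -> None:
    if m.scale != "log2":
        raise ScaleError(f"{op} expects a log2-scale matrix, got {m.scale!r}")


def _wrap(m: AbundanceMatrix, est: _MatrixNormalizer, method: str,
          scale: str | None = None, mode: str = "global") -> NormalizationResult:
    out = est.fit(m.values.T).output_.T
    matrix = m.with_values(out, scale=scale)
    return NormalizationResult(matrix=matrix, method=method, mode=mode,
                               diagnostics=est.diagnostics_)


def normalize_median(m: AbundanceMatrix) -> NormalizationResult:
    _require_log2(m, "median normalization")
    return _wrap(m, MedianNormalizer(), "median")


def normalize_quantile(m: AbundanceMatrix) -> NormalizationResult:
    _require_log2(m, "quantile normalization")
    return _wrap(m, QuantileNormalizer(), "quantile")


def normalize_linreg(m: AbundanceMatrix, variant: str = "rlr") -> NormalizationResult:
    _require_log2(m, "linear regression normalization")
    return _wrap(m, RlrNormalizer(variant=variant), variant)


def normalize_loess(m: AbundanceMatrix, variant: str = "fast_ref") -> NormalizationResult:
    _require_log2(m, "loess normalization")
    name = "loess_f" if variant == "fast_ref" else "loess_cyc"
    return _wrap(m, LoessNormalizer(variant=variant), name)


def normalize_progenesis(m: AbundanceMatrix,
                         reference: int | str = "auto") -> NormalizationResult:
    _require_log2(m, "progenesis normalization")
    return _wrap(m, ProgenesisNormalizer(reference=reference), "progenesis")


def _normalize_log2_passthrough(m: AbundanceMatrix) -> NormalizationResult:
    """The log2 baseline: no correction beyond the log2 transform itself."""
    _require_log2(m, "log2 baseline")
    return NormalizationResult(matrix=m.with_values(m.values.copy()),
                               method="log2", diagnostics={})


# registry; vsn/eigenms live in their own modules and are registered there
MethodFn = Callable[..., NormalizationResult]
METHOD_REGISTRY: dict[str, MethodFn] = {
    "log2": _normalize_log2_passthrough,
    "median": normalize_median,
    "quantile": normalize_quantile,
    "rlr": lambda m, **kw: normalize_linreg(m, variant="rlr"),
    "rlr_ma": lambda m, **kw: normalize_linreg(m, variant="rlr_ma"),
    "rlr_ma_cyclic": lambda m, **kw: normalize_linreg(m, variant="rlr_ma_cyclic"),
    "loess_f": lambda m, **kw: normalize_loess(m, variant="fast_ref"),
    "loess_cyc": lambda m, **kw: normalize_loess(m, variant="cyclic"),
    "progenesis": lambda m, **kw: normalize_progenesis(m),
}


def normalize(m: AbundanceMatrix, method: str,
              design: StudyDesign | None = None, **kwargs) -> NormalizationResult:
    """Run a registered normalization method by name.

    ``vsn`` expects a raw-scale matrix, every other method log2.
    ``eigenms`` additionally requires ``design`` for its group labels.
    """
    from . import eigenms, vsn  # noqa: F401  (registers their methods)
    if method not in METHOD_REGISTRY:
        raise ProtNormError(
            f"unknown method {method!r}; available: {sorted(METHOD_REGISTRY)}")
    fn = METHOD_REGISTRY[method]
    if method == "eigenms":
        if design is None:
            raise ProtNormError("eigenms requires a study design")
        return fn(m, design, **kwargs)
    return fn(m, **kwargs)
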