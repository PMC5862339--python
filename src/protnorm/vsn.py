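"""Variance-stabilizing normalization (arsinh / generalized-log transform).

Model: raw intensity for protein i in sample s follows an
additive–multiplicative error model, and the per-sample transform

    h_s(y) = arsinh(a_s + b_s * y),          b_s > 0

maps it to a scale on which the variance no longer depends on the mean.
At high intensity (b_s·y >> 1) the transform is log-like,
h_s(y)/ln2 ≈ log2(y) + log2(2 b_s), so the output is reported in glog2
units and is directly comparable to log2 data up to a per-sample constant.

The per-sample parameters (a_s, b_s) are estimated by robust maximum
likelihood: the per-protein means and error variance are profiled out of a
Gaussian likelihood (with the Jacobian of the transform), and a
least-trimmed-squares outer loop drops the worst-fitting fraction of
proteins — differentially abundant proteins must not drive the calibration.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .io_model import AbundanceMatrix, ScaleError
from .normalization import (
    METHOD_REGISTRY,
    NormalizationResult,
    _MatrixNormalizer,
)

__all__ = ["VsnNormalizer", "normalize_vsn"]

_LN2 = np.log(2.0)


# floor on the profiled error variance (arsinh-scale units²); keeps the
# likelihood bounded on noiseless input without distorting noisy fits
_VAR_FLOOR = 1e-12


def _profile_nll(params: np.ndarray, Y: np.ndarray,
                 row_mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative profile log-likelihood and its gradient over kept rows.

    params = [a_1..a_S, log b_1..log b_S]; Y is proteins × samples raw.
    The per-protein means and the error variance are profiled out; the
    Jacobian of h keeps the likelihood comparable across (a, b). Rows with
    fewer than two observations carry no replicate information and enter
    only through the Jacobian when nothing else is available (degenerate
    single-sample input), where the likelihood reduces to the log-limit.
    """
    S = Y.shape[1]
    a = params[:S]
    logb = params[S:]
    b = np.exp(logb)
    Z = a[None, :] + Y * b[None, :]
    H = np.arcsinh(Z)
    obs = ~np.isnan(H)
    keep = obs & row_mask[:, None]
    n_obs = keep.sum(axis=1)
    keep_rss = keep & (n_obs >= 2)[:, None]
    N = int(keep_rss.sum())
    jac_mask = keep_rss if N >= 2 else (obs & row_mask[:, None])
    if jac_mask.sum() < 1:
        return np.inf, np.zeros_like(params)

    grad = np.zeros_like(params)
    one_pz2 = 1.0 + Z**2
    dH_da = np.where(jac_mask | keep_rss, 1.0 / np.sqrt(one_pz2), 0.0)
    Yb = np.where(obs, Y, 0.0) * b[None, :]

    f = 0.0
    if N >= 2:
        mu = np.sum(np.where(keep_rss, H, 0.0), axis=1) / np.maximum(
            keep_rss.sum(axis=1), 1)
        resid = np.where(keep_rss, H - mu[:, None], 0.0)
        rss = float(np.sum(resid**2))
        if rss / N > _VAR_FLOOR:
            f += 0.5 * N * np.log(rss / N)
            # d rss/d theta_s touches sample-s cells only; the mu term cancels
            scale = N / rss
            grad[:S] += scale * np.sum(resid * dH_da, axis=0)
            grad[S:] += scale * np.sum(resid * dH_da * Yb, axis=0)
        else:
            f += 0.5 * N * np.log(_VAR_FLOOR)

    # -sum log h' = -sum(log b - 0.5 log(1+Z^2))
    logjac = np.where(jac_mask, logb[None, :] - 0.5 * np.log1p(Z**2), 0.0)
    f -= float(np.sum(logjac))
    zz = np.where(jac_mask, Z / one_pz2, 0.0)
    grad[:S] += np.sum(zz, axis=0)
    grad[S:] += np.sum(zz * Yb, axis=0) - jac_mask.sum(axis=0)
    return f, grad


def _row_rss(params: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Mean squared residual per protein row under the current transform."""
    S = Y.shape[1]
    a, b = params[:S], np.exp(params[S:])
    H = np.arcsinh(a[None, :] + Y * b[None, :])
    obs = ~np.isnan(H)
    n = obs.sum(axis=1)
    mu = np.nansum(np.where(obs, H, 0.0), axis=1) / np.maximum(n, 1)
    resid = np.where(obs, H - mu[:, None], 0.0)
    out = np.sum(resid**2, axis=1) / np.maximum(n - 1, 1)
    out[n < 2] = np.inf
    return out


class VsnNormalizer(_MatrixNormalizer):
    """Variance stabilization transformer (raw intensities in, glog2 out).

    Parameters
    ----------
    lts_fraction : float
        Fraction of proteins kept by the least-trimmed-squares outer loop.
    max_outer : int
        Maximum trimming/refit alternations.
    tol : float
        Convergence threshold on the parameter change between alternations.
    """

    def __init__(self, lts_fraction: float = 0.9, max_outer: int = 10,
                 tol: float = 1e-8, max_iter: int = 200):
        self.lts_fraction = lts_fraction
        self.max_outer = max_outer
        self.tol = tol
        self.max_iter = max_iter

    def _normalize(self, V, y):
        Y = V  # proteins × samples, raw scale
        finite = Y[~np.isnan(Y)]
        if finite.size and np.any(finite < 0):
            raise ScaleError("vsn expects non-negative raw intensities")
        n, S = Y.shape

        obs = ~np.isnan(Y)
        if not np.any(obs.sum(axis=1) >= 2):
            # no replicate information at all (single usable sample): the
            # likelihood is unidentified; fall back to a pure glog with the
            # linear region below the smallest observed intensity
            a = np.zeros(S)
            b = np.empty(S)
            for j in range(S):
                vals = Y[obs[:, j], j]
                pos = vals[vals > 0]
                b[j] = 100.0 / pos.min() if pos.size else 1.0
            H = np.arcsinh(a[None, :] + Y * b[None, :]) / _LN2
            return H, {"a": a, "b": b, "converged": True,
                       "trimmed_fraction": 0.0, "degenerate": True}

        # moment-based starting values: put the transform's linear→log
        # crossover near the lower quartile of each sample
        a0 = np.zeros(S)
        logb0 = np.empty(S)
        for j in range(S):
            vals = Y[~np.isnan(Y[:, j]), j]
            q = np.quantile(vals[vals > 0], 0.25) if np.any(vals > 0) else 1.0
            logb0[j] = -np.log(max(q, 1e-12))
        params = np.concatenate([a0, logb0])
        bounds = [(None, None)] * S + [(lb - 30.0, lb + 30.0) for lb in logb0]

        row_mask = np.ones(n, dtype=bool)
        converged = False
        n_keep = max(2, int(np.floor(self.lts_fraction * n)))
        for _ in range(self.max_outer):
            res = minimize(
                _profile_nll, params, args=(Y, row_mask), method="L-BFGS-B",
                jac=True, bounds=bounds, options={"maxiter": self.max_iter})
            new_params = res.x
            delta = float(np.max(np.abs(new_params - params)))
            params = new_params
            rss = _row_rss(params, Y)
            order = np.argsort(rss, kind="stable")
            new_mask = np.zeros(n, dtype=bool)
            new_mask[order[:n_keep]] = True
            if delta < self.tol or (delta < 1e-6 and np.array_equal(new_mask, row_mask)):
                converged = True
                break
            row_mask = new_mask
        if not converged and delta >= 1e-3:
            import warnings
            warnings.warn("vsn optimizer did not fully converge; "
                          "returning best parameters found", RuntimeWarning)

        a, b = params[:S], np.exp(params[S:])
        H = np.arcsinh(a[None, :] + Y * b[None, :]) / _LN2
        return H, {"a": a, "b": b, "converged": converged,
                   "trimmed_fraction": 1.0 - n_keep / n}


def normalize_vsn(m: AbundanceMatrix, **kwargs) -> NormalizationResult:
    """Variance stabilization of a raw matrix; output on the glog2 scale.

    This is the one method that consumes untransformed intensities: the
    arsinh transform itself plays the role of the log transform.
    """
    if m.scale != "raw":
        raise ScaleError(f"vsn expects a raw-scale matrix, got {m.scale!r}")
    est = VsnNormalizer(**kwargs)
    out = est.fit(m.values.T).output_.T
    matrix = m.with_values(out, scale="glog2")
    return NormalizationResult(matrix=matrix, method="vsn",
                               diagnostics=est.diagnostics_)


METHOD_REGISTRY["vsn"] = normalize_vsn
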