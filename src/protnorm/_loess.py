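"""Local polynomial (loess) smoother used for MA-trend normalization.

Degree-2 local polynomial with tricube neighborhood weights and bisquare
robustness iterations. For speed the fit is evaluated on a quantile grid of
the predictor and linearly interpolated to arbitrary points, the same
shortcut classical implementations expose via a ``delta`` parameter.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LoessSmoother", "loess_fit"]


class LoessSmoother:
    """Fit M ~ A with a robust local polynomial.

    Parameters
    ----------
    frac : float
        Fraction of points in each local neighborhood (span).
    degree : int
        Local polynomial degree (0, 1 or 2).
    robust_iters : int
        Number of bisquare reweighting iterations after the initial fit.
    grid_size : int
        Number of quantile-spaced evaluation points; predictions elsewhere
        are linear interpolations.
    """

    def __init__(self, frac: float = 0.75, degree: int = 2,
                 robust_iters: int = 3, grid_size: int = 128) -> None:
        if not 0 < frac <= 1:
            raise ValueError("frac must be in (0, 1]")
        if degree not in (0, 1, 2):
            raise ValueError("degree must be 0, 1 or 2")
        self.frac = frac
        self.degree = degree
        self.robust_iters = robust_iters
        self.grid_size = grid_size

    def fit(self, x: np.ndarray, y: np.ndarray) -> "LoessSmoother":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        n = x.size
        if n < 3:
            raise ValueError("need at least 3 finite points to smooth")
        if np.ptp(x) == 0:
            raise ValueError("degenerate predictor: all A values equal")
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]

        # quantile-spaced evaluation grid over the observed range
        g = min(self.grid_size, n)
        qpos = np.linspace(0, n - 1, g).astype(int)
        grid = np.unique(xs[qpos])
        g = grid.size

        k = max(self.degree + 2, int(np.ceil(self.frac * n)))
        k = min(k, n)

        # contiguous k-nearest windows on sorted x for every grid point
        left = np.searchsorted(xs, grid, side="left")
        starts = np.clip(left - k // 2, 0, n - k)
        # slide each window to the true k-NN position
        for idx in range(g):
            s = starts[idx]
            while s > 0 and grid[idx] - xs[s - 1] < xs[s + k - 1] - grid[idx]:
                s -= 1
            while s + k < n and xs[s + k] - grid[idx] < grid[idx] - xs[s]:
                s += 1
            starts[idx] = s

        win = starts[:, None] + np.arange(k)[None, :]          # (g, k)
        xw = xs[win]
        yw = ys[win]
        d = np.abs(xw - grid[:, None])
        h = np.maximum(d.max(axis=1, keepdims=True), 1e-12)
        w = (1 - (d / h) ** 3) ** 3
        w = np.clip(w, 0, None)

        robust = np.ones(n)
        fitted_grid = np.zeros(g)
        for it in range(self.robust_iters + 1):
            wr = w * robust[win]
            fitted_grid = self._solve(grid, xw, yw, wr)
            if it == self.robust_iters:
                break
            resid = ys - np.interp(xs, grid, fitted_grid)
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            u = resid / (6.0 * s)
            robust = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)

        self.grid_x_ = grid
        self.grid_y_ = fitted_grid
        return self

    def _solve(self, grid: np.ndarray, xw: np.ndarray, yw: np.ndarray,
               w: np.ndarray) -> np.ndarray:
        dx = xw - grid[:, None]
        p = self.degree
        # weighted normal equations per grid point, built from moments
        nb = p + 1
        A = np.empty((grid.size, nb, nb))
        b = np.empty((grid.size, nb))
        pows = [np.ones_like(dx)]
        for m in range(1, 2 * p + 1):
            pows.append(pows[-1] * dx)
        for r in range(nb):
            b[:, r] = np.sum(w * pows[r] * yw, axis=1)
            for c in range(nb):
                A[:, r, c] = np.sum(w * pows[r + c], axis=1)
        # ridge jitter keeps near-singular windows (constant y, few points) stable
        A += 1e-10 * np.eye(nb)
        coef = np.linalg.solve(A, b[..., None])[..., 0]
        return coef[:, 0]

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, np.nan)
        ok = np.isfinite(x)
        out[ok] = np.interp(x[ok], self.grid_x_, self.grid_y_)
        return out


def loess_fit(x: np.ndarray, y: np.ndarray, eval_x: np.ndarray | None = None,
              frac: float = 0.75, degree: int = 2,
              robust_iters: int = 3) -> np.ndarray:
    """Convenience wrapper: fit y ~ x and predict at ``eval_x`` (default x)."""
    sm = LoessSmoother(frac=frac, degree=degree, robust_iters=robust_iters).fit(x, y)
    return sm.predict(x if eval_x is None else eval_x)
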