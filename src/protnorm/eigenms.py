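"""EigenMS-style bias removal: SVD of ANOVA residuals with a permutation test.

The treatment-group effect is estimated first (per-protein group means) so
that removing systematic trends cannot erase true biology. The residual
matrix is then decomposed by SVD; singular vectors whose singular value is
larger than expected under a within-sample permutation null are treated as
systematic (nonbiological) trends and subtracted. When no trend is
significant the data are returned untouched — in particular, per-sample
total intensities equal those of the log2 input, which is a signature of
this method among the normalizations here.

Trend estimation uses only proteins observed in every sample; proteins
with missing values pass through unchanged (their indices are reported in
the diagnostics).
"""

from __future__ import annotations

import numpy as np

from .io_model import AbundanceMatrix, ProtNormError, ScaleError, StudyDesign
from .normalization import METHOD_REGISTRY, NormalizationResult

__all__ = ["EigenMSNormalizer", "normalize_eigenms"]


class EigenMSNormalizer:
    """Fit/transform interface for EigenMS bias removal.

    ``fit(X, y)`` expects ``X`` of shape (n_samples, n_proteins) and ``y``
    a group label per sample.

    Parameters
    ----------
    alpha : float
        Significance level of the sequential permutation test on singular
        values.
    n_permutations : int
        Number of within-sample permutations of the residual matrix per
        tested trend.
    random_state : int
        Seed for the permutation draws.
    """

    def __init__(self, alpha: float = 0.05, n_permutations: int = 99,
                 random_state: int = 17):
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.random_state = random_state

    # sklearn-compatible surface
    def get_params(self, deep=True):
        return {"alpha": self.alpha, "n_permutations": self.n_permutations,
                "random_state": self.random_state}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        V = np.asarray(X, dtype=float).T  # proteins × samples
        groups = np.asarray(y)
        n, S = V.shape
        if S < 3:
            raise ProtNormError("eigenms needs at least 3 samples")
        if groups.shape[0] != S:
            raise ProtNormError("one group label per sample required")
        labels, inverse = np.unique(groups, return_inverse=True)
        counts = np.bincount(inverse)
        if np.any(counts < 2):
            raise ProtNormError("every group needs at least 2 samples")

        complete = ~np.isnan(V).any(axis=1)
        C = V[complete]
        if C.shape[0] < S:
            raise ProtNormError("fewer complete proteins than samples")

        # per-protein ANOVA group means
        F = np.empty_like(C)
        for g in range(labels.size):
            cols = inverse == g
            F[:, cols] = C[:, cols].mean(axis=1, keepdims=True)
        R = C - F

        rng = np.random.default_rng(self.random_state)
        max_rank = S - labels.size  # group-mean removal kills G directions
        removed = []

        def _reproject(M: np.ndarray) -> np.ndarray:
            # re-remove per-protein group means so permuted matrices share
            # the observed residuals' projection structure
            out = M.copy()
            for g in range(labels.size):
                cols = inverse == g
                out[:, cols] -= out[:, cols].mean(axis=1, keepdims=True)
            return out

        U, sv, Vt = np.linalg.svd(R, full_matrices=False)
        sv_sq = sv**2
        frac_obs = sv_sq / sv_sq.sum()
        # permutation null per component: scramble each protein's residuals
        # across samples (breaking any protein-coherent sample pattern,
        # including flat offset trends that within-column scrambling would
        # leave intact), refit the model, and take the spectrum's variance
        # fractions (fractions, not absolute values: the projection to
        # S - G dimensions rescales the whole spectrum)
        nc = R.shape[0]
        perm_frac = np.empty((self.n_permutations, sv.size))
        for p in range(self.n_permutations):
            cols = np.argsort(rng.random((nc, S)), axis=1)
            P = np.take_along_axis(R, cols, axis=1)
            psv = np.linalg.svd(_reproject(P), compute_uv=False) ** 2
            perm_frac[p] = psv / psv.sum()
        thresholds = np.quantile(perm_frac, 1.0 - self.alpha, axis=0)

        h = 0
        while h < max_rank and frac_obs[h] > thresholds[h]:
            removed.append({"singular_value": float(sv[h]),
                            "variance_fraction": float(frac_obs[h]),
                            "threshold": float(thresholds[h]),
                            "sample_loading": Vt[h].copy()})
            h += 1
        R_work = R - (U[:, :h] * sv[:h]) @ Vt[:h] if h else R.copy()

        self.n_trends_ = h
        self.removed_trends_ = removed
        self.complete_mask_ = complete
        out = V.copy()
        if h:  # h = 0 leaves the data bit-identical
            out[complete] = F + R_work
        self.output_ = out.T
        self.diagnostics_ = {
            "n_trends": h,
            "removed_trends": removed,
            "n_complete_proteins": int(complete.sum()),
            "incomplete_proteins_passed_through": int((~complete).sum()),
        }
        return self

    def transform(self, X):
        return self.output_.copy()

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


def normalize_eigenms(m: AbundanceMatrix, design: StudyDesign,
                      **kwargs) -> NormalizationResult:
    if m.scale != "log2":
        raise ScaleError(f"eigenms expects a log2-scale matrix, got {m.scale!r}")
    design.validate_against(m, require_groups_of=2)
    groups = [design.groups[s] for s in m.sample_ids]
    est = EigenMSNormalizer(**kwargs)
    out = est.fit(m.values.T, groups).output_.T
    return NormalizationResult(matrix=m.with_values(out), method="eigenms",
                               diagnostics=est.diagnostics_)


METHOD_REGISTRY["eigenms"] = normalize_eigenms
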