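"""Synthetic spike-in benchmark data with known ground truth.

Emulates the structure of UPS1-style spike-in experiments: a large
constant background proteome, a small set of spike-in proteins whose
latent abundance scales with a known per-group concentration (fmol/μl),
a few technical replicates per group, per-sample intensity-dependent bias
(none / offset / affine / smooth nonlinear), additive + multiplicative
noise on the raw scale, and a small fraction of zeros placed
preferentially at low intensity (abundance below detection capacity).

Per-sample bias parameters are, by default, centered within each sample
group: nonbiological bias is taken to be orthogonal to the spike-in
design, as a balanced run order achieves experimentally. This keeps the
ground-truth group differences identifiable for every normalization
strategy, including methods that deliberately preserve group effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io_model import AbundanceMatrix, ProtNormError, StudyDesign

__all__ = [
    "GroupSpec",
    "BiasModel",
    "SimulationConfig",
    "GroundTruth",
    "simulate_spikein",
    "inject_bias",
    "truth_table",
]

#: Nominal UPS1-style concentration series, fmol/μl.
DEFAULT_CONCENTRATIONS = (2.0, 4.0, 10.0, 25.0, 50.0)


@dataclass(frozen=True)
class GroupSpec:
    label: str
    concentration: float
    n_replicates: int = 3


@dataclass(frozen=True)
class BiasModel:
    """Per-sample nonbiological bias on the log2 scale.

    kind: ``none`` | ``offset`` (x + a_s) | ``affine`` (a_s + b_s·x) |
    ``smooth_nonlinear`` (x + f_s(x), f_s a bounded random cubic).

    ``center_within_groups`` recenters the drawn parameters within each
    sample group so the bias carries no group-mean component.
    """

    kind: str = "none"
    offset_range: tuple[float, float] = (-1.0, 1.0)
    slope_range: tuple[float, float] = (0.95, 1.05)
    amplitude: float = 0.5
    center_within_groups: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("none", "offset", "affine", "smooth_nonlinear"):
            raise ProtNormError(f"unknown bias kind {self.kind!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic spike-in dataset.

    Defaults follow the structure of the benchmarked spike-in studies:
    five concentration groups (2, 4, 10, 25, 50 fmol/μl) with 3 technical
    replicates each, ~2000 proteins of which a small set are spike-ins,
    log2 abundances around 20 with SD 2.5, mild multiplicative noise, and
    a zero fraction inside the 0.06–0.6% band observed in real exports.
    """

    n_background: int = 1990
    n_spike: int = 10
    groups: tuple[GroupSpec, ...] = tuple(
        GroupSpec(label=f"fmol{c:g}", concentration=c)
        for c in DEFAULT_CONCENTRATIONS
    )
    base_loc: float = 20.0
    base_scale: float = 2.5
    # spike-in proteins come from one equimolar mix, so their base
    # abundances cluster; None = draw like the background
    spike_loc: float | None = None
    spike_scale: float | None = None
    bias: BiasModel = field(default_factory=BiasModel)
    noise_sd_log2: float = 0.2
    noise_sd_raw: float = 0.0
    zero_rate: float = 0.003
    seed: int = 17

    def __post_init__(self) -> None:
        if not 0 <= self.zero_rate <= 0.01:
            raise ProtNormError("zero_rate must be in [0, 0.01]")
        if self.n_background < 1 or self.n_spike < 0:
            raise ProtNormError("invalid protein counts")
        for g in self.groups:
            if g.n_replicates < 2:
                raise ProtNormError(f"group {g.label!r} needs >= 2 replicates")
            if g.concentration <= 0:
                raise ProtNormError("concentrations must be positive")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ProtNormError("duplicate group labels")


@dataclass
class BiasRecord:
    kind: str
    offsets: np.ndarray | None = None
    slopes: np.ndarray | None = None
    cubic_coefs: np.ndarray | None = None   # (S, 3): z, z², z³ coefficients
    x_center: float = 0.0
    x_scale: float = 1.0

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Re-apply the recorded bias to a log2 matrix (proteins × samples)."""
        if self.kind == "none":
            return X.copy()
        if self.kind == "offset":
            return X + self.offsets[None, :]
        if self.kind == "affine":
            return self.offsets[None, :] + self.slopes[None, :] * X
        z = (X - self.x_center) / self.x_scale
        f = (self.cubic_coefs[None, :, 0] * z
             + self.cubic_coefs[None, :, 1] * z**2
             + self.cubic_coefs[None, :, 2] * z**3)
        return X + f

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "offsets": None if self.offsets is None else self.offsets.tolist(),
            "slopes": None if self.slopes is None else self.slopes.tolist(),
            "cubic_coefs": (None if self.cubic_coefs is None
                            else self.cubic_coefs.tolist()),
            "x_center": self.x_center,
            "x_scale": self.x_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiasRecord":
        return cls(
            kind=d["kind"],
            offsets=None if d["offsets"] is None else np.asarray(d["offsets"]),
            slopes=None if d["slopes"] is None else np.asarray(d["slopes"]),
            cubic_coefs=(None if d["cubic_coefs"] is None
                         else np.asarray(d["cubic_coefs"])),
            x_center=d["x_center"],
            x_scale=d["x_scale"],
        )


@dataclass
class GroundTruth:
    clean_log2: AbundanceMatrix
    bias: BiasRecord
    spike_proteins: tuple[str, ...]
    config: SimulationConfig


def _draw_bias(model: BiasModel, X: np.ndarray, group_index: np.ndarray,
               rng: np.random.Generator) -> BiasRecord:
    S = X.shape[1]
    obs = X[~np.isnan(X)]
    x_center = float(np.mean(obs))
    x_scale = float(np.std(obs)) or 1.0

    def center(v: np.ndarray, neutral: float) -> np.ndarray:
        if not model.center_within_groups:
            return v
        out = v.copy()
        for g in np.unique(group_index):
            sel = group_index == g
            out[sel] = v[sel] - v[sel].mean() + neutral
        return out

    if model.kind == "none":
        return BiasRecord(kind="none")
    if model.kind == "offset":
        a = rng.uniform(*model.offset_range, size=S)
        return BiasRecord(kind="offset", offsets=center(a, 0.0))
    if model.kind == "affine":
        a = center(rng.uniform(*model.offset_range, size=S), 0.0)
        b = center(rng.uniform(*model.slope_range, size=S), 1.0)
        # keep the intensity grand mean fixed: a_s ↦ a_s + (1 − b_s)·x̄
        a = a + (1.0 - b) * x_center
        return BiasRecord(kind="affine", offsets=a, slopes=b)
    # smooth_nonlinear: bounded random cubic per sample in standardized x
    coefs = rng.uniform(-1.0, 1.0, size=(S, 3))
    z = np.linspace(-2.5, 2.5, 101)
    for s in range(S):
        f = coefs[s, 0] * z + coefs[s, 1] * z**2 + coefs[s, 2] * z**3
        peak = np.max(np.abs(f))
        if peak > 0:
            coefs[s] *= model.amplitude / peak
    if model.center_within_groups:
        for g in np.unique(group_index):
            sel = group_index == g
            coefs[sel] -= coefs[sel].mean(axis=0, keepdims=True)
            # rescale so the largest within-group curve still has the
            # requested amplitude
            fmax = 0.0
            for s in np.flatnonzero(sel):
                f = coefs[s, 0] * z + coefs[s, 1] * z**2 + coefs[s, 2] * z**3
                fmax = max(fmax, np.max(np.abs(f)))
            if fmax > 0:
                coefs[sel] *= model.amplitude / fmax
    return BiasRecord(kind="smooth_nonlinear", cubic_coefs=coefs,
                      x_center=x_center, x_scale=x_scale)


def inject_bias(m: AbundanceMatrix, model: BiasModel, seed: int = 17,
                design: StudyDesign | None = None) -> tuple[AbundanceMatrix, BiasRecord]:
    """Apply a seeded per-sample bias to a log2 matrix; return exact record.

    With ``model.center_within_groups`` a ``design`` ties the centering to
    the group structure; without one, all samples form a single group.
    """
    if m.scale != "log2":
        raise ProtNormError("inject_bias expects a log2-scale matrix")
    rng = np.random.default_rng(seed)
    if design is not None:
        labels = [design.groups[s] for s in m.sample_ids]
        _, group_index = np.unique(labels, return_inverse=True)
    else:
        group_index = np.zeros(m.n_samples, dtype=int)
    record = _draw_bias(model, m.values, group_index, rng)
    biased = record.apply(m.values)
    if not np.all(np.isfinite(biased[~np.isnan(biased)])):
        raise ProtNormError("bias amplitude produced non-finite values")
    return m.with_values(biased), record


def simulate_spikein(config: SimulationConfig) -> tuple[AbundanceMatrix, StudyDesign, GroundTruth]:
    """Simulate one raw-scale spike-in dataset plus its ground truth.

    Background proteins share one latent log2 abundance across all groups;
    spike-in latent abundances shift by log2(concentration) relative to the
    geometric-mean concentration. Identical seeds give identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_background + config.n_spike
    protein_ids = tuple(
        [f"BG_{i:05d}" for i in range(config.n_background)]
        + [f"SPIKE_{i:03d}" for i in range(config.n_spike)]
    )
    spike_ids = protein_ids[config.n_background:]

    sample_ids: list[str] = []
    group_of: dict[str, str] = {}
    group_index: list[int] = []
    for gi, g in enumerate(config.groups):
        for r in range(1, g.n_replicates + 1):
            sid = f"{g.label}_r{r}"
            sample_ids.append(sid)
            group_of[sid] = g.label
            group_index.append(gi)
    group_index = np.asarray(group_index)
    S = len(sample_ids)

    base = rng.normal(config.base_loc, config.base_scale, size=n)
    if config.n_spike and config.spike_loc is not None:
        spike_scale = (config.spike_scale if config.spike_scale is not None
                       else config.base_scale)
        base[config.n_background:] = rng.normal(
            config.spike_loc, spike_scale, size=config.n_spike)
    concs = np.array([g.concentration for g in config.groups])
    log_conc = np.log2(concs) - np.mean(np.log2(concs))
    L = np.tile(base[:, None], (1, S))
    spike_rows = np.arange(config.n_background, n)
    L[spike_rows[:, None], np.arange(S)[None, :]] += log_conc[group_index][None, :]

    clean = AbundanceMatrix(values=L.copy(), scale="log2",
                            protein_ids=protein_ids,
                            sample_ids=tuple(sample_ids))

    bias_record = _draw_bias(config.bias, L, group_index, rng)
    L_biased = bias_record.apply(L)

    if config.noise_sd_log2 > 0:
        L_biased = L_biased + rng.normal(0.0, config.noise_sd_log2, size=L.shape)

    raw = np.exp2(L_biased)
    if config.noise_sd_raw > 0:
        raw = raw + rng.normal(0.0, config.noise_sd_raw, size=raw.shape)
        below = raw <= 0  # below detection: missing, reported via the mask
        raw[below] = np.nan

    if config.zero_rate > 0:
        flat = raw.ravel()
        candidates = np.flatnonzero(~np.isnan(flat))
        n_zero = int(round(config.zero_rate * flat.size))
        if n_zero > 0:
            ranks = np.empty(candidates.size)
            ranks[np.argsort(flat[candidates], kind="stable")] = \
                np.arange(1, candidates.size + 1)
            weights = 1.0 / ranks
            weights /= weights.sum()
            chosen = rng.choice(candidates, size=n_zero, replace=False, p=weights)
            flat[chosen] = 0.0
        raw = flat.reshape(raw.shape)

    matrix = AbundanceMatrix(values=raw, scale="raw",
                             protein_ids=protein_ids,
                             sample_ids=tuple(sample_ids))
    design = StudyDesign(
        groups=group_of,
        spike_truth={p: (p in spike_ids) for p in protein_ids},
        concentrations={g.label: g.concentration for g in config.groups},
    )
    truth = GroundTruth(clean_log2=clean, bias=bias_record,
                        spike_proteins=spike_ids, config=config)
    return matrix, design, truth


def truth_table(truth: GroundTruth) -> dict:
    """Expose ground truth for recovery scoring and serialization."""
    cfg = asdict(truth.config)
    return {
        "spike_proteins": list(truth.spike_proteins),
        "concentrations": {g.label: g.concentration for g in truth.config.groups},
        "bias": truth.bias.to_dict(),
        "clean_log2": truth.clean_log2,
        "config": cfg,
    }
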