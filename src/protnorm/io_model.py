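"""Core data containers and preprocessing for protein-level intensity tables.

The package works on protein × sample abundance matrices as exported by
label-free quantification software (one header row of sample identifiers,
one protein-identifier column, non-negative raw intensities). Zero
intensities denote abundance below detection and are converted to missing
values before any transformation; all downstream analysis happens on the
log2 (or, for variance stabilization, glog2) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "StudyDesign",
    "ProtNormError",
    "ScaleError",
    "DesignMismatchError",
    "NegativeValueError",
    "DuplicateIdError",
    "ParseError",
    "read_abundance_table",
    "write_abundance_table",
    "preprocess_zeros",
    "log2_transform",
]

#: String values parsed as a missing cell in delimited input.
NA_STRINGS = ("", "NA", "NaN", "nan", "na")

VALID_SCALES = ("raw", "log2", "glog2")


class ProtNormError(ValueError):
    """Base class for errors raised by protnorm."""


class ScaleError(ProtNormError):
    """An operation received a matrix on the wrong scale."""


class DesignMismatchError(ProtNormError):
    """Sample/protein identifiers in the design do not match the matrix."""


class NegativeValueError(ProtNormError):
    """Negative intensity encountered on the raw scale."""


class DuplicateIdError(ProtNormError):
    """Duplicate protein or sample identifiers."""


class ParseError(ProtNormError):
    """A cell could not be parsed as a number or missing value."""


@dataclass(frozen=True)
class AbundanceMatrix:
    """A proteins × samples intensity grid with an explicit scale.

    Parameters
    ----------
    values
        Float array of shape ``(n_proteins, n_samples)``. Missing cells are
        ``NaN``. On the raw scale all finite values must be >= 0; on the
        log2/glog2 scales all non-missing values must be finite.
    scale
        One of ``"raw"``, ``"log2"`` or ``"glog2"``.
    protein_ids, sample_ids
        Unique, ordered identifiers matching the grid dimensions.
    """

    values: np.ndarray
    scale: str
    protein_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "protein_ids", tuple(str(p) for p in self.protein_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise ProtNormError("values must be a 2-D proteins × samples array")
        if self.scale not in VALID_SCALES:
            raise ScaleError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise DuplicateIdError("duplicate protein identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateIdError("duplicate sample identifiers")
        if values.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise ProtNormError(
                f"grid shape {values.shape} does not match id counts "
                f"({len(self.protein_ids)} proteins, {len(self.sample_ids)} samples)"
            )
        finite = values[~np.isnan(values)]
        if self.scale == "raw":
            if np.any(finite < 0):
                raise NegativeValueError("raw-scale intensities must be >= 0 or missing")
        else:
            if np.any(~np.isfinite(finite)):
                raise ProtNormError(f"{self.scale}-scale values must be finite or missing")

    # -- basic geometry -------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean grid, ``True`` wherever the value is absent."""
        return np.isnan(self.values)

    # -- conversion helpers ---------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.protein_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scale: str = "raw") -> "AbundanceMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            scale=scale,
            protein_ids=tuple(str(i) for i in frame.index),
            sample_ids=tuple(str(c) for c in frame.columns),
        )

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "AbundanceMatrix":
        """Return a copy with new values (and optionally a new scale)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       scale=self.scale if scale is None else scale)

    def subset_samples(self, sample_ids: list[str] | tuple[str, ...]) -> "AbundanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceMatrix(
            values=self.values[:, idx],
            scale=self.scale,
            protein_ids=self.protein_ids,
            sample_ids=tuple(sample_ids),
        )


@dataclass(frozen=True)
class StudyDesign:
    """Sample → group mapping with optional spike-in ground truth.

    ``spike_truth`` maps protein ids to ``True`` (spike-in, true positive)
    or ``False`` (background, true negative). ``concentrations`` holds the
    nominal spike concentration per group in fmol/μl.
    """

    groups: Mapping[str, str]
    spike_truth: Mapping[str, bool] = field(default_factory=dict)
    concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", dict(self.groups))
        object.__setattr__(self, "spike_truth", dict(self.spike_truth))
        object.__setattr__(self, "concentrations", dict(self.concentrations))

    @property
    def group_labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.groups.values():
            seen.setdefault(g, None)
        return tuple(seen)

    def samples_in(self, group: str) -> tuple[str, ...]:
        return tuple(s for s, g in self.groups.items() if g == group)

    def validate_against(self, m: AbundanceMatrix, require_groups_of: int = 1) -> None:
        missing = [s for s in m.sample_ids if s not in self.groups]
        if missing:
            raise DesignMismatchError(f"samples without a group label: {missing}")
        extra = [s for s in self.groups if s not in m.sample_ids]
        if extra:
            raise DesignMismatchError(f"design lists samples absent from the matrix: {extra}")
        if require_groups_of > 1:
            for g in self.group_labels:
                if len(self.samples_in(g)) < require_groups_of:
                    raise DesignMismatchError(
                        f"group {g!r} has fewer than {require_groups_of} samples"
                    )

    def subset(self, groups: tuple[str, str] | list[str]) -> "StudyDesign":
        keep = {s: g for s, g in self.groups.items() if g in groups}
        return StudyDesign(
            groups=keep,
            spike_truth=self.spike_truth,
            concentrations={g: c for g, c in self.concentrations.items() if g in groups},
        )


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _read_delimited(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep=None,
        engine="python",
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )


def _parse_numeric(frame: pd.DataFrame, path: str | Path) -> np.ndarray:
    raw = frame.to_numpy(dtype=object)
    out = np.empty(raw.shape, dtype=float)
    for (i, j), cell in np.ndenumerate(raw):
        text = cell.strip() if isinstance(cell, str) else cell
        if text in NA_STRINGS:
            out[i, j] = np.nan
            continue
        try:
            out[i, j] = float(text)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: cell ({frame.index[i]!r}, {frame.columns[j]!r}) "
                f"is not numeric: {cell!r}"
            ) from None
    return out


def read_abundance_table(
    path: str | Path,
    design_path: str | Path,
    truth_path: str | Path | None = None,
) -> tuple[AbundanceMatrix, StudyDesign]:
    """Read a raw-scale abundance table and its sample → group design.

    The abundance file is delimited text with a header row of sample ids and
    a leading protein-id column. The design file has columns ``sample_id``
    and ``group``. An optional truth file has columns ``protein_id`` and
    ``is_spike`` plus, optionally, one column per group label holding that
    group's nominal spike concentration.
    """
    frame = _read_delimited(path)
    if frame.index.duplicated().any() or frame.columns.duplicated().any():
        raise DuplicateIdError(f"{path}: duplicate protein or sample identifiers")
    values = _parse_numeric(frame, path)
    if np.any(values[~np.isnan(values)] < 0):
        raise NegativeValueError(f"{path}: negative intensities on the raw scale")
    matrix = AbundanceMatrix(
        values=values,
        scale="raw",
        protein_ids=tuple(str(i) for i in frame.index),
        sample_ids=tuple(str(c) for c in frame.columns),
    )

    design_frame = pd.read_csv(design_path, sep=None, engine="python", dtype=str)
    for col in ("sample_id", "group"):
        if col not in design_frame.columns:
            raise DesignMismatchError(f"{design_path}: missing column {col!r}")
    if design_frame["sample_id"].duplicated().any():
        raise DuplicateIdError(f"{design_path}: duplicate sample ids")
    groups = dict(zip(design_frame["sample_id"], design_frame["group"]))

    spike_truth: dict[str, bool] = {}
    concentrations: dict[str, float] = {}
    if truth_path is not None:
        truth = pd.read_csv(truth_path, sep=None, engine="python", dtype=str)
        for col in ("protein_id", "is_spike"):
            if col not in truth.columns:
                raise DesignMismatchError(f"{truth_path}: missing column {col!r}")
        truthy = {"1", "true", "True", "TRUE", "yes"}
        spike_truth = {
            pid: (str(v).strip() in truthy)
            for pid, v in zip(truth["protein_id"], truth["is_spike"])
        }
        group_set = set(groups.values())
        for col in truth.columns:
            if col in group_set:
                vals = pd.to_numeric(truth[col], errors="coerce").dropna()
                if len(vals):
                    concentrations[col] = float(vals.iloc[0])

    design = StudyDesign(groups=groups, spike_truth=spike_truth, concentrations=concentrations)
    design.validate_against(matrix)
    return matrix, design


def write_abundance_table(m: AbundanceMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix as delimited text; missing cells become empty fields.

    Finite values are written with shortest round-trip ``repr`` so a
    read → write → read cycle is bit-identical.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(sep.join(["protein_id", *m.sample_ids]) + "\n")
        for i, pid in enumerate(m.protein_ids):
            cells = [
                "" if np.isnan(v) else repr(float(v)) for v in m.values[i]
            ]
            fh.write(sep.join([pid, *cells]) + "\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_zeros(m: AbundanceMatrix) -> AbundanceMatrix:
    """Convert exact zeros (abundance below detection) to missing values.

    Only meaningful on the raw scale, before any log transform.
    """
    if m.scale != "raw":
        raise ScaleError("preprocess_zeros expects a raw-scale matrix")
    values = m.values.copy()
    values[values == 0] = np.nan
    return m.with_values(values)


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """log2-transform a raw matrix whose zeros were already made missing."""
    if m.scale != "raw":
        raise ScaleError("log2_transform expects a raw-scale matrix")
    values = m.values
    finite = values[~np.isnan(values)]
    if np.any(finite <= 0):
        raise ProtNormError(
            "log2_transform requires strictly positive intensities; "
            "run preprocess_zeros first"
        )
    with np.errstate(divide="ignore"):
        out = np.log2(values)
    return m.with_values(out, scale="log2")
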