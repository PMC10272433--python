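"""Pearson FC matrices, Fisher z-transform, and basal-ganglia FC statistics.

Functional connectivity between ROIs is the Pearson correlation of their
within-task concatenated series, held in a symmetric 116 x 116 weighted
matrix per participant (and per task). The variance-stabilising Fisher
transform z = atanh(r) is applied element-wise before any averaging or
group statistics — averages of z values above 1 are only reachable on the
z scale, which is why local basal-ganglia coupling statistics can exceed 1.

Local FC of the basal ganglia is the mean z over the four cross edges
between two bilateral structures (L-L, L-R, R-L, R-R; within-structure
homotopic edges belong to no named pair and are excluded). Global FC is
the mean z between a seed (one bilateral structure, or all six regions)
and the 110 non-basal-ganglia atlas regions. Negative weights are used
as-is; no thresholding.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .atlas import BG_REGIONS, BG_STRUCTURES
from .schedule import TaskSegmentSeries

__all__ = [
    "BG_PAIRS",
    "BG_SEEDS",
    "FCMatrix",
    "correlation_matrix",
    "fisher_z",
    "local_bg_fc",
    "global_bg_fc",
    "TaskConnectivity",
]

#: Named basal-ganglia structure pairs -> the two bilateral structures.
BG_PAIRS = {
    "Caudate-Putamen": ("Caudate", "Putamen"),
    "Caudate-Pallidum": ("Caudate", "Pallidum"),
    "Putamen-Pallidum": ("Putamen", "Pallidum"),
}

#: Global-FC seed names. Single structures combine L+R; "BG-average" all six.
BG_SEEDS = ("Caudate", "Putamen", "Pallidum", "BG-average")

_R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric weighted connectivity matrix on the r or Fisher-z scale."""

    values: np.ndarray
    scale: str  # "pearson_r" | "fisher_z"
    region_names: tuple[str, ...]
    task: str | None = None
    block: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "region_names", tuple(self.region_names))
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"matrix must be square, got {v.shape}")
        if v.shape[0] != len(self.region_names):
            raise ValueError("matrix size does not match region names")
        if not np.allclose(v, v.T, atol=0, rtol=0, equal_nan=False):
            raise ValueError("matrix is not symmetric")
        if self.scale == "pearson_r":
            off = ~np.eye(v.shape[0], dtype=bool)
            if np.any(np.abs(v[off]) > 1 + 1e-12):
                raise ValueError("pearson_r entries must lie in [-1, 1]")

    def index_of(self, name: str) -> int:
        try:
            return self.region_names.index(name)
        except ValueError:
            raise KeyError(f"unknown region name: {name!r}") from None

    def to_tsv(self, path: str | Path) -> None:
        names = list(self.region_names)
        pd.DataFrame(self.values, index=names, columns=names).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str, task: str | None = None,
                 block: int | None = None) -> "FCMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame.to_numpy(dtype=float), scale, tuple(frame.columns), task, block)


def correlation_matrix(
    segment: TaskSegmentSeries | np.ndarray,
    region_names: tuple[str, ...],
    task: str | None = None,
    block: int | None = None,
) -> FCMatrix:
    """Pairwise Pearson correlation of ROI columns over a task segment."""
    if isinstance(segment, TaskSegmentSeries):
        task = task or segment.task
        data = segment.data
    else:
        data = np.asarray(segment, dtype=float)
    if data.ndim != 2 or data.shape[0] < 3:
        raise ValueError("segment must be T x regions with T >= 3")
    sd = data.std(axis=0)
    dead = np.where(sd == 0)[0]
    if dead.size:
        names = [region_names[i] for i in dead[:5]]
        raise ValueError(f"zero-variance ROI series: {names}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r, "pearson_r", tuple(region_names), task, block)


def fisher_z(m: FCMatrix) -> FCMatrix:
    """Element-wise z = 0.5 * ln((1+r)/(1-r)), diagonal set to 0."""
    if m.scale != "pearson_r":
        raise ValueError(f"fisher_z expects a pearson_r matrix, got {m.scale!r}")
    r = np.clip(m.values, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return FCMatrix(z, "fisher_z", m.region_names, m.task, m.block)


def _structure_indices(m: FCMatrix, structure: str) -> list[int]:
    return [m.index_of(name) for name in BG_STRUCTURES[structure]]


def local_bg_fc(m: FCMatrix, pair: str) -> float:
    """Mean z over the 4 cross edges of a named basal-ganglia pair."""
    if m.scale != "fisher_z":
        raise ValueError("local_bg_fc expects a fisher_z matrix")
    if pair not in BG_PAIRS:
        raise KeyError(f"unknown basal-ganglia pair {pair!r}; one of {list(BG_PAIRS)}")
    a, b = BG_PAIRS[pair]
    ia, ib = _structure_indices(m, a), _structure_indices(m, b)
    return float(m.values[np.ix_(ia, ib)].mean())


def global_bg_fc(m: FCMatrix, seed: str) -> float:
    """Mean z between a basal-ganglia seed and the 110 non-BG regions."""
    if m.scale != "fisher_z":
        raise ValueError("global_bg_fc expects a fisher_z matrix")
    if seed not in BG_SEEDS:
        raise KeyError(f"unknown seed {seed!r}; one of {list(BG_SEEDS)}")
    if seed == "BG-average":
        seed_idx = [m.index_of(n) for n in BG_REGIONS]
    else:
        seed_idx = _structure_indices(m, seed)
    bg_idx = {m.index_of(n) for n in BG_REGIONS}
    other = [i for i in range(len(m.region_names)) if i not in bg_idx]
    return float(m.values[np.ix_(seed_idx, other)].mean())


class TaskConnectivity(BaseEstimator, TransformerMixin):
    """Transformer mapping task segments to Fisher-z FC matrices.

    ``transform`` accepts a single segment (T x regions array or
    :class:`TaskSegmentSeries`) or a list of them and returns the
    corresponding :class:`FCMatrix` objects on the requested scale.
    """

    def __init__(self, region_names: tuple[str, ...] = (), scale: str = "fisher_z"):
        self.region_names = region_names
        self.scale = scale

    def fit(self, X=None, y=None):
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValueError(f"unknown scale {self.scale!r}")
        return self

    def _one(self, seg):
        m = correlation_matrix(seg, tuple(self.region_names))
        return fisher_z(m) if self.scale == "fisher_z" else m

    def transform(self, X):
        if isinstance(X, (TaskSegmentSeries, np.ndarray)):
            return self._one(X)
        return [self._one(seg) for seg in X]
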