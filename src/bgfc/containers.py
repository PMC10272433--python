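"""In-memory containers for ROI time series and confound signals."""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["RoiTimeSeriesSet", "ConfoundSet"]


@dataclass(frozen=True)
class RoiTimeSeriesSet:
    """T x n_regions matrix of mean ROI signals with its sampling interval.

    Columns follow the atlas label-table order; the order is identical for
    every subject so matrices are comparable element-wise.
    """

    data: np.ndarray
    tr_seconds: float
    region_names: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "region_names", tuple(self.region_names))
        if arr.ndim != 2:
            raise ValueError(f"data must be 2-D (T x regions), got {arr.shape}")
        if arr.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        if arr.shape[1] != len(self.region_names):
            raise ValueError(
                f"{arr.shape[1]} columns but {len(self.region_names)} region names"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.isfinite(arr).all():
            raise ValueError("time series contain non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RoiTimeSeriesSet":
        return replace(self, data=data)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=list(self.region_names))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, tr_seconds: float) -> "RoiTimeSeriesSet":
        return cls(frame.to_numpy(dtype=float), tr_seconds, tuple(frame.columns))


@dataclass(frozen=True)
class ConfoundSet:
    """Nuisance signals: white-matter mean, CSF mean and 6 motion parameters."""

    wm: np.ndarray
    csf: np.ndarray
    motion: np.ndarray

    def __post_init__(self) -> None:
        wm = np.asarray(self.wm, dtype=float).ravel()
        csf = np.asarray(self.csf, dtype=float).ravel()
        motion = np.asarray(self.motion, dtype=float)
        object.__setattr__(self, "wm", wm)
        object.__setattr__(self, "csf", csf)
        object.__setattr__(self, "motion", motion)
        if motion.ndim != 2 or motion.shape[1] != 6:
            raise ValueError(f"motion must be T x 6, got {motion.shape}")
        if not (len(wm) == len(csf) == motion.shape[0]):
            raise ValueError("confound series lengths differ")

    @property
    def n_volumes(self) -> int:
        return len(self.wm)

    def as_matrix(self) -> np.ndarray:
        """T x 8 design block: [wm, csf, motion(6)]."""
        return np.column_stack([self.wm, self.csf, self.motion])

    def to_frame(self) -> pd.DataFrame:
        cols = {"wm": self.wm, "csf": self.csf}
        for i in range(6):
            cols[f"motion{i + 1}"] = self.motion[:, i]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConfoundSet":
        motion = frame[[f"motion{i + 1}" for i in range(6)]].to_numpy(dtype=float)
        return cls(frame["wm"].to_numpy(dtype=float), frame["csf"].to_numpy(dtype=float), motion)
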