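"""Nuisance regression and temporal bandpass filtering of ROI time series.

The cleaning model follows the standard task/rest FC recipe: least-squares
regression of white-matter, CSF and six motion signals (plus an intercept),
then a zero-phase 4th-order Butterworth bandpass at 0.01-0.08 Hz applied
forward-backward with reflective padding. Regression precedes filtering;
an optional linear detrend (on by default) runs between the two to avoid
ramp leakage into the passband.

Both stages are scikit-learn transformers and compose in a
:class:`sklearn.pipeline.Pipeline`; :func:`clean_roi_timeseries` is the
container-level convenience wrapper.

Regression is applied to ROI-level series. Because regression and ROI
averaging are both linear in the voxel data and the confounds are shared
across voxels, this commutes with the voxel-level formulation; the
voxel-level path (regress each voxel, then average) is exercised through
:mod:`bgfc.imaging` on volumetric inputs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ConfoundSet, RoiTimeSeriesSet

__all__ = [
    "CleaningConfig",
    "NuisanceRegressor",
    "BandpassFilter",
    "regress_nuisance",
    "bandpass",
    "clean_roi_timeseries",
]


@dataclass(frozen=True)
class CleaningConfig:
    """Bandpass and detrend settings.

    The printed band "(0.01-0.08)" is read as Hz, the field convention for
    slow FC fluctuations. ``filter_order`` is the order of each Butterworth
    pass (applied twice, so the effective attenuation doubles).
    """

    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    filter_order: int = 4
    detrend: bool = True

    def validate(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not (0.0 < self.band_low_hz < self.band_high_hz < nyquist):
            raise ValueError(
                f"band ({self.band_low_hz}, {self.band_high_hz}) Hz must satisfy "
                f"0 < low < high < Nyquist ({nyquist:.4f} Hz at TR {tr_seconds} s)"
            )


def _linear_detrend(X: np.ndarray) -> np.ndarray:
    """Least-squares removal of mean + linear trend (closed form)."""
    T = X.shape[0]
    t = np.arange(T, dtype=float)
    t -= t.mean()
    Xc = X - X.mean(axis=0)
    slope = (t @ Xc) / (t @ t)
    return Xc - np.outer(t, slope)


def _check_2d(X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D array (T x series), got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("input contains non-finite values")
    return arr


class NuisanceRegressor(BaseEstimator, TransformerMixin):
    """Least-squares removal of confound signals from each column.

    Parameters
    ----------
    add_intercept:
        Include a constant column in the design (default True), so output
        columns are demeaned residuals.

    Attributes
    ----------
    design_ : ndarray of shape (T, p)
        Validated design matrix ([intercept] + confounds) stored by ``fit``.
    hat_ : ndarray of shape (p, T)
        Pseudo-inverse of the design, used to project out the confounds.
    """

    def __init__(self, add_intercept: bool = True):
        self.add_intercept = add_intercept

    def fit(self, X, y=None, confounds=None):
        X = _check_2d(X)
        if confounds is None:
            raise ValueError("confounds are required (T x k array or ConfoundSet)")
        if isinstance(confounds, ConfoundSet):
            confounds = confounds.as_matrix()
        C = _check_2d(confounds)
        if C.shape[0] != X.shape[0]:
            raise ValueError(
                f"confound length {C.shape[0]} != series length {X.shape[0]}"
            )
        # all-zero confound columns are absent signals, not collinear ones
        keep = np.any(C != 0, axis=0)
        C = C[:, keep]
        design = np.column_stack([np.ones(X.shape[0]), C]) if self.add_intercept else C
        if design.shape[1] == 0:
            raise ValueError("no usable confound columns")
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # identify near-dependent columns from the QR diagonal
            _, r = np.linalg.qr(design)
            diag = np.abs(np.diag(r))
            tol = diag.max() * max(design.shape) * np.finfo(float).eps
            bad = [int(i) for i in np.where(diag <= tol)[0]]
            base = ["wm", "csf"] + [f"motion{i+1}" for i in range(6)]
            kept_names = [base[i] if i < len(base) else f"col{i}" for i in np.where(keep)[0]]
            names = (["intercept"] if self.add_intercept else []) + kept_names
            labelled = [names[i] if i < len(names) else f"col{i}" for i in bad]
            raise ValueError(
                f"rank-deficient nuisance design (rank {rank} < {design.shape[1]}); "
                f"collinear columns: {labelled}"
            )
        self.design_ = design
        self.hat_ = np.linalg.pinv(design)
        return self

    def transform(self, X) -> np.ndarray:
        X = _check_2d(X)
        if X.shape[0] != self.design_.shape[0]:
            raise ValueError("series length differs from fitted design")
        beta = self.hat_ @ X
        return X - self.design_ @ beta


class BandpassFilter(BaseEstimator, TransformerMixin):
    """Zero-phase Butterworth bandpass (forward-backward, reflective padding).

    ``fit`` validates the band against the Nyquist frequency implied by
    ``tr_seconds`` and designs the filter; ``transform`` applies it
    column-wise with ``scipy.signal.filtfilt`` so the output has no phase
    lag. An optional linear detrend precedes filtering.
    """

    def __init__(
        self,
        tr_seconds: float = 0.906,
        band_low_hz: float = 0.01,
        band_high_hz: float = 0.08,
        filter_order: int = 4,
        detrend: bool = True,
    ):
        self.tr_seconds = tr_seconds
        self.band_low_hz = band_low_hz
        self.band_high_hz = band_high_hz
        self.filter_order = filter_order
        self.detrend = detrend

    def _config(self) -> CleaningConfig:
        return CleaningConfig(
            self.band_low_hz, self.band_high_hz, self.filter_order, self.detrend
        )

    def fit(self, X=None, y=None):
        self._config().validate(self.tr_seconds)
        nyq = 1.0 / (2.0 * self.tr_seconds)
        self.ba_ = signal.butter(
            self.filter_order,
            [self.band_low_hz / nyq, self.band_high_hz / nyq],
            btype="band",
        )
        self.padlen_ = 3 * max(len(self.ba_[0]), len(self.ba_[1]))
        return self

    def transform(self, X) -> np.ndarray:
        X = _check_2d(X)
        if X.shape[0] <= 3 * self.padlen_:
            raise ValueError(
                f"series of {X.shape[0]} volumes too short for stable filtering "
                f"(need > {3 * self.padlen_})"
            )
        if self.detrend:
            X = _linear_detrend(X)
        b, a = self.ba_
        return signal.filtfilt(b, a, X, axis=0, padlen=self.padlen_)


def regress_nuisance(ts: RoiTimeSeriesSet, confounds: ConfoundSet) -> RoiTimeSeriesSet:
    """Residualise every ROI column on [intercept, wm, csf, 6 motion]."""
    reg = NuisanceRegressor().fit(ts.data, confounds=confounds)
    return ts.with_data(reg.transform(ts.data))


def bandpass(ts: RoiTimeSeriesSet, cfg: CleaningConfig | None = None) -> RoiTimeSeriesSet:
    """Zero-phase bandpass of every ROI column (with optional detrend)."""
    cfg = cfg or CleaningConfig()
    filt = BandpassFilter(
        ts.tr_seconds, cfg.band_low_hz, cfg.band_high_hz, cfg.filter_order, cfg.detrend
    ).fit()
    return ts.with_data(filt.transform(ts.data))


def clean_roi_timeseries(
    ts: RoiTimeSeriesSet,
    confounds: ConfoundSet,
    cfg: CleaningConfig | None = None,
) -> RoiTimeSeriesSet:
    """Full cleaning: nuisance regression, then detrend + bandpass."""
    return bandpass(regress_nuisance(ts, confounds), cfg)
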