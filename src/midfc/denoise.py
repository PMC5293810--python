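"""Subject-level denoising: frame discard, smoothing, nuisance regression,
band-pass filtering.

The stage order is fixed: drop initial frames -> spatial smoothing ->
nuisance regression -> temporal band-pass.  Frame censoring happens later,
at the correlation stage, so the filter sees an uninterrupted time axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from midfc.volume import Bold4D

DEFAULT_DROP_FRAMES = 5
DEFAULT_FWHM_MM = 4.0
DEFAULT_BAND_HZ = (0.009, 0.08)

#: named nuisance regressors (intercept added at regression time)
NUISANCE_COLUMNS = (
    "whole_brain", "white_matter", "ventricle",
    "whole_brain_deriv", "white_matter_deriv", "ventricle_deriv",
    "mot_tx", "mot_ty", "mot_tz", "mot_rx", "mot_ry", "mot_rz",
)


@dataclass
class NuisanceSet:
    """The 12 named nuisance regressors for one subject.

    Three tissue signals (whole brain, white matter, ventricle), their
    backward-difference first derivatives, and the six rigid-body motion
    parameters.  Motion-parameter derivatives are excluded by default but
    can be appended via :func:`build_nuisance`'s ``motion_derivatives``
    switch.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            raise ValueError("nuisance column names must be unique")

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_timepoints(self) -> int:
        return len(self.frame)


def drop_initial_frames(series: Bold4D, motion: np.ndarray,
                        n: int = DEFAULT_DROP_FRAMES) -> tuple[Bold4D, np.ndarray]:
    """Discard the first ``n`` frames of the series and its motion trace.

    The leading frames precede steady-state magnetisation and carry a
    signal transient; both the BOLD series and the realignment-parameter
    trace are shortened together so they stay frame-aligned.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] != series.n_timepoints:
        raise ValueError("motion trace and series lengths differ")
    if n < 0:
        raise ValueError("n must be non-negative")
    if series.n_timepoints <= n:
        raise ValueError(
            f"cannot drop {n} frames from a {series.n_timepoints}-frame series"
        )
    if n == 0:
        return series, motion
    return series.copy_with(series.data[..., n:]), motion[n:]


def gaussian_smooth(series: Bold4D, fwhm: float = DEFAULT_FWHM_MM) -> Bold4D:
    """Smooth each frame with an isotropic Gaussian kernel.

    ``fwhm`` is in millimetres and converted per axis to voxel units via
    the affine's voxel sizes; sigma = fwhm / (2*sqrt(2*ln 2)).
    """
    if fwhm < 0:
        raise ValueError(f"FWHM must be non-negative, got {fwhm}")
    if fwhm == 0:
        return series.copy_with(series.data.copy())
    sigma_mm = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / series.grid.voxel_sizes
    out = ndimage.gaussian_filter(series.data, sigma=(*sigma_vox, 0.0),
                                  mode="reflect")
    return series.copy_with(out)


def _backward_diff(x: np.ndarray) -> np.ndarray:
    """Backward first difference with the first element set to 0."""
    return np.concatenate([[0.0], np.diff(x)])


def build_nuisance(series: Bold4D,
                   masks: dict[str, np.ndarray],
                   motion: np.ndarray,
                   motion_derivatives: bool = False) -> NuisanceSet:
    """Assemble the nuisance design for one subject.

    Parameters
    ----------
    series : Bold4D
        The (smoothed) BOLD series.
    masks : dict with keys ``whole_brain``, ``white_matter``, ``ventricle``
        Boolean tissue masks on the series' grid.
    motion : ndarray, shape (T, 6)
        Rigid-body realignment parameters, frame-aligned with the series.
    motion_derivatives : bool
        Also append backward differences of the six motion parameters
        (off by default: derivatives are taken only of the tissue signals).

    Returns
    -------
    NuisanceSet
        12 named regressors (18 with ``motion_derivatives``).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (series.n_timepoints, 6):
        raise ValueError(
            f"motion trace must be ({series.n_timepoints}, 6), got {motion.shape}"
        )
    cols: dict[str, np.ndarray] = {}
    for name in ("whole_brain", "white_matter", "ventricle"):
        if name not in masks:
            raise ValueError(f"missing tissue mask: {name}")
        m = np.asarray(masks[name], dtype=bool)
        if m.shape != series.shape3:
            raise ValueError(f"mask {name!r} shape does not match series")
        if not m.any():
            raise ValueError(f"tissue mask {name!r} is empty")
        cols[name] = series.data[m].mean(axis=0)
    for name in ("whole_brain", "white_matter", "ventricle"):
        cols[name + "_deriv"] = _backward_diff(cols[name])
    for i, name in enumerate(("mot_tx", "mot_ty", "mot_tz",
                              "mot_rx", "mot_ry", "mot_rz")):
        cols[name] = motion[:, i]
    if motion_derivatives:
        for i, name in enumerate(("mot_tx", "mot_ty", "mot_tz",
                                  "mot_rx", "mot_ry", "mot_rz")):
            cols[name + "_deriv"] = _backward_diff(motion[:, i])
    return NuisanceSet(frame=pd.DataFrame(cols))


def regress_nuisance(series: Bold4D, nuisance: NuisanceSet) -> Bold4D:
    """Remove nuisance variance by per-voxel ordinary least squares.

    An intercept is always included.  Returns the residual series on the
    same grid.  Raises if the design (with intercept) is rank deficient,
    naming the offending columns.
    """
    X = nuisance.matrix
    T = series.n_timepoints
    if X.shape[0] != T:
        raise ValueError("nuisance design and series lengths differ")
    k = X.shape[1] + 1
    if T <= k + 1:
        raise ValueError(f"need more than {k + 1} frames to fit {k} regressors")
    design = np.column_stack([np.ones(T), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that do not increase rank when added in order
        bad = []
        cur = design[:, :1]
        for j, name in enumerate(nuisance.names):
            cand = np.column_stack([cur, design[:, j + 1]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(name)
            else:
                cur = cand
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    flat = series.data.reshape(-1, T).T            # (T, V)
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta
    return series.copy_with(resid.T.reshape(series.data.shape))


def _bandpass_sos(low: float, high: float, tr: float, order: int = 2) -> np.ndarray:
    nyquist = 0.5 / tr
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyquist:
        raise ValueError(
            f"upper band edge {high} Hz is not below the Nyquist frequency "
            f"{nyquist:.4f} Hz for TR = {tr} s"
        )
    return signal.butter(order, [low, high], btype="bandpass",
                         fs=1.0 / tr, output="sos")


def bandpass(series: Bold4D,
             low: float = DEFAULT_BAND_HZ[0],
             high: float = DEFAULT_BAND_HZ[1],
             tr: float | None = None) -> Bold4D:
    """Zero-phase temporal band-pass filter applied per voxel.

    A second-order Butterworth band-pass run forward and backward
    (``sosfiltfilt``, effective 4th order, zero phase) so that the
    filtering never shifts signal timing.  Edge effects are controlled by
    ``sosfiltfilt``'s odd-reflection padding.  The default band
    0.009-0.08 Hz isolates low-frequency resting-state fluctuations.
    """
    tr = series.tr if tr is None else tr
    sos = _bandpass_sos(low, high, tr)
    T = series.n_timepoints
    flat = series.data.reshape(-1, T)
    out = signal.sosfiltfilt(sos, flat, axis=1)
    return series.copy_with(np.ascontiguousarray(out.reshape(series.data.shape)))


def bandpass_timeseries(x: np.ndarray,
                        low: float,
                        high: float,
                        tr: float) -> np.ndarray:
    """Band-pass 1D/2D time series (time on the last axis); same filter as
    :func:`bandpass`."""
    sos = _bandpass_sos(low, high, tr)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)
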