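"""Head-motion quality control: framewise displacement, DVARS, scrubbing.

Two per-frame metrics flag motion-corrupted frames:

* **FD** (framewise displacement): sum of absolute frame-to-frame changes
  of the three rigid-body translations (mm) plus the three rotations (rad)
  converted to arc displacement on a sphere of radius ``r`` (default
  50 mm, the approximate distance from the centre of MNI space to the
  cortex).
* **DVARS**: root mean square, over brain voxels, of the frame-to-frame
  change in % BOLD intensity.  The series is first rescaled so that its
  spatio-temporal mean within the brain mask equals 100, making a unit
  difference equal to one percent of mean signal.

Frames whose FD exceeds 0.5 mm or whose DVARS exceeds 0.5% BOLD are
censored ("scrubbed") before correlation maps are computed.  Both metrics
are defined as backward differences and are set to 0 at the first frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from midfc.volume import Bold4D

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.5
DEFAULT_DVARS_THRESHOLD_PCT = 0.5


@dataclass
class MotionMetrics:
    """Per-frame motion metrics for one subject."""

    fd: np.ndarray          # mm, length T
    dvars: np.ndarray       # % BOLD, length T
    radius_mm: float = DEFAULT_HEAD_RADIUS_MM

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        self.dvars = np.asarray(self.dvars, dtype=float)
        if self.fd.shape != self.dvars.shape:
            raise ValueError("fd and dvars must have the same length")


@dataclass
class CensorMask:
    """Boolean keep/drop decision per frame plus the thresholds applied."""

    keep: np.ndarray
    fd_threshold: float = DEFAULT_FD_THRESHOLD_MM
    dvars_threshold: float = DEFAULT_DVARS_THRESHOLD_PCT

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def removed_fraction(self) -> float:
        return float(1.0 - self.keep.mean())


def _validate_trace(motion: np.ndarray) -> np.ndarray:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(
            f"motion trace must have 6 columns (dx dy dz a b g), got shape {motion.shape}"
        )
    if motion.shape[0] < 2:
        raise ValueError("motion trace must have at least 2 frames")
    bad = ~np.isfinite(motion)
    if bad.any():
        frame = int(np.nonzero(bad.any(axis=1))[0][0])
        raise ValueError(f"non-finite motion parameters at frame {frame}")
    return motion


def framewise_displacement(motion: np.ndarray,
                           radius: float = DEFAULT_HEAD_RADIUS_MM) -> np.ndarray:
    """Framewise displacement from a (T, 6) rigid-body parameter trace.

    FD(t) = |Δdx| + |Δdy| + |Δdz| + r(|Δα| + |Δβ| + |Δγ|), with Δ the
    backward frame difference and r the head radius in mm converting
    rotations (radians) to displacements.  FD(0) = 0 by convention.

    Parameters
    ----------
    motion : ndarray, shape (T, 6)
        Columns dx, dy, dz in mm then α, β, γ in radians.
    radius : float
        Rotation-to-displacement conversion radius in mm.

    Returns
    -------
    ndarray, shape (T,)
        FD in mm; non-negative, first element 0.
    """
    motion = _validate_trace(motion)
    delta = np.abs(np.diff(motion, axis=0))
    fd = delta[:, :3].sum(axis=1) + radius * delta[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def to_percent_bold(data: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Rescale a 4D series so the within-mask grand mean equals 100.

    After this rescaling a frame-to-frame difference of 1 is 1% of mean
    BOLD signal, which is the unit DVARS is thresholded in.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    grand_mean = data[brain_mask].mean()
    if grand_mean == 0:
        raise ValueError("series mean is zero within the brain mask; "
                         "% BOLD scale undefined")
    return data * (100.0 / grand_mean)


def dvars(series: Bold4D, brain_mask: np.ndarray) -> np.ndarray:
    """DVARS per frame, in % BOLD units.

    The series is rescaled to % BOLD (grand within-mask mean 100), then
    DVARS(t) is the root of the mean over in-mask voxels of the squared
    intensity difference between frames t and t−1.  DVARS(0) = 0.

    Parameters
    ----------
    series : Bold4D
        4D BOLD series (any intensity scale; rescaled internally).
    brain_mask : boolean ndarray matching the series' spatial shape.

    Returns
    -------
    ndarray, shape (T,)
        DVARS in % BOLD; non-negative, first element 0.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != series.shape3:
        raise ValueError("brain mask shape does not match series")
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    if series.n_timepoints < 2:
        raise ValueError("DVARS needs at least 2 frames")
    pct = to_percent_bold(series.data, brain_mask)
    voxels = pct[brain_mask]                     # (V, T)
    sq = np.diff(voxels, axis=1) ** 2
    out = np.sqrt(sq.mean(axis=0))
    return np.concatenate([[0.0], out])


def censor_mask(fd: np.ndarray,
                dvars_values: np.ndarray,
                fd_threshold: float = DEFAULT_FD_THRESHOLD_MM,
                dvars_threshold: float = DEFAULT_DVARS_THRESHOLD_PCT) -> CensorMask:
    """Scrubbing mask: drop every frame where FD or DVARS exceeds its limit.

    A frame is removed iff ``fd > fd_threshold`` **or**
    ``dvars > dvars_threshold`` (strict inequalities).  Defaults are
    0.5 mm and 0.5% BOLD.
    """
    fd = np.asarray(fd, dtype=float)
    dvars_values = np.asarray(dvars_values, dtype=float)
    if fd.shape != dvars_values.shape:
        raise ValueError(
            f"fd and dvars lengths differ: {fd.shape} vs {dvars_values.shape}"
        )
    keep = ~((fd > fd_threshold) | (dvars_values > dvars_threshold))
    return CensorMask(keep=keep, fd_threshold=fd_threshold,
                      dvars_threshold=dvars_threshold)


def motion_metrics(series: Bold4D, motion: np.ndarray, brain_mask: np.ndarray,
                   radius: float = DEFAULT_HEAD_RADIUS_MM) -> MotionMetrics:
    """Convenience wrapper computing FD and DVARS together."""
    if np.asarray(motion).shape[0] != series.n_timepoints:
        raise ValueError("motion trace and series lengths differ")
    return MotionMetrics(fd=framewise_displacement(motion, radius=radius),
                         dvars=dvars(series, brain_mask),
                         radius_mm=radius)
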