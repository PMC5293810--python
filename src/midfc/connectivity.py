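"""Per-subject seed connectivity: censored correlation and Fisher-z maps.

The seed time course is the unweighted spatial mean of the BOLD series
over the seed voxels.  Each brain voxel's Pearson correlation with the
seed is computed over the *kept* frames only (scrubbing deletes censored
frames outright rather than interpolating), then mapped through the
variance-stabilising Fisher transform z = 0.5*ln[(1+r)/(1-r)].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from midfc import io as mio
from midfc.cohort import SeedMaskPair, SubjectRecord, TissueMasks
from midfc.denoise import (
    DEFAULT_BAND_HZ,
    DEFAULT_DROP_FRAMES,
    DEFAULT_FWHM_MM,
    bandpass,
    build_nuisance,
    drop_initial_frames,
    gaussian_smooth,
    regress_nuisance,
)
from midfc.motion import (
    CensorMask,
    DEFAULT_DVARS_THRESHOLD_PCT,
    DEFAULT_FD_THRESHOLD_MM,
    censor_mask,
    dvars,
    framewise_displacement,
)
from midfc.volume import Bold4D, GridGeometry

DEFAULT_MIN_KEPT_FRAMES = 30
_R_CLIP = 1.0 - 1e-7


@dataclass
class PipelineParams:
    """Tunable knobs of the subject-level pipeline, with study defaults."""

    drop_frames: int = DEFAULT_DROP_FRAMES
    fwhm_mm: float = DEFAULT_FWHM_MM
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ
    fd_threshold: float = DEFAULT_FD_THRESHOLD_MM
    dvars_threshold: float = DEFAULT_DVARS_THRESHOLD_PCT
    min_kept_frames: int = DEFAULT_MIN_KEPT_FRAMES
    motion_derivatives: bool = False


@dataclass
class SubjectZMap:
    """One subject's Fisher-z connectivity map for one seed."""

    z: np.ndarray               # 3D; NaN outside the brain mask
    seed: str                   # "VTA" | "SNc"
    subject_id: str
    n_kept: int
    affine: np.ndarray
    record: SubjectRecord | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 3:
            raise ValueError("z map must be 3D")


def seed_timecourse(series: Bold4D, seed_mask: np.ndarray) -> np.ndarray:
    """Unweighted spatial mean of the series over the seed voxels."""
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != series.shape3:
        raise ValueError(
            f"seed mask shape {seed_mask.shape} does not match the series "
            f"grid {series.shape3}"
        )
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    return series.data[seed_mask].mean(axis=0)


def correlation_map(series: Bold4D,
                    seed_tc: np.ndarray,
                    censor: CensorMask | None,
                    brain_mask: np.ndarray,
                    min_kept_frames: int = DEFAULT_MIN_KEPT_FRAMES) -> np.ndarray:
    """Pearson correlation of every in-mask voxel with the seed time course,
    using kept frames only.

    Out-of-mask voxels are set to NaN.  Voxels with zero temporal variance
    get r = 0; their count is reported through a warning so group maps
    stay finite without silently hiding degenerate data.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    seed_tc = np.asarray(seed_tc, dtype=float)
    T = series.n_timepoints
    if seed_tc.shape != (T,):
        raise ValueError("seed time course length does not match the series")
    keep = np.ones(T, dtype=bool) if censor is None else censor.keep
    if keep.shape != (T,):
        raise ValueError("censor mask length does not match the series")
    n_kept = int(keep.sum())
    if n_kept < min_kept_frames:
        raise ValueError(
            f"only {n_kept} frames survive censoring "
            f"(minimum {min_kept_frames}); subject unusable"
        )
    x = seed_tc[keep]
    x = x - x.mean()
    sx = np.sqrt((x ** 2).sum())
    if sx == 0:
        raise ValueError("seed time course has zero variance on kept frames")
    vox = series.data[brain_mask][:, keep]
    vox = vox - vox.mean(axis=1, keepdims=True)
    sv = np.sqrt((vox ** 2).sum(axis=1))
    zero_var = sv == 0
    sv[zero_var] = 1.0
    r = (vox @ x) / (sv * sx)
    r[zero_var] = 0.0
    n_zero = int(zero_var.sum())
    if n_zero:
        warnings.warn(f"{n_zero} zero-variance voxels set to r = 0", stacklevel=2)
    rmap = np.full(series.shape3, np.nan)
    rmap[brain_mask] = np.clip(r, -1.0, 1.0)
    return rmap


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher's variance-stabilising transform z = 0.5*ln[(1+r)/(1-r)].

    Correlations are clipped to |r| <= 1 - 1e-7 before the transform so z
    stays finite at r = +/-1.  NaNs (out-of-mask sentinels) pass through.
    """
    arr = np.asarray(r, dtype=float)
    finite = np.isfinite(arr)
    if np.any(np.abs(arr[finite]) > 1.0 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    out = np.arctanh(np.clip(arr, -_R_CLIP, _R_CLIP))
    out = np.where(finite, out, arr)
    if np.isscalar(r):
        return float(out)
    return out


def run_subject(bold: Bold4D,
                motion: np.ndarray,
                seeds: SeedMaskPair,
                tissues: TissueMasks,
                params: PipelineParams | None = None,
                record: SubjectRecord | None = None,
                subject_id: str = "subject") -> dict:
    """The full subject-level pipeline, in memory.

    Stages, in order: initial-frame discard -> Gaussian smoothing ->
    nuisance regression (tissue signals + derivatives + motion) ->
    band-pass -> motion metrics -> censoring -> seed correlation ->
    Fisher z.  FD comes from the motion trace and DVARS from the smoothed
    series (the % BOLD scale is undefined on mean-zero residuals), and
    both are applied as frame deletion at the correlation stage.

    Returns a dict with ``zmaps`` ({"VTA": SubjectZMap, "SNc": ...}),
    ``r_maps``, and a ``qc`` block (FD/DVARS traces, censor mask, removed
    fraction).
    """
    params = params or PipelineParams()
    if record is not None:
        subject_id = record.subject_id
    try:
        series, motion = drop_initial_frames(bold, motion, n=params.drop_frames)
        series = gaussian_smooth(series, fwhm=params.fwhm_mm)
        fd = framewise_displacement(motion)
        dv = dvars(series, tissues.whole_brain)
        nuis = build_nuisance(series, tissues.as_dict(), motion,
                              motion_derivatives=params.motion_derivatives)
        series = regress_nuisance(series, nuis)
        series = bandpass(series, *params.band_hz)
        censor = censor_mask(fd, dv, fd_threshold=params.fd_threshold,
                             dvars_threshold=params.dvars_threshold)
        zmaps: dict[str, SubjectZMap] = {}
        r_maps: dict[str, np.ndarray] = {}
        for name in ("VTA", "SNc"):
            tc = seed_timecourse(series, seeds.mask(name))
            rmap = correlation_map(series, tc, censor, tissues.whole_brain,
                                   min_kept_frames=params.min_kept_frames)
            r_maps[name] = rmap
            zmaps[name] = SubjectZMap(z=fisher_z(rmap), seed=name,
                                      subject_id=subject_id,
                                      n_kept=censor.n_kept,
                                      affine=bold.affine.copy(),
                                      record=record)
    except Exception as exc:
        raise RuntimeError(f"subject {subject_id}: {exc}") from exc
    qc = {
        "subject_id": subject_id,
        "fd": fd,
        "dvars": dv,
        "keep": censor.keep,
        "n_kept": censor.n_kept,
        "removed_fraction": censor.removed_fraction,
        "fd_threshold": censor.fd_threshold,
        "dvars_threshold": censor.dvars_threshold,
    }
    return {"zmaps": zmaps, "r_maps": r_maps, "qc": qc}


def subject_pipeline(paths: dict[str, str | Path],
                     params: PipelineParams | None = None,
                     out_dir: str | Path | None = None,
                     subject_id: str | None = None) -> dict:
    """Path-based wrapper around :func:`run_subject`.

    ``paths`` must provide ``bold``, ``motion``, ``vta``, ``snc``,
    ``brain``, ``white_matter`` and ``ventricle``.  When ``out_dir`` is
    given, the two z maps and a QC sidecar JSON are written there.
    """
    required = ("bold", "motion", "vta", "snc", "brain", "white_matter",
                "ventricle")
    missing = [k for k in required if k not in paths]
    if missing:
        raise ValueError(f"missing input paths: {missing}")
    sid = subject_id or Path(paths["bold"]).name.split("_bold")[0]
    bold = mio.load_bold(paths["bold"])
    motion = mio.load_motion(paths["motion"])
    if motion.shape[0] != bold.n_timepoints:
        raise ValueError(
            f"subject {sid}: motion trace ({motion.shape[0]} frames) does not "
            f"match the BOLD series ({bold.n_timepoints} frames)")
    vta, _ = mio.load_mask(paths["vta"])
    snc, _ = mio.load_mask(paths["snc"])
    brain, _ = mio.load_mask(paths["brain"])
    wm, _ = mio.load_mask(paths["white_matter"])
    csf, _ = mio.load_mask(paths["ventricle"])
    seeds = SeedMaskPair(vta=vta, snc=snc, grid=bold.grid)
    tissues = TissueMasks(whole_brain=brain, white_matter=wm, ventricle=csf)
    result = run_subject(bold, motion, seeds, tissues, params=params,
                         subject_id=sid)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, zmap in result["zmaps"].items():
            mio.save_map(out_dir / f"{sid}_z_{name.lower()}.nii.gz",
                         np.nan_to_num(zmap.z), zmap.affine)
        qc = result["qc"]
        sidecar = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in qc.items()}
        (out_dir / f"{sid}_qc.json").write_text(json.dumps(sidecar, indent=2))
    return result
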