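"""File formats: NIfTI volumes and masks, motion traces, metadata, config.

NIfTI I/O goes through nibabel; the repetition time is stored in the
header's fourth zoom (the time-step field).  Motion parameters use the
whitespace-delimited realignment-parameter dialect: one row per frame,
columns dx dy dz (mm), then the three rotations (rad).  Metadata is a
comma-delimited table with header subject_id,age,sex,site,tr,n_timepoints.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from midfc.volume import Bold4D

METADATA_COLUMNS = ("subject_id", "age", "sex", "site", "tr", "n_timepoints")


def save_bold(path: str | Path, bold: Bold4D) -> None:
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    zooms = img.header.get_zooms()
    img.header.set_zooms((*zooms[:3], float(bold.tr)))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def load_bold(path: str | Path) -> Bold4D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got {data.ndim}D")
    tr = float(img.header.get_zooms()[3])
    if tr <= 0:
        raise ValueError(f"{path}: header lacks a positive TR")
    return Bold4D(data=data, affine=np.asarray(img.affine), tr=tr)


def save_mask(path: str | Path, mask: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.asarray(affine))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (boolean mask, affine)."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj) > 0, np.asarray(img.affine)


def save_map(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    """A 3D statistic or z map."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))


def load_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj, dtype=float), np.asarray(img.affine)


def save_motion(path: str | Path, motion: np.ndarray) -> None:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion trace must be (T, 6), got {motion.shape}")
    np.savetxt(str(path), motion, fmt="%.8e")


def load_motion(path: str | Path) -> np.ndarray:
    motion = np.loadtxt(str(path))
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"{path}: motion trace must have 6 columns")
    return motion


def save_metadata(path: str | Path, metadata: pd.DataFrame) -> None:
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata lacks columns {missing}")
    metadata.to_csv(str(path), index=False)


def load_metadata(path: str | Path) -> pd.DataFrame:
    metadata = pd.read_csv(str(path))
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"{path}: metadata lacks columns {missing}")
    return metadata


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(path: str | Path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
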