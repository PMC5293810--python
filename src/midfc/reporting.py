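"""Cluster labeling and report tables.

Surviving clusters are reported the way midbrain-connectivity studies
print them: volume in mm^3, peak Z (with peaks beyond Z = 8 shown as the
display token "Inf"), the peak's MNI coordinate in mm, a hemisphere side
code, and a free-text anatomical label supplied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

from midfc.volume import GridGeometry

TABLE_COLUMNS = ["volume_mm3", "peak_z", "x", "y", "z", "side", "label"]
Z_DISPLAY_CAP = 8.0
MIDLINE_MM = 2.0

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),    # faces only
    18: ndimage.generate_binary_structure(3, 2),   # faces + edges
    26: ndimage.generate_binary_structure(3, 3),   # faces + edges + corners
}


@dataclass
class ClusterRow:
    """One reported cluster."""

    volume_mm3: float
    peak_z: float               # numeric; rendering may print "Inf"
    peak_mni: tuple[float, float, float]
    side: str                   # "L" | "R" | "L/R"
    label: str = ""


def label_clusters(mask: np.ndarray, connectivity: int = 18
                   ) -> tuple[np.ndarray, int]:
    """Connected components of a suprathreshold mask.

    Components are relabeled deterministically: descending voxel count,
    ties broken by the lexicographically smallest voxel coordinate.  The
    default 18-neighbourhood (faces + edges) matches the dominant SPM
    convention; 6 and 26 are also available.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    mask = np.asarray(mask, dtype=bool)
    raw, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return raw, 0
    order = []
    for lab in range(1, n + 1):
        where = np.argwhere(raw == lab)
        order.append((-where.shape[0], tuple(where.min(axis=0)), lab))
    order.sort()
    out = np.zeros_like(raw)
    for new, (_, _, old) in enumerate(order, start=1):
        out[raw == old] = new
    return out, n


def _side_of(peak_x: float, cluster_x: np.ndarray) -> str:
    spans_midline = (cluster_x < 0).any() and (cluster_x > 0).any()
    if spans_midline or abs(peak_x) <= MIDLINE_MM:
        return "L/R"
    return "L" if peak_x < 0 else "R"


def cluster_table(clusters: list[dict],
                  grid: GridGeometry,
                  label_lookup: dict | None = None) -> pd.DataFrame:
    """Build the report table from :func:`midfc.inference.cluster_fwe` output.

    Each row carries the cluster's volume (voxel count times voxel
    volume), signed peak Z, peak MNI coordinate (mm, via the grid
    affine), a side code (peak x < -2 mm: "L"; > 2 mm: "R"; |x| <= 2 mm
    or a cluster spanning the midline: "L/R"), and a pass-through label
    from ``label_lookup`` (keyed by peak MNI tuple) if provided.

    An empty cluster list yields an empty table with the header columns.
    """
    rows = []
    vol = grid.voxel_volume
    for c in clusters:
        peak_ijk = np.asarray(c["peak_ijk"], dtype=float)
        peak_mni = grid.voxel_to_mm(peak_ijk)
        cluster_x = grid.voxel_to_mm(np.argwhere(c["mask"]))[:, 0]
        label = ""
        if label_lookup:
            label = label_lookup.get(tuple(np.round(peak_mni).astype(int)), "")
        rows.append({
            "volume_mm3": c["n_voxels"] * vol,
            "peak_z": float(c["peak_z"]),
            "x": float(peak_mni[0]),
            "y": float(peak_mni[1]),
            "z": float(peak_mni[2]),
            "side": _side_of(float(peak_mni[0]), cluster_x),
            "label": label,
        })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def render_table(table: pd.DataFrame) -> pd.DataFrame:
    """Display form of a cluster table: peaks beyond |Z| = 8 print "Inf"."""
    out = table.copy()
    out["peak_z"] = [
        "Inf" if abs(z) > Z_DISPLAY_CAP else f"{z:.2f}" for z in table["peak_z"]
    ]
    return out


def reference_slope_test_regions() -> pd.DataFrame:
    """The bundled reference list of men-only age-effect clusters.

    Twelve regions (3 with VTA connectivity changes, 9 with SNc) whose
    male age-regression slopes enter the men-vs-women slope-difference
    battery; this region count sets the battery's Bonferroni divisor.
    """
    with resources.files("midfc.data").joinpath("age_clusters_men.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
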