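"""Volumetric and surface measures from label maps.

The five study measures: total brain volume (TBV), choroid-plexus volume
(ChPV), cortical-plate volume (CoPV), cerebellar volume (CBV) — all voxel
counts × spacing³ — and cortical-plate surface area (CoPA) from a
marching-cubes isosurface.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage import measure as skmeasure

from .synthetic import CohortManifest
from .volume import LabelMap, read_labelmap

__all__ = ["label_volume", "label_surface_area", "normalized_chpv",
           "measures_from_labelmap", "build_measure_table",
           "MEASURE_COLUMNS"]

MEASURE_COLUMNS = ["scan_id", "subject_id", "site_id", "ga_weeks", "sex",
                   "hemisphere", "TBV", "ChPV", "CoPV", "CBV", "CoPA",
                   "ChPV_norm"]

#: label ids in the phantom/atlas labelling scheme
LABEL_BRAIN, LABEL_CHP, LABEL_COP, LABEL_CB = 1, 2, 3, 4


def _mask_of(labels: LabelMap | np.ndarray, label_id: int) -> np.ndarray:
    arr = labels.values if isinstance(labels, LabelMap) else np.asarray(labels)
    return arr == label_id


def _spacing(labels, spacing_mm) -> float:
    if spacing_mm is None:
        if isinstance(labels, LabelMap):
            spacing_mm = labels.spacing_mm[0]
        else:
            raise ValueError("spacing_mm required for bare arrays")
    if np.isscalar(spacing_mm):
        spacing_mm = float(spacing_mm)
    else:
        spacing_mm = float(spacing_mm[0])
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    return spacing_mm


def label_volume(labels: LabelMap | np.ndarray, label_id: int,
                 spacing_mm: float | None = None) -> float:
    """Volume of one label in mm³: voxel count × spacing³ (absent label → 0)."""
    sp = _spacing(labels, spacing_mm)
    return float(_mask_of(labels, label_id).sum()) * sp ** 3


def label_surface_area(labels: LabelMap | np.ndarray, label_id: int,
                       spacing_mm: float | None = None) -> float:
    """Surface area of one label in mm² from a marching-cubes isosurface.

    The binary mask is zero-padded by 2 voxels (so surfaces at the grid edge
    close properly), lightly Gaussian-smoothed (σ = 0.5 voxel — enough to
    suppress the voxelisation staircase that biases marching-cubes areas of
    curved surfaces upward by ~8%, while barely rounding genuine edges),
    meshed at the 0.5 level, and the triangle areas are summed.  An empty
    label gives 0.
    """
    from scipy.ndimage import gaussian_filter

    sp = _spacing(labels, spacing_mm)
    mask = _mask_of(labels, label_id)
    if not mask.any():
        return 0.0
    padded = gaussian_filter(np.pad(mask.astype(np.float64), 2), 0.5)
    verts, faces, _, _ = skmeasure.marching_cubes(padded, level=0.5)
    return float(skmeasure.mesh_surface_area(verts, faces)) * sp ** 2


def normalized_chpv(chpv_mm3: float, tbv_mm3: float) -> float:
    """Choroid-plexus share of total brain volume (ChPV / TBV)."""
    if tbv_mm3 <= 0:
        raise ValueError("TBV must be positive")
    return chpv_mm3 / tbv_mm3


def measures_from_labelmap(labels: LabelMap,
                           spacing_mm: float | None = None) -> dict:
    """All five measures from one label map.

    TBV counts every foreground label (the whole brain mask); ChPV, CoPV and
    CBV count their own labels; CoPA is the mesh area of the CoP shell.
    """
    sp = _spacing(labels, spacing_mm)
    arr = labels.values if isinstance(labels, LabelMap) else np.asarray(labels)
    tbv = float((arr > 0).sum()) * sp ** 3
    chpv = label_volume(arr, LABEL_CHP, sp)
    copv = label_volume(arr, LABEL_COP, sp)
    cbv = label_volume(arr, LABEL_CB, sp)
    copa = label_surface_area(arr, LABEL_COP, sp)
    return {"TBV": tbv, "ChPV": chpv, "CoPV": copv, "CBV": cbv, "CoPA": copa,
            "ChPV_norm": normalized_chpv(chpv, tbv) if tbv > 0 else np.nan}


def build_measure_table(manifest: CohortManifest) -> pd.DataFrame:
    """One row of measures + metadata per scan, sorted by (ga_weeks, scan_id).

    Scans whose label files are missing are reported (as rows with NaN
    measures and a console warning) and the run continues.
    """
    rows = []
    for rec in manifest.records:
        row = {"scan_id": rec.scan_id, "subject_id": rec.subject_id,
               "site_id": rec.site_id, "ga_weeks": rec.ga_weeks,
               "sex": rec.sex, "hemisphere": rec.hemisphere}
        try:
            lab = read_labelmap(rec.labels_path)
            row.update(measures_from_labelmap(lab))
        except (FileNotFoundError, OSError) as exc:
            import warnings
            warnings.warn(f"{rec.scan_id}: cannot read labels "
                          f"({exc}); measures set to NaN")
            row.update({k: np.nan for k in
                        ("TBV", "ChPV", "CoPV", "CBV", "CoPA", "ChPV_norm")})
        rows.append(row)
    df = pd.DataFrame(rows, columns=MEASURE_COLUMNS)
    return df.sort_values(["ga_weeks", "scan_id"]).reset_index(drop=True)
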