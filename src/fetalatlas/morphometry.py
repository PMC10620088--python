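"""Tensor-based morphometry on deformation fields.

The Jacobian determinant of a deformation measures local volume change; its
logarithm symmetrises expansion against contraction around zero.  Because the
registration stage emits template→scan (backward) fields, a structure that is
*larger in the scan* than in the template shows a determinant above 1.
Group comparisons subtract mean log-Jacobian maps: the two-week temporal
contrast JD = mean(J^a) − mean(J^b), and the hemispheric asymmetry contrast
mean(left) − mean(mirrored right).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import DeformationField
from .preprocess import mirror_midsagittal
from .registration import (AtlasTemplate, DemonsParams, affine_size_normalize,
                           apply_affine, build_groupwise_atlas)
from .volume import Volume3D

__all__ = [
    "JacobianMap", "JDMap",
    "jacobian_determinant", "log_jacobian", "jd_group_difference",
    "temporal_pair_atlas", "asymmetry_logjacobians",
]

#: determinants are clamped here before taking the logarithm
LOG_CLAMP_EPS = 1e-6


@dataclass
class JacobianMap:
    """Per-voxel Jacobian determinant (or its log) of a deformation."""

    values: np.ndarray
    is_log: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class JDMap:
    """Voxel-wise difference of group-mean log-Jacobians (weeks a vs b)."""

    values: np.ndarray
    n_a: int
    n_b: int
    week_a: float | None = None
    week_b: float | None = None


def jacobian_determinant(dfield: DeformationField) -> JacobianMap:
    """Determinant of ∇(x + u(x)) by finite differences.

    Central differences at interior voxels, one-sided at the boundary faces
    (``np.gradient`` semantics).  Statistics downstream should erode masks by
    one voxel to drop the one-sided boundary estimates.
    """
    u = dfield.vectors
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite displacement field")
    shape = u.shape[:3]
    J = np.empty(shape + (3, 3))
    for i in range(3):
        for j, g in enumerate(np.gradient(u[..., i])):
            J[..., i, j] = g
        J[..., i, i] += 1.0
    return JacobianMap(np.linalg.det(J), is_log=False)


def log_jacobian(dfield: DeformationField,
                 eps: float = LOG_CLAMP_EPS) -> JacobianMap:
    """Natural log of the Jacobian determinant, clamped at ``eps`` below."""
    det = jacobian_determinant(dfield).values
    return JacobianMap(np.log(np.maximum(det, eps)), is_log=True)


def _stack(maps) -> np.ndarray:
    arrs = [m.values if isinstance(m, JacobianMap) else np.asarray(m)
            for m in maps]
    if not arrs:
        raise ValueError("empty group")
    if any(a.shape != arrs[0].shape for a in arrs):
        raise ValueError("maps must share a common grid")
    return np.stack(arrs)


def jd_group_difference(logjacs_a, logjacs_b,
                        week_a: float | None = None,
                        week_b: float | None = None) -> JDMap:
    """JD = mean over group a − mean over group b, voxel-wise.

    With backward fields, regions that are larger at the later week b carry
    larger J^b, so structural expansion from a to b appears as negative JD
    under this subtraction order; the sign convention is recorded by the
    (week_a, week_b) metadata.
    """
    A, B = _stack(logjacs_a), _stack(logjacs_b)
    if A.shape[1:] != B.shape[1:]:
        raise ValueError("groups live on different grids")
    return JDMap(A.mean(0) - B.mean(0), n_a=A.shape[0], n_b=B.shape[0],
                 week_a=week_a, week_b=week_b)


def _normalize_scans(scans, masks):
    """Affine size normalisation of multi-channel scans via their masks."""
    first_chan = [sc[0] for sc in scans]
    _, tfs = affine_size_normalize(first_chan, masks)
    out = []
    for sc, tf in zip(scans, tfs):
        out.append(tuple(apply_affine(ch, tf, order=1) for ch in sc))
    return out


def temporal_pair_atlas(scans_week_a, scans_week_b, masks_a, masks_b,
                        params: DemonsParams | None = None,
                        week_a: float | None = None,
                        week_b: float | None = None,
                        size_normalize: bool = True,
                        ) -> tuple[AtlasTemplate, JDMap, list[np.ndarray]]:
    """Joint two-timepoint atlas and its temporal JD contrast.

    Scans from weeks a and b (b = a + 2 in the weekly design) are pooled into
    one groupwise template representing the intermediate age; per-scan
    log-Jacobians are returned in template space along with
    JD = mean(J^a) − mean(J^b).
    """
    if week_a is not None and week_b is not None and week_b != week_a + 2:
        raise ValueError("temporal pairs are two weeks apart (b = a + 2)")
    if not scans_week_a or not scans_week_b:
        raise ValueError("both week groups must be non-empty")
    scans = list(scans_week_a) + list(scans_week_b)
    if size_normalize:
        scans = _normalize_scans(scans, list(masks_a) + list(masks_b))
    atlas = build_groupwise_atlas(scans, params, week=week_a)
    n_a = len(scans_week_a)
    logjacs = atlas.log_jacobians
    jd = jd_group_difference(logjacs[:n_a], logjacs[n_a:],
                             week_a=week_a, week_b=week_b)
    return atlas, jd, logjacs


def asymmetry_logjacobians(left_scans, right_scans, left_masks, right_masks,
                           params: DemonsParams | None = None,
                           week: float | None = None,
                           mirror_right: bool = True,
                           size_normalize: bool = True,
                           ) -> tuple[AtlasTemplate, list[np.ndarray],
                                      list[np.ndarray]]:
    """Hemispheric-asymmetry morphometry at one gestational week.

    Right-visible scans are flipped across the midsagittal plane so they
    spatially match the left maps, a joint groupwise template is built over
    {left, mirrored right}, and each scan's log-Jacobian in template space is
    returned, split by group and ready for permutation testing.  Inputs are
    affine size-normalised first, so detected effects are morphological
    rather than global-size differences.
    """
    if len(left_scans) < 2 or len(right_scans) < 2:
        raise ValueError("need at least 2 scans per hemisphere group")
    right = list(right_scans)
    rmasks = [np.asarray(m) for m in right_masks]
    if mirror_right:
        right = [tuple(mirror_midsagittal(ch) if isinstance(ch, Volume3D)
                       else Volume3D(np.asarray(ch)[::-1].copy())
                       for ch in sc) for sc in right]
        rmasks = [m[::-1].copy() for m in rmasks]
    scans = list(left_scans) + right
    if size_normalize:
        scans = _normalize_scans(scans, list(left_masks) + rmasks)
    atlas = build_groupwise_atlas(scans, params, week=week)
    n_l = len(left_scans)
    return atlas, atlas.log_jacobians[:n_l], atlas.log_jacobians[n_l:]
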