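"""Diffeomorphic multi-channel log-demons registration and groupwise atlases.

Pairwise registration is symmetric-forces demons in the log domain: a
stationary velocity field is updated from per-channel demons forces (fluid
smoothing of the update, first-order log-domain composition, diffusion
smoothing of the velocity), and exponentiated by scaling and squaring into a
guaranteed-diffeomorphic displacement field.  Atlas construction is
template-free: every scan is registered to an evolving voxel-wise mean
template, the per-scan velocities are debiased by subtracting their mean, and
the template is rebuilt from the warped scans until it stops changing.

Direction convention: every emitted field maps *template* coordinates into
*scan* coordinates (backward warping), so ``warp_volume(scan, field)`` pulls
the scan into template space.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .fields import (DeformationField, VelocityField, compose_fields,
                     exp_velocity, identity_grid, invert_field, warp_array)
from .volume import Volume3D

__all__ = [
    "DemonsParams", "AtlasTemplate", "AffineTransform",
    "demons_multichannel", "warp_volume", "build_groupwise_atlas",
    "affine_size_normalize", "apply_affine",
    "save_atlas_bundle", "load_atlas_bundle",
    "exp_velocity", "compose_fields", "invert_field",
]


@dataclass
class DemonsParams:
    """Tunable parameters of the log-demons optimisation.

    ``iterations`` is ordered finest→coarsest resolution; σs are in voxels at
    the working resolution.  ``channel_weights`` defaults to equal weights
    normalised to sum to 1.
    """

    n_levels: int = 3
    iterations: tuple[int, ...] = (25, 50, 100)
    sigma_fluid: float = 2.0
    sigma_diffusion: float = 1.0
    max_step: float = 2.0
    channel_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.sigma_fluid <= 0 or self.sigma_diffusion <= 0:
            raise ValueError("smoothing sigmas must be positive")
        if len(self.iterations) < self.n_levels:
            raise ValueError("need an iteration count per pyramid level")

    def weights(self, n_channels: int) -> np.ndarray:
        if self.channel_weights is None:
            w = np.full(n_channels, 1.0 / n_channels)
        else:
            w = np.asarray(self.channel_weights, dtype=np.float64)
            if len(w) != n_channels:
                raise ValueError("one weight per channel required")
            if w.sum() <= 0:
                raise ValueError("weights must sum to a positive value")
            w = w / w.sum()
        return w


def _as_array(x) -> np.ndarray:
    return np.asarray(x.values if isinstance(x, Volume3D) else x,
                      dtype=np.float64)


def _downsample(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return arr
    sm = ndimage.gaussian_filter(arr, 0.5 * factor)
    return ndimage.zoom(sm, 1.0 / factor, order=1, prefilter=False)


def _upsample_velocity(v: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    out = np.empty(shape + (3,))
    zoom = [t / s for t, s in zip(shape, v.shape[:3])]
    for k in range(3):
        out[..., k] = ndimage.zoom(v[..., k], zoom, order=1,
                                   prefilter=False) * zoom[k]
    return out


def _demons_update(fixed: list[np.ndarray], grads: list[np.ndarray],
                   moving: list[np.ndarray], disp: np.ndarray,
                   weights: np.ndarray, max_step: float) -> np.ndarray:
    """Symmetric-forces demons step, weighted over channels."""
    upd = np.zeros(disp.shape)
    coords = identity_grid(disp.shape[:3]) + disp
    pts = [coords[..., k] for k in range(3)]
    for w, F, gF, M in zip(weights, fixed, grads, moving):
        if w == 0.0:
            continue
        Mw = ndimage.map_coordinates(M, pts, order=1, mode="nearest")
        diff = F - Mw
        gM = np.stack(np.gradient(Mw), -1)
        J = 0.5 * (gF + gM)
        Jsq = (J ** 2).sum(-1)
        denom = Jsq + (diff ** 2) / (max_step ** 2)
        step = np.where(denom > 1e-12, diff / np.maximum(denom, 1e-12), 0.0)
        upd += w * step[..., None] * J
    return upd


def demons_multichannel(fixed_channels, moving_channels,
                        params: DemonsParams | None = None,
                        init_velocity: VelocityField | None = None,
                        ) -> tuple[VelocityField, DeformationField]:
    """Register ``moving`` onto ``fixed`` (both lists of aligned channels).

    Returns the stationary velocity and its exponential; the displacement
    satisfies ``moving(x + u(x)) ≈ fixed(x)``.  The per-channel mean squared
    difference is tracked at the finest level; an increase of more than 10%
    over its starting value aborts with diagnostics.
    """
    params = params or DemonsParams()
    fixed = [_as_array(c) for c in fixed_channels]
    moving = [_as_array(c) for c in moving_channels]
    if len(fixed) != len(moving):
        raise ValueError("channel count mismatch")
    if any(f.shape != fixed[0].shape for f in fixed + moving):
        raise ValueError("all channels must share one grid")
    if any(not np.all(np.isfinite(c)) for c in fixed + moving):
        raise ValueError("non-finite channel values")
    weights = params.weights(len(fixed))
    shape = fixed[0].shape

    v: np.ndarray | None = None
    for level in range(params.n_levels - 1, -1, -1):
        factor = 2 ** level
        lshape = tuple(max(4, n // factor) for n in shape)
        if factor == 1:
            Fs, Ms = fixed, moving
        else:
            Fs = [_downsample(F, factor) for F in fixed]
            Ms = [_downsample(M, factor) for M in moving]
            lshape = Fs[0].shape
        grads = [np.stack(np.gradient(F), -1) for F in Fs]
        if v is None:
            if init_velocity is not None:
                v = _upsample_velocity(init_velocity.vectors, lshape) \
                    if init_velocity.grid_shape != lshape \
                    else init_velocity.vectors.copy()
            else:
                v = np.zeros(lshape + (3,))
        else:
            v = _upsample_velocity(v, lshape)

        mse0 = mse = _channel_mse(Fs, Ms, v, weights)
        for _ in range(params.iterations[level]):
            # inner-loop exponential at the 0.5-voxel step bound is enough
            # for force evaluation; the returned field is re-exponentiated
            # at full accuracy below
            vf = VelocityField(v)
            n_fast = max(1, int(np.ceil(np.log2(
                max(vf.max_magnitude(), 1e-12) / 0.5))))
            disp = exp_velocity(vf, n_fast).vectors
            upd = _demons_update(Fs, grads, Ms, disp, weights, params.max_step)
            for k in range(3):
                upd[..., k] = ndimage.gaussian_filter(upd[..., k],
                                                      params.sigma_fluid)
            v = v + upd  # first-order log-domain composition (BCH order 1)
            for k in range(3):
                v[..., k] = ndimage.gaussian_filter(v[..., k],
                                                    params.sigma_diffusion)
        if level == 0:
            mse = _channel_mse(Fs, Ms, v, weights)
            if mse0 > 1e-15 and mse > 1.10 * mse0:
                raise RuntimeError(
                    f"demons diverged: similarity rose from {mse0:.3e} "
                    f"to {mse:.3e}")
    vel = VelocityField(v)
    return vel, exp_velocity(vel)


def _channel_mse(Fs, Ms, v, weights) -> float:
    disp = exp_velocity(VelocityField(v)).vectors
    total = 0.0
    for w, F, M in zip(weights, Fs, Ms):
        Mw = warp_array(M, disp, order=1, mode="nearest")
        total += w * float(((F - Mw) ** 2).mean())
    return total


def warp_volume(vol: Volume3D, dfield: DeformationField,
                interpolation: str = "trilinear") -> Volume3D:
    """Backward-mapping resampling of a volume through a displacement field."""
    if vol.shape != dfield.grid_shape:
        raise ValueError("volume/field grid mismatch")
    order = {"trilinear": 1, "nearest": 0}[interpolation]
    return vol.with_values(warp_array(vol.values, dfield.vectors, order=order))


@dataclass
class AtlasTemplate:
    """A group-average template with the per-scan fields that produced it."""

    mean_image: Volume3D
    week: float | None
    hemisphere: str | None
    fields: list[DeformationField]
    velocities: list[VelocityField]
    log_jacobians: list[np.ndarray]
    n_scans: int
    mean_channels: list[np.ndarray] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_scans < 2:
            raise ValueError("an atlas needs at least 2 scans")

    def mean_displacement_magnitude(self) -> float:
        stack = np.stack([f.vectors for f in self.fields])
        return float(np.sqrt((stack.mean(0) ** 2).sum(-1)).max())


def build_groupwise_atlas(scans, params: DemonsParams | None = None,
                          week: float | None = None,
                          hemisphere: str | None = None,
                          max_outer: int = 10, tol: float = 1e-3,
                          ) -> AtlasTemplate:
    """Template-free groupwise atlas over multi-channel scans.

    ``scans`` is a list of per-scan channel tuples (e.g. ``(intensity,
    edge)``), all on one grid.  Starting from the voxel-wise mean, the loop
    (1) registers every scan to the current template, (2) subtracts the mean
    velocity from each scan's velocity (debiasing, which keeps the template
    centred in the population), (3) rebuilds the template as the voxel-wise
    mean of the warped channels, and stops when the RMS template change drops
    below ``tol`` of the intensity range or after ``max_outer`` iterations.
    The result is invariant to scan order up to floating-point summation.
    """
    from .morphometry import log_jacobian  # local import avoids a cycle

    params = params or DemonsParams()
    if len(scans) < 2:
        raise ValueError("groupwise atlas needs at least 2 scans")
    chans = [[_as_array(c) for c in scan] for scan in scans]
    n_ch = len(chans[0])
    if any(len(sc) != n_ch for sc in chans):
        raise ValueError("every scan must supply the same channels")
    shape = chans[0][0].shape
    spacing = (scans[0][0].spacing_mm
               if isinstance(scans[0][0], Volume3D) else (1.0, 1.0, 1.0))

    template = [np.mean([sc[c] for sc in chans], axis=0) for c in range(n_ch)]
    intensity_range = max(float(np.ptp(template[0])), 1e-12)
    vels: list[VelocityField | None] = [None] * len(chans)

    prev_mse = np.inf
    for outer in range(max_outer):
        new_vels = []
        for i, sc in enumerate(chans):
            v, _ = demons_multichannel(template, sc, params,
                                       init_velocity=vels[i])
            new_vels.append(v)
        # debias: recentre the velocity ensemble on zero mean
        mean_v = np.mean([v.vectors for v in new_vels], axis=0)
        vels = [VelocityField(v.vectors - mean_v) for v in new_vels]
        disps = [exp_velocity(v) for v in vels]
        warped = [[warp_array(sc[c], d.vectors, order=1, mode="nearest")
                   for c in range(n_ch)] for sc, d in zip(chans, disps)]
        new_template = [np.mean([w[c] for w in warped], axis=0)
                        for c in range(n_ch)]
        change = float(np.sqrt(np.mean((new_template[0] - template[0]) ** 2)))
        mse = float(np.mean([((w[0] - new_template[0]) ** 2).mean()
                             for w in warped]))
        template = new_template
        if change < tol * intensity_range:
            break
        if mse > 1.10 * prev_mse and outer > 0:
            raise RuntimeError("groupwise atlas diverged "
                               f"(dissimilarity {prev_mse:.3e} -> {mse:.3e})")
        prev_mse = min(prev_mse, mse)

    logjacs = [log_jacobian(d).values for d in disps]
    return AtlasTemplate(
        mean_image=Volume3D(template[0], spacing),
        week=week, hemisphere=hemisphere,
        fields=disps, velocities=list(vels), log_jacobians=logjacs,
        n_scans=len(chans), mean_channels=template)


def save_atlas_bundle(atlas: AtlasTemplate, out_dir) -> "Path":
    """Write an atlas as a directory bundle.

    Layout: ``template.nii.gz``, ``fields/scan###.nii.gz`` (4D NIfTI, three
    vector components in voxel units, template→scan direction),
    ``logjac/scan###.nii.gz``, and ``meta.json`` with week, hemisphere,
    scan count and the field direction convention.
    """
    import json
    from pathlib import Path

    import nibabel as nib

    from .volume import write_volume

    out = Path(out_dir)
    (out / "fields").mkdir(parents=True, exist_ok=True)
    (out / "logjac").mkdir(parents=True, exist_ok=True)
    write_volume(atlas.mean_image, out / "template.nii.gz")
    sp = atlas.mean_image.spacing_mm
    aff = np.diag(list(sp) + [1.0])
    for i, (f, lj) in enumerate(zip(atlas.fields, atlas.log_jacobians)):
        nib.save(nib.Nifti1Image(f.vectors.astype(np.float32), aff),
                 str(out / "fields" / f"scan{i:03d}.nii.gz"))
        nib.save(nib.Nifti1Image(np.asarray(lj, dtype=np.float32), aff),
                 str(out / "logjac" / f"scan{i:03d}.nii.gz"))
    (out / "meta.json").write_text(json.dumps({
        "week": atlas.week, "hemisphere": atlas.hemisphere,
        "n_scans": atlas.n_scans,
        "field_direction": atlas.fields[0].direction if atlas.fields else
        "template_to_scan",
        "spacing_mm": list(sp),
    }, indent=2, sort_keys=True))
    return out


def load_atlas_bundle(bundle_dir) -> AtlasTemplate:
    """Read an atlas bundle written by :func:`save_atlas_bundle`.

    Velocities are not persisted; the loaded template carries empty
    velocity slots (fields and log-Jacobians are what analyses consume).
    """
    import json
    from pathlib import Path

    import nibabel as nib

    from .volume import read_volume

    bundle = Path(bundle_dir)
    meta = json.loads((bundle / "meta.json").read_text())
    mean_image = read_volume(bundle / "template.nii.gz")
    fields, logjacs = [], []
    for path in sorted((bundle / "fields").glob("scan*.nii.gz")):
        arr = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
        fields.append(DeformationField(arr, meta["field_direction"]))
    for path in sorted((bundle / "logjac").glob("scan*.nii.gz")):
        logjacs.append(np.asanyarray(nib.load(str(path)).dataobj)
                       .astype(np.float64))
    return AtlasTemplate(mean_image=mean_image, week=meta["week"],
                         hemisphere=meta["hemisphere"], fields=fields,
                         velocities=[], log_jacobians=logjacs,
                         n_scans=meta["n_scans"])


@dataclass
class AffineTransform:
    """12-parameter affine ``y = A x + t`` in voxel coordinates.

    ``isotropic_scale`` is det(A)^{1/3}, recorded separately so analyses can
    exclude global size.
    """

    matrix: np.ndarray
    translation: np.ndarray

    @property
    def isotropic_scale(self) -> float:
        return float(np.linalg.det(self.matrix) ** (1.0 / 3.0))


def _moments(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argwhere(mask)
    if len(idx) == 0:
        raise ValueError("empty mask")
    mu = idx.mean(0)
    cov = np.cov(idx.T, bias=True) + np.eye(3) * 1e-9
    return mu, cov


def _sym_sqrt(C: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    return V @ np.diag(np.sqrt(np.maximum(w, 1e-12))) @ V.T


def apply_affine(vol: Volume3D, tf: AffineTransform,
                 order: int = 1) -> Volume3D:
    """Resample a volume through ``y = A x + t`` (backward mapping)."""
    Ainv = np.linalg.inv(tf.matrix)
    grid = identity_grid(vol.shape)
    src = (grid - tf.translation) @ Ainv.T
    vals = ndimage.map_coordinates(np.asarray(vol.values, np.float64),
                                   [src[..., k] for k in range(3)],
                                   order=order, mode="constant")
    if order == 0:
        vals = np.rint(vals)
    return vol.with_values(vals)


def affine_size_normalize(volumes: list[Volume3D], masks: list[np.ndarray],
                          target_mask: np.ndarray | None = None,
                          ) -> tuple[list[Volume3D], list[AffineTransform]]:
    """Moments-based affine normalisation of each input onto a target shape.

    For every (volume, brain mask) pair, the affine matching the mask's
    centroid and second moments to the target's is computed in closed form
    (``A = C_t^{1/2} C_s^{-1/2}`` with symmetric square roots, so no spurious
    rotation is introduced for near-aligned inputs), the volume is resampled
    through it, and the transform — including its isotropic-scale component —
    is returned.  ``target_mask`` defaults to the first input's mask.
    """
    if len(volumes) != len(masks):
        raise ValueError("one mask per volume required")
    tgt = masks[0] if target_mask is None else target_mask
    mu_t, C_t = _moments(np.asarray(tgt) > 0)
    St = _sym_sqrt(C_t)
    out_vols, out_tf = [], []
    for vol, mask in zip(volumes, masks):
        mu_s, C_s = _moments(np.asarray(mask) > 0)
        A = St @ np.linalg.inv(_sym_sqrt(C_s))
        t = mu_t - A @ mu_s
        tf = AffineTransform(A, t)
        out_vols.append(apply_affine(vol, tf, order=1))
        out_tf.append(tf)
    return out_vols, out_tf
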