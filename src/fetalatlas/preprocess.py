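"""Standardisation of individual scans into the common coordinate space.

The stages mirror a fetal-ultrasound atlas pipeline: resampling to isotropic
0.6 mm voxels, cropping to a fixed 160-cube around the brain centre,
seven-parameter rigid+scale landmark alignment, brain masking, histogram
matching to an age-matched reference, monogenic-signal edge maps, and
hemisphere selection / midsagittal mirroring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import LabelMap, Volume3D

__all__ = [
    "LandmarkSet", "SimilarityTransform",
    "resample_isotropic", "crop_to_cube", "rigid_align", "apply_similarity",
    "mask_brain", "histogram_match", "monogenic_feature_asymmetry",
    "select_hemisphere", "mirror_midsagittal",
]

#: log-Gabor centre wavelengths as fractions of the grid extent
DEFAULT_FA_SCALES = (0.075, 0.125, 0.175)


@dataclass
class LandmarkSet:
    """Labelled 3D points (mm), e.g. on the corpus callosum / CSP complex."""

    labels: tuple[str, ...]
    points_mm: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.points_mm = np.asarray(self.points_mm, dtype=np.float64)
        if self.points_mm.ndim != 2 or self.points_mm.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if len(self.labels) != len(self.points_mm):
            raise ValueError("label/point count mismatch")
        if len(self.points_mm) < 3:
            raise ValueError("need at least 3 landmarks")

    @classmethod
    def from_tsv(cls, path) -> "LandmarkSet":
        labels, pts = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("label\t"):
                    continue
                name, x, y, z = line.split("\t")
                labels.append(name)
                pts.append([float(x), float(y), float(z)])
        return cls(tuple(labels), np.array(pts))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tx_mm\ty_mm\tz_mm\n")
            for name, p in zip(self.labels, self.points_mm):
                fh.write(f"{name}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\n")


@dataclass
class SimilarityTransform:
    """Seven-parameter transform: 3 translations (mm), rotation, isotropic scale.

    Maps source points as ``scale * R @ p + t``.
    """

    rotation: np.ndarray      # (3, 3) orthonormal, det +1
    translation_mm: np.ndarray  # (3,)
    scale: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation_mm = np.asarray(self.translation_mm, dtype=np.float64)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation determinant must be +1")

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        return self.scale * points_mm @ self.rotation.T + self.translation_mm

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self ∘ other (apply ``other`` first)."""
        return SimilarityTransform(
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation_mm + self.translation_mm,
            self.scale * other.scale)


def resample_isotropic(vol: Volume3D, target_mm: float = 0.6) -> Volume3D:
    """Resample to isotropic voxels using trilinear interpolation.

    The field of view is preserved (output extent equals input extent up to
    one voxel).  A volume already on the target grid is returned unchanged.
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    sp = vol.spacing_mm
    if any(s <= 0 for s in sp):
        raise ValueError("missing or non-positive spacing metadata")
    if vol.is_isotropic and abs(sp[0] - target_mm) < 1e-9:
        return vol.copy()
    zoom = [s / target_mm for s in sp]
    new_shape = [max(1, int(round(n * z))) for n, z in zip(vol.shape, zoom)]
    # sample output voxel centres back onto the input grid
    coords = np.meshgrid(*[
        (np.arange(m) * target_mm) / s for m, s in zip(new_shape, sp)],
        indexing="ij")
    values = ndimage.map_coordinates(np.asarray(vol.values, dtype=np.float64),
                                     coords, order=1, mode="nearest")
    return Volume3D(values, (target_mm,) * 3, vol.origin_mm)


def crop_to_cube(vol: Volume3D, size: int = 160,
                 centre: tuple[int, int, int] | None = None) -> Volume3D:
    """Crop (with zero padding) to a ``size``³ cube around ``centre``.

    ``centre`` defaults to the grid centre.  Regions falling outside the
    original grid are zero-filled, so any centre inside the grid is valid.
    """
    if centre is None:
        centre = tuple(n // 2 for n in vol.shape)
    if any(c < 0 or c >= n for c, n in zip(centre, vol.shape)):
        raise ValueError(f"centre {centre} outside grid {vol.shape}")
    out = np.zeros((size, size, size), dtype=np.float64)
    lo = [c - size // 2 for c in centre]
    src = tuple(slice(max(0, l), min(n, l + size))
                for l, n in zip(lo, vol.shape))
    dst = tuple(slice(max(0, -l), max(0, -l) + (s.stop - s.start))
                for l, s in zip(lo, src))
    out[dst] = vol.values[src]
    origin = tuple(o + l * s for o, l, s in zip(vol.origin_mm, lo, vol.spacing_mm))
    return Volume3D(out, vol.spacing_mm, origin)


def rigid_align(landmarks: LandmarkSet,
                template_landmarks: LandmarkSet) -> SimilarityTransform:
    """Closed-form least-squares similarity transform (Umeyama/Procrustes).

    Finds the 7-parameter transform (rotation, translation, one isotropic
    scale) mapping ``landmarks`` onto ``template_landmarks`` with minimal
    summed squared distance.
    """
    if landmarks.labels != template_landmarks.labels:
        raise ValueError("landmark labels must match pairwise")
    src = landmarks.points_mm
    dst = template_landmarks.points_mm
    mu_s, mu_d = src.mean(0), dst.mean(0)
    sc, dc = src - mu_s, dst - mu_d
    var_s = (sc ** 2).sum() / len(src)
    if var_s < 1e-12:
        raise ValueError("degenerate landmark configuration (coincident points)")
    # collinearity check: rank of centred source must be >= 2
    if np.linalg.matrix_rank(sc, tol=1e-8 * np.abs(sc).max()) < 2:
        raise ValueError("degenerate landmark configuration (collinear points)")
    cov = dc.T @ sc / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    scale = float(np.trace(np.diag(D) @ S) / var_s)
    t = mu_d - scale * R @ mu_s
    return SimilarityTransform(R, t, scale)


def apply_similarity(vol: Volume3D, transform: SimilarityTransform,
                     order: int = 1) -> Volume3D:
    """Resample a volume through a similarity transform (backward mapping)."""
    inv_scale = 1.0 / transform.scale
    Rinv = transform.rotation.T
    grid = np.stack(np.meshgrid(*[np.arange(n, dtype=np.float64)
                                  for n in vol.shape], indexing="ij"), -1)
    sp = np.array(vol.spacing_mm)
    world = grid * sp + np.array(vol.origin_mm)
    src_world = inv_scale * (world - transform.translation_mm) @ Rinv.T
    src_vox = (src_world - np.array(vol.origin_mm)) / sp
    values = ndimage.map_coordinates(np.asarray(vol.values, np.float64),
                                     [src_vox[..., k] for k in range(3)],
                                     order=order, mode="constant")
    return vol.with_values(values)


def mask_brain(vol: Volume3D, mask: LabelMap | np.ndarray) -> Volume3D:
    """Zero every voxel outside the brain mask."""
    m = mask.mask() if isinstance(mask, LabelMap) else np.asarray(mask) > 0
    if m.shape != vol.shape:
        raise ValueError(f"mask grid {m.shape} != volume grid {vol.shape}")
    return vol.with_values(np.where(m, vol.values, 0.0))


def histogram_match(vol: Volume3D, reference: Volume3D, n_levels: int = 256,
                    mask: np.ndarray | None = None,
                    ref_mask: np.ndarray | None = None) -> Volume3D:
    """Monotone intensity remapping so the output CDF matches the reference's.

    Quantile mapping at ``n_levels`` evenly spaced quantiles; when brain masks
    are supplied the mapping is estimated (and applied) within them only.  A
    constant reference is degenerate and the input is returned unchanged.
    """
    m = np.ones(vol.shape, bool) if mask is None else np.asarray(mask) > 0
    rm = (np.ones(reference.shape, bool) if ref_mask is None
          else np.asarray(ref_mask) > 0)
    src = vol.values[m]
    ref = reference.values[rm]
    if src.size == 0 or ref.size == 0:
        raise ValueError("empty volume or reference within mask")
    if np.ptp(ref) < 1e-12 or np.ptp(src) < 1e-12:
        return vol.copy()  # degenerate: identity mapping
    q = np.linspace(0.0, 1.0, n_levels)
    src_q = np.quantile(src, q)
    ref_q = np.quantile(ref, q)
    out = vol.values.copy()
    out[m] = np.interp(vol.values[m], src_q, ref_q)
    return vol.with_values(out)


def _log_gabor_monogenic(values: np.ndarray, wavelength_vox: float,
                         sigma_on_f: float = 0.55):
    """Isotropic log-Gabor bandpass + Riesz transform of a 3D image.

    Returns ``(even, odd_magnitude)`` — the bandpass response and the
    magnitude of the 3-component Riesz (odd) response.
    """
    shape = values.shape
    freqs = np.meshgrid(*[np.fft.fftfreq(n) for n in shape], indexing="ij")
    f = np.sqrt(sum(fk ** 2 for fk in freqs))
    f[0, 0, 0] = 1.0  # avoid log(0); DC is zeroed below
    f0 = 1.0 / wavelength_vox
    lg = np.exp(-(np.log(f / f0) ** 2) / (2.0 * np.log(sigma_on_f) ** 2))
    lg[0, 0, 0] = 0.0
    F = np.fft.fftn(values)
    even = np.real(np.fft.ifftn(F * lg))
    odd_sq = np.zeros(shape)
    for fk in freqs:
        riesz = np.fft.ifftn(F * lg * (1j * fk / f))
        odd_sq += np.real(riesz) ** 2
    return even, np.sqrt(odd_sq)


def monogenic_feature_asymmetry(
        vol: Volume3D,
        scales: tuple[float, ...] = DEFAULT_FA_SCALES,
        noise_k: float = 2.0,
        epsilon: float = 1e-4) -> Volume3D:
    """Multiscale feature-asymmetry edge map from the 3D monogenic signal.

    For each scale a rotationally invariant log-Gabor bandpass (centre
    wavelength ``scale × grid extent`` voxels, σ/f₀ = 0.55) and its Riesz
    transform give even/odd filter responses; feature asymmetry is the
    rectified ``(|odd| − |even| − T) / (energy + ε)`` averaged over scales,
    where the noise floor ``T = noise_k × median(|odd|)``.  The result lies in
    [0, 1], peaks on step edges (fissures, tissue interfaces) and is invariant
    to positive affine intensity rescaling.
    """
    values = np.asarray(vol.values, dtype=np.float64)
    if np.ptp(values) < 1e-12:
        return vol.with_values(np.zeros_like(values))
    extent = max(values.shape)
    fa = np.zeros_like(values)
    for lam in scales:
        wavelength = lam * extent
        even, odd = _log_gabor_monogenic(values, wavelength)
        energy = np.sqrt(even ** 2 + odd ** 2)
        floor = noise_k * np.median(odd)
        # ε is scaled by the mean energy so the measure stays invariant under
        # positive affine intensity changes (energy is DC-free)
        fa += np.maximum(odd - np.abs(even) - floor, 0.0) / (
            energy + epsilon * energy.mean())
    fa /= len(scales)
    return vol.with_values(np.clip(fa, 0.0, 1.0))


def select_hemisphere(vol: Volume3D, hemisphere: str,
                      margin: int = 10) -> Volume3D:
    """Keep the visible hemisphere plus ``margin`` voxels past the midline.

    After alignment the midsagittal plane is the central axis-0 plane; axis 0
    runs left→right, so the left hemisphere occupies the low-index half.
    """
    nx = vol.shape[0]
    mid = nx // 2
    if margin >= mid:
        raise ValueError(f"margin {margin} must be < half grid width {mid}")
    if hemisphere not in ("left", "right"):
        raise ValueError(f"hemisphere must be 'left' or 'right', got {hemisphere!r}")
    out = vol.values.copy()
    if hemisphere == "left":
        out[mid + margin:, :, :] = 0.0
    else:
        out[:mid - margin, :, :] = 0.0
    return vol.with_values(out)


def mirror_midsagittal(vol: Volume3D) -> Volume3D:
    """Flip across the midsagittal plane: voxel (x, y, z) → (X−1−x, y, z)."""
    return vol.with_values(vol.values[::-1, :, :].copy())
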