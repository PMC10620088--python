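"""Stationary velocity fields and diffeomorphic displacement fields.

All fields are stored in voxel units on the image grid as arrays of shape
``(X, Y, Z, 3)``.  Displacement fields follow the backward-warping convention
used throughout the package: a field attached to a scan maps *template*
coordinates into *scan* coordinates, so resampling a scan through its field
pulls it into template space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VelocityField", "DeformationField",
    "warp_array", "warp_field", "compose_fields", "invert_field",
    "exp_velocity", "identity_grid",
]


@dataclass
class VelocityField:
    """Per-voxel stationary velocity 3-vectors (voxel units)."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.ndim != 4 or v.shape[-1] != 3:
            raise ValueError(f"expected shape (X, Y, Z, 3), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("velocity field contains non-finite values")
        self.vectors = v

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.vectors ** 2).sum(-1)).max())

    def __neg__(self) -> "VelocityField":
        return VelocityField(-self.vectors)


@dataclass
class DeformationField:
    """Per-voxel displacement 3-vectors (voxel units).

    ``direction`` records which way the mapping goes; the registration stage
    always emits ``"template_to_scan"`` fields (backward warping).
    """

    vectors: np.ndarray
    direction: str = "template_to_scan"

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.ndim != 4 or v.shape[-1] != 3:
            raise ValueError(f"expected shape (X, Y, Z, 3), got {v.shape}")
        self.vectors = v

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.vectors ** 2).sum(-1)).max())

    @classmethod
    def zero(cls, shape: tuple[int, int, int]) -> "DeformationField":
        return cls(np.zeros(shape + (3,)))


def identity_grid(shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel-index coordinate grid of shape ``(X, Y, Z, 3)``."""
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def warp_array(values: np.ndarray, disp: np.ndarray, order: int = 1,
               mode: str = "constant", cval: float = 0.0) -> np.ndarray:
    """Resample ``values`` at ``x + disp(x)`` (backward mapping).

    ``order=1`` is trilinear (intensity images); ``order=0`` is nearest
    neighbour (label maps).
    """
    if values.shape != disp.shape[:3]:
        raise ValueError(f"grid mismatch: {values.shape} vs {disp.shape[:3]}")
    coords = identity_grid(values.shape) + disp
    return ndimage.map_coordinates(
        np.asarray(values, dtype=np.float64),
        [coords[..., k] for k in range(3)],
        order=order, mode=mode, cval=cval)


def _interp_vectors(vec: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a vector field at fractional coordinates.

    Samples beyond the grid clamp to the edge (``mode='nearest'``), which keeps
    composed fields finite near the boundary.
    """
    out = np.empty_like(vec)
    pts = [coords[..., k] for k in range(3)]
    for k in range(3):
        out[..., k] = ndimage.map_coordinates(vec[..., k], pts, order=1,
                                              mode="nearest")
    return out


def compose_fields(f: DeformationField, g: DeformationField) -> DeformationField:
    """Displacement of the composition f∘g: ``(f∘g)(x) = g(x) + f(x + g(x))``."""
    if f.grid_shape != g.grid_shape:
        raise ValueError("cannot compose fields on different grids")
    coords = identity_grid(g.grid_shape) + g.vectors
    return DeformationField(g.vectors + _interp_vectors(f.vectors, coords),
                            direction=f.direction)


def invert_field(f: DeformationField, n_iter: int = 30,
                 tol: float = 0.05) -> DeformationField:
    """Numerical inverse by fixed-point iteration.

    Solves ``u_inv(x) = -u(x + u_inv(x))``; converges for displacement fields
    with Lipschitz constant < 1 (all diffeomorphic fields this package emits).

    Raises
    ------
    RuntimeError
        If the residual ``|(f o f_inv) - id|`` does not drop below ``tol``
        voxels; the message reports the max residual reached.
    """
    grid = identity_grid(f.grid_shape)
    inv = np.zeros_like(f.vectors)
    for _ in range(n_iter):
        inv_new = -_interp_vectors(f.vectors, grid + inv)
        step = np.abs(inv_new - inv).max()
        inv = inv_new
        if step < 0.25 * tol:
            break
    residual = compose_fields(f, DeformationField(inv, f.direction))
    res = float(np.sqrt((residual.vectors ** 2).sum(-1)).max())
    if res > tol:
        raise RuntimeError(
            f"field inversion did not converge: max residual {res:.3f} voxels")
    return DeformationField(inv, direction=f.direction)


def exp_velocity(v: VelocityField, n_steps: int | None = None) -> DeformationField:
    """Exponential of a stationary velocity field by scaling and squaring.

    The field is scaled by ``2**-n`` so the largest scaled displacement is at
    most 0.125 voxel (well under the 0.5-voxel stability bound; the tighter
    default keeps the one-Euler-step error below interpolation error), flowed
    one Euler step, then squared (self-composed) ``n`` times.  The result is
    a diffeomorphic displacement field.
    """
    if not np.all(np.isfinite(v.vectors)):
        raise ValueError("non-finite velocity field")
    max_mag = v.max_magnitude()
    if n_steps is None:
        n_steps = max(0, int(np.ceil(np.log2(max(max_mag, 1e-12) / 0.125))))
    d = DeformationField(v.vectors / (2.0 ** n_steps))
    for _ in range(n_steps):
        d = compose_fields(d, d)
    return d
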