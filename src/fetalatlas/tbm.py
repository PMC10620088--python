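"""Voxel-wise inference for tensor-based morphometry.

General linear model t-maps with a residualised covariate, threshold-free
cluster enhancement (TFCE), max-statistic permutation testing with
family-wise error control (Freedman–Lane scheme, exhaustive enumeration when
feasible), PCA shape models of deformation fields, and parcellation-overlap
cluster tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numba
import numpy as np
import pandas as pd

from .fields import DeformationField
from .volume import LabelMap

__all__ = [
    "DesignMatrix", "StatMap", "ShapeModel",
    "residualize_covariate", "glm_tstat", "tfce_enhance", "permutation_fwer",
    "pca_shape_model", "shape_variation_at_sd",
    "components_for_variance_fraction", "cluster_region_overlap",
]


# --------------------------------------------------------------------------
# design and GLM

@dataclass
class DesignMatrix:
    """Per-scan design: group code ±1, optional covariate, intercept.

    The covariate is residualised against {intercept, group} on construction
    so the group contrast is not diluted by shared variance.
    """

    group: np.ndarray
    covariate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=np.float64)
        if not np.all(np.isin(self.group, (-1.0, 1.0))):
            raise ValueError("group codes must be +1 / -1")
        if self.covariate is not None:
            cov = np.asarray(self.covariate, dtype=np.float64)
            if cov.shape != self.group.shape:
                raise ValueError("covariate length mismatch")
            self.covariate = residualize_covariate(cov, self.group)

    @property
    def n(self) -> int:
        return len(self.group)

    def matrix(self) -> np.ndarray:
        cols = [np.ones(self.n), self.group]
        if self.covariate is not None:
            cols.append(self.covariate)
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient design matrix")
        return X

    def reduced_matrix(self) -> np.ndarray:
        cols = [np.ones(self.n)]
        if self.covariate is not None:
            cols.append(self.covariate)
        return np.column_stack(cols)


def residualize_covariate(covariate: np.ndarray,
                          group: np.ndarray) -> np.ndarray:
    """Least-squares residual of the covariate on {intercept, group}."""
    covariate = np.asarray(covariate, dtype=np.float64)
    group = np.asarray(group, dtype=np.float64)
    if covariate.shape != group.shape:
        raise ValueError("length mismatch")
    if len(covariate) < 3 and np.ptp(group) == 0:
        raise ValueError("cannot residualize: constant group with n < 3")
    Z = np.column_stack([np.ones_like(group), group])
    beta, *_ = np.linalg.lstsq(Z, covariate, rcond=None)
    return covariate - Z @ beta


def _tstat_matrix(Y: np.ndarray, X: np.ndarray, contrast_col: int = 1
                  ) -> np.ndarray:
    """Per-column OLS t statistic for one coefficient. Y is (n, n_vox)."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(0) / max(dof, 1)
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[contrast_col, contrast_col],
                            1e-300))
    return beta[contrast_col] / se


def glm_tstat(maps, design: DesignMatrix,
              mask: np.ndarray | None = None) -> np.ndarray:
    """Voxel-wise t statistic for the group coefficient.

    ``maps`` is a list (or stacked array) of per-scan volumes; with no
    covariate this reduces exactly to the pooled two-sample t statistic.
    """
    Y, shape, m = _flatten_maps(maps, mask)
    if Y.shape[0] != design.n:
        raise ValueError("number of maps != design rows")
    X = design.matrix()
    if Y.shape[0] < X.shape[1] + 1:
        raise ValueError("too few scans for the design")
    t = np.zeros(np.prod(shape))
    t[m] = _tstat_matrix(Y, X)
    return t.reshape(shape)


def _flatten_maps(maps, mask):
    arr = np.stack([np.asarray(m, dtype=np.float64) for m in maps]) \
        if not isinstance(maps, np.ndarray) else np.asarray(maps, np.float64)
    shape = arr.shape[1:]
    flat = arr.reshape(arr.shape[0], -1)
    if mask is None:
        m = np.ones(flat.shape[1], dtype=bool)
    else:
        m = np.asarray(mask).reshape(-1) > 0
    return flat[:, m], shape, m


# --------------------------------------------------------------------------
# TFCE

_OFFSETS_26 = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                        for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)],
                       dtype=np.int64)
_OFFSETS_6 = np.array([(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                       (0, -1, 0), (0, 0, 1), (0, 0, -1)], dtype=np.int64)


@numba.njit(cache=True)
def _uf_find(parent, off, x, path):  # pragma: no cover
    """Union-find root of x with path compression; offsets kept consistent.

    ``off[u]`` is u's accumulated-contribution offset relative to its parent;
    a node's total value is ``cum[root] + sum of offsets along its path``.
    Returns (root, total offset of x).
    """
    depth = 0
    r = x
    while parent[r] != r:
        path[depth] = r
        depth += 1
        r = parent[r]
    # accumulate offsets root-ward, re-parent every node directly to root
    total = 0.0
    for i in range(depth - 1, -1, -1):
        u = path[i]
        total += off[u]
        off[u] = total
        parent[u] = r
    # off[x] now holds x's total offset (or 0 if x was the root)
    return r, (off[x] if depth > 0 else 0.0)


@numba.njit(cache=True)
def _tfce_positive(vals, offsets, E, H, dh, n_steps):  # pragma: no cover
    """TFCE of the non-negative part of a map.

    Thresholds are processed descending with an incremental union-find over
    suprathreshold voxels: per threshold each component root accrues
    ``size^E · h^H · dh``, and per-node offsets recorded at merge time keep
    late-joining voxels from inheriting earlier contributions.
    """
    nx, ny, nz = vals.shape
    n = nx * ny * nz
    out = np.zeros((nx, ny, nz))
    maxv = vals.max()
    if maxv <= 0.0:
        return out
    flat = vals.copy().reshape(n)
    order = np.argsort(flat)[::-1]
    parent = np.empty(n, dtype=np.int64)
    off = np.zeros(n)
    cum = np.zeros(n)
    size = np.zeros(n, dtype=np.int64)
    inserted = np.zeros(n, dtype=np.uint8)
    root_list = np.empty(n, dtype=np.int64)
    root_pos = np.empty(n, dtype=np.int64)
    n_roots = 0
    path = np.empty(64, dtype=np.int64)
    ptr = 0
    for step in range(n_steps, 0, -1):
        h = step * dh
        if h > maxv + 1e-12:
            continue
        # the >= comparison carries a 1e-9 relative guard: with dh = max/100
        # the map maximum lands exactly on the top threshold, and without the
        # guard a 1-ulp perturbation of the input flips its inclusion there
        # (a discontinuity of h²·dh in the output)
        h_guard = h * (1.0 - 1e-9)
        # insert voxels with value >= h, union with inserted neighbours
        while ptr < n and flat[order[ptr]] >= h_guard:
            lin = order[ptr]
            ptr += 1
            parent[lin] = lin
            size[lin] = 1
            cum[lin] = 0.0
            off[lin] = 0.0
            inserted[lin] = 1
            root_pos[lin] = n_roots
            root_list[n_roots] = lin
            n_roots += 1
            z = lin % nz
            y = (lin // nz) % ny
            x = lin // (ny * nz)
            for o in range(offsets.shape[0]):
                xi = x + offsets[o, 0]
                yi = y + offsets[o, 1]
                zi = z + offsets[o, 2]
                if xi < 0 or xi >= nx or yi < 0 or yi >= ny \
                        or zi < 0 or zi >= nz:
                    continue
                nb = (xi * ny + yi) * nz + zi
                if inserted[nb] == 0:
                    continue
                ra, _ = _uf_find(parent, off, lin, path)
                rb, _ = _uf_find(parent, off, nb, path)
                if ra == rb:
                    continue
                if size[ra] < size[rb]:  # union by size
                    ra, rb = rb, ra
                parent[rb] = ra
                off[rb] = cum[rb] - cum[ra]
                size[ra] += size[rb]
                # rb is no longer a root: swap-remove from the registry
                pos = root_pos[rb]
                last = root_list[n_roots - 1]
                root_list[pos] = last
                root_pos[last] = pos
                n_roots -= 1
        # accrue this threshold's contribution on every component root
        for i in range(n_roots):
            r = root_list[i]
            cum[r] += (size[r] ** E) * (h ** H) * dh
    for i in range(n):
        if inserted[i] == 1:
            r, delta = _uf_find(parent, off, i, path)
            lin = i
            z = lin % nz
            y = (lin // nz) % ny
            x = lin // (ny * nz)
            out[x, y, z] = cum[r] + delta
    return out


def tfce_enhance(stat: np.ndarray, E: float = 0.5, H: float = 2.0,
                 dh: float | None = None, connectivity: int = 26,
                 n_steps: int = 100) -> np.ndarray:
    """Threshold-free cluster enhancement of a statistic map.

    ``TFCE(v) = Σ_h e(h, v)^E · h^H · dh`` where ``e(h, v)`` is the size of
    v's connected suprathreshold component at height h, summed over
    thresholds ``h = dh, 2dh, …`` up to the voxel's own value.  The negative
    tail is enhanced on ``−stat`` and re-signed, giving a signed two-tailed
    map.  ``dh`` defaults to ``max(|stat|)/n_steps``.
    """
    stat = np.asarray(stat, dtype=np.float64)
    if not np.all(np.isfinite(stat)):
        raise ValueError("non-finite statistic map")
    if connectivity == 26:
        offsets = _OFFSETS_26
    elif connectivity == 6:
        offsets = _OFFSETS_6
    else:
        raise ValueError("connectivity must be 6 or 26")
    vmax = float(np.abs(stat).max())
    if vmax == 0.0:
        return np.zeros_like(stat)
    if dh is None:
        dh = vmax / n_steps
    if dh <= 0:
        raise ValueError("dh must be positive")
    n_steps_eff = int(np.ceil(vmax / dh))
    pos = _tfce_positive(np.maximum(stat, 0.0), offsets, E, H, dh, n_steps_eff)
    neg = _tfce_positive(np.maximum(-stat, 0.0), offsets, E, H, dh, n_steps_eff)
    return pos - neg


# --------------------------------------------------------------------------
# permutation inference

@dataclass
class StatMap:
    """Results of voxel-wise permutation inference."""

    tstat: np.ndarray
    tfce: np.ndarray
    p_corrected: np.ndarray
    significant: np.ndarray
    n_permutations: int
    alpha: float
    seed: int | None
    exhaustive: bool


def _permutation_indices(design: DesignMatrix, n_perm: int,
                         rng: np.random.Generator):
    """Row permutations: exhaustive over distinct group assignments when the
    number of rearrangements fits in ``n_perm``, random otherwise."""
    n = design.n
    n_plus = int((design.group > 0).sum())
    n_distinct = comb(n, n_plus)
    if n_distinct <= n_perm:
        plus_pos = np.flatnonzero(design.group > 0)
        minus_pos = np.flatnonzero(design.group < 0)
        perms = []
        for subset in combinations(range(n), n_plus):
            subset = np.array(subset)
            rest = np.setdiff1d(np.arange(n), subset)
            perm = np.empty(n, dtype=np.intp)
            perm[plus_pos] = subset
            perm[minus_pos] = rest
            perms.append(perm)
        return np.array(perms), True
    return np.array([rng.permutation(n) for _ in range(n_perm)]), False


def permutation_fwer(maps, design: DesignMatrix, n_perm: int = 5000,
                     alpha: float = 0.05, seed: int | None = 0,
                     two_tailed: bool = True, mask: np.ndarray | None = None,
                     E: float = 0.5, H: float = 2.0,
                     connectivity: int = 26) -> StatMap:
    """Max-TFCE permutation test with family-wise error correction.

    Freedman–Lane scheme: the reduced model (intercept + covariate) is
    fitted, its residuals are permuted by group-label exchange, the full
    model is refitted and the permuted |t| map TFCE-enhanced; the maximum of
    each permuted map forms the null distribution.  Corrected
    ``p(v) = (1 + #{perm max ≥ TFCE(v)}) / (1 + n_perm)`` for random
    sampling, or the exact fraction when all distinct rearrangements are
    enumerated.  Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    Y, shape, m = _flatten_maps(maps, mask)
    if Y.shape[0] != design.n:
        raise ValueError("number of maps != design rows")
    X = design.matrix()
    Z = design.reduced_matrix()
    rng = np.random.default_rng(seed)
    perms, exhaustive = _permutation_indices(design, n_perm, rng)
    n_used = len(perms)

    beta_z, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    fitted = Z @ beta_z
    resid = Y - fitted
    # route the observed data through the same reconstruction as the
    # permuted surrogates, so the identity rearrangement is bitwise equal to
    # the observed statistic (guarantees p ≥ 1/n_perm)
    Y = fitted + resid

    def tfce_of(Yp: np.ndarray) -> np.ndarray:
        t = np.zeros(np.prod(shape))
        t[m] = _tstat_matrix(Yp, X)
        t = t.reshape(shape)
        if two_tailed:
            return np.abs(tfce_enhance(np.abs(t), E=E, H=H,
                                       connectivity=connectivity))
        return tfce_enhance(t, E=E, H=H, connectivity=connectivity)

    t_obs = np.zeros(np.prod(shape))
    t_obs[m] = _tstat_matrix(Y, X)
    t_obs = t_obs.reshape(shape)
    tfce_obs = tfce_enhance(np.abs(t_obs) if two_tailed else t_obs,
                            E=E, H=H, connectivity=connectivity)
    tfce_mag = np.abs(tfce_obs)

    max_null = np.empty(n_used)
    for i, perm in enumerate(perms):
        Yp = fitted + resid[perm]
        max_null[i] = tfce_of(Yp).max()

    flat = tfce_mag.reshape(-1)
    # ulp-scale tie guard: mathematically tied rearrangements (e.g. the
    # group-swapped complement, whose |t| map is identical) must count as
    # exceedances even when float summation order perturbs them by one ulp
    tol = 1e-9 * max_null.max() if max_null.size else 0.0
    exceed = (max_null[None, :] >= flat[:, None] - tol).sum(1)
    if exhaustive:
        p = exceed / n_used  # identity assignment is among the enumeration
    else:
        p = (1.0 + exceed) / (1.0 + n_used)
    p = p.reshape(shape)
    p = np.where(tfce_mag > 0, p, 1.0)
    return StatMap(tstat=t_obs, tfce=tfce_obs, p_corrected=p,
                   significant=p < alpha, n_permutations=n_used, alpha=alpha,
                   seed=seed, exhaustive=exhaustive)


# --------------------------------------------------------------------------
# PCA shape modelling

@dataclass
class ShapeModel:
    """Linear statistical shape model over flattened deformation fields."""

    mean: np.ndarray
    components: np.ndarray          # (k, d), orthonormal rows
    variances: np.ndarray           # (k,), non-increasing
    field_shape: tuple | None
    size_corrected: bool
    n_samples: int

    @property
    def explained_fractions(self) -> np.ndarray:
        total = self.variances.sum()
        if total <= 0:
            return np.zeros_like(self.variances)
        return self.variances / total

    @property
    def cumulative_fractions(self) -> np.ndarray:
        return np.cumsum(self.explained_fractions)


def _flatten_fields(fields, mask):
    rows, field_shape = [], None
    for f in fields:
        if isinstance(f, DeformationField):
            arr = f.vectors
        else:
            arr = np.asarray(f, dtype=np.float64)
        if field_shape is None:
            field_shape = arr.shape
        elif arr.shape != field_shape:
            raise ValueError("fields on different grids")
        if mask is not None:
            sel = np.asarray(mask) > 0
            arr = arr[sel] if arr.shape == sel.shape else arr[sel, :]
        rows.append(arr.reshape(-1))
    return np.stack(rows), field_shape


def pca_shape_model(fields, size_corrected: bool = False,
                    mask: np.ndarray | None = None,
                    var_tol: float = 1e-12) -> ShapeModel:
    """Mean-centred PCA over flattened vector fields (or scalar maps).

    Components are orthonormal, variances non-increasing, and explained
    fractions sum to 1 over the retained components; components with
    numerically zero variance are dropped (identical inputs give an empty
    model).  ``size_corrected`` records that affine size was removed
    upstream — it does not itself alter the fields.
    """
    data, field_shape = _flatten_fields(fields, mask)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 fields")
    mean = data.mean(0)
    centred = data - mean
    U, s, Vt = np.linalg.svd(centred, full_matrices=False)
    variances = s ** 2 / (n - 1)
    keep = variances > var_tol * max(variances[0] if len(variances) else 0.0,
                                     1.0)
    return ShapeModel(mean=mean, components=Vt[keep],
                      variances=variances[keep], field_shape=field_shape,
                      size_corrected=size_corrected, n_samples=n)


def shape_variation_at_sd(model: ShapeModel, component: int,
                          multiplier: float) -> np.ndarray:
    """Field at ``mean + multiplier·√λ_k·component_k``, reshaped if possible."""
    if component >= len(model.variances):
        raise IndexError(f"component {component} out of range")
    flat = model.mean + multiplier * np.sqrt(model.variances[component]) \
        * model.components[component]
    if model.field_shape is not None and flat.size == np.prod(model.field_shape):
        return flat.reshape(model.field_shape)
    return flat


def components_for_variance_fraction(model: ShapeModel,
                                     fraction: float) -> int:
    """Smallest k whose cumulative explained variance reaches ``fraction``."""
    if not 0.0 < fraction < 1.0 + 1e-12:
        raise ValueError("fraction must be in (0, 1]")
    if len(model.variances) == 0:
        raise ValueError("empty shape model")
    cum = model.cumulative_fractions
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


# --------------------------------------------------------------------------
# parcellation overlap

def cluster_region_overlap(sig_mask: np.ndarray,
                           parcellation: LabelMap | np.ndarray,
                           display_threshold: float = 0.10) -> pd.DataFrame:
    """Per-region summary of a significance mask against a parcellation.

    For each labelled region: the percentage of the region's voxels that are
    significant (drives the ``display`` flag at ``display_threshold``), and
    the percentage of all significant (cluster) voxels that fall inside the
    region.
    """
    if isinstance(parcellation, LabelMap):
        labels, names = parcellation.values, parcellation.labels
    else:
        labels, names = np.asarray(parcellation), {}
    sig = np.asarray(sig_mask) > 0
    if sig.shape != labels.shape:
        raise ValueError("mask/parcellation grid mismatch")
    region_ids = [int(r) for r in np.unique(labels) if r != 0]
    if not region_ids:
        raise ValueError("empty parcellation")
    n_sig_total = int(sig.sum())
    rows = []
    for rid in region_ids:
        region = labels == rid
        n_region = int(region.sum())
        n_both = int((sig & region).sum())
        pct_region = 100.0 * n_both / n_region if n_region else 0.0
        pct_cluster = 100.0 * n_both / n_sig_total if n_sig_total else 0.0
        rows.append({
            "region_id": rid,
            "region_name": names.get(rid, f"region{rid}"),
            "pct_region_significant": pct_region,
            "pct_cluster_in_region": pct_cluster,
            "display": pct_region >= 100.0 * display_threshold,
        })
    return pd.DataFrame(rows)
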