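"""Phantom fetal-brain cohort generator with recorded ground truth.

The study design being emulated: eight acquisition sites contribute 3D
ultrasound scans across 14–31 gestational weeks, at least ten scans per week
per visible hemisphere.  Each phantom is an ellipsoidal "brain" whose volume
follows a quadratic growth trajectory with a 13-fold increase from week 14 to
week 31, a cortical-plate shell whose sinusoidal surface folding deepens with
age, a choroid-plexus blob whose share of brain volume regresses from 8.3% at
14 weeks to roughly 0.4% by 30 weeks, a cerebellar blob, tissue-specific mean
intensities, and multiplicative unit-mean speckle.  Every random choice is
seeded and every ground-truth parameter is written to a JSON sidecar so
recovery tests never re-derive it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import fields as flds
from .fields import DeformationField, VelocityField, exp_velocity, warp_array
from .preprocess import LandmarkSet
from .volume import LabelMap, Volume3D, write_labelmap, write_volume

__all__ = [
    "PhantomSpec", "ScanRecord", "CohortManifest", "SITE_IDS",
    "tbv_trajectory", "chp_fraction_default", "fold_amplitude_default",
    "generate_phantom", "generate_cohort", "inject_asymmetry",
    "apply_known_warp", "random_smooth_velocity", "phantom_landmarks",
    "default_asymmetry_region", "simulate_site_measures",
]

#: the eight acquisition sites of the emulated multi-site design
SITE_IDS = ("site01", "site02", "site03", "site04",
            "site05", "site06", "site07", "site08")

GA_MIN, GA_MAX = 14.0, 31.0

#: tissue mean intensities for the piecewise-constant phantom (before speckle)
TISSUE_MEANS = {0: 0.0, 1: 0.35, 2: 0.85, 3: 0.60, 4: 0.55}

# Quadratic TBV trajectory TBV(ga) ∝ (ga − GA0)² chosen so the week-31 /
# week-14 volume ratio is 13.19 (317.60 / 24.08); absolute units are left
# unspecified and only the ratio is calibrated.
_TBV_RATIO = 317.60 / 24.08
_GA0 = (31.0 - np.sqrt(_TBV_RATIO) * 14.0) / (1.0 - np.sqrt(_TBV_RATIO))

#: brain semi-axes at week 31 as fractions of half the grid extent (x, y, z)
_AXES31 = (0.42, 0.36, 0.32)


def tbv_trajectory(ga_weeks: float) -> float:
    """Relative brain volume at ``ga_weeks``, normalised to 1.0 at week 31."""
    return float(((ga_weeks - _GA0) / (31.0 - _GA0)) ** 2)


def chp_fraction_default(ga_weeks: float) -> float:
    """Default choroid-plexus share of brain volume (fraction of TBV).

    Exponential decay calibrated to 8.3% at 14 weeks and 0.4% at 30 weeks;
    monotonically non-increasing on [14, 31].
    """
    return float(0.083 * (0.004 / 0.083) ** ((ga_weeks - 14.0) / 16.0))


def fold_amplitude_default(ga_weeks: float) -> float:
    """Default cortical-fold amplitude (voxel units at a 64³ grid scale).

    Zero through 16 weeks (lissencephalic brain), then growing linearly —
    folding accelerates through the second trimester.
    """
    return float(max(0.0, (ga_weeks - 16.0) / (31.0 - 16.0)) * 1.5)


@dataclass
class PhantomSpec:
    """Full parameterisation of a single phantom brain.

    ``fold_amplitude`` and ``chp_fraction`` default to the gestational-age
    dependent calibrations above when left as None.  ``site_shift`` scales
    linear brain size by (1 + shift); ``asym_dilation`` applies a radial
    expansion of factor (1 + dilation) to the default asymmetry region.
    """

    ga_weeks: float
    grid_size: int = 64
    spacing_mm: float = 0.6
    noise_level: float = 0.3
    fold_amplitude: float | None = None
    chp_fraction: float | None = None
    site_id: str = SITE_IDS[0]
    site_shift: float = 0.0
    asym_dilation: float = 0.0
    size_jitter: float = 0.0   # per-subject multiplicative size factor − 1
    warp_amplitude: float = 0.0  # max |v| of the per-subject random warp, voxels
    seed: int = 0

    def __post_init__(self) -> None:
        if not (GA_MIN <= self.ga_weeks <= GA_MAX):
            raise ValueError(f"ga_weeks must be in [{GA_MIN}, {GA_MAX}]")
        if self.grid_size < 32:
            raise ValueError("grid_size must be >= 32")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")

    def resolved_fold_amplitude(self) -> float:
        amp = (fold_amplitude_default(self.ga_weeks)
               if self.fold_amplitude is None else self.fold_amplitude)
        return amp * self.grid_size / 64.0

    def resolved_chp_fraction(self) -> float:
        return (chp_fraction_default(self.ga_weeks)
                if self.chp_fraction is None else self.chp_fraction)

    def semi_axes(self) -> np.ndarray:
        """Brain ellipsoid semi-axes in voxels at this spec's GA and size."""
        scale = (tbv_trajectory(self.ga_weeks) ** (1.0 / 3.0)
                 * (1.0 + self.site_shift) * (1.0 + self.size_jitter))
        return np.array(_AXES31) * (self.grid_size / 2.0) * scale


def _normalized_radius(shape: int, centre: np.ndarray, axes: np.ndarray):
    grid = np.stack(np.meshgrid(*[np.arange(shape, dtype=np.float64)] * 3,
                                indexing="ij"), -1)
    u = (grid - centre) / axes
    rho = np.sqrt((u ** 2).sum(-1))
    return u, rho


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, LabelMap]:
    """Render one phantom brain: intensity volume plus label map.

    Labels: 0 background, 1 brain parenchyma, 2 ChP, 3 CoP shell, 4 CB.
    Identical specs produce bit-identical output.

    Raises
    ------
    ValueError
        If the grid is too small to contain the GA-scaled ellipsoid with a
        2-voxel margin, or too small to resolve it (min semi-axis < 3 voxels).
    """
    G = spec.grid_size
    axes = spec.semi_axes()
    amp_vox = spec.resolved_fold_amplitude()
    if axes.min() < 3.0:
        raise ValueError(
            f"grid {G} too small to resolve the week-{spec.ga_weeks} brain "
            f"(min semi-axis {axes.min():.2f} voxels)")
    if axes.max() + amp_vox > G / 2.0 - 2.0:
        raise ValueError(
            f"grid {G} too small to contain the scaled ellipsoid "
            f"(max extent {axes.max() + amp_vox:.1f} voxels)")
    centre = np.full(3, (G - 1) / 2.0)
    u, rho = _normalized_radius(G, centre, axes)

    # folded outer surface: rho <= 1 + A·F(θ, φ), fold amplitude in
    # normalised units relative to the mean semi-axis
    amp = amp_vox / axes.mean()
    with np.errstate(invalid="ignore"):
        theta = np.arctan2(u[..., 1], u[..., 0])
        phi = np.arctan2(u[..., 2], np.sqrt(u[..., 0] ** 2 + u[..., 1] ** 2))
    folds = amp * np.sin(6.0 * theta) * np.cos(4.0 * phi)
    surface = 1.0 + folds
    brain = rho <= surface

    labels = np.zeros((G, G, G), dtype=np.int16)
    labels[brain] = 1

    # cortical-plate shell: outermost band of the folded surface,
    # ~2 voxels thick in normalised units
    shell_t = 2.0 / axes.mean()
    labels[brain & (rho > surface - shell_t)] = 3

    # choroid plexus: a smaller ellipsoid of the same shape so its analytic
    # volume share equals chp_fraction exactly; offset posteriorly
    f_chp = spec.resolved_chp_fraction()
    chp_scale = f_chp ** (1.0 / 3.0)
    chp_centre = centre + np.array([0.0, -0.25, 0.10]) * axes
    _, rho_chp = _normalized_radius(G, chp_centre, axes * chp_scale)
    labels[(rho_chp <= 1.0) & brain] = 2

    # cerebellum: a spherical blob in the inferior-posterior quadrant
    cb_centre = centre + np.array([0.0, -0.55, -0.45]) * axes
    cb_radius = 0.22 * axes.mean()
    _, rho_cb = _normalized_radius(G, cb_centre, np.full(3, cb_radius))
    labels[(rho_cb <= 1.0) & brain & (labels != 2)] = 4

    intensity = np.zeros((G, G, G), dtype=np.float64)
    for lab, mean in TISSUE_MEANS.items():
        intensity[labels == lab] = mean
    # concentric laminae in the parenchyma (ventricular/intermediate/subplate
    # zones): smooth radial intensity modulation that deforms with the tissue,
    # giving registration interior structure to track
    par = labels == 1
    intensity[par] *= 1.0 + 0.18 * np.cos(7.0 * np.pi * rho[par])

    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed)
        re = ndimage.gaussian_filter(rng.standard_normal((G, G, G)), 1.2)
        im = ndimage.gaussian_filter(rng.standard_normal((G, G, G)), 1.2)
        speckle = re ** 2 + im ** 2
        speckle /= speckle.mean()  # unit-mean multiplicative field
        intensity *= np.maximum(1.0 + spec.noise_level * (speckle - 1.0), 0.0)

    sp = (spec.spacing_mm,) * 3
    vol = Volume3D(intensity, sp)
    lab = LabelMap(labels, sp)

    if spec.asym_dilation != 0.0:
        region = default_asymmetry_region(spec)
        vol, lab, _ = inject_asymmetry(vol, lab, region, spec.asym_dilation)
    return vol, lab


def default_asymmetry_region(spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of the canonical asymmetry-injection region.

    A ball in the left parietal area of the phantom (low axis-0 indices),
    radius 40% of the mean semi-axis, abutting the cortical-plate shell from
    inside so the induced expansion displaces high-contrast boundaries that
    registration can track.
    """
    G = spec.grid_size
    axes = spec.semi_axes()
    centre = np.full(3, (G - 1) / 2.0) + np.array([-0.50, 0.10, 0.10]) * axes
    radius = 0.40 * axes.mean()
    _, rho = _normalized_radius(G, centre, np.full(3, radius))
    return rho <= 1.0


def inject_asymmetry(volume: Volume3D, labelmap: LabelMap,
                     region_mask: np.ndarray, dilation: float
                     ) -> tuple[Volume3D, LabelMap, DeformationField]:
    """Radially dilate a compact region by linear factor (1 + dilation).

    The map is identity outside a support ball (core radius + a smooth cosine
    taper), exactly uniform scaling inside the core, and returns the analytic
    backward displacement field that was applied.  The region must not touch
    the volume boundary, because the deformation must vanish there.
    """
    if dilation <= -0.3:
        raise ValueError("dilation must exceed -0.3 to stay diffeomorphic")
    region = np.asarray(region_mask) > 0
    if region.shape != volume.shape:
        raise ValueError("region mask grid mismatch")
    if dilation == 0.0:
        return (volume.copy(),
                labelmap.with_values(labelmap.values.copy()),
                DeformationField.zero(volume.shape))
    if not region.any():
        raise ValueError("empty region mask")
    idx = np.argwhere(region)
    centre = idx.mean(0)
    r_core = float(np.sqrt(((idx - centre) ** 2).sum(1)).max()) + 0.5
    r_out_core = (1.0 + max(dilation, 0.0)) * r_core
    taper = max(3.0, 0.8 * r_core)
    R = r_out_core + taper
    if any(centre[k] - R < 1.0 or centre[k] + R > volume.shape[k] - 2.0
           for k in range(3)):
        raise ValueError("region support reaches the volume boundary; "
                         "the deformation must vanish at the boundary")

    grid = flds.identity_grid(volume.shape)
    delta = grid - centre
    r = np.sqrt((delta ** 2).sum(-1))
    w = np.zeros_like(r)
    w[r <= r_out_core] = 1.0
    band = (r > r_out_core) & (r < R)
    w[band] = 0.5 * (1.0 + np.cos(np.pi * (r[band] - r_out_core) / taper))
    # backward map: sample output voxel y at c + σ(|y−c|)·(y−c)/|y−c|
    shrink = dilation / (1.0 + dilation)
    factor = 1.0 - w * shrink
    disp = delta * (factor - 1.0)[..., None]
    dfield = DeformationField(disp)

    warped = warp_array(volume.values, disp, order=1)
    warped_lab = warp_array(labelmap.values.astype(np.float64), disp, order=0)
    return (volume.with_values(warped),
            labelmap.with_values(np.rint(warped_lab).astype(np.int16)),
            dfield)


def apply_known_warp(volume: Volume3D, dfield: DeformationField,
                     order: int = 1) -> Volume3D:
    """Resample a volume under a known field with the pipeline interpolator."""
    return volume.with_values(warp_array(volume.values, dfield.vectors,
                                         order=order))


def random_smooth_velocity(shape: tuple[int, int, int], max_voxels: float,
                           rng: np.random.Generator,
                           smooth_sigma: float = 4.0) -> VelocityField:
    """Smooth random stationary velocity field, zero at the boundary.

    Gaussian white noise per component, smoothed at ``smooth_sigma`` voxels,
    apodised by a cosine window so deformations vanish at the edges, then
    scaled to the requested maximum magnitude.
    """
    v = np.stack([ndimage.gaussian_filter(rng.standard_normal(shape),
                                          smooth_sigma) for _ in range(3)], -1)
    window = np.ones(shape)
    for ax, n in enumerate(shape):
        prof = np.sin(np.linspace(0.0, np.pi, n)) ** 2
        window *= prof.reshape([-1 if k == ax else 1 for k in range(3)])
    v *= window[..., None]
    mag = np.sqrt((v ** 2).sum(-1)).max()
    if mag > 0:
        v *= max_voxels / mag
    return VelocityField(v)


def phantom_landmarks(spec: PhantomSpec) -> LandmarkSet:
    """Synthetic midsagittal landmarks emulating the CC / CSP complex.

    Three non-collinear points on the midsagittal plane, scaled with the
    brain, in world millimetres.
    """
    G, sp = spec.grid_size, spec.spacing_mm
    axes = spec.semi_axes()
    c = (G - 1) / 2.0
    pts_vox = np.array([
        [c, c + 0.45 * axes[1], c + 0.15 * axes[2]],   # genu
        [c, c - 0.35 * axes[1], c + 0.20 * axes[2]],   # splenium
        [c, c + 0.10 * axes[1], c - 0.15 * axes[2]],   # CSP
    ])
    return LandmarkSet(("cc_genu", "cc_splenium", "csp"), pts_vox * sp)


@dataclass
class ScanRecord:
    """One scan's metadata row in a cohort manifest."""

    scan_id: str
    subject_id: str
    site_id: str
    ga_weeks: float
    sex: str
    hemisphere: str
    image_path: str
    labels_path: str

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if not (GA_MIN <= self.ga_weeks <= GA_MAX):
            raise ValueError("ga_weeks outside atlas range")


MANIFEST_COLUMNS = ["scan_id", "subject_id", "site_id", "ga_weeks", "sex",
                    "hemisphere", "image_path", "labels_path"]


@dataclass
class CohortManifest:
    """Ordered collection of scan records plus generator provenance."""

    records: list[ScanRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.scan_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate scan_ids in manifest")

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records],
                            columns=MANIFEST_COLUMNS)

    def to_tsv(self, path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, sep="\t", index=False)
        prov = path.with_suffix(".provenance.json")
        prov.write_text(json.dumps(self.provenance, indent=2, sort_keys=True))
        return path

    @classmethod
    def from_tsv(cls, path) -> "CohortManifest":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        records = [ScanRecord(**{k: row[k] for k in MANIFEST_COLUMNS})
                   for _, row in df.iterrows()]
        prov_path = path.with_suffix(".provenance.json")
        prov = json.loads(prov_path.read_text()) if prov_path.exists() else {}
        return cls(records, prov)

    def validate_files(self) -> None:
        missing = [p for r in self.records
                   for p in (r.image_path, r.labels_path)
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"{len(missing)} referenced files missing, "
                                    f"first: {missing[0]}")

    def subset(self, week: float | None = None,
               hemisphere: str | None = None) -> "CohortManifest":
        recs = [r for r in self.records
                if (week is None or r.ga_weeks == week)
                and (hemisphere is None or r.hemisphere == hemisphere)]
        return CohortManifest(recs, dict(self.provenance))


GENERATOR_VERSION = "1.0"


def generate_cohort(weeks: list[float], n_per_week_per_hemisphere: int,
                    out_dir, site_effects: dict[str, float] | None = None,
                    asym_effects: dict | None = None, seed: int = 0,
                    grid_size: int = 64, spacing_mm: float = 0.6,
                    noise_level: float = 0.3, size_jitter_sd: float = 0.04,
                    warp_amplitude: float = 1.5) -> CohortManifest:
    """Generate a phantom cohort: images, label maps, sidecars, manifest.

    Per week, ``n`` left-visible and ``n`` right-visible phantoms are drawn
    with per-subject size jitter (lognormal, sd ``size_jitter_sd``) and smooth
    random diffeomorphic shape perturbations (max ``warp_amplitude`` voxels),
    assigned round-robin + shuffled across the eight sites.  ``site_effects``
    maps site ids to linear size shifts; ``asym_effects`` (e.g.
    ``{"dilation": 0.15, "hemisphere": "left"}``) injects the canonical
    regional dilation into one hemisphere group.  Identical arguments produce
    identical manifests and files.
    """
    if not weeks:
        raise ValueError("weeks list is empty")
    if n_per_week_per_hemisphere < 2:
        raise ValueError("need at least 2 scans per week per hemisphere")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    site_effects = site_effects or {}
    asym = asym_effects or {}
    asym_dil = float(asym.get("dilation", 0.0))
    asym_hemi = asym.get("hemisphere", "left")

    root_ss = np.random.SeedSequence(seed)
    records: list[ScanRecord] = []
    truth: dict[str, dict] = {}
    counter = 0
    for wi, week in enumerate(weeks):
        week_ss = np.random.SeedSequence([seed, wi])
        week_rng = np.random.default_rng(week_ss)
        n_week = 2 * n_per_week_per_hemisphere
        sites = [SITE_IDS[k % len(SITE_IDS)] for k in range(n_week)]
        week_rng.shuffle(sites)
        hemis = (["left"] * n_per_week_per_hemisphere
                 + ["right"] * n_per_week_per_hemisphere)
        for si in range(n_week):
            scan_ss = np.random.SeedSequence([seed, wi, si])
            rng = np.random.default_rng(scan_ss)
            phantom_seed = int(rng.integers(0, 2 ** 31 - 1))
            site = sites[si]
            hemi = hemis[si]
            jitter = float(np.exp(rng.normal(0.0, size_jitter_sd)) - 1.0)
            dil = asym_dil if hemi == asym_hemi else 0.0
            spec = PhantomSpec(
                ga_weeks=week, grid_size=grid_size, spacing_mm=spacing_mm,
                noise_level=noise_level, site_id=site,
                site_shift=float(site_effects.get(site, 0.0)),
                asym_dilation=dil, size_jitter=jitter,
                warp_amplitude=warp_amplitude, seed=phantom_seed)
            vol, lab = generate_phantom(spec)
            warp_max = 0.0
            if warp_amplitude > 0:
                v = random_smooth_velocity(vol.shape, warp_amplitude, rng)
                d = exp_velocity(v)
                vol = apply_known_warp(vol, d, order=1)
                lab = lab.with_values(np.rint(
                    warp_array(lab.values.astype(np.float64), d.vectors,
                               order=0)).astype(np.int16))
                warp_max = float(d.max_magnitude())

            scan_id = f"scan{counter:04d}"
            subject_id = f"subj{counter:04d}"
            counter += 1
            img_path = out_dir / f"{scan_id}_image.nii.gz"
            lab_path = out_dir / f"{scan_id}_labels.nii.gz"
            write_volume(vol, img_path)
            write_labelmap(lab, lab_path)
            sex = str(rng.choice(["F", "M"]))
            records.append(ScanRecord(scan_id, subject_id, site, week, sex,
                                      hemi, str(img_path), str(lab_path)))
            truth[scan_id] = {
                "spec": {k: v for k, v in asdict(spec).items()},
                "size_jitter": jitter,
                "asym_dilation": dil,
                "warp_max_voxels": warp_max,
            }
            (out_dir / f"{scan_id}_truth.json").write_text(
                json.dumps(truth[scan_id], indent=2, sort_keys=True))

    provenance = {
        "generator_version": GENERATOR_VERSION,
        "seed": seed,
        "entropy": int(root_ss.entropy),
        "weeks": list(map(float, weeks)),
        "n_per_week_per_hemisphere": n_per_week_per_hemisphere,
        "grid_size": grid_size,
        "spacing_mm": spacing_mm,
        "noise_level": noise_level,
        "site_effects": {k: float(v) for k, v in site_effects.items()},
        "asym_effects": {k: (float(v) if isinstance(v, (int, float)) else v)
                         for k, v in asym.items()},
        "size_jitter_sd": size_jitter_sd,
        "warp_amplitude": warp_amplitude,
    }
    manifest = CohortManifest(records, provenance)
    manifest.to_tsv(out_dir / "manifest.tsv")
    return manifest


def simulate_site_measures(n_sites: int = 8, n_per_site: int = 50,
                           between_site_fraction: float = 0.05,
                           site_shift_sd: dict[str, float] | None = None,
                           ga_slope: float = 0.0, seed: int = 0,
                           measure: str = "TBV") -> pd.DataFrame:
    """Direct numeric simulation of a multi-site measure table.

    Site means are drawn so the expected between-site share of total variance
    equals ``between_site_fraction`` (one-way random-effects model with unit
    total variance); ``site_shift_sd`` optionally fixes specific sites' mean
    shifts in pooled-s.d. units instead.  ``ga_slope`` adds a common linear
    gestational-age trend.  Used by site-variability recovery simulations
    where rendering image phantoms would be gratuitous.
    """
    if not 0.0 <= between_site_fraction < 1.0:
        raise ValueError("between_site_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    sigma_b = np.sqrt(between_site_fraction)
    sigma_w = np.sqrt(1.0 - between_site_fraction)
    rows = []
    for s in range(n_sites):
        site = SITE_IDS[s % len(SITE_IDS)] if n_sites <= len(SITE_IDS) \
            else f"site{s + 1:02d}"
        if site_shift_sd and site in site_shift_sd:
            mu = float(site_shift_sd[site])
        else:
            mu = rng.normal(0.0, sigma_b)
        ga = rng.uniform(GA_MIN, GA_MAX, n_per_site)
        vals = mu + ga_slope * (ga - ga.mean()) + rng.normal(0, sigma_w,
                                                            n_per_site)
        for j in range(n_per_site):
            rows.append({"scan_id": f"s{s:02d}_{j:03d}", "site_id": site,
                         "ga_weeks": float(ga[j]), measure: float(vals[j])})
    return pd.DataFrame(rows)
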