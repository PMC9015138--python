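"""Synthetic whole-body FDG-PET phantoms with ground-truth labels.

The generator emulates the gross features of a whole-body FDG distribution
that the pipeline depends on — not PET physics.  A low-uptake body background
(SUV ≈ 1) fills an elliptic-cylinder "torso"; organ- and lesion-like blobs
with class-specific uptake levels, sizes, textures and cranio-caudal
locations are placed inside it:

* brain and urinary bladder — the high-uptake landmarks at the scan extremes
  that the cropping heuristic keys on,
* a posterior midline column of elongated skeleton blobs, paired kidneys,
  heart, head-and-neck foci (salivary-gland level), scattered
  gastrointestinal foci, paired lateral brown-fat foci, occasional liver and
  genital foci,
* ellipsoidal tumor lesions anywhere in the nodal stations, and rare
  composed volumes (tumor+non-tumor, non-tumor+non-tumor) built from two
  overlapping blobs.

Every blob has a Gaussian SUV profile whose width and amplitude are
calibrated analytically against the pipeline's denoising filter: after
Gaussian smoothing with ``calibration_sigma`` (default 2 voxels, the
pipeline's standard denoising width) the blob peaks at its nominal class SUV
and its SUV-2.5 isocontour coincides with the ground-truth boundary.  The
threshold + watershed stage therefore recovers the truth regions to a known
accuracy instead of an accuracy that depends on blob size.  Class-specific
multiplicative log-normal noise provides texture.  All randomness flows from
a single seed; the same seed reproduces the phantom bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .volume import PETVolume

DEFAULT_SHAPE = (68, 52, 200)
DEFAULT_SPACING = (3.0, 3.0, 3.0)
DEFAULT_BACKGROUND_SUV = 1.0
DEFAULT_BACKGROUND_NOISE_SD = 0.12
DEFAULT_THRESHOLD = 2.5      # post-smoothing isocontour at the truth boundary
DEFAULT_CALIBRATION_SIGMA = 2.0   # denoising width the profiles are calibrated for
_PROFILE_FLOOR = 0.02        # blob tails below this contribution are cut
_EXCLUSION_RHO = 1.25        # normalized-radius keep-out zone between blobs
MAX_PLACEMENT_ATTEMPTS = 100


class PlacementError(RuntimeError):
    """Raised when a blob cannot be placed without overlap."""


@dataclass(frozen=True)
class BlobTemplate:
    """Sampling rules for the blobs of one tissue class.

    ``vol_ml`` bounds are sampled log-uniformly; ``suv`` is the peak uptake
    before smoothing, normal with standard deviation ``suv_sd`` and clipped to
    ``suv_clip``.  ``lateral`` selects the placement rule (``center``,
    ``left``, ``right``, ``paired``, ``posterior``, ``column``, ``any``);
    ``aspect_z`` elongates the ellipsoid along z.  ``secondary_suv`` marks
    composed volumes built from two overlapping blobs, the second at the
    given uptake level.
    """

    cls: str
    suv: float
    suv_sd: float
    vol_ml: tuple[float, float]
    z_range: tuple[float, float]
    lateral: str = "any"
    count: tuple[int, int] = (1, 1)
    poisson_mean: float | None = None
    min_count: int = 0
    presence: float = 1.0
    texture_sd: float = 0.08
    aspect_z: tuple[float, float] = (0.9, 1.1)
    suv_clip: tuple[float, float] = (3.4, 14.0)
    secondary_suv: float | None = None


def default_templates(brain_present: bool = True) -> list[BlobTemplate]:
    """Blob templates for a whole-body scan of a pediatric lymphoma patient.

    Per-patient expected counts roughly mirror the class frequencies of the
    clinical reference cohort (skeleton-heavy; liver, genital and bladder
    volumes rare) with an average of 4.1 tumor lesions per patient.
    """
    t = [
        BlobTemplate("BRAIN", 9.0, 0.5, (60, 90), (0.045, 0.06), "center",
                     presence=1.0 if brain_present else 0.0,
                     texture_sd=0.04, aspect_z=(0.8, 0.9)),
        BlobTemplate("BF", 5.5, 0.5, (8, 12), (0.12, 0.20), "paired",
                     count=(2, 2), presence=0.1, texture_sd=0.10),
        BlobTemplate("HN", 5.5, 0.4, (6, 12), (0.11, 0.18), "neck",
                     count=(1, 2), texture_sd=0.07),
        BlobTemplate("SK", 5.0, 0.3, (10, 20), (0.18, 0.82), "column",
                     count=(4, 5), texture_sd=0.06, aspect_z=(1.4, 1.8)),
        BlobTemplate("HT", 6.0, 0.5, (25, 40), (0.30, 0.38), "center",
                     presence=0.5, texture_sd=0.08),
        BlobTemplate("LI", 4.0, 0.25, (20, 35), (0.42, 0.48), "right",
                     presence=0.03, texture_sd=0.05),
        BlobTemplate("RK", 7.0, 0.5, (14, 22), (0.50, 0.58), "right"),
        BlobTemplate("LK", 7.0, 0.5, (14, 22), (0.50, 0.58), "left"),
        BlobTemplate("GI", 5.5, 0.6, (8, 16), (0.58, 0.75), "any",
                     presence=0.6, texture_sd=0.12),
        BlobTemplate("G", 5.0, 0.4, (8, 12), (0.86, 0.91), "center",
                     presence=0.05),
        BlobTemplate("BL", 10.0, 1.0, (15, 25), (0.93, 0.96), "center",
                     texture_sd=0.05),
        BlobTemplate("T", 10.0, 1.2, (8, 35), (0.14, 0.84), "any",
                     poisson_mean=4.1, min_count=1,
                     texture_sd=0.20, aspect_z=(0.8, 1.6), suv_clip=(8.0, 13.0)),
        BlobTemplate("T+NT", 10.0, 1.0, (10, 20), (0.20, 0.80), "any",
                     presence=0.3, texture_sd=0.15, secondary_suv=4.5,
                     suv_clip=(8.0, 13.0)),
        BlobTemplate("NT+NT", 5.5, 0.4, (10, 18), (0.20, 0.80), "any",
                     presence=0.1, texture_sd=0.10, secondary_suv=4.0),
    ]
    return t


@dataclass
class PhantomSpec:
    """Full description of one synthetic scan."""

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    background_suv: float = DEFAULT_BACKGROUND_SUV
    background_noise_sd: float = DEFAULT_BACKGROUND_NOISE_SD
    outside_suv: float = 0.02
    threshold: float = DEFAULT_THRESHOLD
    calibration_sigma: float = DEFAULT_CALIBRATION_SIGMA
    body_fraction: tuple[float, float] = (0.44, 0.42)
    templates: list[BlobTemplate] = field(default_factory=default_templates)
    seed: int = 0

    def __post_init__(self) -> None:
        for t in self.templates:
            if t.suv <= self.threshold:
                raise ValueError(
                    f"class {t.cls}: SUV mean {t.suv} must exceed the "
                    f"segmentation threshold {self.threshold}")


@dataclass
class Phantom:
    """A generated scan with voxel-level truth labels and a region table."""

    volume: PETVolume
    truth_labels: np.ndarray
    truth_table: pd.DataFrame
    patient_id: str = ""
    brain_present: bool = True

    def truth_mask(self, region_id: int) -> np.ndarray:
        return self.truth_labels == region_id


def _body_mask(shape, body_fraction) -> np.ndarray:
    nx, ny, nz = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    bx, by = body_fraction[0] * nx, body_fraction[1] * ny
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    disk = ((x - cx) / bx) ** 2 + ((y - cy) / by) ** 2 <= 1.0
    return np.repeat(disk[:, :, None], nz, axis=2)


def _sample_center(rng, template, shape, body_fraction, pair_sign):
    nx, ny, nz = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    bx, by = body_fraction[0] * nx, body_fraction[1] * ny
    z = (template.z_range[0]
         + rng.random() * (template.z_range[1] - template.z_range[0])) * (nz - 1)
    rule = template.lateral
    if rule in ("center", "column"):
        x = cx + rng.normal(0, 0.05 * nx)
        y = cy + rng.normal(0, 0.06 * ny)
        if rule == "column":
            x = cx + rng.normal(0, 0.02 * nx)
            y = cy + 0.45 * by + rng.normal(0, 0.03 * ny)
    elif rule in ("left", "right"):
        sign = 1.0 if rule == "right" else -1.0
        x = cx + sign * (0.45 + 0.1 * rng.random()) * bx
        y = cy + rng.normal(0, 0.08 * ny)
    elif rule == "neck":
        x = cx + rng.uniform(-0.35, 0.35) * bx
        y = cy + rng.normal(0, 0.08 * ny)
    elif rule == "paired":
        x = cx + pair_sign * (0.40 + 0.1 * rng.random()) * bx
        y = cy - 0.2 * by + rng.normal(0, 0.05 * ny)
    elif rule == "posterior":
        x = cx + rng.normal(0, 0.05 * nx)
        y = cy + 0.45 * by + rng.normal(0, 0.03 * ny)
    else:  # "any": uniform over a scaled body cross-section
        while True:
            u = rng.uniform(-1, 1)
            v = rng.uniform(-1, 1)
            if u * u + v * v <= 1.0:
                break
        x = cx + u * 0.62 * bx
        y = cy + v * 0.58 * by
    return np.array([x, y, z])


def _box_deltas(shape, center, half_extent):
    """Per-axis distance grids over a clipped bounding box, plus the box slices."""
    lo = np.maximum(np.floor(center - half_extent).astype(int), 0)
    hi = np.minimum(np.ceil(center + half_extent).astype(int) + 1, shape)
    if np.any(hi <= lo):
        return None, None
    grids = np.ix_(*(np.arange(l, h) for l, h in zip(lo, hi)))
    deltas = [g - c for g, c in zip(grids, center)]
    slices = tuple(slice(l, h) for l, h in zip(lo, hi))
    return deltas, slices


def _profile_params(amp, radii_vox, bg, threshold, sigma, min_width=0.35):
    """Pre-smoothing Gaussian widths and amplitude for a calibrated blob.

    Chosen so that after isotropic Gaussian smoothing with ``sigma`` the blob
    peaks at ``amp`` and crosses ``threshold`` at the truth semi-axes.  Blobs
    narrower than the smoothing kernel are clamped to ``min_width`` (their
    recovered extent then slightly exceeds the truth ellipsoid).
    """
    k = np.log((amp - bg) / (threshold - bg))
    u_post = radii_vox / np.sqrt(2.0 * k)
    u_pre = np.sqrt(np.maximum(u_post ** 2 - sigma ** 2, min_width ** 2))
    amp_pre = (amp - bg) * float(np.prod(u_post / u_pre))
    return u_pre, amp_pre


def _radii_vox(vol_ml, aspect, spacing) -> np.ndarray:
    """Ellipsoid semi-axes in voxel units for a target volume and z elongation."""
    v_mm3 = vol_ml * 1000.0
    r_xy = (3.0 * v_mm3 / (4.0 * np.pi * aspect)) ** (1.0 / 3.0)
    radii_mm = np.array([r_xy, r_xy, r_xy * aspect])
    return radii_mm / np.asarray(spacing, dtype=float)


def generate_phantom(spec: PhantomSpec, patient_id: str = "") -> Phantom:
    """Generate one phantom scan from a spec (deterministic given ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    nz = shape[2]
    body = _body_mask(shape, spec.body_fraction)
    img = np.where(body, spec.background_suv, spec.outside_suv).astype(float)
    labels = np.zeros(shape, dtype=np.int32)
    occupancy = np.zeros(shape, dtype=bool)
    bg = spec.background_suv
    rows = []
    region_id = 0
    brain_present = True

    for template in spec.templates:
        if template.poisson_mean is not None:
            count = max(template.min_count, int(rng.poisson(template.poisson_mean)))
        else:
            count = int(rng.integers(template.count[0], template.count[1] + 1))
        if template.presence < 1.0 and rng.random() >= template.presence:
            count = 0
        if template.cls == "BRAIN" and template.presence == 0.0:
            brain_present = False
        if template.cls == "BRAIN" and count == 0:
            brain_present = False
        column_zs = None
        if template.lateral == "column" and count > 0:
            edges = np.linspace(template.z_range[0], template.z_range[1], count + 1)
            column_zs = [(edges[i] + edges[i + 1]) / 2.0 for i in range(count)]
        for i in range(count):
            placed = False
            for _attempt in range(MAX_PLACEMENT_ATTEMPTS):
                amp = float(np.clip(rng.normal(template.suv, template.suv_sd),
                                    *template.suv_clip))
                vol_ml = float(np.exp(rng.uniform(np.log(template.vol_ml[0]),
                                                  np.log(template.vol_ml[1]))))
                aspect = float(rng.uniform(*template.aspect_z))
                pair_sign = 1.0 if i % 2 == 0 else -1.0
                center = _sample_center(rng, template, shape, spec.body_fraction,
                                        pair_sign)
                if column_zs is not None:
                    jitter = rng.normal(0, 0.01)
                    center[2] = float(np.clip(column_zs[i] + jitter, 0, 1)) * (nz - 1)
                radii = _radii_vox(vol_ml, aspect, spec.spacing)
                parts = [(center, radii, amp)]
                if template.secondary_suv is not None:
                    vol2 = 0.6 * vol_ml
                    radii2 = _radii_vox(vol2, 1.0, spec.spacing)
                    theta = rng.uniform(0, 2 * np.pi)
                    rbar1 = float(np.exp(np.log(radii).mean()))
                    rbar2 = float(np.exp(np.log(radii2).mean()))
                    off = 0.8 * (rbar1 + rbar2)
                    center2 = center + off * np.array([np.cos(theta), np.sin(theta), 0.0])
                    amp2 = float(np.clip(rng.normal(template.secondary_suv, 0.3),
                                         spec.threshold + 0.8, None))
                    parts.append((center2, radii2, amp2))

                truth = np.zeros(shape, dtype=bool)
                zone = np.zeros(shape, dtype=bool)
                ok = True
                for c, r, _a in parts:
                    # the truth ellipsoid must fit fully inside the grid
                    if np.any(c - r < 1) or np.any(c + r > np.array(shape) - 2):
                        ok = False
                        break
                    deltas, slc = _box_deltas(shape, c, r * _EXCLUSION_RHO)
                    if deltas is None:
                        ok = False
                        break
                    rho2 = sum((d / ri) ** 2 for d, ri in zip(deltas, r))
                    truth[slc] |= rho2 <= 1.0
                    zone[slc] |= rho2 <= _EXCLUSION_RHO ** 2
                if not ok or not truth.any():
                    continue
                if not body[truth].all():
                    continue
                if (occupancy & zone).any():
                    continue
                # paint the blob: Gaussian profile calibrated so that after
                # pipeline denoising the peak sits at the class SUV and the
                # threshold isocontour at the truth boundary
                for c, r, a in parts:
                    u_pre, amp_pre = _profile_params(a, r, bg, spec.threshold,
                                                     spec.calibration_sigma)
                    cut = u_pre * np.sqrt(2.0 * np.log(amp_pre / _PROFILE_FLOOR))
                    deltas, slc = _box_deltas(shape, c, cut)
                    arg = sum((d / ui) ** 2 for d, ui in zip(deltas, u_pre))
                    contrib = bg + amp_pre * np.exp(-0.5 * arg)
                    img[slc] = np.maximum(img[slc], contrib)
                if template.texture_sd > 0:
                    tex = np.exp(rng.normal(0.0, template.texture_sd,
                                            size=int(truth.sum())))
                    img[truth] *= tex
                region_id += 1
                labels[truth] = region_id
                occupancy |= zone
                voxel_ml = np.prod(spec.spacing) / 1000.0
                centroid = np.argwhere(truth).mean(axis=0)
                rows.append({"region_id": region_id, "class": template.cls,
                             "volume_ml": float(truth.sum() * voxel_ml),
                             "suv_peak": amp,
                             "centroid_x": centroid[0], "centroid_y": centroid[1],
                             "centroid_z": centroid[2]})
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place a {template.cls} blob after "
                    f"{MAX_PLACEMENT_ATTEMPTS} attempts")

    noise_zone = body & (labels == 0)
    img[noise_zone] += rng.normal(0.0, spec.background_noise_sd,
                                  size=int(noise_zone.sum()))
    img = np.clip(img, 0.0, None)
    table = pd.DataFrame(rows, columns=["region_id", "class", "volume_ml",
                                        "suv_peak", "centroid_x", "centroid_y",
                                        "centroid_z"])
    vol = PETVolume(voxels=img, spacing=spec.spacing, units="suv")
    return Phantom(volume=vol, truth_labels=labels, truth_table=table,
                   patient_id=patient_id, brain_present=brain_present)


def generate_cohort(n_patients: int, seed: int = 0,
                    spec: PhantomSpec | None = None,
                    brain_absent_fraction: float = 0.15) -> list[Phantom]:
    """Generate a cohort of phantoms with per-patient randomized specs.

    A fraction of patients (default 15%, matching the observed rate of scans
    without the brain in the field of view) is generated without a brain blob
    to exercise the cropping failure mode.  Body cross-sections vary mildly
    between patients.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be at least 1")
    base = spec if spec is not None else PhantomSpec()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_patients + 1)
    meta_rng = np.random.default_rng(child_seeds[0])
    phantoms = []
    for i in range(n_patients):
        brain_present = bool(meta_rng.random() >= brain_absent_fraction)
        scale = float(meta_rng.uniform(0.95, 1.05))
        templates = [replace(t, presence=0.0) if (t.cls == "BRAIN" and not brain_present)
                     else t for t in base.templates]
        pspec = replace(base,
                        body_fraction=(base.body_fraction[0] * scale,
                                       base.body_fraction[1] * scale),
                        templates=templates,
                        seed=int(np.random.default_rng(child_seeds[i + 1])
                                 .integers(0, 2 ** 31 - 1)))
        phantoms.append(generate_phantom(pspec, patient_id=f"P{i:03d}"))
    return phantoms
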