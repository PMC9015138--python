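"""The 31 per-region classification features.

Three families, computed on the original grid and normalized afterwards so
that values are comparable across patients and scanners without resampling:

* 19 SUV-based features — order statistics and moments of the region's SUV
  values, neighbourhood grey-tone difference (NGTDM) texture, and the mean
  SUV difference between the region and its surrounding shell;
* 6 shape features — surface/volume measures and a surface-regularity score;
* 6 spatial location features — the principal-axis direction and the centroid
  expressed in body-normalized coordinates.

SUV statistics and texture are resolution-independent by construction (they
live in absolute SUV, quantized with the same 0.5-SUV bins as segmentation);
size features are scaled by the cropped body length, and the centroid by the
body bounding box, so scanner resolution and patient size drop out.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import ConvexHull, QhullError

from .crop import CropBoundaries
from .segment import (DEFAULT_BIN_WIDTH, DEFAULT_SUV_THRESHOLD, HALF_OFFSETS,
                      SegmentedRegion, TextureUndefinedError, _pair_slices,
                      quantize_suv)

NGTDM_EPS = 1e-6
DEFAULT_SURFACE_PAIRS = 500
DEFAULT_SHELL_THICKNESS = 1

SUV_FEATURES = [
    "suv_max", "suv_min", "suv_mean", "suv_median", "suv_range",
    "suv_variance", "suv_energy", "suv_entropy", "suv_kurtosis",
    "suv_uniformity", "suv_mad", "suv_rms", "suv_std", "suv_skewness",
    "ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
    "ngtdm_complexity", "outside_difference",
]
SHAPE_FEATURES = [
    "area_surface_ratio", "surface_difference", "scaled_surface_area",
    "scaled_volume", "compactness", "max_diameter",
]
LOCATION_FEATURES = [
    "axis_x", "axis_y", "axis_z", "centroid_x", "centroid_y", "centroid_z",
]

#: canonical order of the 31 classification features
FEATURE_NAMES = SUV_FEATURES + SHAPE_FEATURES + LOCATION_FEATURES

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# SUV statistics


def suv_statistics(vol, region: SegmentedRegion,
                   bin_width: float = DEFAULT_BIN_WIDTH,
                   origin: float = DEFAULT_SUV_THRESHOLD) -> dict[str, float]:
    """First-order statistics of the region's SUV values (14 scalars).

    Entropy and uniformity use the same fixed 0.5-SUV-bin histogram as the
    segmentation texture.  Kurtosis follows the Pearson convention (a normal
    distribution scores 3); skewness and kurtosis of constant or single-voxel
    regions are defined as 0.
    """
    v = vol.voxels[tuple(region.coords.T)].astype(float)
    mean = float(v.mean())
    var = float(v.var())          # population variance
    q = quantize_suv(v, bin_width, origin)
    p = np.bincount(q).astype(float)
    p = p[p > 0] / len(q)
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())
    if var > 0 and len(v) > 1:
        skewness = float(stats.skew(v, bias=True))
        kurtosis = float(stats.kurtosis(v, fisher=False, bias=True))
    else:
        skewness = 0.0
        kurtosis = 0.0
    return {
        "suv_max": float(v.max()),
        "suv_min": float(v.min()),
        "suv_mean": mean,
        "suv_median": float(np.median(v)),
        "suv_range": float(v.max() - v.min()),
        "suv_variance": var,
        "suv_energy": float((v ** 2).sum()),
        "suv_entropy": entropy,
        "suv_kurtosis": kurtosis,
        "suv_uniformity": uniformity,
        "suv_mad": float(np.abs(v - mean).mean()),
        "suv_rms": float(np.sqrt((v ** 2).mean())),
        "suv_std": float(np.sqrt(var)),
        "suv_skewness": skewness,
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features(vol, region: SegmentedRegion,
                   bin_width: float = DEFAULT_BIN_WIDTH,
                   origin: float = DEFAULT_SUV_THRESHOLD,
                   eps: float = NGTDM_EPS) -> dict[str, float]:
    """Neighbourhood grey-tone difference matrix texture (4 scalars).

    For every region voxel with at least one 26-neighbour inside the region,
    the absolute difference between its grey tone ``i`` and the mean tone of
    those neighbours is accumulated into ``s_i``; with ``p_i`` the tone
    probabilities, the standard coarseness / contrast / busyness / complexity
    follow.  A perfectly flat region has ``s_i = 0`` everywhere: coarseness is
    capped at ``1/eps`` and the other three are defined as 0.
    """
    if region.n_voxels < 2:
        raise TextureUndefinedError("NGTDM needs at least two voxels")
    from .segment import _region_box
    q, m = _region_box(vol, region, bin_width, origin)
    nb_sum = np.zeros(q.shape, dtype=float)
    nb_cnt = np.zeros(q.shape, dtype=float)
    for off in HALF_OFFSETS:
        src, dst = _pair_slices(q.shape, off)
        # accumulate in both directions of each offset
        nb_sum[dst] += np.where(m[src], q[src], 0)
        nb_cnt[dst] += m[src]
        nb_sum[src] += np.where(m[dst], q[dst], 0)
        nb_cnt[src] += m[dst]
    valid = m & (nb_cnt > 0)
    if not valid.any():
        raise TextureUndefinedError("region has no valid neighbourhoods")
    tones = q[valid]
    diffs = np.abs(tones - nb_sum[valid] / nb_cnt[valid])
    n_tones = int(tones.max()) + 1
    n_i = np.bincount(tones, minlength=n_tones).astype(float)
    s_i = np.bincount(tones, weights=diffs, minlength=n_tones)
    n_valid = float(valid.sum())
    p_i = n_i / n_valid
    present = np.nonzero(p_i > 0)[0]
    ng_p = len(present)
    ps = float((p_i * s_i).sum())

    coarseness = 1.0 / max(ps, eps)
    ii = present[:, None].astype(float)
    jj = present[None, :].astype(float)
    pi = p_i[present][:, None]
    pj = p_i[present][None, :]
    if ng_p > 1:
        contrast = float((pi * pj * (ii - jj) ** 2).sum() / (ng_p * (ng_p - 1))
                         * s_i.sum() / n_valid)
        busy_den = float(np.abs(ii * pi - jj * pj).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
        si = s_i[present][:, None]
        sj = s_i[present][None, :]
        complexity = float((np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum()
                           / n_valid)
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
    }


# ---------------------------------------------------------------------------
# outside difference


def outside_difference(vol, region: SegmentedRegion,
                       other_regions_mask: np.ndarray | None = None,
                       thickness: int = DEFAULT_SHELL_THICKNESS) -> float:
    """Mean SUV inside the region minus the mean over its surrounding shell.

    The shell is the ``thickness``-voxel 26-connected dilation ring around the
    region, excluding voxels that belong to other segmented regions.
    """
    if region.n_voxels >= vol.voxels.size:
        raise ValueError("region fills the whole grid; no surrounding exists")
    m = region.mask(vol.shape)
    shell = ndimage.binary_dilation(m, structure=_STRUCT_26, iterations=thickness) & ~m
    if other_regions_mask is not None:
        shell &= ~np.asarray(other_regions_mask, dtype=bool)
    if not shell.any():
        raise ValueError("surrounding shell is empty")
    inside = float(vol.voxels[m].mean())
    outside = float(vol.voxels[shell].mean())
    return inside - outside


# ---------------------------------------------------------------------------
# shape


def _surface_area_and_voxels(mask: np.ndarray, spacing) -> tuple[float, np.ndarray]:
    """Surface area from exposed voxel faces, and the surface voxel coordinates."""
    dx, dy, dz = spacing
    face_area = {0: dy * dz, 1: dx * dz, 2: dx * dy}
    area = 0.0
    exposed = np.zeros(mask.shape, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            neighbour = np.roll(mask, shift, axis=axis)
            # rolled-in border values come from the far side; faces at the
            # array border are always exposed
            edge = [slice(None)] * 3
            edge[axis] = 0 if shift == 1 else -1
            neighbour[tuple(edge)] = False
            faces = mask & ~neighbour
            area += face_area[axis] * faces.sum()
            exposed |= faces
    return float(area), np.argwhere(exposed)


def _max_diameter(coords_mm: np.ndarray) -> float:
    if len(coords_mm) < 2:
        return 0.0
    pts = coords_mm
    if len(pts) > 96:
        try:
            hull = ConvexHull(pts, qhull_options="QJ")
            pts = pts[hull.vertices]
        except QhullError:
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).max())


def _surface_difference(surf_vox: np.ndarray, spacing, n_pairs: int,
                        rng: np.random.Generator) -> float:
    """Mean Euclidean / geodesic distance ratio over sampled surface voxel pairs.

    The geodesic runs along the 26-connected graph of surface voxels with
    physical edge lengths, so the ratio is 1 for perfectly straight paths and
    decreases for folded or irregular surfaces.
    """
    n = len(surf_vox)
    if n < 2:
        return 1.0
    spacing = np.asarray(spacing, dtype=float)
    mm = surf_vox * spacing
    index = {tuple(v): i for i, v in enumerate(map(tuple, surf_vox))}
    rows, cols, weights = [], [], []
    for off in HALF_OFFSETS:
        shifted = surf_vox + np.array(off)
        w = float(np.sqrt(((np.array(off) * spacing) ** 2).sum()))
        for i, t in enumerate(map(tuple, shifted)):
            j = index.get(t)
            if j is not None:
                rows.append(i)
                cols.append(j)
                weights.append(w)
    if not rows:
        return 1.0
    graph = coo_matrix((weights + weights, (rows + cols, cols + rows)), shape=(n, n))
    n_sources = min(n, max(2, int(np.ceil(n_pairs / max(1, n - 1)))), 25)
    sources = rng.choice(n, size=n_sources, replace=False)
    per_source = max(1, n_pairs // n_sources)
    dist = dijkstra(graph.tocsr(), directed=False, indices=sources)
    ratios = []
    for k, s in enumerate(sources):
        targets = rng.choice(n, size=min(per_source, n), replace=False)
        for t in targets:
            if t == s or not np.isfinite(dist[k, t]) or dist[k, t] <= 0:
                continue
            eu = float(np.sqrt(((mm[s] - mm[t]) ** 2).sum()))
            ratios.append(eu / dist[k, t])
    return float(np.mean(ratios)) if ratios else 1.0


def shape_features(region: SegmentedRegion, spacing=None,
                   n_surface_pairs: int = DEFAULT_SURFACE_PAIRS,
                   surface_seed: int = 0) -> dict[str, float]:
    """Raw (un-normalized) shape measures of one region.

    Returns physical quantities: surface area in mm^2, volume in ml, the
    volume/surface ratio in mm, sphere-normalized compactness
    ``36 pi V^2 / S^3`` (exactly 1 for an ideal sphere), the maximum voxel
    centre distance in mm, and the surface-difference score in (0, 1].
    ``scaled_surface_area``/``scaled_volume``/``max_diameter`` are produced
    from these by :func:`normalize_features`.
    """
    spacing = tuple(spacing) if spacing is not None else region.spacing
    lo = region.coords.min(axis=0)
    shape = tuple(region.coords.max(axis=0) - lo + 1)
    mask = np.zeros(shape, dtype=bool)
    mask[tuple((region.coords - lo).T)] = True
    surface_mm2, surf_vox = _surface_area_and_voxels(mask, spacing)
    volume_mm3 = region.n_voxels * spacing[0] * spacing[1] * spacing[2]
    coords_mm = region.coords * np.asarray(spacing)
    rng = np.random.default_rng(surface_seed)
    return {
        "surface_mm2": surface_mm2,
        "volume_ml": volume_mm3 / 1000.0,
        "area_surface_ratio": volume_mm3 / surface_mm2,
        "compactness": 36.0 * np.pi * volume_mm3 ** 2 / surface_mm2 ** 3,
        "max_diameter_mm": _max_diameter(coords_mm),
        "surface_difference": _surface_difference(surf_vox, spacing,
                                                  n_surface_pairs, rng),
    }


# ---------------------------------------------------------------------------
# location


def location_features(region: SegmentedRegion, boundaries: CropBoundaries,
                      grid_shape, axis_tol: float = 1e-9) -> dict[str, float]:
    """Centroid and major-axis direction in body-normalized coordinates.

    The centroid is expressed as fractions of the body bounding box: x and y
    over the grid extent, z over the cropped interval ``[z_top, z_bottom]``.
    The major axis is the unit eigenvector of the voxel-coordinate inertia
    tensor belonging to the largest eigenvalue, sign-fixed to a non-negative
    z component (then x, then y for axes lying in the axial plane); a
    degenerate isotropic tensor maps to ``(0, 0, 1)``.
    """
    if not boundaries.both_found:
        raise ValueError("location features require found crop boundaries")
    nx, ny, _ = grid_shape
    mm = region.coords * np.asarray(region.spacing, dtype=float)
    centroid_vox = region.coords.mean(axis=0)
    cz = (centroid_vox[2] - boundaries.z_top) / (boundaries.z_bottom - boundaries.z_top)
    cx = centroid_vox[0] / max(nx - 1, 1)
    cy = centroid_vox[1] / max(ny - 1, 1)

    centred = mm - mm.mean(axis=0)
    cov = centred.T @ centred / len(mm)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] - evals[0] <= axis_tol * max(evals[-1], 1.0):
        axis = np.array([0.0, 0.0, 1.0])
    else:
        axis = evecs[:, -1]
        if axis[2] < -axis_tol:
            axis = -axis
        elif abs(axis[2]) <= axis_tol:
            if axis[0] < -axis_tol:
                axis = -axis
            elif abs(axis[0]) <= axis_tol and axis[1] < 0:
                axis = -axis
    return {
        "axis_x": float(axis[0]),
        "axis_y": float(axis[1]),
        "axis_z": float(axis[2]),
        "centroid_x": float(cx),
        "centroid_y": float(cy),
        "centroid_z": float(cz),
    }


# ---------------------------------------------------------------------------
# normalization and assembly


def normalize_features(raw: dict[str, float], spacing,
                       boundaries: CropBoundaries) -> dict[str, float]:
    """Transform raw size measures to a standardized body size.

    The reference length is the cropped body length ``L = (z_bottom - z_top) * dz``
    in mm.  ``scaled_volume = volume_ml / L^3 * 1e6``,
    ``scaled_surface_area = surface_mm2 / L^2 * 1e4`` and
    ``max_diameter = max_diameter_mm / L`` are dimensionless; all other
    features are size- and resolution-independent already and pass through.
    """
    if not boundaries.both_found:
        raise ValueError("normalization requires found crop boundaries")
    body_len = (boundaries.z_bottom - boundaries.z_top) * float(spacing[2])
    if body_len <= 0:
        raise ValueError("cropped body length must be positive")
    out = dict(raw)
    out["scaled_volume"] = raw["volume_ml"] / body_len ** 3 * 1e6
    out["scaled_surface_area"] = raw["surface_mm2"] / body_len ** 2 * 1e4
    out["max_diameter"] = raw["max_diameter_mm"] / body_len
    return out


def compute_feature_vector(vol, region: SegmentedRegion,
                           boundaries: CropBoundaries,
                           other_regions_mask: np.ndarray | None = None,
                           bin_width: float = DEFAULT_BIN_WIDTH,
                           origin: float = DEFAULT_SUV_THRESHOLD,
                           n_surface_pairs: int = DEFAULT_SURFACE_PAIRS,
                           surface_seed: int = 0,
                           shell_thickness: int = DEFAULT_SHELL_THICKNESS) -> dict[str, float]:
    """All 31 features of one region, normalized, as an ordered dict."""
    raw: dict[str, float] = {}
    raw.update(suv_statistics(vol, region, bin_width, origin))
    raw.update(ngtdm_features(vol, region, bin_width, origin))
    raw["outside_difference"] = outside_difference(vol, region,
                                                   other_regions_mask,
                                                   shell_thickness)
    raw.update(shape_features(region, vol.spacing, n_surface_pairs, surface_seed))
    raw.update(location_features(region, boundaries, vol.shape))
    full = normalize_features(raw, vol.spacing, boundaries)
    return {name: float(full[name]) for name in FEATURE_NAMES}
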