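"""Candidate-region segmentation: thresholding, watershed, texture merge, size filter.

The segmentation chain is deliberately simple and fully deterministic:

1. ``threshold_mask`` — voxels with SUV below 2.5 are excluded (a sensitive
   fixed threshold meant to keep every potential tumor lesion),
2. ``watershed_segment`` — flooding watershed on the negated SUV topography,
   basins seeded at regional maxima, so every masked voxel ends up in exactly
   one catchment basin,
3. ``texture_merge`` — neighbouring basins with similar grey-level
   co-occurrence texture (mean of contrast, entropy and inverse difference
   moment) are merged while their aggregated texture difference is strictly
   below a threshold of two,
4. ``filter_small`` — regions below 2.0 ml are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima
from skimage.segmentation import watershed

DEFAULT_SUV_THRESHOLD = 2.5
DEFAULT_MERGE_THRESHOLD = 2.0
DEFAULT_MIN_VOLUME_ML = 2.0
DEFAULT_BIN_WIDTH = 0.5

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

#: the 13 half-space neighbour offsets of the 26-neighbourhood (distance one,
#: all directions); each unordered voxel pair is visited exactly once.
HALF_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


class TextureUndefinedError(ValueError):
    """Raised when a region is too small to carry co-occurrence texture."""


@dataclass
class SegmentedRegion:
    """A connected set of voxels in a parent grid.

    ``coords`` is an ``(n, 3)`` integer array of voxel indices; the physical
    volume follows from the voxel spacing: ``|coords| * dx*dy*dz / 1000`` ml.
    """

    region_id: int
    coords: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.intp).reshape(-1, 3)
        if len(self.coords) == 0:
            raise ValueError("a segmented region must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        return len(self.coords)

    @property
    def volume_ml(self) -> float:
        dx, dy, dz = self.spacing
        return self.n_voxels * dx * dy * dz / 1000.0

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.coords.T)] = True
        return m


@dataclass(frozen=True)
class TextureSummary:
    """Grey-level co-occurrence texture of one region.

    ``aggregated`` — the mean of contrast, entropy and inverse difference
    moment — is the single scalar the merge criterion compares.
    """

    contrast: float
    entropy: float
    inverse_difference_moment: float

    @property
    def aggregated(self) -> float:
        return (self.contrast + self.entropy + self.inverse_difference_moment) / 3.0


# ---------------------------------------------------------------------------
# thresholding and watershed


def threshold_mask(vol, threshold: float = DEFAULT_SUV_THRESHOLD) -> np.ndarray:
    """Binary mask of voxels with SUV greater than or equal to ``threshold``."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return vol.voxels >= threshold


def watershed_segment(vol, mask: np.ndarray) -> np.ndarray:
    """Flooding watershed of the masked SUV topography.

    Catchment basins are seeded at the regional maxima of the SUV image inside
    the mask and flooded on the negated intensities with 26-connectivity.
    Every masked voxel is assigned to exactly one basin (label >= 1); unmasked
    voxels are background 0.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(vol.shape, dtype=np.int32)
    if not mask.any():
        return labels
    seeds = local_maxima(vol.voxels, connectivity=3) & mask
    markers, _ = ndimage.label(seeds, structure=_STRUCT_26)
    labels = watershed(-vol.voxels, markers=markers, mask=mask,
                       connectivity=_STRUCT_26)
    return labels.astype(np.int32)


def regions_from_labels(labels: np.ndarray, spacing, patient_id: str = "") -> list[SegmentedRegion]:
    """Materialize :class:`SegmentedRegion` objects from an integer label grid."""
    regions = []
    objects = ndimage.find_objects(labels)
    for lab, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        local = np.argwhere(labels[slc] == lab)
        if len(local) == 0:
            continue
        offset = np.array([s.start for s in slc])
        regions.append(SegmentedRegion(region_id=lab, coords=local + offset,
                                       spacing=tuple(spacing), patient_id=patient_id))
    return regions


# ---------------------------------------------------------------------------
# co-occurrence texture


def quantize_suv(values: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH,
                 origin: float = DEFAULT_SUV_THRESHOLD) -> np.ndarray:
    """Quantize SUV values into fixed-width bins anchored at the segmentation threshold.

    Bin ``i`` covers ``[origin + i*w, origin + (i+1)*w)``; values below the
    origin (possible only outside segmented masks) clip into bin 0.  Absolute
    SUV binning keeps texture comparable across scans and scanners.
    """
    q = np.floor((np.asarray(values, dtype=float) - origin) / bin_width).astype(np.int64)
    return np.clip(q, 0, None)


def _pair_slices(shape, offset):
    src, dst = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def _region_box(vol, region: SegmentedRegion, bin_width: float, origin: float):
    """Quantized bounding-box image and membership mask for one region."""
    lo = region.coords.min(axis=0)
    hi = region.coords.max(axis=0)
    shape = tuple(hi - lo + 1)
    q = np.zeros(shape, dtype=np.int64)
    m = np.zeros(shape, dtype=bool)
    idx = tuple((region.coords - lo).T)
    q[idx] = quantize_suv(vol.voxels[tuple(region.coords.T)], bin_width, origin)
    m[idx] = True
    return q, m


def glcm_texture(vol, region: SegmentedRegion,
                 bin_width: float = DEFAULT_BIN_WIDTH,
                 origin: float = DEFAULT_SUV_THRESHOLD) -> TextureSummary:
    """Symmetric 3-D co-occurrence texture of a region at distance one.

    Voxel pairs at distance one in all 26 directions, both inside the region,
    are counted symmetrically into a co-occurrence matrix over the quantized
    SUV bins; the matrix is normalized to probabilities ``p(i, j)`` and

    * contrast              ``sum (i-j)^2 p``
    * entropy               ``-sum p log2 p``      (0 log 0 := 0)
    * inverse difference moment ``sum p / (1 + (i-j)^2)``
    """
    if region.n_voxels < 2:
        raise TextureUndefinedError("co-occurrence texture needs at least two voxels")
    q, m = _region_box(vol, region, bin_width, origin)
    n_bins = int(q[m].max()) + 1
    counts = np.zeros((n_bins, n_bins), dtype=float)
    for off in HALF_OFFSETS:
        src, dst = _pair_slices(q.shape, off)
        both = m[src] & m[dst]
        if not both.any():
            continue
        a = q[src][both]
        b = q[dst][both]
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
    total = counts.sum()
    if total == 0:
        raise TextureUndefinedError("region has no interior voxel pairs")
    p = counts / total
    i, j = np.indices(p.shape)
    contrast = float((((i - j) ** 2) * p).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    return TextureSummary(contrast, entropy, idm)


# ---------------------------------------------------------------------------
# texture merge


def _label_adjacency(labels: np.ndarray) -> dict[int, set[int]]:
    """26-adjacency between nonzero labels."""
    neighbours: dict[int, set[int]] = {}
    for off in HALF_OFFSETS:
        src, dst = _pair_slices(labels.shape, off)
        a = labels[src]
        b = labels[dst]
        sel = (a > 0) & (b > 0) & (a != b)
        if not sel.any():
            continue
        for x, y in zip(a[sel].ravel(), b[sel].ravel()):
            neighbours.setdefault(int(x), set()).add(int(y))
            neighbours.setdefault(int(y), set()).add(int(x))
    return neighbours


def texture_merge(labels: np.ndarray, vol, threshold: float = DEFAULT_MERGE_THRESHOLD,
                  bin_width: float = DEFAULT_BIN_WIDTH,
                  origin: float = DEFAULT_SUV_THRESHOLD,
                  textures: dict[int, float] | None = None) -> np.ndarray:
    """Merge neighbouring basins with similar aggregated co-occurrence texture.

    Best-first schedule: the currently most similar 26-adjacent label pair is
    merged whenever its absolute aggregated-texture difference is *strictly*
    below ``threshold``; the merged region's texture is recomputed before the
    next step, until no adjacent pair qualifies.  Regions too small to carry a
    texture never merge.  The label count never increases and the masked voxel
    set is conserved.

    ``textures`` may pre-seed aggregated values per label (used in tests to
    exercise the strict-inequality contract directly).
    """
    labels = np.asarray(labels)
    present = [int(l) for l in np.unique(labels) if l > 0]
    if not present:
        return labels.copy()
    spacing = vol.spacing
    coords = {lab: np.argwhere(labels == lab) for lab in present}

    def aggregated(lab: int) -> float | None:
        region = SegmentedRegion(lab, coords[lab], spacing)
        try:
            return glcm_texture(vol, region, bin_width, origin).aggregated
        except TextureUndefinedError:
            return None

    agg: dict[int, float | None] = {}
    for lab in present:
        if textures is not None and lab in textures:
            agg[lab] = textures[lab]
        else:
            agg[lab] = aggregated(lab)

    neighbours = _label_adjacency(labels)
    alive = set(present)
    while True:
        best_pair, best_diff = None, np.inf
        for a in sorted(alive):
            if agg[a] is None:
                continue
            for b in sorted(neighbours.get(a, ())):
                if b <= a or b not in alive or agg[b] is None:
                    continue
                diff = abs(agg[a] - agg[b])
                if diff < best_diff:
                    best_pair, best_diff = (a, b), diff
        if best_pair is None or not best_diff < threshold:
            break
        a, b = best_pair
        coords[a] = np.vstack([coords[a], coords[b]])
        del coords[b]
        alive.discard(b)
        nb = neighbours.pop(b, set())
        for c in nb:
            neighbours.get(c, set()).discard(b)
            if c != a:
                neighbours.setdefault(a, set()).add(c)
                neighbours.setdefault(c, set()).add(a)
        agg[a] = aggregated(a)

    merged = np.zeros_like(labels)
    for lab in sorted(alive):
        merged[tuple(coords[lab].T)] = lab
    return merged


def filter_small(regions, min_ml: float = DEFAULT_MIN_VOLUME_ML):
    """Keep regions whose volume is at least ``min_ml`` millilitres."""
    if min_ml <= 0:
        raise ValueError(f"min_ml must be positive, got {min_ml}")
    return [r for r in regions if r.volume_ml >= min_ml]
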