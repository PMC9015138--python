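"""Denoising, SUV conversion and coronal quality-control projections.

The pipeline order is: Gaussian smoothing of the raw intensities first, SUV
conversion second.  The two steps commute up to the scalar SUV factor, but the
stated processing order is preserved so intermediate outputs match.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .volume import (META_DOSE, META_WEIGHT, MetadataError, PETVolume,
                     ValidationError)

DEFAULT_SIGMA = 2.0


def gaussian_smooth(vol: PETVolume, sigma: float = DEFAULT_SIGMA,
                    sigma_in_mm: bool = False) -> PETVolume:
    """Denoise a volume with an isotropic Gaussian filter.

    Parameters
    ----------
    vol:
        Input volume (any units).
    sigma:
        Filter width.  Interpreted in voxel units by default; set
        ``sigma_in_mm=True`` to give it in mm (it is then divided by the
        per-axis spacing).
    sigma_in_mm:
        Whether ``sigma`` is a physical length rather than a voxel count.

    Notes
    -----
    Reflect boundary handling is used so that high-uptake structures near the
    scan ends (brain, bladder) — later used as cropping landmarks — are not
    artificially dimmed at the edges.
    """
    if sigma < 0:
        raise ValidationError(f"sigma must be non-negative, got {sigma}")
    if not np.all(np.isfinite(vol.voxels)):
        raise ValidationError("cannot smooth non-finite voxel values")
    if sigma == 0:
        return vol.with_voxels(vol.voxels.copy())
    if sigma_in_mm:
        sigmas = [sigma / s for s in vol.spacing]
    else:
        sigmas = [sigma] * 3
    smoothed = ndimage.gaussian_filter(vol.voxels, sigma=sigmas, mode="reflect")
    # The filter kernel is non-negative and sums to one; tiny negative values
    # can still arise from floating point, clip to keep the invariant.
    return vol.with_voxels(np.clip(smoothed, 0.0, None))


def compute_suv(vol: PETVolume) -> PETVolume:
    """Convert activity concentration (Bq/ml) to standardized uptake values.

    ``SUV = activity [Bq/ml] * body weight [g] / injected dose [Bq]``.

    The injected dose is assumed to be decay-corrected to scan start.
    """
    if vol.units == "suv":
        warnings.warn("volume is already in SUV units; returning it unchanged",
                      stacklevel=2)
        return vol.with_voxels(vol.voxels.copy())
    try:
        dose = float(vol.meta[META_DOSE])
        weight = float(vol.meta[META_WEIGHT])
    except KeyError as exc:
        raise MetadataError(
            f"SUV conversion needs {META_DOSE} and {META_WEIGHT} in meta"
        ) from exc
    if dose <= 0 or weight <= 0:
        raise MetadataError(f"dose and weight must be positive, got dose={dose}, weight={weight}")
    suv = vol.voxels * (weight * 1000.0) / dose
    return vol.with_voxels(suv, units="suv")


def coronal_projection(vol: PETVolume) -> np.ndarray:
    """Maximum-intensity projection along the antero-posterior (y) axis.

    Returns an ``(nx, nz)`` image used for visual plausibility checks only;
    it plays no role in classification.
    """
    if vol.units != "suv":
        raise ValidationError("coronal projection expects an SUV volume")
    return vol.voxels.max(axis=1)
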