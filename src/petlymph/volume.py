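"""In-memory PET volume container and NIfTI input/output.

The package works on whole-body FDG-PET scans stored as 3-D scalar grids.
Array axes follow the nibabel canonical order ``(x, y, z)`` with

* ``x`` — left/right (lateral),
* ``y`` — antero-posterior,
* ``z`` — cranio-caudal, index 0 at the cranial end and increasing caudally.

Voxel values are either activity concentration in Bq/ml (``units="activity"``)
or standardized uptake values (``units="suv"``).  Activity volumes carry the
injected dose and body weight needed for SUV conversion in :attr:`PETVolume.meta`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

VALID_UNITS = ("activity", "suv")

#: metadata keys used by :func:`petlymph.preprocess.compute_suv`
META_DOSE = "injected_dose_bq"
META_WEIGHT = "body_weight_kg"
META_DECAY = "decay_corrected"


class ValidationError(ValueError):
    """Raised when voxel data violate the container invariants."""


class MetadataError(KeyError):
    """Raised when acquisition metadata required for an operation is missing."""


@dataclass
class PETVolume:
    """A 3-D PET scan with voxel spacing and acquisition metadata.

    Parameters
    ----------
    voxels:
        3-D ``float`` array of non-negative finite values.
    spacing:
        Voxel edge lengths ``(dx, dy, dz)`` in mm, all positive.
    units:
        ``"activity"`` (Bq/ml) or ``"suv"``.
    meta:
        Free-form acquisition metadata; SUV conversion expects
        ``injected_dose_bq`` and ``body_weight_kg``.  Activity values are
        assumed to be decay-corrected already.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    units: str = "suv"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValidationError(f"expected a 3-D grid, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("voxel values must be finite")
        if np.any(self.voxels < 0):
            raise ValidationError("voxel values must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.units not in VALID_UNITS:
            raise ValidationError(f"units must be one of {VALID_UNITS}, got {self.units!r}")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (1 ml = 1000 mm^3)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def with_voxels(self, voxels: np.ndarray, units: str | None = None) -> "PETVolume":
        """Return a copy of this volume with new voxel data (same geometry)."""
        return replace(self, voxels=np.asarray(voxels, dtype=float),
                       units=self.units if units is None else units,
                       meta=dict(self.meta))

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_nifti(cls, path: str | Path, units: str = "suv",
                   meta_path: str | Path | None = None) -> "PETVolume":
        """Load a volume from a ``.nii``/``.nii.gz`` file.

        ``meta_path`` may point to a JSON sidecar holding dose/weight metadata
        for activity volumes.
        """
        img = nib.load(str(path))
        voxels = np.asarray(img.get_fdata(), dtype=float)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        meta: dict = {}
        if meta_path is not None:
            meta = json.loads(Path(meta_path).read_text())
            units = meta.get("units", units)
        return cls(voxels=voxels, spacing=spacing, units=units, meta=meta)

    def to_nifti(self, path: str | Path) -> None:
        """Write the volume to NIfTI with a diagonal spacing affine."""
        affine = np.diag(list(self.spacing) + [1.0])
        nib.save(nib.Nifti1Image(self.voxels.astype(np.float32), affine), str(path))
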