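"""End-to-end orchestration: preprocess → crop → segment → features → classify → evaluate.

:class:`PipelineConfig` holds every tunable constant of the workflow in one
serializable object; :func:`process_scan` runs the image stages on a single
volume, :func:`build_labeled_dataset` assembles a region-level feature table
for a phantom cohort (labels taken from the voxel ground truth), and
:func:`run_pipeline` ties everything together up to the evaluation report.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd

from . import crop as crop_mod
from . import features as feat_mod
from . import preprocess, segment
from .classify import CVConfig, nested_cv
from .evaluate import (ConfusionMatrix, EvaluationReport, binary_metrics,
                       patient_summary, per_class_accuracy)
from .phantom import Phantom
from .volume import PETVolume


@dataclass
class PipelineConfig:
    """All pipeline constants; round-trips losslessly through JSON.

    Defaults are the workflow's standard operating point: Gaussian denoising
    with sigma 2.0 (voxel units), SUV threshold 2.5, texture-merge threshold
    2.0, 2.0 ml minimum region volume, and the cropping heuristic's profile
    smoothing / peak-prominence / extremity-band constants.
    """

    sigma: float = 2.0
    sigma_in_mm: bool = False
    suv_threshold: float = 2.5
    texture_merge_threshold: float = 2.0
    min_volume_ml: float = 2.0
    bin_width: float = 0.5
    crop_profile_sigma: float = 2.0
    crop_prominence_fraction: float = 0.25
    crop_band_fraction: float = 0.6
    strict_crop: bool = False
    shell_thickness: int = 1
    surface_pairs: int = 500
    surface_seed: int = 0
    cv: CVConfig = field(default_factory=CVConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.cv, dict):
            self.cv = CVConfig(**self.cv)
        for name in ("sigma", "suv_threshold", "texture_merge_threshold",
                     "min_volume_ml", "bin_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        payload = json.loads(text)
        payload["cv"] = CVConfig(**payload.get("cv", {}))
        cfg = cls(**payload)
        return cfg


def process_scan(vol: PETVolume, config: PipelineConfig | None = None,
                 patient_id: str = "") -> SimpleNamespace:
    """Run the image stages on one scan.

    Returns a namespace with the smoothed SUV volume, crop boundaries, the
    final label grid, surviving regions, their feature table and per-stage
    region counts (for stage bookkeeping: counts never increase from
    watershed to features).
    """
    config = config or PipelineConfig()
    counts: dict[str, int] = {}

    smoothed = preprocess.gaussian_smooth(vol, config.sigma, config.sigma_in_mm)
    if smoothed.units == "activity":
        smoothed = preprocess.compute_suv(smoothed)

    boundaries = crop_mod.find_crop_boundaries(
        smoothed, band_fraction=config.crop_band_fraction,
        smooth_sigma=config.crop_profile_sigma,
        prominence_fraction=config.crop_prominence_fraction)

    mask = segment.threshold_mask(smoothed, config.suv_threshold)
    labels = segment.watershed_segment(smoothed, mask)
    counts["watershed"] = int(labels.max())
    labels = segment.texture_merge(labels, smoothed,
                                   threshold=config.texture_merge_threshold,
                                   bin_width=config.bin_width,
                                   origin=config.suv_threshold)
    regions = segment.regions_from_labels(labels, smoothed.spacing, patient_id)
    counts["merged"] = len(regions)
    regions = segment.filter_small(regions, config.min_volume_ml)
    counts["volume_filtered"] = len(regions)
    regions = crop_mod.filter_regions_by_boundaries(regions, boundaries,
                                                    strict=config.strict_crop)
    counts["crop_filtered"] = len(regions)

    all_mask = np.isin(labels, [r.region_id for r in regions]) if regions else None
    feature_rows = []
    if boundaries.both_found:
        for region in regions:
            other = all_mask & ~region.mask(smoothed.shape)
            fv = feat_mod.compute_feature_vector(
                smoothed, region, boundaries, other_regions_mask=other,
                bin_width=config.bin_width, origin=config.suv_threshold,
                n_surface_pairs=config.surface_pairs,
                surface_seed=config.surface_seed,
                shell_thickness=config.shell_thickness)
            feature_rows.append({"patient_id": patient_id,
                                 "region_id": region.region_id,
                                 "volume_ml": region.volume_ml, **fv})
    elif regions:
        warnings.warn(f"scan {patient_id or '<unnamed>'}: crop boundaries not "
                      "found; features skipped", stacklevel=2)
    features = pd.DataFrame(feature_rows)
    counts["features"] = len(features)
    return SimpleNamespace(volume=smoothed, boundaries=boundaries,
                           labels=labels, regions=regions,
                           features=features, stage_counts=counts)


def match_truth_labels(regions, truth_labels: np.ndarray,
                       truth_table: pd.DataFrame) -> list[str | None]:
    """Assign each segmented region the majority ground-truth class it overlaps.

    Regions overlapping no truth blob map to ``None`` (background artifacts).
    """
    id_to_class = dict(zip(truth_table["region_id"], truth_table["class"]))
    out = []
    for region in regions:
        ids = truth_labels[tuple(region.coords.T)]
        ids = ids[ids > 0]
        if len(ids) == 0:
            out.append(None)
            continue
        vals, cnts = np.unique(ids, return_counts=True)
        out.append(id_to_class[int(vals[cnts.argmax()])])
    return out


def build_labeled_dataset(phantoms: list[Phantom],
                          config: PipelineConfig | None = None) -> pd.DataFrame:
    """Run the image pipeline on a phantom cohort and attach ground-truth labels.

    Returns one row per surviving region: ``patient_id``, ``region_id``,
    ``volume_ml``, the 31 features and the ``label`` column.  Regions without
    truth overlap are dropped.
    """
    config = config or PipelineConfig()
    frames = []
    for ph in phantoms:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = process_scan(ph.volume, config, patient_id=ph.patient_id)
        if result.features.empty:
            continue
        labels = match_truth_labels(result.regions, ph.truth_labels,
                                    ph.truth_table)
        df = result.features.copy()
        df["label"] = labels
        df = df[df["label"].notna()]
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def run_pipeline(phantoms: list[Phantom],
                 config: PipelineConfig | None = None) -> SimpleNamespace:
    """Full workflow on a labeled cohort: dataset, nested CV, evaluation report.

    Returns a namespace with the labeled dataset, the :class:`~petlymph.classify.CVResult`
    and the :class:`~petlymph.evaluate.EvaluationReport` built from the
    repetition-averaged confusion matrix and the modal per-region predictions.
    """
    config = config or PipelineConfig()
    dataset = build_labeled_dataset(phantoms, config)
    if dataset.empty:
        raise RuntimeError("no regions survived the pipeline; nothing to classify")
    cv = dataclasses.replace(config.cv, seed=config.seed)
    result = nested_cv(dataset, cv)
    cm = ConfusionMatrix(result.mean_confusion.astype(int))
    report = EvaluationReport(
        confusion=cm,
        binary=binary_metrics(cm),
        per_class=per_class_accuracy(cm),
        patients=patient_summary(pd.DataFrame({
            "patient_id": dataset["patient_id"],
            "manual": dataset["label"],
            "automatic": result.predictions["modal"],
        })))
    return SimpleNamespace(dataset=dataset, cv_result=result, report=report,
                           config=config)
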