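"""Evaluation surfaces: confusion matrix, binary tumor metrics, per-class and per-patient reports.

All proportions are kept raw internally; the ``*_percent`` accessors round
half-up to whole percent, the convention used when reporting clinical
classification performance (so 82.5% prints as 83%).

The package ships the 14-class confusion matrix of a clinical reference
evaluation of this pipeline on 60 Hodgkin-lymphoma PET scans (853 segmented
volumes) as package data; :func:`load_reference_confusion` returns it, and the
acceptance checks recompute every derived metric from it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .classify import CLASS_ORDER, TUMOR_CLASSES


def round_half_up_percent(proportion: float) -> int:
    """Whole-percent rounding with halves rounding up (0.825 → 83)."""
    return int(math.floor(proportion * 100.0 + 0.5))


@dataclass
class ConfusionMatrix:
    """14x14 count matrix; rows = automatic class, columns = manual class."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reindex(index=CLASS_ORDER, columns=CLASS_ORDER,
                                        fill_value=0).astype(int)
        if (self.table.to_numpy() < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())

    @property
    def row_marginals(self) -> pd.Series:
        return self.table.sum(axis=1)

    @property
    def column_marginals(self) -> pd.Series:
        return self.table.sum(axis=0)


@dataclass
class BinaryMetrics:
    """Tumor/non-tumor decomposition with T and T+NT counting as tumor."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise ZeroDivisionError("no manual tumor volumes; sensitivity undefined")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn)

    @property
    def f1(self) -> float:
        return 2.0 / (1.0 / self.sensitivity + 1.0 / self.ppv)

    def percentages(self) -> dict[str, int]:
        return {name: round_half_up_percent(getattr(self, name))
                for name in ("sensitivity", "specificity", "ppv", "npv", "f1")}


def confusion(manual, automatic) -> ConfusionMatrix:
    """Count matrix from aligned manual and automatic label sequences."""
    manual = list(manual)
    automatic = list(automatic)
    if len(manual) != len(automatic):
        raise ValueError("label lists must be aligned and equal length")
    bad = (set(manual) | set(automatic)) - set(CLASS_ORDER)
    if bad:
        raise ValueError(f"labels outside the class vocabulary: {sorted(bad)}")
    table = pd.DataFrame(0, index=CLASS_ORDER, columns=CLASS_ORDER, dtype=int)
    for m, a in zip(manual, automatic):
        table.loc[a, m] += 1
    return ConfusionMatrix(table)


def binary_metrics(cm: ConfusionMatrix) -> BinaryMetrics:
    """Collapse the 14-class matrix to the tumor/non-tumor 2x2 table."""
    t = cm.table
    tumor = [c for c in CLASS_ORDER if c in TUMOR_CLASSES]
    non = [c for c in CLASS_ORDER if c not in TUMOR_CLASSES]
    return BinaryMetrics(
        tp=int(t.loc[tumor, tumor].to_numpy().sum()),
        fp=int(t.loc[tumor, non].to_numpy().sum()),
        fn=int(t.loc[non, tumor].to_numpy().sum()),
        tn=int(t.loc[non, non].to_numpy().sum()),
    )


def per_class_accuracy(cm: ConfusionMatrix) -> dict[str, float]:
    """Per manual class: correct calls over column total (NaN when the class is absent).

    Kidneys are additionally reported pooled under ``"KIDNEYS"``: a right or
    left kidney volume counts as correct when it is called either kidney.
    """
    out: dict[str, float] = {}
    t = cm.table
    for cls in CLASS_ORDER:
        col = t[cls].sum()
        out[cls] = float(t.loc[cls, cls] / col) if col > 0 else float("nan")
    kid_total = int(t[["RK", "LK"]].to_numpy().sum())
    if kid_total > 0:
        kid_correct = int(t.loc[["RK", "LK"], ["RK", "LK"]].to_numpy().sum())
        out["KIDNEYS"] = kid_correct / kid_total
    else:
        out["KIDNEYS"] = float("nan")
    return out


def patient_summary(results: pd.DataFrame) -> dict:
    """Per-patient error accounting over a region-level result table.

    ``results`` needs columns ``patient_id``, ``manual`` and ``automatic``.
    A tumor false negative is a manual-tumor region called non-tumor; a false
    positive is the converse.  Returns per-patient counts and the global
    tallies (patients with all tumor lesions correct, with exactly one false
    negative, with at least one false positive, with everything correct).
    """
    required = {"patient_id", "manual", "automatic"}
    if not required <= set(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    per_patient = []
    for pid, grp in results.groupby("patient_id", sort=True):
        man_tumor = grp["manual"].isin(TUMOR_CLASSES)
        auto_tumor = grp["automatic"].isin(TUMOR_CLASSES)
        fn = int((man_tumor & ~auto_tumor).sum())
        fp = int((~man_tumor & auto_tumor).sum())
        wrong = int((grp["manual"] != grp["automatic"]).sum())
        per_patient.append({"patient_id": pid, "n_regions": len(grp),
                            "n_tumor": int(man_tumor.sum()),
                            "false_negative_tumor": fn,
                            "false_positive_nontumor": fp,
                            "misclassified": wrong})
    df = pd.DataFrame(per_patient)
    return {
        "per_patient": df,
        "n_patients": len(df),
        "all_tumor_correct": int((df["false_negative_tumor"] == 0).sum()),
        "exactly_one_false_negative": int((df["false_negative_tumor"] == 1).sum()),
        "with_false_positive": int((df["false_positive_nontumor"] > 0).sum()),
        "all_correct": int((df["misclassified"] == 0).sum()),
    }


@dataclass
class EvaluationReport:
    """Bundled evaluation outputs with deterministic JSON serialization."""

    confusion: ConfusionMatrix
    binary: BinaryMetrics
    per_class: dict[str, float]
    patients: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "confusion": {r: {c: int(self.confusion.table.loc[r, c])
                              for c in CLASS_ORDER} for r in CLASS_ORDER},
            "total": self.confusion.total,
            "binary": {"tp": self.binary.tp, "fp": self.binary.fp,
                       "fn": self.binary.fn, "tn": self.binary.tn,
                       **{k: v for k, v in self.binary.percentages().items()}},
            "per_class_percent": {k: (None if np.isnan(v) else round_half_up_percent(v))
                                  for k, v in self.per_class.items()},
        }
        if self.patients is not None:
            d["patients"] = {k: v for k, v in self.patients.items() if k != "per_patient"}
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def text_table(self) -> str:
        """Human-readable confusion matrix mirroring the clinical report layout."""
        t = self.confusion.table
        cols = [c for c in CLASS_ORDER if t[c].sum() > 0 or t.loc[c].sum() > 0]
        lines = ["automatic \\ manual  " + "  ".join(f"{c:>6}" for c in cols + ["sum"])]
        for r in cols:
            vals = [int(t.loc[r, c]) for c in cols]
            lines.append(f"{r:<19} " + "  ".join(f"{v:6d}" for v in vals + [sum(vals)]))
        col_sums = [int(t[c].sum()) for c in cols]
        lines.append(f"{'sum':<19} " + "  ".join(f"{v:6d}" for v in col_sums + [self.confusion.total]))
        return "\n".join(lines)


def evaluate(manual, automatic, patient_ids=None) -> EvaluationReport:
    """Full evaluation from aligned label sequences (and optional patient ids)."""
    cm = confusion(manual, automatic)
    patients = None
    if patient_ids is not None:
        patients = patient_summary(pd.DataFrame({
            "patient_id": list(patient_ids), "manual": list(manual),
            "automatic": list(automatic)}))
    return EvaluationReport(confusion=cm, binary=binary_metrics(cm),
                            per_class=per_class_accuracy(cm), patients=patients)


def load_reference_confusion() -> ConfusionMatrix:
    """The shipped clinical reference confusion matrix (853 volumes, 60 patients)."""
    with resources.files("petlymph.data").joinpath(
            "clinical_confusion_matrix.csv").open() as fh:
        table = pd.read_csv(fh, index_col=0)
    return ConfusionMatrix(table)
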