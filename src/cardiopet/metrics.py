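"""Segmentation evaluation metrics: overlap, surface distance, volumes.

Conventions (documented because the field uses several):

* sensitivity is the recall of the reference, |P ∩ R| / |R|;
* Dice/Jaccard of two empty masks is reported as 1 with a warning, of one
  empty mask as 0; surface distance on any empty mask is an error, never 0;
* surface voxels are mask voxels with at least one 6-connected background
  neighbour (the array border counts as background), distances are
  voxel-centre to voxel-centre in physical mm;
* the symmetric mean surface distance is the mean of the two directed mean
  distances (not the pooled-surface mean);
* volume relative error is 100 · (predicted − reference) / reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumetric_io import GeometryError, LabelMap, TASK2_LABEL_NAMES, Task

__all__ = [
    "UndefinedMetricError",
    "LabelMetrics",
    "MetricsReport",
    "overlap_metrics",
    "mean_surface_distance",
    "volume_metrics",
    "evaluate_labelmap",
]


class UndefinedMetricError(ValueError):
    """A metric is mathematically undefined for the given masks."""


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask, dtype=bool)


def overlap_metrics(pred, ref) -> tuple[float, float, float]:
    """Dice, Jaccard, and sensitivity of two binary masks.

    dice = 2|P∩R| / (|P|+|R|), jaccard = |P∩R| / |P∪R|,
    sensitivity = |P∩R| / |R|.
    """
    pred, ref = _as_bool(pred), _as_bool(ref)
    if pred.shape != ref.shape:
        raise GeometryError(f"mask shapes differ: {pred.shape} vs {ref.shape}")
    n_pred = int(pred.sum())
    n_ref = int(ref.sum())
    n_int = int((pred & ref).sum())
    if n_pred == 0 and n_ref == 0:
        warnings.warn("both masks empty; overlap metrics reported as 1", stacklevel=2)
        return 1.0, 1.0, 1.0
    dice = 2.0 * n_int / (n_pred + n_ref)
    jaccard = n_int / (n_pred + n_ref - n_int)
    sensitivity = n_int / n_ref if n_ref > 0 else 0.0
    return dice, jaccard, sensitivity


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with a 6-connected background neighbour (border = background)."""
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def mean_surface_distance(pred, ref, spacing) -> float:
    """Symmetric mean surface distance between two masks, in mm."""
    pred, ref = _as_bool(pred), _as_bool(ref)
    if pred.shape != ref.shape:
        raise GeometryError(f"mask shapes differ: {pred.shape} vs {ref.shape}")
    if not pred.any() or not ref.any():
        raise UndefinedMetricError("surface distance undefined for an empty mask")
    spacing = np.asarray(spacing, dtype=float)
    pts_pred = np.argwhere(_surface_voxels(pred)) * spacing
    pts_ref = np.argwhere(_surface_voxels(ref)) * spacing
    d_pred_to_ref = cKDTree(pts_ref).query(pts_pred)[0]
    d_ref_to_pred = cKDTree(pts_pred).query(pts_ref)[0]
    return 0.5 * (float(d_pred_to_ref.mean()) + float(d_ref_to_pred.mean()))


def volume_metrics(pred, ref, spacing) -> tuple[float, float, float, float]:
    """Predicted/reference volumes (ml), their difference, and volume-RE%.

    RE% = 100 · (predicted − reference) / reference; undefined (error) for
    an empty reference.
    """
    pred, ref = _as_bool(pred), _as_bool(ref)
    if pred.shape != ref.shape:
        raise GeometryError(f"mask shapes differ: {pred.shape} vs {ref.shape}")
    vv_ml = float(np.prod(np.asarray(spacing, dtype=float))) / 1000.0
    predicted_ml = float(pred.sum()) * vv_ml
    reference_ml = float(ref.sum()) * vv_ml
    difference_ml = predicted_ml - reference_ml
    if reference_ml == 0:
        raise UndefinedMetricError("volume-RE% undefined for an empty reference")
    re_pct = 100.0 * difference_ml / reference_ml
    return predicted_ml, reference_ml, difference_ml, re_pct


@dataclass(frozen=True)
class LabelMetrics:
    """Evaluation record for one label code."""

    code: int
    name: str
    dice: float
    jaccard: float
    sensitivity: float
    mean_surface_distance_mm: float | None  # None when undefined (empty mask)
    predicted_volume_ml: float
    reference_volume_ml: float
    volume_difference_ml: float
    volume_re_pct: float | None  # None when the reference is empty


@dataclass
class MetricsReport:
    """Per-label evaluation of a predicted against a reference label map."""

    rows: list[LabelMetrics] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def summary(self) -> dict[str, str]:
        """Mean ± SD (min–max) per metric, over labels with defined values."""
        df = self.to_dataframe()
        out = {}
        for col in (
            "dice", "jaccard", "sensitivity", "mean_surface_distance_mm",
            "volume_difference_ml", "volume_re_pct",
        ):
            vals = df[col].dropna().astype(float)
            if len(vals) == 0:
                out[col] = "n/a"
                continue
            out[col] = (
                f"{vals.mean():.3f} ± {vals.std(ddof=0):.3f} "
                f"({vals.min():.3f}–{vals.max():.3f})"
            )
        return out

    def to_dict(self) -> dict:
        return {
            "labels": [vars(r) for r in self.rows],
            "summary": self.summary(),
        }


def evaluate_labelmap(pred: LabelMap, ref: LabelMap) -> MetricsReport:
    """Evaluate every non-background code of a predicted label map.

    Codes are taken from the task convention shared by both maps; a code
    missing from one map still yields a row (overlap 0, surface distance
    undefined) so reports stay complete on degenerate predictions.
    """
    if pred.task is not ref.task:
        raise ValueError(f"task mismatch: {pred.task.value} vs {ref.task.value}")
    if not pred.same_geometry(ref):
        raise GeometryError("predicted and reference geometries differ")

    if pred.task is Task.TASK2_COMPONENTS:
        names = TASK2_LABEL_NAMES
    else:
        names = {1: "whole_heart"}

    report = MetricsReport()
    for code, name in names.items():
        p = pred.mask(code)
        r = ref.mask(code)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dice, jaccard, sens = overlap_metrics(p, r)
        try:
            msd = mean_surface_distance(p, r, pred.spacing)
        except UndefinedMetricError:
            msd = None
        vv_ml = pred.voxel_volume_mm3 / 1000.0
        predicted_ml = float(p.sum()) * vv_ml
        reference_ml = float(r.sum()) * vv_ml
        re_pct = (
            100.0 * (predicted_ml - reference_ml) / reference_ml
            if reference_ml > 0 else None
        )
        report.rows.append(LabelMetrics(
            code=code,
            name=name,
            dice=dice,
            jaccard=jaccard,
            sensitivity=sens,
            mean_surface_distance_mm=msd,
            predicted_volume_ml=predicted_ml,
            reference_volume_ml=reference_ml,
            volume_difference_ml=predicted_ml - reference_ml,
            volume_re_pct=re_pct,
        ))
    return report
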