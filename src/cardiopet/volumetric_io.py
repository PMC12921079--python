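"""Volumetric image containers, NIfTI I/O, SUV conversion, label resampling.

All grids in this package are axis-aligned: the physical position of voxel
``(i, j, k)`` is ``origin + (i, j, k) * spacing`` in millimetres, 0-based.
NIfTI affines are written as ``diag(spacing)`` plus the origin translation;
on read, spacing is taken from the affine column norms and the origin from
its translation column.  Oblique acquisitions are outside this package's
scope and are rejected on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Unit",
    "Task",
    "VolumeGrid",
    "LabelMap",
    "SUVParams",
    "FormatError",
    "GeometryError",
    "read_volume",
    "read_labels",
    "write_volume",
    "write_labels",
    "to_suv",
    "resample_labels",
]


class FormatError(ValueError):
    """Raised for unreadable or malformed image files."""


class GeometryError(ValueError):
    """Raised when two grids that must share geometry do not."""


class Unit(str, Enum):
    """Physical unit carried by a :class:`VolumeGrid`."""

    ACTIVITY_BQ_PER_ML = "activity_Bq_per_ml"
    SUV = "SUV"
    HU = "HU"
    UNITLESS = "unitless"


class Task(str, Enum):
    """Segmentation task convention for a :class:`LabelMap`.

    ``TASK1_WHOLE_HEART``: binary mask of all cardiac tissue (code 1).
    ``TASK2_COMPONENTS``: 1 = LV myocardium (LM), 2 = LV cavity, 3 = RV.
    """

    TASK1_WHOLE_HEART = "task1_whole_heart"
    TASK2_COMPONENTS = "task2_components"


TASK_CODES: dict[Task, frozenset[int]] = {
    Task.TASK1_WHOLE_HEART: frozenset({0, 1}),
    Task.TASK2_COMPONENTS: frozenset({0, 1, 2, 3}),
}

#: Human-readable names for the task #2 component codes.
TASK2_LABEL_NAMES: dict[int, str] = {1: "LM", 2: "LV_cavity", 3: "RV"}

LM, LV_CAVITY, RV = 1, 2, 3
WHOLE_HEART = 1


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D scalar field with physical voxel geometry.

    Parameters
    ----------
    values
        3-D array of voxel values (activity concentration, SUV, or HU).
    spacing
        Per-axis voxel size in mm, all strictly positive.
    origin
        Physical position (mm) of voxel ``(0, 0, 0)``.
    unit
        One of :class:`Unit`.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: Unit = Unit.UNITLESS

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise FormatError(f"expected a 3-D volume, got ndim={values.ndim}")
        object.__setattr__(self, "values", values)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(spacing) != 3 or len(origin) != 3:
            raise FormatError("spacing and origin must be 3-vectors")
        if any(s <= 0 for s in spacing):
            raise FormatError(f"non-positive voxel spacing {spacing}")
        if not np.all(np.isfinite(values)):
            raise FormatError("volume contains NaN or Inf values")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "unit", Unit(self.unit))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "VolumeGrid | LabelMap", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_values(self, values: np.ndarray, unit: Unit | None = None) -> "VolumeGrid":
        return VolumeGrid(values, self.spacing, self.origin, unit or self.unit)


@dataclass(frozen=True)
class LabelMap:
    """Integer-coded segmentation on a :class:`VolumeGrid` geometry."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    task: Task = Task.TASK1_WHOLE_HEART

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise FormatError(f"expected a 3-D label map, got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded):
                raise FormatError("label map contains non-integer values")
            labels = rounded.astype(np.int16)
        object.__setattr__(self, "labels", labels)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in spacing):
            raise FormatError(f"non-positive voxel spacing {spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        task = Task(self.task)
        object.__setattr__(self, "task", task)
        present = set(np.unique(labels).tolist())
        if not present <= TASK_CODES[task]:
            raise FormatError(
                f"codes {sorted(present - TASK_CODES[task])} invalid for {task.value}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "VolumeGrid | LabelMap", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def mask(self, code: int) -> np.ndarray:
        """Binary mask of one label code."""
        return self.labels == code

    def foreground(self) -> np.ndarray:
        """Binary mask of all non-background voxels."""
        return self.labels != 0

    def with_labels(self, labels: np.ndarray, task: Task | None = None) -> "LabelMap":
        return LabelMap(labels, self.spacing, self.origin, task or self.task)


@dataclass(frozen=True)
class SUVParams:
    """Quantification parameters for body-weight-normalised SUV.

    ``injected_activity_Bq`` is the injected tracer activity in Bq,
    ``patient_weight_g`` the patient weight in grams.  Decay correction is
    assumed already applied upstream (attenuation- and scatter-corrected
    reconstructions); no decay term enters the conversion.
    """

    injected_activity_Bq: float
    patient_weight_g: float

    def __post_init__(self) -> None:
        if not (self.injected_activity_Bq > 0):
            raise ValueError("injected activity must be > 0 Bq")
        if not (self.patient_weight_g > 0):
            raise ValueError("patient weight must be > 0 g")


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine_from_geometry(spacing, origin) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    return affine


def _geometry_from_affine(affine: np.ndarray) -> tuple[tuple, tuple]:
    rot = affine[:3, :3]
    spacing = np.sqrt((rot**2).sum(axis=0))
    if np.any(spacing <= 0):
        raise FormatError(f"non-positive voxel spacing in affine: {spacing}")
    # Axis-aligned check: each column must point along one world axis.
    if not np.allclose(np.abs(rot), np.diag(spacing), atol=1e-3 * spacing.max()):
        raise FormatError("oblique NIfTI orientations are not supported")
    return tuple(float(s) for s in spacing), tuple(float(o) for o in affine[:3, 3])


def read_volume(path: str | Path, unit: Unit | str = Unit.UNITLESS) -> VolumeGrid:
    """Read a 3-D NIfTI volume.

    The unit tag is supplied by the caller (the file format does not carry
    it) and defaults to unitless.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D image, got shape {data.shape}")
    spacing, origin = _geometry_from_affine(img.affine)
    return VolumeGrid(data, spacing, origin, Unit(unit))


def read_labels(path: str | Path, task: Task | str = Task.TASK1_WHOLE_HEART) -> LabelMap:
    """Read an integer label map from NIfTI under the given task convention."""
    grid = read_volume(path)
    return LabelMap(np.rint(grid.values).astype(np.int16), grid.spacing, grid.origin, Task(task))


def write_volume(grid: VolumeGrid, path: str | Path) -> None:
    """Write a volume as NIfTI (float32 for scalars)."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"output directory does not exist: {path.parent}")
    affine = _affine_from_geometry(grid.spacing, grid.origin)
    nib.save(nib.Nifti1Image(grid.values.astype(np.float32), affine), path)


def write_labels(label_map: LabelMap, path: str | Path) -> None:
    """Write a label map as integer-typed NIfTI (lossless round-trip)."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"output directory does not exist: {path.parent}")
    affine = _affine_from_geometry(label_map.spacing, label_map.origin)
    nib.save(nib.Nifti1Image(label_map.labels.astype(np.int16), affine), path)


# ---------------------------------------------------------------------------
# SUV conversion


def to_suv(activity: VolumeGrid, params: SUVParams) -> VolumeGrid:
    """Convert an activity-concentration volume (Bq/ml) to SUV.

    SUV = activity concentration / (injected activity / patient weight),
    i.e. voxel values are divided by the whole-body mean concentration one
    would observe if the tracer distributed uniformly.
    """
    if activity.unit is not Unit.ACTIVITY_BQ_PER_ML:
        raise ValueError(
            f"to_suv expects unit {Unit.ACTIVITY_BQ_PER_ML.value}, got {activity.unit.value}"
        )
    factor = params.injected_activity_Bq / params.patient_weight_g
    return activity.with_values(activity.values / factor, Unit.SUV)


# ---------------------------------------------------------------------------
# Label resampling


def _nearest_source_indices(
    target_shape, target_spacing, target_origin, source_shape, source_spacing, source_origin
):
    """Per-axis nearest-neighbour source indices for every target voxel.

    Returns one 1-D index array per axis (separable because grids are
    axis-aligned) with -1 marking out-of-extent targets.
    """
    per_axis = []
    for ax in range(3):
        centers = target_origin[ax] + np.arange(target_shape[ax]) * target_spacing[ax]
        idx = np.rint((centers - source_origin[ax]) / source_spacing[ax]).astype(np.int64)
        idx[(idx < 0) | (idx >= source_shape[ax])] = -1
        per_axis.append(idx)
    return per_axis


def resample_labels(
    label_map: LabelMap,
    target: VolumeGrid | LabelMap,
) -> LabelMap:
    """Resample a label map onto another grid's geometry (nearest neighbour).

    Each target voxel takes the code of the source voxel whose centre is
    nearest in physical coordinates; target voxels outside the source extent
    become background.  Output codes are always a subset of input codes.
    """
    if label_map.same_geometry(target):
        return LabelMap(label_map.labels.copy(), target.spacing, target.origin, label_map.task)
    per_axis = _nearest_source_indices(
        target.shape, target.spacing, target.origin,
        label_map.shape, label_map.spacing, label_map.origin,
    )
    if any((idx < 0).all() for idx in per_axis):
        raise GeometryError("source and target grids have disjoint physical extents")
    ii = per_axis[0][:, None, None]
    jj = per_axis[1][None, :, None]
    kk = per_axis[2][None, None, :]
    inside = (ii >= 0) & (jj >= 0) & (kk >= 0)
    out = np.zeros(target.shape, dtype=label_map.labels.dtype)
    src = label_map.labels[np.clip(ii, 0, None), np.clip(jj, 0, None), np.clip(kk, 0, None)]
    out[inside] = src[inside]
    return LabelMap(out, target.spacing, target.origin, label_map.task)
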