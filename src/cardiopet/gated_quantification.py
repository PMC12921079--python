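"""Gated cardiac function: volume curves, EDV/ESV, ejection fraction.

Per-gate cavity volumes are voxel counts times voxel volume.  End-diastole
is the gate with the maximum volume, end-systole the minimum (no temporal
smoothing or interpolation between gates); EF = 100 · (EDV − ESV) / EDV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumetric_io import GeometryError, LabelMap, Task, VolumeGrid, LV_CAVITY

__all__ = ["GatedStudy", "VolumeCurve", "volume_curve", "sum_gates", "es_ed_sort"]


@dataclass
class GatedStudy:
    """An ordered series of per-gate label maps on a common geometry."""

    gates: list[LabelMap]
    pet_frames: list[VolumeGrid] | None = None

    def __post_init__(self) -> None:
        if len(self.gates) < 2:
            raise ValueError("a gated study needs at least 2 gates")
        first = self.gates[0]
        for g in self.gates[1:]:
            if not first.same_geometry(g) or g.task is not first.task:
                raise GeometryError("all gates must share geometry and task")

    @property
    def n_gates(self) -> int:
        return len(self.gates)


@dataclass(frozen=True)
class VolumeCurve:
    """Per-gate volume series with derived function measures."""

    volumes_ml: tuple[float, ...]
    label_code: int
    edv_ml: float
    esv_ml: float
    ef_pct: float
    ed_gate: int
    es_gate: int


def volume_curve(study: GatedStudy, label_code: int = LV_CAVITY) -> VolumeCurve:
    """Volume curve and EDV/ESV/EF for one label across the gates."""
    from .volumetric_io import TASK_CODES

    if label_code not in TASK_CODES[study.gates[0].task] or label_code == 0:
        raise ValueError(f"label code {label_code} invalid for {study.gates[0].task.value}")
    vv_ml = study.gates[0].voxel_volume_mm3 / 1000.0
    volumes = tuple(float((g.labels == label_code).sum()) * vv_ml for g in study.gates)
    if max(volumes) == 0:
        raise ValueError(f"label {label_code} absent in every gate; degenerate curve")
    ed_gate = int(np.argmax(volumes))
    es_gate = int(np.argmin(volumes))
    edv, esv = volumes[ed_gate], volumes[es_gate]
    ef = 100.0 * (edv - esv) / edv
    return VolumeCurve(volumes, label_code, edv, esv, ef, ed_gate, es_gate)


def sum_gates(frames: list[VolumeGrid]) -> VolumeGrid:
    """Voxelwise sum of gated PET frames (the static 'summed' image)."""
    if not frames:
        raise ValueError("cannot sum an empty frame list")
    first = frames[0]
    total = np.zeros(first.shape, dtype=np.float64)
    for f in frames:
        if not first.same_geometry(f) or f.unit is not first.unit:
            raise GeometryError("all frames must share geometry and unit")
        total += f.values
    return first.with_values(total)


def es_ed_sort(study: GatedStudy, label_code: int = LV_CAVITY) -> list[int]:
    """Gate indices ordered from end-systole to end-diastole.

    Sorted by ascending cavity volume; ties keep original gate order.
    """
    curve = volume_curve(study, label_code)
    return sorted(range(study.n_gates), key=lambda i: (curve.volumes_ml[i], i))
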