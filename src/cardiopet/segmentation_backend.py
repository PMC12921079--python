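"""Pluggable segmentation backends and whole-heart false-positive suppression.

A trained neural model (e.g. an nnU-Net pipeline) is a replaceable
component behind :class:`BackendContract`; its weights are not part of this
package.  The rule-based backends here exist so the full pipeline —
segment, suppress, evaluate, quantify — can be exercised deterministically
on phantoms.  Their accuracy is a property of the phantom tests, not a
claim of parity with trained models.
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumetric_io import (
    GeometryError,
    LabelMap,
    TASK_CODES,
    Task,
    Unit,
    VolumeGrid,
    read_labels,
    write_volume,
    LM,
    LV_CAVITY,
    RV,
    WHOLE_HEART,
)
from .synthetic_phantom import FWHM_TO_SIGMA

__all__ = [
    "BackendContract",
    "BackendError",
    "rulebased_whole_heart",
    "rulebased_components",
    "suppress_false_positives",
    "run_external_backend",
]


class BackendError(RuntimeError):
    """An external backend violated its contract."""


@dataclass(frozen=True)
class BackendContract:
    """Invocation contract for a segmentation backend.

    ``command`` is a shell-free argument list; it is invoked as
    ``command + [input_nifti, output_nifti]`` and must write a label map on
    the same grid as the input, using the declared task's codes.
    """

    identifier: str
    task: Task
    command: tuple[str, ...]


def rulebased_whole_heart(
    suv: VolumeGrid,
    smooth_fwhm_mm: float = 4.0,
    threshold_suv: float = 0.8,
    bridge_cut_mm: float = 4.0,
) -> LabelMap:
    """Deterministic whole-heart segmentation from PET uptake (task #1).

    Gaussian-smooth, threshold, cut thin bridges to adjacent uptake (liver)
    with a physical opening, keep the 26-connected component with the
    largest hole-filled volume, fill its holes, and morphologically close.
    Frames without uptake (e.g. pre-arrival dynamic frames) yield an empty
    mask with a warning.
    """
    if suv.unit is not Unit.SUV:
        raise ValueError(f"expected an SUV volume, got {suv.unit.value}")
    values = suv.values
    if smooth_fwhm_mm > 0:
        sigma = [smooth_fwhm_mm * FWHM_TO_SIGMA / s for s in suv.spacing]
        values = ndimage.gaussian_filter(values, sigma=sigma)
    mask = values > threshold_suv
    if not mask.any():
        warnings.warn("no voxel above threshold; returning an empty whole-heart mask",
                      stacklevel=2)
        return LabelMap(np.zeros(suv.shape, np.int16), suv.spacing, suv.origin,
                        Task.TASK1_WHOLE_HEART)
    structure = np.ones((3, 3, 3), bool)  # 26-connectivity
    if bridge_cut_mm > 0:
        from .label_harmonization import _ball_structure

        ball = _ball_structure(bridge_cut_mm, suv.spacing)
        opened = ndimage.binary_opening(mask, structure=ball)
        if opened.any():
            mask = opened
    labelled, n = ndimage.label(mask, structure=structure)
    if n > 1:
        # select by hole-filled volume so a thick-walled heart with low-uptake
        # cavities beats a solid liver blob of similar surface extent
        filled_sizes = [
            int(ndimage.binary_fill_holes(labelled == i).sum()) for i in range(1, n + 1)
        ]
        mask = labelled == (1 + int(np.argmax(filled_sizes)))
    mask = ndimage.binary_fill_holes(mask)
    mask = ndimage.binary_closing(mask, structure=structure, iterations=2)
    return LabelMap(mask.astype(np.int16) * WHOLE_HEART, suv.spacing, suv.origin,
                    Task.TASK1_WHOLE_HEART)


def rulebased_components(
    suv: VolumeGrid,
    whole_heart: LabelMap,
    lm_threshold_suv: float = 2.0,
    blood_threshold_suv: float = 0.7,
    shell_close_mm: float = 6.0,
) -> LabelMap:
    """Deterministic cardiac-component segmentation within the whole heart.

    Within the whole-heart mask: LM = high-uptake voxels; the LV cavity is
    the largest low-uptake region enclosed by the (morphologically closed)
    LM shell; the RV is the largest remaining blood-like low-uptake region.
    Degenerate inputs (no enclosed cavity) produce a partial result with a
    warning.
    """
    if suv.unit is not Unit.SUV:
        raise ValueError(f"expected an SUV volume, got {suv.unit.value}")
    if not suv.same_geometry(whole_heart):
        raise GeometryError("SUV and whole-heart geometries differ")
    heart = whole_heart.foreground()
    lm = heart & (suv.values > lm_threshold_suv)
    labels = np.zeros(suv.shape, dtype=np.int16)
    labels[lm] = LM
    low = heart & ~lm
    if not low.any():
        warnings.warn("uniform uptake inside heart: no cavities found", stacklevel=2)
        return LabelMap(labels, suv.spacing, suv.origin, Task.TASK2_COMPONENTS)

    from .label_harmonization import _ball_structure

    structure = np.ones((3, 3, 3), bool)
    # closing plugs small defects in the shell so the cavity stays enclosed
    lm_closed = lm
    if shell_close_mm > 0:
        lm_closed = ndimage.binary_closing(lm, structure=_ball_structure(shell_close_mm, suv.spacing))
    lm_hull = ndimage.binary_fill_holes(lm_closed)
    enclosed = low & lm_hull  # cavity candidates interior to the LM shell

    comp, n = ndimage.label(low, structure=structure)
    lv_region = np.zeros_like(low)
    if enclosed.any():
        # LV cavity: the connected low region with the most voxels inside the hull
        cand_sizes = ndimage.sum_labels(enclosed, comp, index=np.arange(1, n + 1))
        lv_id = 1 + int(np.argmax(cand_sizes))
        lv_region = (comp == lv_id) & lm_hull
        labels[lv_region] = LV_CAVITY
    else:
        warnings.warn("no cavity enclosed by the myocardium; partial result",
                      stacklevel=2)

    # RV: largest remaining blood-like region (excludes low-uptake fringe
    # voxels swept into the whole-heart mask by smoothing/closing)
    outside = low & ~lv_region & (suv.values > blood_threshold_suv)
    comp_o, n_o = ndimage.label(outside, structure=structure)
    if n_o > 0:
        sizes = ndimage.sum_labels(outside, comp_o, index=np.arange(1, n_o + 1))
        rv_id = 1 + int(np.argmax(sizes))
        labels[comp_o == rv_id] = RV
    return LabelMap(labels, suv.spacing, suv.origin, Task.TASK2_COMPONENTS)


def suppress_false_positives(components: LabelMap, whole_heart: LabelMap) -> LabelMap:
    """Remove component voxels outside the whole-heart mask.

    Voxelwise intersection: every labelled voxel outside the whole heart is
    set to background, voxels inside are untouched.  The output is always a
    subset of both inputs.
    """
    if not components.same_geometry(whole_heart):
        raise GeometryError("component and whole-heart geometries differ")
    out = components.labels.copy()
    out[~whole_heart.foreground()] = 0
    return components.with_labels(out)


def run_external_backend(contract: BackendContract, suv: VolumeGrid) -> LabelMap:
    """Run an external segmentation command and validate its output.

    The command receives the input and output NIfTI paths as its last two
    arguments.  The returned map must match the input geometry and use only
    the codes of the declared task; violations raise :class:`BackendError`
    with diagnostics.  Never required by the test suite's core paths.
    """
    with tempfile.TemporaryDirectory() as tmp:
        in_path = Path(tmp) / "input.nii.gz"
        out_path = Path(tmp) / "output.nii.gz"
        write_volume(suv, in_path)
        proc = subprocess.run(
            [*contract.command, str(in_path), str(out_path)],
            capture_output=True, text=True,
        )
        if proc.returncode != 0:
            raise BackendError(
                f"backend '{contract.identifier}' exited {proc.returncode}: {proc.stderr}"
            )
        if not out_path.exists():
            raise BackendError(f"backend '{contract.identifier}' wrote no output")
        try:
            result = read_labels(out_path, contract.task)
        except Exception as exc:  # invalid codes surface here
            raise BackendError(
                f"backend '{contract.identifier}' returned an invalid label map: {exc}"
            ) from exc
    if not result.same_geometry(suv):
        raise BackendError(
            f"backend '{contract.identifier}' returned mismatched geometry: "
            f"{result.shape}/{result.spacing} vs {suv.shape}/{suv.spacing}"
        )
    return result
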