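"""Parametric digital cardiac PET/CT phantom with exact ground truth.

The phantom is deliberately geometric rather than anatomical: the LV
myocardium is the shell between two concentric ellipsoids, the RV a
laterally offset ellipsoid clipped against the LV epicardial surface, and
the atria two spheres superior to the ventricles.  This keeps every truth
volume analytically known, which is what makes the generator usable as an
oracle for the segmentation, harmonization, metric, and gated-quantification
code.  It emulates the failure modes that matter for CT-less cardiac PET
segmentation — ischemic uptake defects, adjacent liver uptake, PET/CT rigid
misalignment, gated contraction with a prescribed ejection fraction, and
noisy first-pass dynamic frames — without attempting projection-space PET
simulation or anatomically realistic (XCAT-level) modelling.

HU assignments for the phantom CT are fixed conventions of this package
(lung background -700 HU, myocardium/blood 40 HU, liver 55 HU), chosen to
be plausible, not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumetric_io import (
    GeometryError,
    LabelMap,
    Task,
    Unit,
    VolumeGrid,
    LM,
    LV_CAVITY,
    RV,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_static_phantom",
    "generate_gated_series",
    "generate_dynamic_series",
    "misalign_labels",
    "randomize_heart_interior",
    "blood_input_curve",
    "myocardial_uptake_curve",
]

# Phantom CT conventions (HU)
HU_LUNG = -700.0
HU_SOFT_TISSUE = 40.0
HU_BLOOD = 40.0
HU_LIVER = 55.0

FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # FWHM = 2 sqrt(2 ln 2) sigma


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic cardiac PET/CT study.

    Lengths are mm, uptake levels SUV.  Defaults describe a 2 mm isotropic
    64^3 grid with an LV whose epicardial/endocardial semi-axes are
    (30, 30, 40) / (22, 22, 32) mm, myocardial uptake 5 SUV against a
    1 SUV blood pool and 0.4 SUV background, a 6 mm PSF, and mild
    mean-proportional noise — a plausible perfusion-tracer regime.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    center_mm: tuple[float, float, float] | None = None  # defaults to grid centre

    lv_epi_axes_mm: tuple[float, float, float] = (30.0, 30.0, 40.0)
    lv_endo_axes_mm: tuple[float, float, float] = (22.0, 22.0, 32.0)

    rv_offset_mm: tuple[float, float, float] = (-34.0, 0.0, 0.0)
    rv_axes_mm: tuple[float, float, float] = (20.0, 24.0, 32.0)

    atria_radius_mm: float = 11.0
    atria_offset_mm: float = 44.0  # superior displacement along axis 2

    uptake_lm: float = 5.0
    uptake_lv_cavity: float = 1.0
    uptake_rv_cavity: float = 1.0
    uptake_background: float = 0.4
    uptake_liver: float = 3.0

    liver_center_mm: tuple[float, float, float] = (38.0, 38.0, -56.0)
    liver_radius_mm: float = 28.0

    defect_extent_deg: float = 0.0  # angular sector of the ischemic defect
    defect_center_deg: float = 0.0
    defect_reduction: float = 1.0  # uptake multiplier inside the defect, in [0, 1]

    psf_fwhm_mm: float = 6.0
    noise_scale: float = 0.05
    misalignment_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    n_gates: int = 8
    ef_target_pct: float = 60.0

    n_frames: int = 24
    frame_duration_s: float = 1.0
    blood_onset_s: float = 4.0
    blood_peak_s: float = 8.0
    blood_peak_suv: float = 12.0
    myo_uptake_rate: float = 0.04  # fraction of cumulated blood input per second

    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be > 0")
        if not all(e < p for e, p in zip(self.lv_endo_axes_mm, self.lv_epi_axes_mm)):
            raise ValueError("endocardial semi-axes must be strictly inside epicardial")
        if not (0.0 <= self.ef_target_pct < 90.0):
            raise ValueError("ef_target_pct must lie in [0, 90)")
        if self.n_gates < 2:
            raise ValueError("n_gates must be >= 2")
        if not (0.0 <= self.defect_reduction <= 1.0):
            raise ValueError("defect_reduction must lie in [0, 1]")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.frame_duration_s <= 0:
            raise ValueError("frame_duration_s must be > 0")

    @property
    def resolved_center_mm(self) -> tuple[float, float, float]:
        if self.center_mm is not None:
            return self.center_mm
        return tuple((n - 1) * s / 2.0 for n, s in zip(self.shape, self.spacing))

    def analytic_lv_cavity_ml(self, scale: float = 1.0) -> float:
        a, b, c = self.lv_endo_axes_mm
        return (4.0 / 3.0) * math.pi * (a * scale) * (b * scale) * (c * scale) / 1000.0

    def analytic_lm_shell_ml(self) -> float:
        ae, be, ce = self.lv_epi_axes_mm
        a, b, c = self.lv_endo_axes_mm
        return (4.0 / 3.0) * math.pi * (ae * be * ce - a * b * c) / 1000.0


@dataclass
class PhantomTruth:
    """A realised phantom: images plus exact ground-truth labels and volumes."""

    spec: PhantomSpec
    pet: VolumeGrid  # SUV
    ct: VolumeGrid  # HU
    truth_labels: LabelMap  # task2 codes on the PET grid
    whole_heart: LabelMap  # task1
    ct_labels: LabelMap  # task2, shifted by the misalignment vector
    ct_whole_heart: LabelMap  # task1, shifted likewise
    true_volumes_ml: dict[str, float]
    # gated output
    gates: list["PhantomTruth"] | None = None
    analytic_volume_curve_ml: list[float] | None = None
    # dynamic output
    frames: list[VolumeGrid] | None = None
    frame_times_s: list[float] | None = None


# ---------------------------------------------------------------------------
# geometry helpers


def _physical_coords(shape, spacing, center):
    axes = [np.arange(n) * s - c for n, s, c in zip(shape, spacing, center)]
    return np.meshgrid(*axes, indexing="ij")  # coords relative to heart centre


def _ellipsoid(coords, semi_axes, offset=(0.0, 0.0, 0.0)):
    x, y, z = coords
    a, b, c = semi_axes
    ox, oy, oz = offset
    return ((x - ox) / a) ** 2 + ((y - oy) / b) ** 2 + ((z - oz) / c) ** 2 <= 1.0


def _sphere(coords, radius, offset):
    x, y, z = coords
    ox, oy, oz = offset
    return (x - ox) ** 2 + (y - oy) ** 2 + (z - oz) ** 2 <= radius**2


def _build_compartments(spec: PhantomSpec, endo_scale: float = 1.0):
    """Voxelize the cardiac compartments; returns boolean masks.

    ``endo_scale`` shrinks the endocardial ellipsoid (and the RV) for gated
    contraction; the epicardial surface stays fixed so the wall thickens in
    systole.
    """
    coords = _physical_coords(spec.shape, spec.spacing, spec.resolved_center_mm)
    epi = _ellipsoid(coords, spec.lv_epi_axes_mm)
    endo_axes = tuple(a * endo_scale for a in spec.lv_endo_axes_mm)
    endo = _ellipsoid(coords, endo_axes)
    lm = epi & ~endo
    lv_cavity = endo

    rv_axes = tuple(a * endo_scale for a in spec.rv_axes_mm)
    rv_full = _ellipsoid(coords, rv_axes, spec.rv_offset_mm)
    rv = rv_full & ~epi  # clipped by LV epicardial surface -> disjoint from LM/LV
    if (rv & (lm | lv_cavity)).any():
        raise ValueError("RV overlaps LV after clipping; invalid phantom spec")

    off = spec.atria_offset_mm
    r = spec.atria_radius_mm
    atria = _sphere(coords, r, (-12.0, 0.0, off)) | _sphere(coords, r, (12.0, 0.0, off))
    atria &= ~(lm | lv_cavity | rv)

    liver_offset = tuple(spec.liver_center_mm)
    liver = _sphere(coords, spec.liver_radius_mm, liver_offset)
    liver &= ~(lm | lv_cavity | rv | atria)
    return lm, lv_cavity, rv, atria, liver


def _whole_heart_mask(lm, lv_cavity, rv, atria):
    union = lm | lv_cavity | rv | atria
    # closing bridges the RV/LV clip gap, mimicking a single smooth cardiac mask
    return ndimage.binary_closing(union, structure=np.ones((3, 3, 3), bool), iterations=2)


def _defect_mask(spec: PhantomSpec, lm: np.ndarray) -> np.ndarray:
    if spec.defect_extent_deg <= 0 or spec.defect_reduction >= 1.0:
        return np.zeros_like(lm)
    coords = _physical_coords(spec.shape, spec.spacing, spec.resolved_center_mm)
    azimuth = np.degrees(np.arctan2(coords[1], coords[0]))
    delta = (azimuth - spec.defect_center_deg + 180.0) % 360.0 - 180.0
    return lm & (np.abs(delta) <= spec.defect_extent_deg / 2.0)


def _uptake_map(spec: PhantomSpec, lm, lv_cavity, rv, atria, liver) -> np.ndarray:
    pet = np.full(spec.shape, spec.uptake_background, dtype=np.float64)
    pet[liver] = spec.uptake_liver
    pet[atria] = spec.uptake_rv_cavity  # atrial blood pool
    pet[lv_cavity] = spec.uptake_lv_cavity
    pet[rv] = spec.uptake_rv_cavity
    pet[lm] = spec.uptake_lm
    defect = _defect_mask(spec, lm)
    pet[defect] *= spec.defect_reduction
    return pet


def _apply_psf_and_noise(pet: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.psf_fwhm_mm > 0:
        sigma_vox = [spec.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in spec.spacing]
        pet = ndimage.gaussian_filter(pet, sigma=sigma_vox)
    if spec.noise_scale > 0:
        # mean-preserving Gaussian noise with variance proportional to the
        # local mean, a simple surrogate for reconstructed-PET noise texture
        std = spec.noise_scale * np.sqrt(np.clip(pet, 0.0, None))
        pet = pet + rng.normal(0.0, 1.0, pet.shape) * std
        pet = np.clip(pet, 0.0, None)
    return pet


def _ct_volume(spec: PhantomSpec, lm, lv_cavity, rv, atria, liver) -> np.ndarray:
    ct = np.full(spec.shape, HU_LUNG, dtype=np.float64)
    ct[liver] = HU_LIVER
    ct[lm] = HU_SOFT_TISSUE
    ct[lv_cavity | rv | atria] = HU_BLOOD
    return ct


def _volumes_ml(spec: PhantomSpec, **masks: np.ndarray) -> dict[str, float]:
    vv = float(np.prod(spec.spacing)) / 1000.0
    return {name: float(mask.sum()) * vv for name, mask in masks.items()}


def misalign_labels(label_map: LabelMap, shift_mm) -> LabelMap:
    """Rigidly translate a label map by ``shift_mm`` (physical mm).

    The translated map at position p carries the source code at p - shift,
    regridded with nearest-neighbour lookup; regions moved in from outside
    the grid become background.  Codes are never invented.
    """
    shift_mm = np.asarray(shift_mm, dtype=float)
    shifted_origin = tuple(o + d for o, d in zip(label_map.origin, shift_mm))
    moved = LabelMap(label_map.labels, label_map.spacing, shifted_origin, label_map.task)
    from .volumetric_io import resample_labels

    return resample_labels(moved, label_map)


def _realize(spec: PhantomSpec, endo_scale: float, rng: np.random.Generator) -> PhantomTruth:
    lm, lv_cavity, rv, atria, liver = _build_compartments(spec, endo_scale)
    heart = _whole_heart_mask(lm, lv_cavity, rv, atria)

    pet_clean = _uptake_map(spec, lm, lv_cavity, rv, atria, liver)
    pet = _apply_psf_and_noise(pet_clean, spec, rng)
    origin = (0.0, 0.0, 0.0)
    pet_grid = VolumeGrid(pet, spec.spacing, origin, Unit.SUV)
    ct_grid = VolumeGrid(_ct_volume(spec, lm, lv_cavity, rv, atria, liver), spec.spacing, origin, Unit.HU)

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[lm] = LM
    labels[lv_cavity] = LV_CAVITY
    labels[rv] = RV
    truth = LabelMap(labels, spec.spacing, origin, Task.TASK2_COMPONENTS)
    heart_map = LabelMap(heart.astype(np.int16), spec.spacing, origin, Task.TASK1_WHOLE_HEART)

    ct_labels = misalign_labels(truth, spec.misalignment_mm)
    ct_heart = misalign_labels(heart_map, spec.misalignment_mm)

    volumes = _volumes_ml(
        spec, LM=lm, LV_cavity=lv_cavity, RV=rv, atria=atria, whole_heart=heart
    )
    return PhantomTruth(
        spec=spec,
        pet=pet_grid,
        ct=ct_grid,
        truth_labels=truth,
        whole_heart=heart_map,
        ct_labels=ct_labels,
        ct_whole_heart=ct_heart,
        true_volumes_ml=volumes,
    )


def generate_static_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate a single static cardiac PET/CT phantom.

    Deterministic given ``spec.seed``.  The ischemic defect scales PET
    uptake only; truth labels always contain the full myocardial shell.
    """
    rng = np.random.default_rng(spec.seed)
    return _realize(spec, endo_scale=1.0, rng=rng)


def _gate_scales(spec: PhantomSpec) -> list[float]:
    """Per-gate endocardial scale factors for a smooth cyclic contraction.

    Gate 0 is end-diastole.  Cavity volume scales with the cube of the
    factor, so the factors are chosen so that the analytic volume curve
    satisfies (EDV - ESV)/EDV = EF/100 exactly: v(g) = 1 - (EF/100) * w(g)
    with w a raised-cosine reaching 1 at mid-cycle, and scale = v^(1/3).
    """
    ef = spec.ef_target_pct / 100.0
    scales = []
    for g in range(spec.n_gates):
        w = 0.5 * (1.0 - math.cos(2.0 * math.pi * g / spec.n_gates))
        scales.append((1.0 - ef * w) ** (1.0 / 3.0))
    return scales


def generate_gated_series(spec: PhantomSpec) -> PhantomTruth:
    """Generate an n-gate contracting phantom with a prescribed ejection fraction.

    The epicardial surface is fixed over the cycle; the endocardial (and RV)
    ellipsoids shrink by a smooth cyclic factor so that the analytic LV
    cavity volume curve has (EDV - ESV)/EDV equal to ``ef_target_pct``/100
    exactly in continuous geometry.  Voxelized truth volumes track the
    analytic curve up to voxelization error.
    """
    scales = _gate_scales(spec)
    # geometric attainability: shrinking only, but guard against degenerate cavity
    if min(scales) <= 0:
        raise ValueError("ef_target_pct geometrically unattainable")
    rng = np.random.default_rng(spec.seed)
    gates = [_realize(spec, s, rng) for s in scales]
    curve = [spec.analytic_lv_cavity_ml(s) for s in scales]
    result = gates[0]
    return PhantomTruth(
        spec=spec,
        pet=result.pet,
        ct=result.ct,
        truth_labels=result.truth_labels,
        whole_heart=result.whole_heart,
        ct_labels=result.ct_labels,
        ct_whole_heart=result.ct_whole_heart,
        true_volumes_ml=result.true_volumes_ml,
        gates=gates,
        analytic_volume_curve_ml=curve,
    )


def blood_input_curve(spec: PhantomSpec, t: np.ndarray) -> np.ndarray:
    """Gamma-variate blood-pool input function, zero before onset."""
    t0, tp, amp = spec.blood_onset_s, spec.blood_peak_s - spec.blood_onset_s, spec.blood_peak_suv
    alpha = 3.0
    tau = np.clip((t - t0) / tp, 0.0, None)
    return amp * tau**alpha * np.exp(alpha * (1.0 - tau))


def myocardial_uptake_curve(spec: PhantomSpec, t: np.ndarray) -> np.ndarray:
    """Myocardial uptake: irreversible trapping of the blood input."""
    tt = np.linspace(0.0, float(np.max(t, initial=0.0)), 2048)
    blood = blood_input_curve(spec, tt)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (blood[1:] + blood[:-1]) * np.diff(tt))])
    return spec.myo_uptake_rate * np.interp(t, tt, cum)


def generate_dynamic_series(spec: PhantomSpec) -> PhantomTruth:
    """Generate noisy first-pass dynamic PET frames (default 1 s duration).

    Early frames carry activity in the blood pool (cavities), later frames
    in the myocardium; frames before tracer arrival contain only background.
    Frame values are the time-average of the analytic curves over each frame
    window.
    """
    lm, lv_cavity, rv, atria, liver = _build_compartments(spec, 1.0)
    base = generate_static_phantom(spec)
    rng = np.random.default_rng(spec.seed + 1)

    frames: list[VolumeGrid] = []
    times: list[float] = []
    nsub = 16  # sub-samples for the per-frame time average
    for i in range(spec.n_frames):
        t0, t1 = i * spec.frame_duration_s, (i + 1) * spec.frame_duration_s
        ts = np.linspace(t0, t1, nsub)
        blood = float(np.mean(blood_input_curve(spec, ts)))
        myo = float(np.mean(myocardial_uptake_curve(spec, ts)))
        pet = np.full(spec.shape, spec.uptake_background * 0.2, dtype=np.float64)
        pet[liver] = 0.3 * blood + 0.1 * myo
        pet[lv_cavity | rv | atria] = blood
        pet[lm] = myo + 0.1 * blood  # spillover-free myocardium plus blood fraction
        pet = _apply_psf_and_noise(pet, spec, rng)
        frames.append(VolumeGrid(pet, spec.spacing, (0.0, 0.0, 0.0), Unit.SUV))
        times.append(0.5 * (t0 + t1))

    base.frames = frames
    base.frame_times_s = times
    return base


def randomize_heart_interior(ct: VolumeGrid, whole_heart: LabelMap, seed: int) -> VolumeGrid:
    """Replace CT values inside the whole-heart mask with uniform random HU.

    In-mask voxels are drawn uniformly from [-100, 100] HU; every voxel
    outside the mask is bit-identical to the input.  Deterministic given
    ``seed``.  This probe tests whether a CT segmentation model relies on
    heart-interior intensity structure.
    """
    if ct.unit is not Unit.HU:
        raise ValueError(f"expected an HU volume, got unit {ct.unit.value}")
    if not ct.same_geometry(whole_heart):
        raise GeometryError("CT and whole-heart mask geometries differ")
    rng = np.random.default_rng(seed)
    out = ct.values.copy()
    mask = whole_heart.foreground()
    out[mask] = rng.uniform(-100.0, 100.0, size=int(mask.sum()))
    return ct.with_values(out)
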