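# Methods

## Coordinate and unit conventions

All grids are axis-aligned; voxel `(i, j, k)` sits at
`origin + (i, j, k) · spacing`, 0-based, in millimetres. NIfTI affines are
written as `diag(spacing)` plus the origin translation, and oblique
orientations are rejected on read — the toolkit targets the axis-aligned
volumes produced by PET/CT reconstruction, not arbitrarily reoriented data.
Volumes carry a unit tag (`activity_Bq_per_ml`, `SUV`, `HU`, `unitless`);
operations check tags rather than guessing.

SUV conversion divides the activity concentration by injected activity per
body weight. No decay-correction term is applied: the conversion assumes the
reconstruction already decay-corrects to a common reference time, which is
standard for attenuation- and scatter-corrected clinical reconstructions.
Users whose injected activity is not decay-corrected to scan start must
correct it before passing `SUVParams`.

## Label harmonization

The refinement of CT-derived labels against PET uptake is

    LM_refined = (PET > t  ∪  dilate(CT_LM, d))  ∩  whole_heart

with `t = 2 SUV` and `d = 2 mm` by default, followed by copying the CT LV
and RV masks into the output (later writes win). Choices that were
genuinely open, and how they were resolved:

- **Union, not intersection, for "combine".** Intersection could never
  produce voxels outside the heart, yet the whole-heart constraint exists
  precisely to remove extra-cardiac voxels that survive combination —
  extra-cardiac uptake (liver) passes the threshold branch. Union is the
  only semantics consistent with that; the LV/RV copy-over then repairs
  cavity voxels the union captures.
- **Strict threshold (`>`).** Boundary-equal voxels are excluded;
  configurable.
- **Physical dilation.** The radius is a length in mm, applied through a
  Euclidean-ball structuring element built from the actual per-axis
  spacing, so a "2 mm" dilation means the same thing at 1.33 mm and at
  4 mm voxel pitch. Voxel membership uses centre-to-centre distance
  ≤ radius.
- **LV/RV copied unrefined**, and the optional whole-heart clip on them is
  off by default.

Two properties of this recipe matter for interpreting results:

- **Exact fixed point.** On an aligned, noise-free study whose uptake
  exceeds the threshold exactly on the true myocardium, the chain returns
  the true LM exactly *when the whole-heart input equals the union of the
  component labels*. If the whole-heart mask is strictly larger (e.g. it
  includes atria or morphological-closing slack), the dilation ring
  survives in the slack region: extra voxels are confined to
  heart-but-not-component space and no true-LM voxel is ever lost. Both
  statements are tested.
- **Improvement regime.** The union keeps every false-positive voxel of
  the CT contour and adds a ring of at least the dilation radius, plus a
  partial-volume halo where blurred uptake crosses the threshold. The
  refinement therefore cannot beat the CT contour when the misalignment is
  at or below the dilation radius — the breakeven is roughly
  `shift ≈ dilation + halo`. Tests assert per-case Dice improvement for
  shifts of 6–8 mm and mean improvement over a seeded 2–8 mm shift grid;
  at 2 mm shifts the refined and CT contours are within ~0.01 Dice of each
  other by construction.

## Evaluation metrics

Dice `2|P∩R|/(|P|+|R|)`, Jaccard `|P∩R|/|P∪R|`, sensitivity `|P∩R|/|R|`
(recall of the reference; the direction is a convention of this package).
Volumes are voxel count × voxel volume; relative volume error is
`100·(V_pred − V_ref)/V_ref`.

Surface distance uses boundary voxels (mask voxels with a 6-connected
background neighbour; the array border counts as background), physical
voxel-centre coordinates, nearest-neighbour distances via a k-d tree, and
the symmetric mean of the two directed means. Degenerate conventions: two
empty masks score overlap 1 with a warning, one empty mask scores 0; surface
distance and relative volume error on empty masks are errors, never
silently 0. Every metric is cross-checked in the tests against brute-force
set enumeration and all-pairs distances on random 8×8×8 masks.

## The phantom

The phantom favours analytic tractability over anatomy: every compartment
is an ellipsoid or sphere so true volumes are known in closed form and
voxelized truth converges to them as spacing shrinks (tested). Defaults,
chosen once as a plausible perfusion-tracer study at clinical PET
resolution:

| parameter | default | note |
|---|---|---|
| grid | 64³ at 2 mm | clinical cardiac PET pitch |
| LV epi / endo semi-axes | (30,30,40) / (22,22,32) mm | ~86 ml wall, ~65 ml cavity |
| uptake LM / blood / background / liver | 5 / 1 / 0.4 / 3 SUV | myocardium-to-blood 5:1 |
| PSF FWHM | 6 mm | reconstructed PET resolution |
| noise scale | 0.05 | Gaussian, variance ∝ local mean |
| gates / EF target | 8 / 60 % | |
| dynamic frames | 24 × 1 s | first-pass regime |

The RV is an offset ellipsoid clipped by the LV epicardial surface
(guaranteeing disjointness); atria are two spheres superior to the
ventricles, part of the whole heart only. The whole-heart truth is a
morphological closing of the compartment union, mimicking a single smooth
cardiac mask. The ischemic defect scales PET uptake in an angular sector of
the wall without touching the truth labels — ground truth is anatomy, not
uptake. CT is piecewise-constant HU (lung −700, myocardium/blood 40, liver
55); these are conventions of the phantom, not measurements. PET blur is an
isotropic Gaussian (FWHM = 2.3548 σ); noise is mean-preserving Gaussian
with variance proportional to the local mean, a simple surrogate for
reconstructed-PET noise texture. All randomness flows through one seeded
generator per call; outputs are bit-reproducible per seed.

**Gated series.** The epicardium stays fixed while the endocardial (and RV)
semi-axes shrink by `s(g) = (1 − EF/100 · w(g))^{1/3}` with `w` a raised
cosine over the cycle, so the analytic cavity-volume curve satisfies
`(EDV − ESV)/EDV = EF/100` exactly and the wall thickens in systole.
Voxel-counted EF at 2 mm lands within 2 percentage points of the target and
the error shrinks at 1 mm (both tested).

**Dynamic series.** The blood pool follows a gamma-variate input function
(onset 4 s, peak 8 s, peak 12 SUV); the myocardium irreversibly traps a
fraction of the cumulated input. Frame values are time-averages of the
analytic curves over each 1 s window, so frame amplitude × duration matches
the numeric integral of the curve (tested). Frames before tracer onset
contain only background — the regime in which a PET-driven segmenter finds
nothing.

**What the phantom does not model:** anatomical shape variation,
respiratory deformation (only rigid misalignment), projection-space physics
(scatter, randoms, reconstruction artefacts), spillover beyond Gaussian
blur, and inter-patient uptake variability. Passing phantom tests shows the
algorithms are correct and robust in these controlled regimes; it does not
certify accuracy on clinical images.

**Heart-interior randomization probe.** In-mask CT voxels are replaced by
uniform continuous values in [−100, 100] HU (the distribution and float
dtype are this package's choice), everything else is bit-identical,
deterministic per seed.

## Rule-based segmentation backend

The backend exists so the pipeline is exercisable without trained weights;
its parameters are engineering choices validated on the phantom, and its
accuracy is a property of those tests — not a claim about clinical
performance. Whole heart: Gaussian smooth (4 mm FWHM), threshold
(0.8 SUV, between background and blood), cut thin bridges to adjacent
uptake with a 4 mm opening, keep the 26-connected component with the
largest hole-filled volume (a thick-walled heart with cavities beats a
solid liver blob of similar extent), fill holes, close. Components within
the whole heart: myocardium above 2 SUV; LV cavity as the largest
low-uptake region enclosed by the (6 mm-closed) myocardial shell; RV as the
largest remaining blood-like (> 0.7 SUV) region. Severe transmural defects
can open the shell faster than the closing can plug it, in which case the
cavity search degrades and a warning is raised — a known limitation of the
stand-in, not of the pipeline contract. False-positive suppression is plain
voxelwise masking by the whole-heart segmentation.

External models plug in through `BackendContract`: a command invoked with
input/output NIfTI paths whose output is validated for geometry and label
codes, with violations reported rather than remapped.

## Problem sizes and tolerances

Tests and the acceptance script run on 64³ × 2 mm phantoms (128³ × 1 mm
for the voxel-refinement checks), 100 random-mask trials for metric/oracle
agreement (exact for overlap and volume, ≤ 1e-9 mm for surface distance),
a 2-seed × 5-direction × 4-magnitude shift grid for the harmonization
property, and EF targets {40, 55, 60} % at 8 gates with a ±2 percentage
point band at 2 mm. Ellipsoid-volume convergence is asserted at 2 %
relative tolerance at 1.5 mm spacing, matching the expected voxelization
error.
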