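# Methods

`lungreg` registers two thoracic CT volumes of the same patient with a
single affine transform, found by a hierarchical per-parameter search
over normalized similarity metrics. This note records the model, the
numerical choices, and what the synthetic evaluation does and does not
demonstrate.

## Why affine

The use case is tumor follow-up: the two exams differ by patient
positioning and by genuine anatomical change (the tumor). A deformable
registration would absorb the tumor's change in size and shape into the
warp, destroying exactly the signal a radiologist wants to see. An
affine map (translation, rotation, anisotropic scale, shear — 12
parameters) aligns the exams globally while leaving local differences
visible. Deformable transforms are deliberately out of scope.

## Pipeline

1. **Normalization.** Each volume is linearly rescaled to [0, 1]
   (min → 0, max → 1). A constant volume maps to zeros with a warning
   rather than an error so degenerate inputs remain processable.
2. **Denoising.** A slice-wise geometric mean filter (default 3×3
   window): each pixel becomes the product of its neighborhood raised to
   1/(m·n). It preserves edges better than the arithmetic mean.
   Intensities are floored at ε = 1/1024 before the product, since a
   single zero pixel would otherwise annihilate its whole window; the
   filter is computed as exp(uniform-filter(log x)) with edge
   replication at borders. The filtered volume feeds only the
   segmentation; metrics are evaluated on the unfiltered data.
3. **Lung segmentation.** A deliberately simple, swappable stand-in:
   threshold dark voxels, drop components touching the axial image
   border (air outside the patient), keep the two largest 3D components,
   fill holes slice by slice (so vessels and tumors inside the lung
   join the region). The threshold is the two-class Otsu value, falling
   back to the three-class multi-Otsu thresholds (dark to bright) when
   the two-class split isolates the background instead of the air — the
   failure mode of piecewise-constant phantoms whose background class
   dominates the histogram. Threshold comparisons carry half-bin slack
   because scikit-image returns 256-bin centers, which matters for
   exactly discrete gray levels. Any routine producing a binary lung
   mask can replace this behind the same interface; airway exclusion
   and left/right separation are out of scope.
4. **Pre-alignment.** The translation equating the two binary lung
   masks' (unweighted) centers of mass, in voxels of the fixed grid. It
   is folded into the search's start parameters, not applied by an
   extra resampling pass.
5. **Cropping and downsizing.** Exams can be reduced to the lung
   bounding cuboid and block-averaged axially (512 → 256 or 128;
   spacing grows by the inverse factor, the slice count is untouched).
   Block averaging is used because plain decimation would alias and
   destabilize the metrics. In the pair pipeline both exams are cropped
   to the **union** of their two lung boxes: cropping each to its own
   box would put them on different grids and silently change the
   meaning of every translation parameter.

## Normalized similarity metrics

For normalized volumes A, B of shape X×Y×Z with joint maximum
Imax = max(A, B), the implemented figures of merit are

- nSSD = 1 − Σ(A−B)² / (X·Y·Z·Imax²)
- nSAD = 1 − Σ|A−B| / (X·Y·Z·Imax)
- R = ΣAB / √(ΣA²·ΣB²)
- nD = 1 − mean[(A > Imax/2) ⊕ (B > Imax/2)]
- nH = 1.75 − H(A,B)
- nMI = 2·MI(A,B) / (H(A)+H(B))

H and MI are Shannon joint entropy and mutual information in bits,
estimated from a joint histogram with uniform bins on [0,1]² (64 bins
by default; intensity 1 falls in the closed top bin). All except nH are
1 for coincident images and bounded in [0,1]; nH is an offset score and
is intentionally not clamped — its absolute level depends on the bin
count, and the 1.75 offset is treated as an arbitrary constant.
Two details differ from a naive transcription of the defining formulas:
R carries the Cauchy–Schwarz square root in its denominator (without it
R(A,A) ≠ 1), and nMI carries no additive constant (a +2 offset would
contradict the [0,1] contract and every value the score is meant to
take). Displaced comparisons are realized by trilinear resampling of
the moving volume onto the fixed grid (nearest-neighbor for masks),
with out-of-field voxels set to background 0; metrics always compare
equal-shape grids. Normalization is per-volume; Imax is taken jointly
inside the metrics. Metrics are evaluated on the full cropped grid, not
restricted to the lung mask.

## The hierarchical per-parameter search

Instead of searching the 12-dimensional space jointly, each parameter
is refined alone while all others are held at their current best, in
the order translation (x, y, z) → rotation x → rotation y → rotation z
→ scale (x, y, z) → shear (xy, xz, yz). One parameter's refinement is a
coarse-to-fine line search: evaluate center ± {1, 2}·step, recenter on
the best, halve the step, repeat until the step drops below the group's
stop threshold. The canonical schedule is

| group       | initial step | range    | stop      |
|-------------|--------------|----------|-----------|
| translation | width/8 vox  | ±width/4 | 1 voxel   |
| rotation    | 7.5°         | ±15°     | 0.25°     |
| scale       | 0.07         | 1±0.14   | 0.005     |
| shear       | 0.07         | ±0.14    | 0.005     |

so a 128-voxel field uses translation steps 16, 8, 4, 2, 1 and stops
when the next step (0.5) would be sub-voxel. Stop thresholds for
rotation/scale/shear are configurable choices, set roughly sub-voxel at
a 128-voxel field. The full sweep runs twice; the second pass restarts
each group from the pass-1 optimum with range and step halved. Ties on
the metric prefer the candidate closest to the group's entry value
(smallest change), then the first enumerated. Rotations, scales and
shears act in physical (mm) space about the fixed exam's lung center of
mass — pre-alignment makes the two centers coincide, and centering the
linear part on the anatomy keeps the small-angle search
well-conditioned on anisotropic grids.

The point of the decomposition is cost: the number of metric
evaluations grows as the **sum** of the per-parameter grid sizes rather
than their **product**. The search never returns a point worse than its
start, and repeated parameter values are served from a cache (the
evaluation counter counts actual metric evaluations, the only
strategy-independent cost unit).

### Baselines

- **Exhaustive grid**: the Cartesian product of explicit per-parameter
  value lists, with a candidate cap (default 20 000) because the cost
  is exponential — it exists to be compared against, and as a
  brute-force oracle at tiny grids.
- **Nelder–Mead simplex** over the 12-vector, minimizing 1 − metric,
  with standard coefficients (reflection 1, expansion 2, contraction
  0.5, shrink 0.5) and an initial simplex offset per coordinate by its
  group's natural increment (2 voxels / 2° / 0.05).
- **Pattern search**: poll ±step on each coordinate (24 probes), move
  to the best improving probe or halve every step, stop when all steps
  are below their group tolerances.

## Synthetic phantoms

`make_thorax` builds a bright ellipsoidal body (intensity 0.6)
containing two dark ellipsoidal lung fields (0.1) on a 0.0 background,
plus optional additive Gaussian noise (sd 0.01 by default, clipped to
[0,1]), and returns the exact lung mask. The default grid is 64×64×48
at (5.12, 5.12, 5) mm — the geometry of a typical 512×512 exam with
1.28 mm axial pixels and 5 mm slices after a 4× axial downsize, cropped
to the thorax. Artificial tumors are spheres of 10–60 mm diameter
rasterized in millimetres (so a 10 mm tumor may legitimately span only
two 5 mm slices), painted at soft-tissue intensity inside a lung, and
required to lie wholly inside the lung mask. Misalignments are drawn
from small fixed sets — translation 1 or 2 voxels per axis, rotation
−1° or −2° per axis, uniform scale 1.01, shear −0.01 — matching the
follow-up simulation protocol; the asymmetric sign sets are kept
literally, with a `symmetric` flag for broader testing. All randomness
is seeded and bit-reproducible.

What the phantom does **not** emulate: CT texture, airways, vessels,
breathing deformation, scanner noise spectra, or partial-volume
boundaries. Consequences worth knowing:

- Piecewise-constant intensities make interpolation blur unusually
  punishing for the histogram metrics. A transform optimal for
  correlation can slightly *lower* nMI relative to the pre-aligned
  stage, because resampling creates new gray levels at region
  boundaries; on textured clinical data the alignment gain dominates.
  The sensitivity statistic therefore uses the *size* of the
  prealigned-to-final interval, |final − prealigned|, whose ordering
  (nMI moves several times more than nSSD) is stable across seeds.
- Passing tests show the machinery is correct and the method's claims
  hold under these controlled conditions; they do not certify clinical
  accuracy on real exams.

## Problem sizes

The shipped studies are sized for a desk run: ground-truth recovery
uses 20 phantom pairs at 64×64×48 (a few seconds per registration,
~230 cached metric evaluations each); the matched-grid cost comparison
uses 3 pairs with 5×5×3×5 per-parameter grids (375-point product vs a
~22-evaluation sweep); the tumor study uses 4 phantoms × 2 diameters.
Larger volumes and batches scale linearly in voxels × evaluations.

## Known limitations

- The segmentation stand-in assumes air-filled lungs inside a brighter
  body; it will fail on exams with large pleural effusion or dense
  consolidation, and performs no airway or left/right separation.
- The search is greedy per parameter: strongly coupled misalignments
  (e.g. large rotation plus large translation) can require the second
  pass or more, and pathological couplings could in principle trap it;
  the bounded ranges assume the pre-alignment already did the coarse
  work.
- Metric evaluation sums over the whole cuboid, so the background
  share of the field of view influences absolute metric levels (nH and
  nMI especially, via the histogram).
- Upsampling, DICOM/PACS handling, HU calibration and multi-core
  execution are out of scope.
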