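# Methods

This note records the model, the tunable parameters, the design choices made
where the design was genuinely open, what the synthetic scenes do and do not
emulate, and the known limitations.

## Model and assumptions

Nuclei are modeled as bright, largely convex blobs against a dark
background, sampled by widely spaced optical sections. The central
assumption is a factorization: within an image plane, resolution is high
enough that a nuclear cross-section can be segmented by local boundary
evidence alone; along z, resolution is low enough that grouping
cross-sections into nuclei needs a learned prior over how a nucleus's
slices relate to one another (size tapering off-center, consistent
intensity, small in-plane drift). The pipeline is therefore:
band-pass filter → per-plane slice segmentation → model-guided grouping →
recovery of masked nuclei → arbitration of redundant detections.

The grouping prior is deliberately simple: one 7-D Gaussian per class
(member / distractor) and a maximum-likelihood decision. Feature
definitions: signed z-offset in planes; in-plane offset normalized by the
center slice's equivalent radius; log radius ratio; log intensity ratio;
and the same offset/radius/intensity triple relative to the closest
intervening slice (which *is* the center slice for candidates on adjacent
planes). Log ratios make the classifier invariant to global intensity
rescaling; the signed (not absolute) z-offset lets asymmetric depth fading
be learned where present. Ties in the log-odds resolve to distractor:
conservative claiming avoids swallowing neighbors.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `nuclear_diameter` | 10 (8 for the benchmark scenes) | px | sets σ_inner = D/4, σ_outer = 1.6 σ_inner, ray length cap, recovery radius |
| `noise_threshold` | 1 (5 for the benchmark scenes) | filtered units | floor for 3D maxima |
| `base_threshold_factor` | 0.5 | — | 2D-maxima floor = factor × noise_threshold; dim slices must survive for recovery |
| `n_rays` | 16 | — | boundary rays per slice |
| `prune_factor` | 2.0 | — | ray discarded when length vs the median of its two angular neighbors exceeds this ratio either way |
| `min_ray_survivors` | 8 | — | slice rejected below this |
| `recovery_radius_factor` | 0.5 | — | recovery sphere = factor × D (physical) |
| `min_cluster` | 2 | slices | "multiple unclaimed slices" gate for recovery |
| `overlap_min_shared` | 1 | slices | conflict gate: any shared slice triggers merge-vs-split scoring |
| `covariance_regularization` | 1e-4 | — | ridge × mean covariance diagonal (floored at 1) added to the diagonal |
| `candidate_z_window` | 3 | planes | superset window for training worksheets |

The two top entries are the only ones normally tuned per dataset; the rest
scale with the diameter or are structural.

Numerical choices: ray marching steps 0.5 px with bilinear interpolation and
linear sub-pixel zero-crossing refinement; truncated rays (max length or
image border) keep their truncated length during pruning, and a slice with
more than half its rays truncated is rejected as a noise ridge; polygon
interior membership uses pixel centers under the even-odd rule; plateau
maxima are reduced to their lexicographically smallest voxel so runs are
bit-reproducible; maxima on the volume border are kept (embryos touch image
edges in practice).

## Extraction, recovery, resolution

Seeds are processed in descending filtered response, so bright nuclei claim
first. The claiming walk moves plane-by-plane up, then down, from the seed;
on each adjacent plane the candidate is the in-plane nearest slice within
the sum of radii of itself and the seed slice, and the walk stops at the
first non-member or empty plane (strict contiguity). Multiple claims may
accumulate; nothing is un-claimed until resolution.

Recovery iterates: among unclaimed slices, any with at least `min_cluster`
unclaimed slices (itself included) within the recovery sphere qualifies; a
nucleus is seeded at the brightest qualifying slice and extracted from the
full slice set, claimed slices included, so redundant fragments overlap
their originals and end up arbitrated rather than orphaned. Each iteration
claims its previously unclaimed seed, so the loop terminates within the
slice count.

Resolution repeatedly takes the pair of nuclei sharing the most slices and
scores merge vs split. The merge configuration keeps one slice per plane;
where the two nuclei contributed distinct slices on the same plane the one
scoring higher against the merge center is kept and the other returns to
the unclaimed pool. A split that would disconnect either nucleus's plane
interval, or strip either of all slices, is infeasible and falls back to
merge. Every applied decision strictly reduces the total number of
(nucleus, slice) claims, so the loop terminates. After resolution the
pipeline asserts, on every run, that no slice has two claimants and every
nucleus occupies a contiguous plane interval.

## Shape-model training

Training data comes from candidate worksheets: for each seed slice, every
slice within `candidate_z_window` planes and within the sum of radii
in-plane is listed, and a curator (or the synthetic ground truth) marks
non-members. Two training-set design choices matter:

- **Off-center seeds.** Each nucleus contributes seeds at its center slice
  and at member slices one plane off-center. Claiming walks start wherever
  a 3D maximum or a recovery seed lands — often not the exact center — so
  the member class must cover imperfectly centered references. (Seeding two
  planes off-center was tried and rejected: it broadens the member class
  enough to merge genuinely distinct stacked nuclei.)
- **Ambiguous-shell exclusion.** A candidate outside a nucleus's rendered
  envelope (semi-axes ⊕ blur, in quadrature) but inside the 2×-blur halo is
  neither clearly signal nor clearly background; such candidates are
  excluded from the supervised set rather than labeled. Labeling them
  "distractor" (as a naive geometric rule would) teaches the model to
  reject the faint tail slices of its own nucleus and caps achievable
  accuracy around 90%; with the shell excluded, held-out candidate
  classification runs at 95–99% across crowding levels.

Priors default to empirical class frequencies. Covariances use the unbiased
estimator plus the ridge above, so a single corrected frame cannot produce
a singular model; two identical examples per class degenerate exactly to
the ridge matrix.

## Synthetic scenes: what they emulate, and what they do not

The generator reproduces, with exact ground truth, the difficulties that
drive detection error in sectioned embryo stacks:

- **Controlled crowding.** Nuclei are placed in contact chains (5 per chain
  by default); each chain step sits at a boundary gap equal to the target
  separation, chains are kept mutually farther apart than that gap, and
  half the steps are biased along z — the under-sampled axis where crowding
  actually hurts. The realized mean nearest-neighbor separation (measured
  with the same bounding-circle statistic the evaluation module reports)
  lands on the target by construction, within ±0.25 slice spacings.
- **Appearance variability.** Per-nucleus radii (4.0 ± 0.4 µm), mild random
  axis ratios (±15%), inter-nuclear intensity 100 ± 25, two intra-nuclear
  intensity modes that *redistribute* signal (regions between modes dim
  toward 1 − amplitude of nominal — brightening-only bumps never produce
  the over-segmentation seen in real data), axial PSF elongation 2.0× the
  1 µm lateral blur (axial σ 2.0 µm, just under the 2.5 µm plane spacing, so
  one-plane gaps remain resolvable), 2% per-plane depth fading, additive
  Gaussian noise (σ 3), optional shot noise.
- **The crowded benchmark** (`crowded_spec`) adds the two specific error
  mechanisms the pipeline's later stages exist for: chain followers at 0.4×
  their anchor's intensity (masked nuclei that are not 3D maxima — recovery's
  quarry) and a 15% admixture of 1.6×-oversized nuclei whose two axial modes
  split them into top/bottom double detections (resolution's quarry).
  Per-stage error accounting aggregates three such scenes (120 nuclei):
  at realistic per-nucleus error rates a single 40-nucleus scene often
  shows zero events of one kind or the other.

Not emulated: rigorous PSF optics (Born–Wolf), nuclear motion or division
between frames, multi-channel imaging, tissue-scale background structure,
and segmentation-boundary fidelity (the generator's ellipsoids have no
surface texture). Passing on these scenes therefore demonstrates the
pipeline's localization logic under the catalogued difficulty factors, not
performance on any particular microscope's data — for that, the two key
parameters and ideally the shape model should be re-tuned/retrained on one
curated frame of the new data.

## Evaluation choices

Matching is optimal one-to-one assignment on physical centroid distance
(pairs beyond one nuclear radius rejected; infeasible pairs are given a
prohibitive cost *before* assignment so the matcher never trades one good
match for two bad ones). Error percentages use the ground-truth count as
denominator. The separation statistic uses the bounding circle of each
nucleus's largest slice and is reported in units of slice spacing; it can
be negative when bounding spheres interpenetrate.

Scene sizes throughout (25–40 nuclei, 128×128×20 voxels) are the package's
benchmark scale: large enough that per-stage patterns and the
error-vs-separation contrast are reproducible across seeds, small enough
that the full suite and the acceptance script run in seconds.

## Known limitations

- The slice-membership classifier is the weakest link (as expected for a
  single-Gaussian design): touching z-stacked nuclei of similar appearance
  are intrinsically ambiguous from one frame, and a few percent error
  remains below quarter-plane separations.
- Redundant detections whose slice sets do not overlap (parallel fragment
  stacks in one nucleus) are invisible to conflict resolution, which only
  arbitrates shared slices.
- Recovery seeds at the brightest unclaimed slice; pathological noise
  textures above the base threshold could seed spurious fragments, though
  the strong DoG smoothing makes this rare.
- The `min_cluster = 2` recovery gate means a nucleus visible in only one
  unclaimed slice is never recovered.
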