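# Methods

This note documents the models, conventions and numerical choices behind
`petlesion`, and what its synthetic validation does and does not show
about real PET data.

## Imaging substrate and conventions

Volumes are 3D grids of standardized uptake values (SUV), dimensionless
and non-negative, with per-axis voxel spacing in mm. All geometry is
index-based; the only world-space quantity used is the spacing, from which
volumes follow as voxel count × (s₁s₂s₃)/1000 cc. Instance segmentations
are integer label maps (0 = background), and anatomical sites are stored
per voxel in a parallel site map with five categories (lymph node, lung,
liver, bone, other). Site maps exist so that *false positives* can inherit
a site from where they occur; a lesion's site is the majority site over
its voxels, ties broken by the alphabetically first name (deterministic
and order-independent). SUV volumes and label maps are exchanged as
NIfTI-1; lesion features as CSV tables.

SUVpeak is the mean SUV over a sphere of 1 cc (configurable) centred on a
voxel, clipped at grid edges — the standard small-sphere peak used in
quantitative response criteria, robust to single-voxel noise. The sphere
contains every voxel whose *center* lies within the radius; at 2 mm
isotropic spacing a 1 cc sphere covers 123 voxels.

## Adaptive-threshold segmentation

The segmenter reproduces the classical front-end of automated PET reading
systems:

1. **Blood-pool reference.** Mean and sample SD (n−1) of SUV over an
   explicitly supplied blood-pool mask. Automatic localisation of the
   blood pool is not attempted.
2. **Focus detection.** Local maxima of the SUV field (≥ all neighbours
   under the configured connectivity, default 26) whose SUVpeak exceeds
   mean + 2·SD of the blood pool. The SUVpeak field is computed by FFT
   convolution of the volume and of an all-ones grid with the sphere
   kernel; their ratio is exactly the clipped-sphere mean.
3. **Contouring.** The connected component above 42 % of the local
   SUVmax. "Local" is resolved by a fixed point: grow at 42 % of the seed
   value, take the maximum over the grown component, re-grow at 42 % of
   that maximum, repeat until stable. The emitted region therefore always
   has a threshold equal to 42 % of its own maximum, independent of which
   interior focus seeded it. If the iteration discovers a hotter maximum
   whose threshold excludes the original seed (a cool local max attached
   to a hot ridge), the component is re-seeded at the running maximum
   rather than aborting; this guarantees termination (the running maximum
   is non-decreasing and bounded) and a region containing its own max.
4. **Filtering and emission.** Components are taken in descending SUVmax
   order; a component overlapping an already-claimed voxel is dropped
   (this subsumes deduplication of identical components grown from
   several seeds inside one lesion, and enforces voxel-disjoint output).
   Components strictly smaller than 0.5 cc are excluded; exactly 0.5 cc
   is retained. IDs are consecutive in descending SUVmax.

The malignancy classifier that commercial systems stack on top of this
front-end is a proprietary trained network and is deliberately out of
scope; segmenter output carries no probability score (the pipeline
assigns 1.0, i.e. "always suspicious", when the segmenter route is used).
Thresholds are applied to raw SUV, not background-subtracted SUV.

For an isolated Gaussian blob of width σ on zero background, the 42 %
isocontour has radius σ·√(−2 ln 0.42) ≈ 1.317 σ, giving a closed-form
volume the segmenter must recover as voxels shrink; this is the primary
geometric validation (within 15 % at 2 mm voxels for σ = 6 mm, within 5 %
at 1 mm).

## Merge-based correspondence

Automated readers fragment lesions and merge adjacent ones, so counts are
compared only after reduction to a one-to-one correspondence:

- any set of ≥ 2 model lesions whose only overlap partner is one common
  expert lesion is merged into a single model lesion, and symmetrically
  for expert lesions; the rule is iterated to a fixed point (it strictly
  decreases lesion counts, so termination is guaranteed);
- merged lesions take the voxel union (label of the largest-volume
  constituent survives; ties to the smaller ID), summed volume, and the
  max of SUVmax, SUVpeak and score — a merged focus is suspicious if any
  fragment was;
- residual many-to-many overlaps are resolved by greedy one-to-one
  assignment in descending shared-voxel order, ties by smaller
  (expert ID, model ID); a pair needs ≥ 1 shared voxel (configurable).

Merging only relabels: total lesion voxels per side are conserved. The
procedure is idempotent, and the merge log records every coalescence for
audit. Greedy assignment is deterministic and, by construction, never
improvable by swapping one matched partner for an unmatched alternative;
it is not guaranteed to maximise total overlap over all assignments in
pathological many-to-many webs (the test suite checks optimality
exhaustively wherever the graph permits).

Classification at score threshold t: model lesions with score < t are
"benign" and dropped (their partners revert to FN); paired survivors are
TP, unpaired survivors FP, unpartnered expert lesions FN. Benign lesions
*do* participate in merging — only classification removes them — so one
correspondence serves an entire threshold sweep. TP and FN are sited by
the expert lesion, FP by the model lesion.

## Agreement metrics

For paired values (per patient or per matched lesion), differences are
d = model − expert: median difference, MAD = median |d|,
MRPD = median (100·d/expert), MARPD = median (100·|d|/expert). Relative
metrics require nonzero expert values and are omitted otherwise. Lesion
*size* agreement uses only matched (TP) pairs at the working threshold;
lesion *count* and *tumor burden* are per patient, with the model burden
including false-positive volumes — an automated burden readout cannot
exclude what it believes to be lesions, and this convention is what
reconciles cohort-level overestimation with per-patient underestimation.

ICC(3,1) is the two-way mixed-effects, single-rater, *consistency*
intraclass correlation (Shrout–Fleiss): with subject mean square MS_R and
residual MS_E from the subject × rater decomposition and k = 2 raters,
ICC = (MS_R − MS_E)/(MS_R + (k−1)·MS_E). The computation is delegated to
`pingouin.intraclass_corr`; the 95 % CI is the standard F-based interval
recomputed unrounded from the reported F statistic and degrees of
freedom. ICC is undefined (returned as absent, with a warning) when both
raters are constant; values are clipped to ≤ 1 against floating-point
overshoot. Consistency ICC is invariant under adding a constant to one
rater and under common rescaling — both are tested exactly.

## Synthetic phantoms and the simulated reader

The generator emulates the statistical structure of a metastatic-melanoma
staging cohort, not PET physics:

- **Phantom.** Box-shaped organ compartments with Gaussian SUV texture
  (lung 0.4, lymph-node stations 0.9, bone 1.0, liver 1.6, background
  0.8), a cylindrical blood pool (mean 1.8, SD 0.15), and hard spherical
  lesions painted at their nominal SUVmax. The whole field is convolved
  with an isotropic Gaussian PSF (default σ = 3 mm) and additive Gaussian
  noise (SD 0.02) is applied, clipped at zero. The expert reference label
  map is the *pre-blur* insert — mimicking CT-refined expert contours —
  while the segmenter sees the blurred volume, mimicking PET-threshold
  contours. Organ uptake is deliberately kept below the blood-pool
  detection band: this front-end has no organ-exclusion logic, so a liver
  at clinical uptake (~2.2) would be segmented wholesale as one giant
  false positive; physiological false positives are instead modelled in
  the reader. Overlapping lesion inserts are rejected to keep truth
  unambiguous.
- **Cohort sampling.** 30 patients by default; lesion counts 1 + negative
  binomial (median ≈ 3, long tail), sites drawn with probabilities
  0.330/0.185/0.128/0.121/0.236 (lymph node/lung/liver/bone/other), radii
  log-normal (median 9 mm, clipped 5–20 mm), SUVmax uniform 4–12, placed
  inside the site's compartment by rejection sampling.
- **Reader.** Per-site detection probabilities (default 0.71/0.58/0.82/
  0.75/0.65 — illustrative of reported per-site recall orderings, not
  fitted), fragmentation (split along the longest axis into contiguous,
  hence connected, pieces), boundary jitter by random dilation/erosion,
  Poisson false-positive candidates (default 43 per patient, matching the
  scale of raw model segmentations per patient in such cohorts) with
  log-normal volumes (median 0.7 cc), and malignancy scores Beta(8,2) for
  detected true lesions vs Beta(2,8) for false positives — so most false
  positives score benign and only the upper tail survives the 0.5
  threshold.

Everything is a pure function of (spec, seed). Closed-form expectations
(Beta tails × detection probability for recall; expected TP/FP ratio for
precision) provide the oracle for parameter recovery: a 30-patient,
1000-lesion score-level cohort reproduces the analytic PR curve within
binomial/Poisson sampling bands, and recall at the 0.5 threshold within
±3 points. For these score-level studies lesions are represented as
single voxels on a coarse grid — degenerate geometry that still exercises
the real correspondence and classification code paths at cohort scale.

**What passing these tests does not show:** the phantom has no scatter,
attenuation, reconstruction noise texture, respiratory motion, organ
boundaries with partial-volume mixtures, or realistic lesion shapes; the
reader's errors are statistically independent across lesions, unlike a
real network's spatially correlated failures. Results on synthetic
cohorts validate the *evaluation machinery*, not any clinical claim about
a particular segmentation model.

## Numerical and design choices

- Sample (n−1) SD for the blood pool; the conventional estimator.
- 26-connectivity default for maxima and components; most permissive
  standard choice, configurable (6/18/26).
- Volume filter reads "smaller than 0.5 cc excluded" literally: < 0.5 cc
  dropped, exactly 0.5 cc kept.
- Local-maximum test uses ≥ (plateaus yield several candidate foci; the
  fixed-point contouring then emits one merged component, deduplicated).
- Median of an even-length sample is the mean of the central order
  statistics (numpy convention).
- Undefined ratios (precision with TP+FP = 0, relative differences with a
  zero reference) are reported as absent, never as zero.
- Problem sizes in tests and the acceptance script (48³–97³ grids,
  cohorts of 4–30 patients, 1000-lesion score-level studies) were chosen
  to exercise every code path at desk scale; all thresholds and
  tolerances are stated next to the checks they belong to.

## Known limitations

- The greedy many-to-many resolution is locally, not globally, optimal;
  an optimal-assignment variant (Hungarian on the overlap matrix) would
  be a drop-in extension.
- The segmenter's fixed-point contour can absorb two physically distinct
  but bridged lesions into one component; the correspondence stage
  compensates at evaluation time, but the segmenter itself has no
  watershed-style separation.
- Site assignment of merged lesions follows the largest constituent
  rather than a re-vote over voxels.
- PR sweeps reuse a single correspondence computed before score
  thresholding rather than re-matching per threshold.
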