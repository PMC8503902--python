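# Methods

## The problem and the model

Paramagnetic rim lesions (PRLs) are chronic active multiple-sclerosis
lesions whose iron-laden phagocyte border appears on a T2*-phase image as a
hypointense rim around the lesion periphery, while the interior stays iso-
or hyperintense. `aprl` treats PRL identification as a two-stage problem:
first turn a voxel-wise lesion probability map into distinct lesion
instances, then classify each instance from the first-order statistics of
its phase intensities.

The package consumes *preprocessed* data: a phase volume that has already
been unwrapped, bias-corrected and intensity-normalized (so intensities are
unitless and roughly zero-centred in normal-appearing tissue), and a
probability map from any lesion segmenter, on the same isometric grid. No
assumption is made about the numeric range of the normalized phase.

## Lesion instance labelling

Stage order, each step on the same grid:

1. **Threshold selection.** The probability map is binarized at every value
   of a user grid (default 0.05…0.95, step 0.05) and the threshold with the
   best Sørensen-Dice overlap against the gold-standard lesion mask is
   kept; ties go to the smallest threshold. The gold mask is used *only*
   here; a fixed threshold bypasses it for unsupervised runs.
2. **Dilation.** One voxel in every direction (3×3×3 box, i.e.
   26-connectivity) — rims live at the lesion boundary, and segmentation
   masks tend to under-cover it.
3. **Tissue exclusion.** CSF and gray-matter masks are removed from the
   *newly added* ring only; original lesion voxels are never removed. This
   guards against ventricular and cortical phase hypointensities leaking
   into lesion samples.
4. **Centre detection.** The probability map is smoothed with a Gaussian
   (σ = 1 voxel by default); a voxel is locally peak-like when its 3×3
   central-difference Hessian has three strictly negative eigenvalues.
   26-connected components of peak-like voxels inside the mask become
   centres, numbered by the lexicographic order of their minimum voxel
   index. If nothing qualifies (e.g. a monotone field), the voxel with the
   maximal smoothed probability is the single centre.
5. **Nearest-neighbour assignment.** Every mask voxel joins the centre
   component with the nearest *member voxel* (Euclidean, voxel units — on
   an isometric grid this equals mm distance up to a constant); exact ties
   go to the smaller label. The label support equals the mask exactly.
6. **Confluence.** Connected components of the mask that contain ≥2 labels
   mark all their labels confluent — the situation where a human rater
   would call one connected blob a cluster of several lesions.
7. **Rim status.** A lesion is rim-positive iff it overlaps the manual
   annotation by at least one voxel. Annotations are line marks (one axial
   line through the lesion centre), not full masks, so the any-overlap rule
   matters.

Connectivity is 26 throughout (consistent with the box dilation); a
6-connectivity switch exists. Whether dilation precedes instance detection
follows the stage order above by construction.

## First-order features

Exactly 44 statistics per lesion over its post-dilation, post-exclusion
voxel sample, in three families: location (mean, median, mode, percentiles,
trimmed/winsorized means, midhinge, trimean …), spread and shape (variance,
SD, IQR = |p75−p25|, mean/median absolute deviations, robust MAD over the
p10–p90 sub-sample, skewness, kurtosis, quartile skew …) and
magnitude/diversity (energy Σxᵢ², total energy = energy × voxel volume,
RMS, uniformity Σp(v)², entropy −Σp(v)log₂p(v)).

Conventions, fixed package-wide:

* **No binning.** p(v) is the empirical relative frequency of the *exact*
  value v in the lesion. On continuous data every value is distinct, so
  entropy = log₂ n and uniformity = 1/n exactly — both become monotone
  functions of lesion size. This is a deliberate property of the unbinned
  definition, not an accident, and it is why these features act as size
  proxies; real scanner data with quantized intensities behaves less
  degenerately. A binning option exists for sensitivity analyses and is
  off by default.
* **Population moments** (1/n), sd = √variance; skew and kurtosis of a
  constant sample are defined as 0; kurtosis is excess (Gaussian → 0).
* Percentiles interpolate linearly between order statistics.
* Ratio features guard their denominators (coefficient of variation is 0
  when the mean is 0, quartile skew 0 when the IQR is 0).
* The intensity sample is sorted before any reduction, which makes every
  feature exactly independent of voxel ordering (bitwise, not just to
  tolerance).
* `total_energy` is an exact scalar multiple of `energy` whenever voxel
  size is constant across a study. Both stay in the roster (both are
  standard catalogue members), with the consequence that permutation
  importance — which cannot distinguish exact duplicates — splits or
  cancels their credit; see below.

## Classification

* **Split by subject** (default 16 train / 4 test), redrawn until both
  sides hold ≥100 lesions; no subject contributes to both sides, in the
  main split and in every resampling iteration.
* **SMOTE.** Synthetic rim-positive rows are built by interpolating a
  minority row toward one of its k = 5 nearest minority neighbours
  (u ~ U(0,1)); the majority class passes through unchanged. The
  oversampling factor defaults to the reciprocal of the minority
  prevalence (≈ 8.3 at 12%), so classes end roughly balanced. Inside
  cross-validation, SMOTE runs on each fold's training part only —
  synthetic rows never appear in fold validation.
* **Random forest**, 500 trees; the number of candidate features per split
  is tuned over {√p, p/3, p/2} by stratified 10-fold CV on held-out-fold
  AUC; all other settings at library defaults, recorded in the run log.
* **Operating point.** Youden's J = sensitivity + specificity − 1,
  evaluated at every distinct score with the rule *positive iff
  score ≥ t*; ties toward the smallest threshold. AUC is the rank
  statistic (ties count ½). The eight derived measures (accuracy, PPV,
  NPV, FPR, FNR, sensitivity, specificity + AUC) always reproduce from the
  confusion counts; 0/0 ratios are reported as NaN.
* **Confluent-lesion subset.** The non-confluent subset is re-evaluated
  with its *own* Youden threshold, since confluence changes the score
  distribution.
* **Empirical CIs.** The split→SMOTE→train→Youden→evaluate chain is
  repeated (default 1000 resplits; any smaller n works for desk-scale
  studies) with per-iteration seeds derived from the master seed by a
  counter, and 2.5/97.5 percentiles are reported per measure.
* **Permutation importance.** Per feature: permute the column, recompute
  the MSE of predicted rim probability against the 0/1 label, report the
  percent increase over the unpermuted baseline (mean over ≥3 permutation
  repeats; the scaled variant divides by the repeat-level SD). The
  baseline MSE is floored at 1e-12 so a perfectly predicting model yields
  finite values.

## The phantom

Each synthetic subject emulates the statistical structure the pipeline
assumes: i.i.d. N(0, σ²) background phase (σ = 1, standing in for
normalized normal-appearing tissue), ellipsoidal lesions with random
orientation and per-axis radii 2–4 voxels, interiors shifted by a uniform
non-negative offset (iso/hyperintense), and — on rim-positive lesions — an
ellipsoidal shell of thickness 1.5 voxels shifted by the rim contrast
(default −2σ). Rim lesions draw radii scaled by 1.25, reflecting that PRLs
tend to be larger than rim-negative lesions. The probability map is the
truth mask blurred with a Gaussian (σ = 1 voxel) and clipped to [0,1]; the
manual annotation is a 1-voxel line on the single axial slice through each
rim lesion's centre, along its longest in-plane axis, clipped to the lesion
support. CSF/GM slabs are placed flush against every third lesion so the
exclusion step has work to do. A fraction of lesions (default 10%) is
placed touching a partner — touching along the pair's long axes, because
instance labelling can only resolve a pair whose probability peaks are
several voxels apart — with at most one rim lesion per pair. Cohorts draw
per-subject lesion counts uniformly within ±30% of the nominal count and
give every subject a derived seed, so the cohort and any single subject
are independently reproducible.

Defaults are chosen as the study conditions the pipeline targets: 20
subjects, ~50 lesions/subject, 12% rim prevalence, 0.65 mm isometric
voxels on a 96³ grid.

**What the phantom does not emulate** — and hence what passing tests do
not show about real data: veins and the central-vein sign, phase wrapping
or filtering residues, partial or broken rims (the shell is complete),
intensity quantization (values are continuous, so the diversity features
collapse to size functions), anatomy (white/gray matter geometry is
reduced to slabs), and scanner noise correlations. The phantom's rim
signal is *strong and volumetric*: the −2σ shell covers most of a small
lesion's voxels, so spread-type features separate the classes essentially
perfectly, and cohort-scale AUCs near 1.0 should be read as "the plumbing
recovers a strong planted signal", not as a claim about clinical
performance. For the same reason the forest's importance ranking on
phantom data favours deviation features (robust MAD, mean absolute
deviation, decile range, …) over the diversity features (uniformity,
entropy, energy): on unbinned continuous intensities the latter are
near-deterministic size transforms and are mutually redundant (and energy
is exactly duplicated by total energy), so permutation importance
attributes the shared signal elsewhere. On real, quantized, subtle-rim
data the balance shifts toward the diversity features.

## Numerical and design choices

* Geometry is done in 0-based voxel coordinates; isometric voxels make
  voxel-space distances proportional to mm.
* NIfTI-1 I/O, one 3D volume per file: masks uint8, label maps uint16,
  intensities float32. Anisotropy beyond 1% warns and proceeds with the
  mean voxel edge.
* Label renumbering, threshold ties, nearest-neighbour ties and Youden
  ties all break deterministically (documented above), so identical
  configuration and seed reproduce every artifact bitwise; the pipeline
  manifest records SHA-256 hashes of all tabular outputs.
* Placement uses bounded rejection sampling (500 tries per lesion, 200 per
  confluent partner) and raises naming the offending lesion if the grid is
  too crowded.
* Empty masks, single-class splits, zero-variance counts and empty
  threshold grids raise informative errors rather than degenerate results.

## Problem sizes

The shipped tests run the full chain at desk scale: unit fixtures on 48³
and 64³ grids with 8–30 lesions, one cohort-scale check at the full study
conditions (20 subjects × ~50 lesions), and resampling CIs at 50 resplits
with reduced forests (60–80 trees, single-point tuning grid). The method
defaults in the library remain 500 trees, 10 folds, the 3-point tuning
grid and 1000 resplits.

## Known limitations

* The 44-feature roster is a documented convention; other first-order
  catalogues differ in the tail of the list.
* Confluent pairs placed with deep overlap or small radii can merge into a
  single instance (one centre) — mirroring the real failure mode where
  confluent clusters are under-segmented; such merges reduce the count
  correlation and are visible in the truth table.
* The rim annotation transfer uses any-overlap: a line that grazes two
  labels marks both rim-positive.
* No infratentorial handling, no gadolinium-enhancement logic, no
  second-order (textural) features.
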