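# aprl

Automated detection of **paramagnetic rim lesions (PRLs)** in multiple
sclerosis from T2*-phase MRI.

Chronic active MS lesions carry iron-laden phagocytes at their edge, which
appear on a susceptibility-sensitive phase image as a hypointense rim around
the lesion periphery. Identifying these rims by eye is slow and
rater-dependent. `aprl` automates the whole chain for researchers working
with preprocessed (bias-corrected, registered, intensity-normalized) phase
volumes and voxel-wise lesion probability maps from any segmenter:

1. **Lesion instance labelling** — the probability map is binarized at the
   Dice-optimal threshold against a gold-standard lesion mask, dilated by
   one voxel (26-connectivity box) to capture the rim signal at the lesion
   boundary, cleaned of CSF/gray-matter voxels introduced by the dilation,
   and split into distinct lesion instances: centres are detected where the
   Gaussian-smoothed probability field has a negative-definite Hessian, and
   remaining voxels join their nearest centre. Touching instances are
   flagged as *confluent*; rim status comes from any overlap with a manual
   line annotation.
2. **First-order radiomics** — 44 intensity statistics per lesion
   (mean, variance, skew, energy = Σxᵢ², uniformity = Σp(xᵢ)²,
   entropy = −Σp(xᵢ)log₂p(xᵢ), percentiles, robust spreads, …), with p(xᵢ)
   the empirical relative frequency of each *exact* intensity value — no
   histogram binning. Population (1/n) moments throughout.
3. **Classification** — subject-level train/test split (16/4 by default,
   ≥100 lesions per side), SMOTE oversampling of the rim-positive minority
   by the reciprocal of its prevalence, a 500-tree random forest tuned by
   10-fold CV, a Youden-J operating point (max sensitivity+specificity−1),
   AUC plus eight confusion-table measures, empirical CIs over resampled
   splits, and permutation variable importance.

A seedable **phantom** module generates complete synthetic subjects (phase
volume, gold mask, probability map, CSF/GM masks, rim line annotations,
truth table), so the entire pipeline runs and is tested without patient
data.

## Worked example

```python
from aprl import PhantomSpec, generate_case, label_lesions, extract_feature_table

spec = PhantomSpec(seed=7)                      # 50 lesions, 12% rims, 96³ @ 0.65 mm
case = generate_case(spec, subject_id="sub-001")
labels, records = label_lesions(case.prob_map, case.gold_mask, case.csf_mask,
                                case.gm_mask, case.prl_annotation,
                                subject_id="sub-001")
table = extract_feature_table(case.phase, labels, records, include_size=True)
print(f"{len(records)} lesions labelled, "
      f"{sum(r.is_prl_truth for r in records)} rim-positive, "
      f"{sum(r.is_confluent for r in records)} confluent")
print(table.groupby("is_prl_truth")[["energy", "uniformity", "entropy",
                                     "size_vox"]].mean().round(4))
```

prints

```
49 lesions labelled, 6 rim-positive, 2 confluent
                 energy  uniformity  entropy  size_vox
is_prl_truth
False          325.7381      0.0033   8.2679  317.8140
True          1228.2441      0.0020   9.0434  557.8333
```

Of 50 generated lesions, one touching pair was merged by instance
labelling (49 records, the resolved pair flagged confluent). Rim lesions
show the expected signature: much higher energy (their hypointense shell
contributes large squared intensities) and lower uniformity (more voxels →
each exact intensity value is rarer). On unbinned continuous intensities
entropy equals log₂(lesion size), so it tracks lesion size directly.

The same stages are available from the shell:

```bash
aprl phantom --config spec.yaml --out cohort/ --seed 1 --subjects 20
aprl label --prob prob.nii.gz --gold gold.nii.gz --csf csf.nii.gz \
     --gm gm.nii.gz --annot rim_lines.nii.gz \
     --out labels.nii.gz --records records.csv
aprl features --phase phase.nii.gz --labels labels.nii.gz \
     --records records.csv --out features.csv --include-size
aprl train --features features.csv --out model/ --seed 1
aprl evaluate --model model/ --features features.csv --out report.json
aprl ci --features features.csv --iters 1000 --out ci.json
aprl run --config run.yaml            # everything end to end
```

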