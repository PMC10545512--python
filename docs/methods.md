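# Methods

This note documents the models, rules and numerical choices behind
`cineqc`, and what the synthetic phantom does and does not establish about
behaviour on clinical data.

## Data model

A study is a set of per-phase 3D integer label stacks (slice, row, col) in
a fixed vocabulary — background 0, LV blood pool (LVBP) 1, LV myocardium
(MYO) 2, RV blood pool (RVBP) 3, with papillary muscle (PAP) 4 appearing
only as a refinement output — plus optional co-registered intensity
volumes and study metadata. Slice 0 is the most basal slice; sidecars
declaring apex-first order are flipped on load, and permuted label
encodings are remapped to the canonical one. Unknown voxel values are
errors, never coerced. Voxel volume is `row_spacing × col_spacing ×
slice_spacing`, i.e. the slice spacing is the center-to-center distance
(thickness + gap); volumes are Simpson-style sums over slices with no
partial-volume weighting, which keeps the analytic phantom an exact oracle
for the voxel-count estimator. DICOM ingestion and long-axis views are out
of scope; the canonical on-disk form is NIfTI-1 + JSON sidecar + CSV
manifests.

## Biomarkers

EDV and ESV are blood-pool volumes at each ventricle's ED/ES phases
(metadata-declared phases win; otherwise ED = phase of maximal, ES = phase
of minimal nonzero blood-pool volume — the two ventricles may use
different frames). SV = EDV − ESV, EF = 100·SV/EDV (missing when
EDV = 0). LV mass is the myocardial volume at the LV ED phase times a
tissue density of 1.05 g/mL (field-standard constant, configurable); mass
is computed at ED only because myocardium is frequently unannotated at ES.

## Screening rules

All thresholds live in `ScreeningConfig`. In-plane checks use 8-neighbour
connectivity per slice (SAX stacks are thick and anisotropic, and contours
are drawn per slice); only the heart-component check is 3D, adding face
adjacency between adjacent slices.

* **frame_completeness** (exclude): ED or ES stack missing or entirely
  empty.
* **coverage_extent / coverage_apex** (flag): segmented LV length (LVBP
  slice count × slice spacing) below 40 mm; or LVBP area on the most
  apical segmented slice above 0.5 × the maximal slice area (a truncated
  apex ends on a large cross-section, a complete one tapers to a point).
* **gap** (flag): per label, any slice with zero voxels strictly between
  two slices containing it.
* **myo_ring_breach / lvbp_rvbp_contact** (flag): on any slice containing
  LVBP, an 8-connected in-plane path of non-MYO voxels from the blood pool
  to the image border (broken *or absent* ring — running the check on
  LVBP-bearing slices rather than only slices containing both LVBP and MYO
  is deliberate, so a stack whose myocardium was never annotated is
  caught); and direct 8-adjacency of LVBP and RVBP (zero-thickness
  septum).
* **external_component** (flag + correction): per phase, the largest 3D
  foreground component is the heart (ties broken toward the
  lexicographically smallest minimum index, for determinism); every other
  component is planned for deletion. Components of more than
  `min_component_voxels` (default 2) voxels are flagged; smaller ones are
  silent noise. This is the only auto-correction: QC deletes exactly the
  planned voxels and nothing else.
* **volume_range** (flag): biomarkers outside configurable plausibility
  intervals (defaults: LVEDV/RVEDV 20–800 mL, LVESV/RVESV 10–700 mL, LVM
  20–500 g — deliberately generous screens for gross errors, not
  normality ranges).
* **sv_discordance** (flag only, never corrected): |LVSV − RVSV| over the
  mean of the two exceeds 0.25. The mean denominator keeps the rule
  symmetric in the two ventricles. Non-positive stroke volumes are flagged
  as implausible rather than tested.
* **duplicate** (flag): identical non-empty voxel arrays anywhere in the
  cohort (within and across studies), found by content digest then exact
  comparison. Empty stacks are completeness failures, not duplicates.

`run_qa_gt` (ground truth) runs completeness, coverage, gaps, anatomy
relations, external components *without* applying corrections, biomarker
checks and duplicates; studies with an exclude entry form the exclusion
list, all other flagged studies are review candidates. `run_qc_post`
(model outputs) runs gaps, anatomy, external components (optionally
applying the deletion plan and re-checking biomarkers on the corrected
study), volume plausibility and SV discordance. Reports are sorted by
(rule, phase, location) and bit-reproducible.

## Papillary exclusion

Per ventricle and per phase (histograms are not pooled across regions,
since coil shading varies), a 256-bin histogram of the intensities inside
the blood-pool mask is thresholded by Otsu's criterion: the interior bin
edge maximizing the between-class variance ω₀ω₁(μ₀ − μ₁)², ties broken
toward the lowest threshold. Voxels darker than the threshold (muscle, on
bright-blood bSSFP; polarity configurable) are reassigned to a dedicated
PAP label by default — so downstream consumers decide whether they count
toward mass; exclusion protocols typically remove them from blood without
adding them to LVM — with MYO or background as alternatives. Dark islands
of ≤ 2 voxels are kept as blood (noise). Two guards make the step safe on
masks that contain no muscle: a single-bin histogram is a degenerate no-op
with a warning rather than an error, and the split is applied only when
the two Otsu classes show a relative contrast of at least 0.2 (Otsu always
*finds* a threshold, even in a unimodal noise-only histogram, where
applying it would carve away half the blood pool; genuine blood–muscle
contrast on bSSFP is far larger than noise, so the guard costs no
sensitivity). The refinement never adds
blood voxels and conserves voxel counts exactly between removed and
reassigned sets.

## Marginalized partial-label loss

For a frame annotated under a protocol lacking some classes, the predicted
probability of each absent class is folded into background
(q_bg = p_bg + Σ_absent p_c) and the composite loss
`ce_weight·CE′ + dice_weight·(1 − meanDice′)` is evaluated over the present
classes: CE′ is the mean cross-entropy of the folded distribution
(log-floored at 1e-12 to stay finite), Dice′ the soft Dice
`(2Σpg + ε)/(Σp + Σg + ε)` with ε = 1e-5, averaged over present
non-background classes. Marginalization was chosen over voxel masking
because it preserves normalization and makes two contracts exact: the loss
is invariant to any per-voxel transfer of mass between an absent class and
background, and reduces identically to the standard composite loss when
all classes are present.

## Validation statistics

Dice is reported in % and is *missing* when a label is empty in both
stacks (both-empty = 100 would inflate scores for absent classes such as
MYO at ES); per-phase values are pooled before taking medians. Bland–
Altman: bias = mean(auto − manual), limits = bias ± 1.96 × sample SD;
Pearson r is missing on constant input. IQR is p75 − p25 with linear
interpolation. Group comparisons use two-sided Mann–Whitney U (between
groups) or Wilcoxon signed-rank against zero (paired; all-zero differences
give p = 1), with significance tiers p < α/n_tests for α ∈ {0.01, 0.001,
0.0001} following the starred-threshold convention. Strata with fewer than
3 studies are reported as insufficient rather than dropped.

## Synthetic phantom

The phantom voxelizes solids of revolution by the voxel-center rule (a
voxel belongs to a structure iff its center lies inside the continuous
solid), so closed-form volumes are unbiased oracles:

* LV blood pool: half-ellipsoid, radius profile r(z) = r·√(1 − (z/L)²),
  volume (2/3)πr²L;
* myocardium: closed annulus of constant wall thickness w on every LV
  slice, volume π(2w·r·πL/4 + w²L);
* RV blood pool: annular sector of thickness t and angle θ sharing its
  inner border with the epicardium (so adjacency rules see a realistic
  septum), volume 0.5θ(2t·∫r_epi dz + t²L_rv);
* papillary muscles: spheres inside a blood pool, *labelled* blood
  (inclusion protocol) but *drawn* at myocardial intensity.

Intensities are per-tissue means (blood 300, myocardium 100, background
60, arbitrary units) plus seeded Gaussian noise (SD 5), i.e. a 40-SD
blood–muscle gap at the defaults — bright-blood bSSFP contrast with the
Otsu separability controlled explicitly. The same seed reproduces a study
bit-for-bit.

The random-cohort generator samples a healthy-to-mildly-dilated adult
population: LV basal radius 24–29 mm, LV extent 80–95 mm, EF 50–65 %, wall
7–9 mm with 2–4 mm systolic thickening, RVEDV 85–105 % of LVEDV, RVSV
within ±8 % of LVSV (the crescent thickness is solved from the target
volume in closed form). These ranges were fixed once as the package's
study conditions. Default grids are 96 × 96 × 12 at 1.4 × 1.4 × 8 mm for
screening tests and 120 × 120 × 50 at 1 × 1 × 2 mm for volumetry
validation — the finer grid matches clinical in-plane resolution while
keeping a 20-phantom validation run under a minute on one CPU.

The defect injector produces a minimal modification per error class:
removed phases, dropped basal/apical slices, interior-slice gaps, stray
components disjoint from the heart, angular holes in the myocardial wall,
absent myocardium at ES, duplicated stacks, implausible voxel geometry
(spacing scaling — volumes scale with the cube of the factor, emulating
corrupt geometry metadata), and RV-ES dilation that forces stroke-volume
discordance (the ES blood pool is grown rather than shrunk because
shrinking a small ESV cannot always move the SV ratio past 25 %, while
growing it provably can).

**What the phantom does not emulate** — and hence what passing tests do
not show about clinical data: trabeculation and partial-volume effects at
contour boundaries, through-plane motion and breath-hold misregistration,
basal-slice valve-plane ambiguity (the leading real-world ground-truth
error), coil-shading intensity gradients, arrhythmia, and congenital
topologies. Screening sensitivity/specificity of 100 %/0 flags on phantoms
bounds rule correctness, not clinical flag rates.

## Numerical and design notes

* Voxel-center voxelization makes volumetry convergence testable: the
  analytic-vs-voxel error decreases as the in-plane spacing is halved
  (verified at 2, 1, 0.5 mm).
* The component tie-break (smallest minimum index) and report sorting
  exist purely for determinism; all outputs, including pipeline CSV/JSON,
  are byte-identical across re-runs, and the run log deliberately records
  a config hash and no timestamps.
* QA never modifies ground truth; QC corrects only external components.
  A correction is applied as a planned voxel set, and a voxel-diff
  invariant guarantees nothing outside the plan changes; a second QC pass
  after correction plans nothing (idempotence).
* The external-command segmentation backend defines the integration
  contract (`exe image.nii.gz labels.nii.gz` per phase, canonical label
  vocabulary); network training/inference itself is out of scope, and the
  passthrough backend stands in for it wherever the pipeline is exercised.
* The view-identification step of a full clinical chain is represented
  only by the manifest's optional `series_type == SAX` filter.

## Known limitations

* Volumetry has no basal-slice inclusion rule (no valve-plane tracking);
  volumes are pure voxel sums over whatever was segmented.
* Otsu separation assumes a bimodal in-mask histogram; low blood–muscle
  contrast or strong shading can defeat it (the degenerate case is a
  reported no-op, not a failure).
* Plausibility ranges and coverage thresholds are screening defaults, not
  clinically validated reference intervals; sites should configure them.
* The loss is a NumPy reference implementation — differentiable ports to
  a training framework must reproduce its folding semantics.
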