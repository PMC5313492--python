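# Methods

## The index

The skeletal tumor-burden index treats focal NaF uptake as a volume
fraction of the skeleton. Given a body-weight-normalized SUV volume and a
binary mask of the segmented axial bones (thoracic/lumbar spine, sacrum,
pelvis, ribs, scapulae, clavicles, sternum — in clinical use produced by a
dedicated segmentation; here either supplied by the user or approximated
by a rule-based CT threshold), the pipeline is

1. **Smoothing.** Gaussian filter with standard deviation σ = 2 mm in
   physical space (per-axis voxel sigma = σ / spacing), kernel truncated
   at 4σ, reflecting boundaries. Smoothing suppresses single-voxel noise
   excursions that would otherwise fragment into an unmanageable number
   of hotspots. It is applied in both operating modes before
   thresholding.
2. **Hotspot detection.** Voxels with smoothed SUV strictly above the
   threshold are grouped into 26-connected components. The automated mode
   fixes the threshold at SUV 15; the manual mode takes a per-patient
   threshold (plausibility range 4–12, warning outside) chosen so that
   all visually malignant lesions are delineated. Components are numbered
   in raster order of their first voxel, which makes hotspot ids stable
   across runs and usable as keys in manual-label files.
3. **Skeletal restriction.** The bone mask is brought onto the PET grid
   by nearest-neighbor resampling (hotspots are PET objects, so volumes
   are measured on the PET grid; the index denominator is the bone volume
   on the mask's native grid). Hotspots with no mask overlap are removed.
   A hotspot with *any* overlap keeps its full volume by default — the
   removal rule concerns only zero-overlap components, and lesion uptake
   frequently bulges past cortical bone — but an `intersection` mode that
   counts only in-bone voxels is available.
4. **Classification (manual mode).** Each hotspot is labeled metastasis
   or benign; benign hotspots (degeneration, inflammation, fractures) are
   excluded. Unlabeled hotspots count as metastasis with a warning, so a
   labels file need only list exclusions; a strict mode requires complete
   labels. The automated mode includes every surviving hotspot.
5. **Index.** `index% = 100 · f · Σ vᵢ / V_bone` with skeletal fraction
   f = 0.33 by default, the approximate share of total skeletal volume
   covered by the segmented bones. The index is reported in percent; a
   lesion load equal to the whole segmented skeleton reads 33%.

Degenerate inputs: an empty bone mask is a hard error (the index is a
ratio); an entirely supra-threshold SUV volume yields a single hotspot
spanning the volume, with a warning.

### Numerical conventions

* Thresholding is strict (`> threshold`), switchable to `≥`.
* Nearest-neighbor resampling rounds the fractional source index with
  round-half-up per axis; target voxels whose nearest source center lies
  outside the source lattice are 0. Grids are axis-aligned
  (spacing + origin); rotated affines are rejected at I/O.
* Voxel-center membership defines all digitizations (sphere/ellipsoid/
  tube rasterization, masks), consistently between the pipeline, the
  phantom generator and the test oracles.
* Volumes are voxel counts × voxel volume; no partial-volume weighting.

## Phantoms

`PhantomSpec` describes a synthetic scene: bone primitives (ellipsoids
and finite cylinders), spherical plateau lesions, soft-tissue background
SUV 1.0, skeletal background SUV 4.0 (mild diffuse uptake, safely below
the automated threshold), optional seeded Gaussian noise (clipped at
zero). Lesions are hard plateaus rather than Gaussian blobs so the
supra-threshold set is exactly the digitized sphere and the expected
index has a closed form; smoothing behavior is validated separately
against a brute-force convolution oracle. The PET and CT grids may differ
(CT finer by default) to exercise resampling.

Ground truth is recomputable from the spec alone: analytic primitive
volumes, voxel-counted (digitized) volumes, a center-in-bone flag per
lesion, and the expected index in both analytic and digitized form. A
lesion extending beyond the lattice switches its truth to the voxel count
with a warning. Bone primitives are assumed non-overlapping when summing
analytic volumes.

What the phantom does **not** emulate: scanner point-spread functions,
scatter/attenuation, pharmacokinetic heterogeneity inside lesions,
irregular bone shapes, or correlated noise. Passing phantom tests
therefore demonstrates geometric and arithmetic correctness of the
pipeline, not clinical segmentation accuracy on real scans.

## Survival statistics

Cohorts are data frames (patient id, biomarker columns, observed time in
years, event indicator). Conventions:

* **Horizon censoring.** Follow-up beyond the horizon (default 5 years)
  becomes (horizon, censored); a time exactly at the horizon keeps its
  event status.
* **Median split.** Median = midpoint of the two central order
  statistics; the high group is *strictly above* the median, ties go
  low. Missing biomarkers are excluded and counted.
* **Kaplan-Meier / log-rank / Cox.** Product-limit estimation, the
  two-group log-rank test and Efron-tie Cox partial-likelihood fits are
  delegated to lifelines; the KM median is the earliest time with
  S(t) ≤ 0.5 and is reported as "not reached" (an infinite sentinel)
  otherwise. Events precede censorings tied at the same time. The Cox
  result additionally carries a score test at β = 0 computed in-package
  (Efron adjustment); for a binary covariate without tied event times it
  coincides with the log-rank chi-square, which the tests verify to
  1e-6. With heavily tied event times the hypergeometric log-rank
  variance and the Efron score information differ slightly; the
  equivalence is claimed (and tested) only for continuous times.
* **C-index.** Harrell's concordance implemented in-package (lifelines
  serves only as a cross-check): a pair is comparable when the shorter
  observed time is an event and the times differ (tied-time pairs are
  not compared); it is concordant when the shorter-lived patient has the
  higher biomarker, matching the HR > 1 orientation; biomarker ties
  count ½. The 95% CI is a seeded percentile bootstrap resampling
  patients (2000 resamples by default).
* **Paired C-index comparison.** Two biomarkers on the same patients
  share the same comparable pairs, so Δ = C_A − C_B is a paired
  contrast. The p-value references Δ against a leave-one-patient-out
  jackknife standard error (both C-indices recomputed without each
  patient) with a t(m−1) distribution. This was a genuinely open design
  point: the obvious alternative — a paired t-test that treats
  per-patient concordance fractions as independent observations —
  ignores the sharing of pairs between patients and, in our null
  simulations (two independent log-normal markers, n = 100, 200
  replicates), rejected 32.5% of the time at nominal 5%. The jackknife
  version rejected 5.0% on the same nulls and retains full power when
  one marker is perfectly concordant and the other uninformative. A
  seeded paired-bootstrap p is available as a cross-check
  (`bootstrap_p=True`). Published p-values computed with other software
  for this comparison should not be expected to reproduce exactly.
* **Bland-Altman.** Differences x − y; bias ± 1.96·sd (sd with
  ddof = 1); the (mean, difference) pairs are returned for plotting.

## Cohort simulator

`CohortSimSpec` draws a log-normal biomarker (log-mean −0.5, log-sd 1.2 —
a right-skewed index distribution spanning roughly 0.05–5, like observed
tumor-burden indices), exponential event times with rate
`baseline · exp(β · biomarker)`, independent exponential censoring and an
administrative 5-year horizon. Defaults (baseline 0.2/year, censoring
0.05/year, β = 0.5) yield ≈30% censoring, matching the censoring share of
the kind of advanced-prostate-cancer cohort the statistics are aimed at.
The exponential baseline gives closed-form checks (mean time 1/rate,
competing-exponential censoring probability); a Weibull baseline is a
natural extension hook but is not implemented.

## Problem sizes used in the checks

The test suite and acceptance script run phantoms up to 128³ voxels,
200 random component-labeling scenes up to 32³ against a flood-fill
oracle, 100 random cohorts (n ≤ 50) against exhaustive pair enumeration,
50 replicates of n = 500 for Cox parameter recovery, and 200 null
replicates of n = 100 for the type-I error of the paired C-index test.
These sizes give stable Monte-Carlo estimates while keeping the whole
suite in the tens of seconds.

## Known limitations

* No DICOM ingestion and no SUV computation from raw counts; inputs are
  already SUV-scaled NIfTI volumes.
* The rule-based CT bone mask (HU threshold + small-component removal)
  is a deliberately simple baseline, not a substitute for anatomical
  skeletal segmentation; per-bone labeling is out of scope.
* The index inherits the biology of NaF uptake: benign osteoblastic
  activity (degeneration, healing fractures) is indistinguishable from
  metastasis without the manual classification step.
* Multivariable Cox, competing risks, time-dependent covariates and
  proportional-hazards diagnostics are out of scope.
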