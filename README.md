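# petburden

Quantifying skeletal tumor burden from ¹⁸F-sodium-fluoride (NaF) PET/CT.

In metastatic prostate cancer, the fraction of the skeleton involved by
tumor is a prognostic imaging biomarker. The planar bone scan index (BSI)
estimates it from 2D scintigraphy; `petburden` computes its 3D PET/CT
analogue: focal supra-threshold NaF uptake is segmented into connected
*hotspots*, hotspots are restricted to the segmented axial skeleton (and,
in manual mode, to those classified as metastatic), and the index is

```
index (%) = 100 · f · Σᵢ vᵢ / V_bone
```

where `vᵢ` are the included hotspot volumes on the PET grid, `V_bone` is
the segmented bone volume on the CT grid, and `f = 0.33` extrapolates the
segmented axial bones — roughly a third of total skeletal volume — to the
whole skeleton (so a lesion load equal to the entire segmented skeleton
reads 33%). Two operating modes are provided:

* **auto** — fixed detection threshold SUV 15, every bone-overlapping
  hotspot included, no human in the loop;
* **manual** — a per-patient threshold (typically SUV 6–9) plus a reader's
  metastasis/benign classification of each hotspot.

Both modes smooth the SUV volume with a 2 mm Gaussian before thresholding
and use 26-connected components.

The package also contains the statistics used to evaluate such indices
against overall survival — administrative 5-year censoring, median split
with Kaplan-Meier curves and the log-rank test, univariate Cox regression,
Harrell's C-index with bootstrap CI and a paired C-index comparison, and
Bland-Altman agreement — plus synthetic phantom and cohort generators with
analytic ground truth, so every stage is testable without patient data.

Intended users: nuclear-medicine and medical-physics researchers
prototyping quantitative PET biomarkers, and anyone needing a tested
reference implementation of the index and its evaluation statistics.

## Worked example

```python
from petburden import (PhantomSpec, Ellipsoid, SphereLesion,
                       generate_phantom, run_pipeline)

spec = PhantomSpec(
    shape=(64, 64, 64), pet_spacing_mm=(2, 2, 2), ct_spacing_mm=(2, 2, 2),
    bones=[Ellipsoid((64, 64, 64), (40, 32, 26))],
    lesions=[SphereLesion((64, 64, 64), 9.0, 20.0),      # inside bone
             SphereLesion((12.0, 12.0, 116.0), 7.0, 20.0)],  # outside bone
)
suv, bone, truth = generate_phantom(spec)
result, hotspots = run_pipeline(suv, bone, "auto", sigma_mm=0.0)
print(f"detected={result.n_hotspots_detected} included={result.n_hotspots_included}")
print(f"index_percent={result.index_percent:.4f}")
print(f"truth: analytic={truth.expected_index_percent:.4f} "
      f"digitized={truth.expected_index_percent_digitized:.4f}")
```

prints

```
detected=2 included=1
index_percent=0.7385
truth: analytic=0.7229 digitized=0.7385
```

Two hotspots are detected; the one outside the skeletal mask is removed,
so only the 9 mm in-bone lesion (3112 mm³ digitized, against a 139 064 mm³
bone volume) contributes: `100 · 0.33 · 3112/139064 = 0.74%`. The pipeline
reproduces the voxel-counted (digitized) truth exactly; the analytic
closed-form truth differs only by digitization error of the sphere on a
2 mm grid.

Evaluating a biomarker on a simulated 200-patient cohort (log hazard 0.5
per index unit, ~30% censored, 5-year horizon):

```python
from petburden import (CohortSimSpec, simulate_cohort, censor_at_horizon,
                       cox_univariate, harrell_cindex, median_split, logrank_test)

cohort, _ = simulate_cohort(CohortSimSpec(n=200, beta_true=0.5, seed=7))
cohort = censor_at_horizon(cohort, 5.0)
cox = cox_univariate(cohort, "biomarker")
ci = harrell_cindex(cohort, "biomarker", seed=7)
split = median_split(cohort, "biomarker")
chi2, p = logrank_test(split.high, split.low)
```

gives `HR = 1.76` (95% CI 1.49–2.07, p = 1.9e-11), `C-index = 0.594`
(95% CI 0.54–0.64 over 16 680 comparable pairs), and a median split at
0.518 with log-rank χ² = 5.6 (p = 0.018) — the high-index group dies
faster, as simulated.

The same computations are available from the shell:

```
petburden phantom --config spec.json --out scene/
petburden compute --pet scene/phantom_suv.nii.gz --bone scene/phantom_bone.nii.gz \
                  --mode auto --out results/
petburden survival --cohort cohort.csv --biomarker bsi --biomarker pet15 \
                   --horizon 5 --out report/
```

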