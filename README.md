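# vesseltraj

Longitudinal morphometry and mixed-effects diffeomorphic trajectory
modelling of cerebral-artery centerlines.

Cerebral arteries lengthen and grow more tortuous with age, and patients
followed for unruptured intracranial aneurysms are scanned with MRA every
few years — giving many short, partially overlapping windows onto a
decades-long process.  `vesseltraj` stitches such windows into one
population trajectory and asks, per patient, *how fast* their vasculature is
changing and *how old* it looks:

* **morphometrics** — per-artery centerline length `L`, arc-chord
  tortuosity index `T = L/C − 1`, and arc-length-weighted mean radius, with
  a paired first-vs-last comparison table (median (IQR) changes, Wilcoxon
  signed-rank tests);
* **trajectory atlas** — a landmark LDDMM model: a template `X0` at
  reference time `t0` is carried along a geodesic by control-point momenta
  `m0` under a 4 mm Gaussian kernel, and each subject is mapped onto that
  trajectory by the time warp `ψ_i(t) = e^{ξ_i}(t − t0 − τ_i) + t0`
  (acceleration `α_i = e^{ξ_i}`, time shift / vascular age `τ_i`) plus a
  space shift from ten ICA-derived geometric sources with loadings `s_i`;
* **group statistics** — Kruskal-Wallis comparisons of `α`, `τ` and source
  loadings across clinical factors, Wilcoxon signed-rank paired tests, Holm-
  Bonferroni post hocs;
* **synthetic cohorts** — a first-class generator of labeled centerline
  geometries with known ground-truth latents, emulating the study design
  (110 subjects, first scan 57.3 (15.8) y, 3.6 (1.3) visits over
  6.1 (2.6) y) so every estimator is validated against truth.

Imaging data behind this class of study is private; everything here runs on
synthetic cohorts by design.

## Worked example

```python
import numpy as np
from vesseltraj import (
    AtlasConfig, CohortConfig, SubjectShapeSeries,
    estimate_atlas, generate_cohort, to_point_set,
)
from scipy.stats import spearmanr

cfg = CohortConfig(n_subjects=24, sigma_xi=0.4, sigma_tau=5.0, n_sources=2,
                   sigma_noise=0.05, visits_mean=4, visits_sd=0, seed=0)
cohort, truth = generate_cohort(cfg)
series = [SubjectShapeSeries(s.subject_id,
                             [sc.age for sc in s.scans],
                             [to_point_set(sc, 8) for sc in s.scans])
          for s in cohort.subjects]
atlas, report = estimate_atlas(series, AtlasConfig(n_sources=2, iters=8))
xi  = np.array([p.xi  for p in atlas.subject_params])
tau = np.array([p.tau for p in atlas.subject_params])
print(f"residual RMS {report.residual_rms:.3f} mm")
print(f"rho(alpha) {spearmanr(np.exp(xi), truth.alpha).statistic:.2f}",
      f"rho(tau) {spearmanr(tau, truth.tau).statistic:.2f}")
```

prints

```
residual RMS 0.107 mm
rho(alpha) 0.92 rho(tau) 0.84
```

i.e. the fit explains the landmarks to about twice the injected 0.05 mm
noise (the remainder is the model's single-geodesic approximation of the
analytic aging trend), and the per-subject acceleration and vascular-age
rank orders are recovered at Spearman ρ = 0.92 and 0.84.

The full analysis lives in `analysis/` as numbered drivers over the
package: `01_simulate_cohort.py` (110-subject demonstration cohort with a
known diabetes acceleration effect and hypertension vascular-age effect),
`02_measure_morphometrics.py` (per-artery table: carotid/anterior
lengthening and rising tortuosity, ACA caliber loss, quiet posterior
circulation), `03_fit_longitudinal_atlas.py`, and
`04_group_comparisons.py` (the injected diabetes effect appears in the
acceleration column, p ≈ 0.03, and hypertension in the time-shift column,
p ≈ 0.002, with the null factors quiet).  Tables land in `results/`.

There is also a CLI:

```bash
vesseltraj simulate --out cohort_dir --seed 0 --n-subjects 20
vesseltraj measure  --in cohort_dir --out morpho.csv
vesseltraj fit      --in cohort_dir --out params.csv --kernel-mm 4 --sources 10
vesseltraj compare  --params params.csv --covariates cohort_dir/covariates.csv \
                    --morphometry morpho.csv --out report_dir
vesseltraj run      --config cfg.yaml          # all stages, one seed
```

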