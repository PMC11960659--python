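# Methods

`vesseltraj` models how the shape of the major cerebral arteries — the
vessels of and around the Circle of Willis — changes with age, from
longitudinal sets of labeled 3D centerline curves.  This note describes the
model, the synthetic-data generator used to validate it, the estimation
procedure, and the numerical and design choices a maintainer would want to
know about.

## Data model

A scan is a set of labeled centerline polylines with a maximal-inscribed
sphere radius at each point (mm, common head frame).  The supported artery
set covers the left/right anterior circulation (internal carotid ICA, middle
cerebral M1, anterior cerebral A1+A2, anterior communicating) and the
posterior circulation (basilar BA, posterior cerebral P1+P2).  For shape
modelling each scan is converted to a fixed-topology landmark set: every
artery is resampled to a fixed number of points uniformly spaced in arc
length, and the per-artery blocks are concatenated in a canonical label
order.  Missing arteries (absent A1 or P1 variants) are carried as
explicitly absent blocks and excluded from fits that require them.

Per-artery morphometrics are the centerline arc length `L` (mm), the
arc-chord tortuosity index `T = L/C − 1` (with `C` the endpoint chord; 0 for
a straight vessel), and the arc-length-weighted mean radius.  The `− 1`
convention is deliberate: published values for near-straight segments (e.g.
M1 ≈ 0.08) are only possible for the excess ratio, not the raw ratio ≥ 1.

## Trajectory model

The population follows a geodesic of a landmark LDDMM model: control points
`c_k` with momenta `m_0` (per year) and a Gaussian kernel
`K(x,y) = exp(−|x−y|²/2σ²)` (default σ = 4 mm) generate a velocity field
whose Hamiltonian flow

    dc/dt = K(c,c) m,      dm/dt = −∇_c ½ mᵀ K(c,c) m

deforms the template `X0` (defined at reference time `t0`, the mean age over
all scans).  The kinetic energy is conserved along exact geodesics; the RK4
integrator keeps the relative drift below 1e−4 at 20 steps, which the tests
check.  Because the Hamiltonian is quadratic, shooting momenta `a·m` for
unit time equals shooting `m` for time `a`; all time points, including
negative ones, are reached through this rescaling.

Subject `i` deviates from the population in time and space:

* time warp `ψ_i(t) = α_i (t − t0 − τ_i) + t0`, with acceleration
  `α_i = exp(ξ_i)` (relative speed of progression) and time shift `τ_i`
  (years; the subject's vascular-age offset — positive τ means the anatomy
  lags chronological age);
* a space shift `Σ_j s_ij A_j` over a small basis of geometric sources
  `A_j` with standardized loadings, applied to the template before transport
  (a first-order stand-in for exact parallel transport of the shift along
  the geodesic).

Priors are `ξ ~ N(0, σ_ξ²)`, `τ ~ N(0, σ_τ²)`, `s ~ N(0, I)`; the landmark
residual is i.i.d. Gaussian.  The model is invariant to jointly rescaling
(α, m0) and to jointly shifting (τ, t0), so after every population update
the latents are centered — mean ξ = 0 and mean τ = 0 exactly, absorbed into
the scale of `m0` and into `t0`.  Both centered and raw parameters are
reported because upstream tools for this model family print non-centered
summaries (e.g. mean accelerations well below 1), which are the same model
in a different gauge.

## Estimation

Estimation is staged, mirroring the usual initialization of longitudinal
shape atlases, followed by block-coordinate MAP ascent:

1. **Template**: iterative Procrustes mean (Kabsch rigid alignment,
   landmark-wise averaging) of the first-visit shapes; by default every scan
   is rigidly aligned to it.  Rigid — never elastic — alignment, so
   registration cannot absorb the morphological change being modelled.
2. **Per-subject geodesic regressions** give per-year momenta (template
   fixed at the first visit).  In the small-deformation regime the
   displacement is linear in the momenta, so a ridge solve provides the
   solution (an L-BFGS polish is available and used in the unit tests).
3. **Population trajectory**: `m0` is the average of the per-subject
   momenta; the template is shot from the mean initial age to the mean age
   over all scans, which becomes `t0`.  The regression residual sets the
   initial noise scale.
4. **Sources**: per-subject mean residual displacement fields are
   decomposed by FastICA (PCA fallback on non-convergence), after projecting
   out the population-velocity direction: sources encode variability
   orthogonal to progression, and a basis able to mimic motion along the
   trajectory would make τ unidentifiable.  Modes are unit-normalized,
   loadings standardized, displacement scale carried separately.  The basis
   is re-extracted once after a preliminary registration pass.
5. **Refinement** alternates: (a) per-subject registration — the loadings
   are linear-Gaussian given (ξ, τ) and are profiled out by an exact
   J-dimensional ridge solve, and the remaining 2-D (ξ, τ) problem is
   globalized with a coarse grid before an L-BFGS polish with ±3-prior-sd
   bounds; (b) a guarded Gauss-Newton ridge step on `m0`, re-linearized
   around the current trajectory, with residuals and warped-time design
   centered *within subject* so static inter-subject shape differences
   cannot contaminate the trend estimate; (c) a guarded robust-weighted
   mean-residual template update; (d) exact M-steps for a robust global
   noise scale (median over per-scan mean squares) and per-subject
   heteroscedastic scales floored at it.  The objective includes the
   Gaussian normalization terms, so every update is monotone in the joint
   log-posterior; the trace is reported and tested.

For speed, the population geodesic is tabulated once per iteration on a
dense warped-time grid (0.25-y steps, one forward and one backward
integration storing landmark and control-point positions) and read by
linear interpolation; trajectory motion is well under a millimetre per
year, so the interpolation error is negligible against the landmark noise.
This makes each subject-registration objective evaluation a table lookup
rather than an ODE solve.

An optional MCMC-SAEM mode appends short Metropolis chains on the subject
latents with Robbins-Monro updates of the variance parameters; it shares
the MAP log-posterior and is smoke-tested, not relied on.

## Synthetic cohort generator

The generator is first-class code: it produces cohorts with known ground
truth against which every estimator is validated.

* **Design**: ~110 subjects; first-scan age truncated-normal 57.32 (15.82) y
  (adults only, resampled below 18); follow-up span truncated-normal 6.11
  (2.60) y; visit count `round(N(3.6, 1.3))` clamped to ≥ 2 (clamping, not
  resampling, keeps the mean within 0.1 of 3.6); interior visits uniform
  over the span.
* **Geometry**: each artery is a helical arc placed in a common head frame.
  A helix with `n` turns, transverse radius `R` and axial rise `H` has
  closed-form arc length and chord, so `(R, H)` are solved exactly for any
  target (length, tortuosity) pair.  The ICA gets two turns (a siphon-like
  segment with tortuosity index ≈ 0.9); M1 and BA are gentle arcs (< 0.2).
  Baselines match typical first-visit medians of the artery set; radii
  taper linearly along the (constant-speed) helix so the arc-length-weighted
  mean radius is exact.
* **Trends**: per-artery drift, linear in *warped* age — length in % per
  decade (multiplicative), tortuosity index and radius in absolute units per
  decade.  Defaults are calibrated so a typical 6-year interval reproduces
  the expected signature: carotid/anterior lengthening about 1 % per 6 y
  with rising tortuosity, and an ACA caliber loss of 3–5 % per 6 y, with the
  posterior circulation nearly flat.
* **Subject structure**: ξ, τ Gaussian with configurable covariate effects
  (binary factors drawn first at configured prevalences, e.g. 61/110
  hypertensive, 18/110 diabetic); source loadings Gaussian through fixed
  smooth sinusoidal displacement fields; i.i.d. Gaussian landmark noise.
  The source fields are evaluated at the reference-age landmarks,
  orthogonalized against the span of trajectory tangents over the cohort's
  age range, and applied by landmark index — hence exactly age-constant and
  exactly separable from progression, mirroring the model's own
  decomposition.  With all variance parameters zero, every subject
  reproduces the population geometry exactly.

**What the generator does not emulate**: real MRA segmentation noise is
structured (flow artifacts, threshold effects), anatomy varies topologically
(missing A1/P1 are supported downstream but not generated), artery shapes
are far richer than helical arcs, and real aging need not follow any
geodesic.  Passing recovery tests therefore demonstrates the estimator's
correctness under the stated generative model, not clinical validity.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` run, at desk scale (8 landmarks
per artery, 4 mm kernel and control spacing, ≈ 240 control points):

* closed-form morphometry (semicircle, helix) and rigid invariance;
* Hamiltonian conservation and shooting semigroup/scaling identities;
* exact statistical oracles (Wilcoxon enumeration vs brute force,
  Kruskal-Wallis hand values, Holm arithmetic, null type-I calibration);
* **parameter recovery**: a 24-subject, 4-visit cohort (σ_ε = 0.05 mm,
  σ_ξ = 0.4, σ_τ = 5 y, 2 sources) refit in MAP mode, checking Spearman
  rank recovery of acceleration and time shift;
* **trend reproduction**: 110-subject cohorts where the configured
  lengthening/tortuosity/caliber signature must be flagged with the right
  signs while zero-trend arteries stay quiet;
* **covariate detection**: a factor at prevalence 18/110 adding +0.5 to ξ
  must be detected by the morphometric progression-rate screen (the
  per-subject slope of summed artery length vs age — monotone in the true
  acceleration and far cheaper than refitting the atlas per replicate),
  while a null factor stays quiet.

## Known limitations

* A single geodesic is a coarse model of seven decades of aging.  For
  cohort draws containing several subjects whose warped ages fall 25+ years
  from the reference time, the extrapolated trajectory degrades and
  time-shift estimates for those subjects can alias to wrong positions;
  rank-recovery of τ then drops below the headline level even though the
  bulk of the cohort is fit well.  The robust noise scales and trimmed
  population updates bound, but do not remove, this effect.
* The acceleration–momenta scale and the time-shift–reference-time origin
  are gauge freedoms; only centered (or otherwise gauged) parameters are
  comparable across fits.
* The space-shift transport is first-order (shift template, then shoot);
  exact parallel transport would differ at second order in the shift size.
* Arc-length resampling makes landmark correspondence slightly nonlinear in
  the underlying anatomical displacement, so a J-mode linear source basis
  cannot be exact even when the generative truth has J modes; the residual
  enters the noise floor.
* Wilcoxon p-values for n > 12 use the tie/continuity-corrected normal
  approximation; Kruskal-Wallis uses the chi-square approximation at all
  sample sizes (conventional, and the group sizes here are ≥ 10 in every
  reported comparison).
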