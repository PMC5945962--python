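# Methods

## The event-based model

The package models disease progression as a fixed ordering *S* of *Z*
biomarker abnormality events under two assumptions: progression is
*monotonic* (no remission — once a biomarker is abnormal it stays abnormal)
and *homogeneous* (every subject follows the same ordering, differing only in
how far along it they are).  A subject at stage *k* ∈ {0..Z} has experienced
the first *k* events of *S*.  Neither a priori staging nor abnormality cut
points are required: both the normal/abnormal distributions and the ordering
are learned from cross-sectional data.

Per biomarker, `P(x|¬E)` is a Gaussian fitted to healthy controls by maximum
likelihood (ML variance, `ddof=0`).  `P(x|E)` is the free component of a
two-Gaussian mixture fitted to manifest patients by EM with the control
component's parameters held fixed — justified here because control status is
genetically determined, so the normal distribution can be estimated from an
uncontaminated group.  The dataset likelihood of an ordering sums over each
subject's unknown stage with a uniform prior `P(k) = 1/(Z+1)` (stage 0 = no
events), and the per-subject stage is the `k` maximising the same inner
term.  Premanifest subjects contribute to ordering inference and staging but
not to the distribution fits.

## Numerical choices

- **Log-space likelihood.** The literal product form underflows at realistic
  *N*; all arithmetic uses per-subject prefix sums of
  `log P(x|E) − log P(x|¬E)` along the ordering combined by log-sum-exp, so
  one sequence evaluation is O(N·Z).  Agreement with a literal naive product
  evaluation is part of the test battery (~1e−15 at Z = 4, N = 10).
- **Search.** Greedy steepest-ascent over all pairwise swaps from random
  restarts (default 10).  On every Z ≤ 6 problem tried it attains the
  exhaustive-enumeration optimum; `exhaustive_ml_sequence` (Z ≤ 8) is kept
  as the oracle.  Ties break lexicographically so runs are reproducible.
- **MCMC.** Metropolis-Hastings with uniform random pairwise-swap proposals
  (symmetric, so acceptance is `min(1, exp(Δ log L))`); defaults 100,000
  iterations, 10,000 burn-in.  Chain settings are conventions of this model
  family, not calibrated values, and are fully configurable.  Note one
  structural quirk: on a flat target every proposal is accepted and the
  chain alternates permutation parity each step; diagnostics that thin the
  chain should use an odd stride.
- **EM for the patient mixture.** Free parameters are the abnormal mean, SD
  and mixing weight; tolerance 1e−6 on the log-likelihood, max 500
  iterations.  Initialisation is deterministic but uses two starts — the
  patient sample moments, and the moments of the patient values on the
  abnormal side of the control mean — keeping the higher-likelihood fit.  A
  single wide start can converge to a one-component solution that absorbs
  both clusters; the split start protects clearly-separated mixtures from
  that optimum.  The abnormal SD is floored at 0.05× the control SD (narrow
  abnormal components are legitimate — basal-forebrain-like events can have
  abnormal SD below the control SD — but density blow-up is not) and the
  weight is clipped to [0.01, 0.99] so both likelihood channels stay
  defined for every subject.
- **Identifiability caveat.** At heavy overlap and n ≈ 120 the *global* ML
  solution of the fixed-component mixture is occasionally a single wide
  component (verified by grid search on simulated data).  Parameter-recovery
  guarantees are therefore stated at the average-over-replicates level; the
  test suite checks mean bias and majority per-replicate recovery.
- **Abnormality thresholds** (descriptive only; the model uses no cut
  points) solve the density-crossing quadratic and take the root between the
  component means, the midpoint for equal SDs, or the root nearest the
  midpoint if none lies between the means.
- **Stage ties** resolve to the smallest k (conservative staging);
  `argmax` order makes this exact.
- **Bootstrap PVD.** Resamples are stratified by diagnosis so the
  distribution-fitting groups are never empty.  Each resample refits the
  mixtures and re-estimates the ML ordering; by default its PVD is that
  ordering's permutation matrix (an option runs a short MCMC chain per
  resample instead), and the element-wise mean over resamples is returned.
- **Covariate correction.** OLS of each volume on age, total intracranial
  volume and reference-coded site, fitted on controls only by default (so
  control residual means are exactly 0 and disease effects cannot leak into
  the coefficients) and applied to everyone; configurable to all-subject
  fitting.  Follow-up visits are corrected and staged with the
  baseline-fitted model — refitting per visit would conflate model change
  with subject change.
- **Selection.** Welch two-tailed t-test (abnormal SDs genuinely differ from
  control SDs, so pooled variance is not assumed) with Bonferroni correction
  (conservative and order-preserving for t-based selection); defaults
  corrected p < 0.001 and |t| > 8.  A bilateral left/right pair is kept only
  if both sides pass.  Outlier removal drops whole subjects with any value
  beyond 5 within-diagnosis-group SDs, with statistics frozen from the first
  pass so the operation is idempotent.

## The synthetic cohort generator

`generate_cohort` emulates a three-arm observational volumetric study with
the exact generative structure the model assumes:

- **Groups and sizes.** 119 HC / 120 preHD / 118 HD by default, from four
  acquisition sites; group-specific age and TIV distributions
  (HC 46.3 ± 10.2 y, preHD 40.8 ± 8.8 y, HD 48.5 ± 9.9 y; TIV 1392/1408/1362
  ± ~140 mL).
- **Events.** Z = 18 by default, named after regions typical of HD volumetry
  (seven bilateral pairs plus midline/CSF volumes).  A planted permutation
  fixes the ordering; a subject at stage k draws the first k events'
  biomarkers from the abnormal component and the rest from the normal one —
  abnormal sets are exactly prefixes of the planted sequence.
- **Effect sizes.** Signed abnormal shifts of 2.5–4 control SDs (tissue
  volumes shrink, CSF spaces grow), abnormal SD 1.2× control (0.8× for the
  basal-forebrain pair, whose patient distribution is narrower than the
  control one).  These separations put every event comfortably past the
  |t| > 8 selection rule at these group sizes.
- **Stage occupancy.** HC concentrated at stage 0 with a geometric tail
  (≈70% at 0 — a small fraction of controls legitimately occupy nonzero
  stages, which slightly contaminates the control fit exactly as elderly
  controls do in practice); preHD uniform over 0..Z; HD weighted toward the
  final stages (reversed geometric).  These are qualitative mimics of the
  observed occupancy shape; no numerical occupancy distribution exists to
  calibrate against.
- **Confounds.** Linear age and TIV effects and additive site offsets on the
  raw scale, small relative to the event shifts (≈0.3%/year of age, 0.05%/mL
  of TIV, ±2% site offsets).
- **Longitudinal follow-up.** Annual visits; each visit advances a patient's
  latent stage by a Poisson increment with mean `stages_per_year × Δt`,
  truncated at Z; controls do not progress (configurable).  Biomarkers are
  redrawn at the visit's stage with the baseline subject's site and TIV.
- **Phenotypes.** Stage-linked scores with planted slopes per stage —
  TMS +0.98, SDMT −1.0, Stroop −1.4, CAP +0.014 — plus Gaussian noise
  (SDs 5, 8, 12, 0.1), signs following clinical convention.
- **Streams.** Each output block (covariates, stages, biomarker noise,
  follow-ups, phenotypes) draws from its own stream derived from the config
  seed, so adding phenotypes never perturbs biomarker draws; identical
  config + seed gives bitwise-identical tables.

**What the generator does not emulate** — and hence what passing tests do
not establish about clinical data: segmentation/measurement error and
site-dependent noise, non-Gaussian or skewed volume distributions,
correlated biomarkers (the model itself assumes independence),
subtype-mixture or non-monotonic progression, CAG-repeat genetics, and
informative dropout.  Recovery results here certify the implementation under
the model's own assumptions, not the model's adequacy for real cohorts.

## Validation battery and problem sizes

The canned studies in `hdebm.evaluation` (run by the test suite and
`scripts/acceptance.py`) use: 50 random tables at Z = 3–6 against the
exhaustive oracle; 10 replicate cohorts at full study scale (Z = 18,
119/120/118) for ordering recovery by Kendall tau; 1,000 subjects at 3-SD
separation for staging accuracy; 20 replicates at n = 118 for mixture bias;
and a 4-visit cohort at a planted 1 stage/year for longitudinal progression,
with manifest patients at their usual late-stage occupancy (so every event
has abnormal examples in the fitting group) and progression measured on
premanifest subjects planted at stages 0–10, leaving headroom below the
stage ceiling.  These sizes keep the full battery at a few minutes on one
core while leaving each check's sampling error well inside its tolerance.

## Known limitations

- The EBM has no intrinsic time scale; stages order subjects but do not
  date them.  Phenotype regressions give only an implicit, approximate
  calibration.
- Events that never occur in the distribution-fitting groups are
  unidentifiable: their mixtures collapse and staging through them is
  arbitrary.  Biomarker selection exists precisely to exclude such markers;
  on synthetic data the same failure is reproduced (and avoided) in the
  longitudinal validation design.
- MCMC positional uncertainty is known to understate ordering uncertainty
  on peaked posteriors; the bootstrap PVD is the more conservative
  instrument.
- Missing biomarker values are rejected rather than imputed.
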