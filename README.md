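# hdebm

Event-based modelling of the order in which regional brain-volume biomarkers
become abnormal in Huntington's disease (HD), with patient staging, ordering
uncertainty, and longitudinal / phenotypic validation — plus a synthetic
cohort generator that reproduces the statistical structure the model assumes,
so the whole pipeline can be exercised and tested without access to clinical
data.

## Who this is for

Researchers in disease-progression modelling and neuroimaging statistics who
want a tested, reusable event-based model (EBM) implementation: given
cross-sectional regional volumes for healthy controls (HC), premanifest gene
carriers (preHD) and manifest patients (HD), the package infers a
*characteristic sequence* of biomarker abnormality events, quantifies its
uncertainty, and assigns each subject a stage along that sequence from a
single visit.

## The model

An *event* `E_i` is biomarker *i*'s transition from its normal to its
abnormal distribution.  Progression is assumed monotonic and homogeneous: a
subject at stage *k* has experienced exactly the first *k* events of an
ordering *S* over the *Z* biomarkers.  With per-biomarker likelihoods
`P(x_ij | E_i)` and `P(x_ij | ¬E_i)`, the data likelihood of an ordering is

    P(X | S) = ∏_j  Σ_{k=0}^{Z}  P(k) ∏_{i≤k} P(x_s(i),j | E_s(i))
                                      ∏_{i>k} P(x_s(i),j | ¬E_s(i))

with a uniform stage prior `P(k) = 1/(Z+1)`.  The normal model per biomarker
is a Gaussian fitted to controls; the abnormal model is the free component of
a two-Gaussian mixture fitted to patients by EM with the control component
held fixed.  The maximum-likelihood ordering is found by greedy pairwise-swap
ascent from random restarts; MCMC over permutations yields a positional
variance diagram (PVD) of ordering uncertainty; bootstrap refits give a
cross-validated PVD.  A subject's stage is the `k` maximising the inner term
for their data alone.

## Worked example

```python
import hdebm

config = hdebm.CohortConfig(seed=42)          # 119 HC / 120 preHD / 118 HD, 18 events
cohort = hdebm.generate_cohort(config)

model = hdebm.EventBasedModel.from_dataframe(cohort.data)
results = model.fit(n_restarts=10, mcmc_samples=20_000, mcmc_burn_in=2_000, seed=42)
print(results.summary())
```

```
Event-Based Model Results
====================================================================
Subjects: 357    Events: 18    Log-likelihood: -1179.24
MCMC samples: 20000    acceptance rate: 0.001
--------------------------------------------------------------------
pos  biomarker              abn. mean  abn. sd  weight  pos. sd
  1  putamen_l                 -0.952    0.522    0.99     0.00
  2  putamen_r                 -1.363    0.424    0.99     0.00
  3  caudate_l                 -1.291    0.465    0.98     0.00
  ...
 17  basal_forebrain_r         -0.305    0.094    0.44     0.00
 18  ventricular_csf            0.222    0.141    0.34     0.00
====================================================================
```

Each row is one event of the recovered ordering (position 1 = earliest):
the fitted abnormal-component mean and SD are on the covariate-corrected
volume scale (volumes shift negative, CSF spaces positive), `weight` is the
fraction of manifest patients whose value the mixture attributes to the
abnormal component (high for early events, low for late ones — late events
have fewer patients past them), and `pos. sd` is the posterior SD of the
event's position from MCMC (0 where the ordering is certain).  The generator
planted exactly this ordering, so the diagonal recovery is the expected
outcome.  Staging the same subjects separates the groups:

```python
stages = results.stage()
dist = hdebm.stage_distribution(stages,
                                cohort.data.set_index("subject_id")["diagnosis"],
                                n_stages=results.n_events)
print(dist[["lower_half", "upper_half"]].round(2))
```

```
       lower_half  upper_half
group
HC           1.00        0.00
HD           0.09        0.91
preHD        0.48        0.52
```

Controls sit in the lower half of the staging range, manifest patients in
the upper half, and premanifest carriers spread across both — the pattern
the staging system is designed to expose.

A command-line pipeline wraps the same steps:

```bash
hdebm simulate --seed 1 --out cohort.csv --n-visits 4
hdebm run --input cohort.csv --seed 1 --out-dir out/
```

writing the ML sequence, distribution fits, PVD (CSV + heatmap), stage
assignments, stage distributions, validation report and a reproducibility
manifest under `out/`.

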