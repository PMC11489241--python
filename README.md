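# scacoms

Derivation, validation and application of a responsiveness-optimized
composite clinical scale for the spinocerebellar ataxias (SCAs).

Existing single scales for SCA — the four-item functional SARA (gait,
stance, sitting, speech; each 0–4), the FARS functional disability stage
(0–6) and the clinician-rated CGI-I (1–7) — often miss small but meaningful
changes in slowly progressing, heterogeneous disease.  The remedy
implemented here, in the lineage of composite endpoints such as ADCOMS and
the cUHDRS, is to let longitudinal natural-history data choose and weight
the items that actually track progression, and then to use the resulting
composite to estimate disease-modification effects and to size trials.

## The method

All item scores are standardized to a unit range (0 = best, 1 = worst).
With *time from baseline* `t` as the response and the items' unit scores
`x₁…x_p` as predictors, a single-response partial least squares (PLS1)
regression is fit on all pooled subject-visits.  Item selection follows
Wold's criterion on the Variable Importance in Projection,

  VIP_j = √( p · Σₐ SSₐ (w_{aj}/‖wₐ‖)² / Σₐ SSₐ ),  SSₐ = qₐ² tₐᵀtₐ,

items with VIP ≤ 0.5 being dropped unless clinically essential,
near-threshold, and carrying > 5% of the composite weight; items acquiring
negative coefficients are removed first, one at a time.  The final PLS
coefficients βⱼ are the composite weights; the composite is
S = Σ βⱼ·uⱼ and each item's percent contribution is 100·βⱼ/Σβ.

Responsiveness is quantified as the MSDR — mean change from baseline (CFB)
divided by its standard deviation, identical in form to the standardized
response mean.  Validation uses weight interchange across cohorts (with
drop-item and redistribute policies for an item one cohort lacks) and
repeated fivefold cross-validation of MSDR bias.  In a two-arm trial the
composite CFB is analyzed by a repeated-measures marginal model (treatment,
visit, their interaction, baseline composite; unstructured working
covariance), yielding LS means, percent progression avoided
(100·(LSM_plb − LSM_trt)/LSM_plb), Cohen's d, and the months of progression
delayed.  A slowing fraction `s` turns an MSDR into a detectable effect
size d = s·MSDR, and exact noncentral-t power (df = 2n−2, ncp = d·√(n/2))
gives per-arm sample sizes.

The patient-level registry and trial data behind the published models are
restricted, so the package includes a synthetic-cohort generator with a
known latent linear-decline model (genotype-specific rates, per-item
logistic links and ordinal discretization) that makes every stage testable
against ground truth.  Published weight sets, LS means and MSDRs are
shipped as inputs in `scacoms.published` for the arithmetic they determine.

## Worked example

```sh
scacoms simulate --seed 7 --n-subjects 300 --out nh.csv
scacoms derive nh.csv --n-components 2 --out model.json
scacoms power --msdr 0.8276 --slowing 0.3 --power 0.8
```

The `derive` step on this seed prints:

```
retained 5 items; total weight 38.8248
  fsara_gait: weight 0.8459 (2.18%)
  fsara_stance: weight 1.9627 (5.06%)
  fsara_speech: weight 0.6507 (1.68%)
  fars_func: weight 0.2995 (0.77%)
  cgi: weight 35.0660 (90.32%)
```

i.e. the sitting item was dropped by the VIP screen and the global-impression
item carries most of the weight, mirroring (in exaggerated form on this raw
simulated cohort — the `analysis/` scripts first apply the analytic-sample
filter, which moderates the CGI share) the qualitative pattern of the
published models.  The `power` line prints `256`: with a composite MSDR
of 0.8276, detecting a 30% slowing of progression at 80% power needs 256
subjects per arm (the same design with the f-SARA total score's MSDR of
0.4826 needs 750).

The full analysis sequence lives under `analysis/` as numbered scripts
(simulate registries → derive composites → cross-validate → treatment
effects → power table); each writes its tables under `results/tables/`.

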