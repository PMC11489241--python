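# Methods

This note documents the models, parameter choices and known limitations of
the package.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Score standardization and scale inventory

Every item is mapped affinely to a unit score in [0, 1] with 0 the best and
1 the worst state: u = (x − min)/(max − min), reversed for better-high
scales.  The shipped inventory covers the four f-SARA items (0–4,
higher-worse), the FARS functional stage (0–6) and CGI-I (1–7).  CGI-I
rates *change since baseline*, so it has no observed baseline value; the
package imputes the "no change" midpoint (raw 4, unit 0.5) at baseline so
that change-from-baseline and composite baselines are defined.  This is
configurable (`ScaleConfig.cgi_baseline_value`).

SARA axial items from natural-history sources are rescaled to the 5-point
f-SARA grid through a per-item monotone lookup table.  The shipped default
is proportional rounding, round(raw · 4/sara_max); it is a documented
stand-in to be replaced by a scale-specific mapping table where one is
available, which is why the mapping is configuration-driven rather than
hard-coded.

The analytic-sample filter mirrors trial inclusion: baseline gait score
within a stated band, plus complete data on all candidate items at baseline
and at 12 or 24 months.  A missing single item invalidates that
subject-visit for composite purposes (complete-case per visit).  Visit
times are stored in months; trial weeks convert at 12/52 months per week.

## Synthetic cohorts

The generator exists because the registry and trial data the methodology
was developed on are restricted.  It simulates the *linear phase* of an
overall sigmoidal decline:

    z_i(t) = z_i0 + r_i·t + ε_it,   r_i = max(0, r_g(i) + η_i)

with z_i0 ~ N(−0.8, 0.8²) on the latent scale, genotype-specific monthly
rates (defaults 0.028/0.025/0.022/0.014 for SCA1/2/3/6, ordered as in the
natural-history literature), subject-level rate heterogeneity
η_i ~ N(0, 0.01²) and visit noise ε ~ N(0, 0.12²).  Item j reports
grid-rounded logistic(λ_j·z + e), with per-item sensitivities λ (gait 1.1,
stance 1.0, speech 0.8, sitting 0.45, functional stage 0.9) and latent
measurement noise (0.45–0.6), so items differ in signal-to-noise — the
property the PLS derivation must detect.  CGI-I is generated from the
latent *change*: unit score 0.5 + 0.55·(z(t) − z(0)) + N(0, 0.12²),
discretized to the 7-point grid and anchored at "no change" at baseline.
Defaults were chosen once to match the published descriptives
(genotype mix dominated by SCA3; baseline f-SARA item means near 1.2–1.5 of
4; item MSDRs of order 0.2–0.8 with CGI the most responsive single item)
and are not tuned thereafter.

Dropout is missing-completely-at-random per follow-up visit (8% default in
natural history, 5% in trials); baseline is always observed.  Trials draw a
pure-SCA3 population by default, with the treated arm's subject-specific
slope multiplied by (1 − s) for slowing fraction s.  All randomness flows
from one `numpy` generator seeded explicitly per call.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: sigmoidal whole-course dynamics, genotype-specific
item profiles beyond rate differences, informative dropout, rater effects or
learning, and floor/ceiling clustering beyond what the logistic link and
grid produce.  Passing recovery tests show the pipeline is correct under
its own assumptions, not that those assumptions hold clinically.

## PLS1 derivation

Predictors are mean-centered but **not** variance-scaled: unit scores
already share a common range, and unscaled coefficients make percent
contributions equal to weight shares (100·β_j/Σβ), which is the arithmetic
the published contribution columns follow.  Rows are pooled subject-visits
(baseline included) with months-from-baseline as the response; whether rows
should instead be subject-level changes is ambiguous in the source
methodology, and subject-visit pooling was adopted as the design choice.

The NIPALS PLS1 fit, the VIP formula (Σ VIP² = p identity), and the
regression vector β = W(PᵀW)⁻¹q are implemented directly and are verified
in the tests against scikit-learn's PLS (scale=False) and a closed-form
one-component oracle.  Constant predictor columns receive weight 0; an
exhausted predictor block truncates the component count with a warning.

The number of components A is not stated by the source methodology.  The
package selects the smallest A whose leave-one-out PRESS is within 5% of
the minimum (parsimony rule), computed **once** on the full design and then
held fixed during resampling (k-fold) — re-selecting A inside every fold
would multiply runtime for no change in the quantity being validated, and
holding tuning constants fixed across resamples is standard practice.  At
very high signal-to-noise the PRESS-optimal A can legitimately exceed 1
even with a single informative predictor (minor components correct the
first component's noise contamination); the 5% parsimony band absorbs this
at moderate noise.

Selection loop order: (1) fit; (2) remove negative-coefficient items one at
a time, most negative first, refitting after each (ties broken by candidate
order); (3) VIP screen at Wold's threshold 0.5, with retention of
`clinical_override` items whose VIP ≥ 0.45 ("approximately 0.5") and whose
weight share exceeds 5%; (4) repeat to stability.  The removal log records
every exclusion with its reason.  The design matrix is fixed on rows
complete for the *initial* candidate set so that successive refits are
comparable.

## Responsiveness and validation

MSDR = mean(CFB)/sd(CFB) with the sample (n−1) SD — the denominator
convention is not specified by the source and n−1 was chosen.  The default
follow-up rule takes each subject's last available visit among {12, 24}
months (natural history) or the final trial week; MSDR is invariant to
positive rescaling of the measure, so composite MSDRs do not depend on the
overall weight scale.

Weight interchange supports the two policies for an item absent from the
target cohort: dropping its weight, or re-inserting it at its original
percent share c via new_weight = W·c/(1 − c) (which preserves the existing
weights' proportions exactly).  Percent bias in k-fold validation is
100·(MSDR_test − MSDR_train)/MSDR_train — negative means out-of-sample
degradation; the sign convention is the package's own.  Folds partition
subjects, never visits, and derivation inside folds re-runs the entire item
selection loop.

## Treatment effects

statsmodels provides no SAS-style MMRM, so the repeated-measures analysis
is a Gaussian GEE with fixed effects treatment, visit, treatment×visit and
baseline composite, an unstructured working covariance (exchangeable, then
independence, as fallbacks), and robust standard errors; inference on
LS-mean contrasts uses the normal approximation.  This targets the same
marginal estimand as an MMRM; small-sample df corrections are a documented
simplification.  The "cohort by treatment" covariate phrase in the source
is ambiguous and is implemented as the standard treatment×visit
interaction.  A zero-variance baseline covariate (noise-free degenerate
trials) is dropped from the design; a perfectly deterministic trial then
yields the exact difference with SE 0.

Cohen's d uses the pooled across-arm sample SD of final-visit CFB — the
source never defines its denominator, and this is the package's choice.
Delay in progression inverts the placebo LS-mean CFB trajectory
(piecewise-linear, prepended with (0, 0)) at the treated arm's final level;
sampling noise can make a fitted trajectory locally decreasing, so the
inversion uses its running-maximum envelope clipped at 0.  Delay is
reported in months and bounded by the follow-up length.

## Power and sample size

Effect size is d = slowing × MSDR.  Power is exact two-sided two-sample
noncentral-t (df = 2n − 2, ncp = d·√(n/2), α = 0.05 default) and sample
size is the smallest integer n per arm reaching the target, bracketed by
the normal approximation and finished by exact integer stepping.  Per-arm
(not total) n at 1:1 allocation reproduces the full published 32-cell table
from the printed MSDRs, which is how the per-arm convention was confirmed.

## Problem sizes in tests and scripts

The test suite and acceptance script use synthetic cohorts of 214–1000
subjects, trials of 100–200 per arm, 20–50 seed replicates for rank and
recovery properties, 200 fold estimates for k-fold bias, and 10⁵
Monte-Carlo replicates for the power cross-check — sizes at which the
Monte-Carlo error of each check is comfortably below its asserted
tolerance.

## Known limitations

* The proportional SARA→f-SARA table is a stand-in for the scale's own
  supplementary mapping.
* GEE/normal inference slightly understates small-sample uncertainty
  relative to a Kenward–Roger-corrected MMRM.
* The published item-level MSDRs, VIPs and weights themselves are not
  reproducible without the restricted data; the package reproduces the
  arithmetic they determine and validates the pipeline on synthetic ground
  truth instead.
* Percent progression avoided is estimated with noticeable sampling noise
  at trial sizes of 200/arm (SE of several points), so single-trial
  recovery checks use a ±10-point band.
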