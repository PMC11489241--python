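"""Treatment-effect estimation on the composite in a two-arm trial.

The composite change from baseline at each post-baseline visit is analyzed
with a repeated-measures marginal model: fixed effects for treatment, visit,
their interaction, and the baseline composite score; within-subject
correlation handled by a working covariance (unstructured by default,
exchangeable as the small-sample fallback), fitted by GEE so the reported
LS-mean contrasts carry robust standard errors.  From the final-visit
LS means the module derives the disease-modification summaries:

* percent progression avoided = 100 x (LSM_placebo - LSM_treated)/LSM_placebo,
* Cohen's d = LSM difference / pooled SD of final-visit CFB,
* delay in progression = follow-up length minus the time at which the
  placebo LS-mean trajectory first reaches the treated arm's final level
  (piecewise-linear interpolation).

Inference uses the normal approximation for LSM contrasts — a documented
simplification appropriate at the trial sizes simulated here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import AnalysisError, ParameterError
from .pls import CompositeModel, score_cohort
from .scale_data import LongitudinalCohort

__all__ = [
    "EffectEstimate",
    "trial_cfb_frame",
    "estimate_lsm",
    "progression_avoided",
    "cohens_d",
    "delay_in_progression",
    "estimate_effects",
]

_Z975 = 1.959963984540054


@dataclass
class EffectEstimate:
    """Per-visit LS means plus the disease-modification summary metrics."""

    lsm: pd.DataFrame  # columns: visit_months, arm, lsm
    difference: float
    se: float
    ci_lower: float
    ci_upper: float
    p_value: float
    cohens_d: float | None = None
    progression_avoided_pct: float | None = None
    delay_months: float | None = None
    sd_change: float | None = None
    model_description: str = ""

    def final_lsm(self, arm: str) -> float:
        final = self.lsm["visit_months"].max()
        row = self.lsm[(self.lsm["visit_months"] == final) & (self.lsm["arm"] == arm)]
        return float(row["lsm"].iloc[0])


def trial_cfb_frame(trial: LongitudinalCohort, model: CompositeModel) -> pd.DataFrame:
    """Composite CFB per subject-visit with arm and baseline-composite columns."""
    scores = score_cohort(trial, model)
    arm = trial.arm_of()
    frame = scores.rename("score").reset_index()
    baseline = frame[frame["visit_months"] == 0.0].set_index("subject_id")["score"]
    frame = frame[frame["visit_months"] > 0.0].copy()
    frame["baseline"] = frame["subject_id"].map(baseline)
    frame["arm"] = frame["subject_id"].map(arm)
    frame = frame.dropna(subset=["baseline", "arm"])
    frame["cfb"] = frame["score"] - frame["baseline"]
    if frame.empty:
        raise AnalysisError("no post-baseline composite scores available")
    return frame


def _fit_marginal_model(frame: pd.DataFrame, covariance: str):
    """GEE fit of cfb ~ arm*visit (+ baseline), with graceful degradation."""
    use_baseline = frame["baseline"].std() > 1e-12
    formula = "cfb ~ C(arm) * C(visit_months)"
    if use_baseline:
        formula += " + baseline"
    structures = {
        "unstructured": sm.cov_struct.Unstructured(),
        "exchangeable": sm.cov_struct.Exchangeable(),
        "independence": sm.cov_struct.Independence(),
    }
    if covariance not in structures:
        raise ParameterError(f"unknown covariance structure {covariance!r}")
    order = [covariance] + [s for s in ("exchangeable", "independence") if s != covariance]
    frame = frame.sort_values(["subject_id", "visit_months"])
    last_exc: Exception | None = None
    for name in order:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mod = smf.gee(
                    formula,
                    groups="subject_id",
                    data=frame,
                    cov_struct=structures[name],
                    family=sm.families.Gaussian(),
                )
                res = mod.fit()
            if np.all(np.isfinite(res.bse)):
                return res, name, use_baseline
        except Exception as exc:  # statsmodels raises a mix of types here
            last_exc = exc
            continue
    # Degenerate data (e.g. noise-free trials): plain OLS cell means.
    try:
        res = smf.ols(formula, data=frame).fit()
        return res, "ols", use_baseline
    except Exception as exc:
        raise AnalysisError(f"marginal model failed to fit: {last_exc or exc}") from exc


def _lsm_contrast(res, frame: pd.DataFrame, use_baseline: bool):
    """LS means per (arm, visit) at the mean baseline, via design-row contrasts."""
    design_info = res.model.data.design_info
    from patsy import dmatrix

    arms = sorted(frame["arm"].unique())
    visits = sorted(frame["visit_months"].unique())
    base_mean = frame["baseline"].mean()
    grid = pd.DataFrame(
        [
            {"arm": a, "visit_months": v, "baseline": base_mean}
            for a in arms
            for v in visits
        ]
    )
    L = np.asarray(dmatrix(design_info, grid))
    est = L @ res.params.to_numpy()
    cov = res.cov_params().to_numpy()
    grid["lsm"] = est
    grid["se"] = np.sqrt(np.maximum(0.0, np.einsum("ij,jk,ik->i", L, cov, L)))
    return grid, L, cov


def estimate_lsm(
    trial: LongitudinalCohort,
    model: CompositeModel,
    covariance: str = "unstructured",
) -> EffectEstimate:
    """Fit the repeated-measures model and return LS means and the final contrast."""
    frame = trial_cfb_frame(trial, model)
    arms = sorted(frame["arm"].unique())
    if len(arms) != 2:
        raise ParameterError(f"exactly two arms required (got {arms})")
    res, structure, use_baseline = _fit_marginal_model(frame, covariance)
    grid, L, cov = _lsm_contrast(res, frame, use_baseline)

    final = grid["visit_months"].max()
    rows = {a: grid.index[(grid["arm"] == a) & (grid["visit_months"] == final)][0] for a in arms}
    # Convention: placebo minus treated; generic cohorts use lexicographic order.
    a_ref = "placebo" if "placebo" in arms else arms[0]
    a_trt = [a for a in arms if a != a_ref][0]
    lvec = L[rows[a_ref]] - L[rows[a_trt]]
    diff = float(lvec @ res.params.to_numpy())
    se = float(np.sqrt(max(0.0, lvec @ cov @ lvec)))
    if se > 0:
        from scipy import stats

        p = 2.0 * stats.norm.sf(abs(diff) / se)
    else:
        p = 0.0 if diff != 0 else 1.0
    desc = (
        f"cfb ~ arm*visit{' + baseline' if use_baseline else ''}; "
        f"working covariance: {structure}; normal-approximation inference"
    )
    return EffectEstimate(
        lsm=grid[["visit_months", "arm", "lsm", "se"]].copy(),
        difference=diff,
        se=se,
        ci_lower=diff - _Z975 * se,
        ci_upper=diff + _Z975 * se,
        p_value=float(p),
        model_description=desc,
    )


def progression_avoided(lsm_placebo: float, lsm_treated: float) -> float:
    """Percent of placebo progression avoided: 100*(placebo - treated)/placebo."""
    if lsm_placebo <= 0:
        raise AnalysisError("progression avoided undefined: placebo LSM must be positive")
    return 100.0 * (lsm_placebo - lsm_treated) / lsm_placebo


def cohens_d(lsm_difference: float, sd_change: float) -> float:
    """Standardized effect size: LSM difference over the pooled CFB SD."""
    if sd_change <= 0:
        raise AnalysisError("Cohen's d undefined: SD of change must be positive")
    return lsm_difference / sd_change


def pooled_final_sd(frame: pd.DataFrame) -> float:
    """Pooled across-arm sample SD of final-visit composite CFB."""
    final = frame["visit_months"].max()
    sub = frame[frame["visit_months"] == final]
    groups = [g["cfb"].to_numpy() for _, g in sub.groupby("arm")]
    num = sum((len(g) - 1) * g.std(ddof=1) ** 2 for g in groups if len(g) > 1)
    den = sum(len(g) - 1 for g in groups if len(g) > 1)
    if den <= 0:
        raise AnalysisError("cannot pool SD: fewer than 2 subjects per arm")
    return float(np.sqrt(num / den))


def delay_in_progression(
    placebo_trajectory: "pd.DataFrame | list[tuple[float, float]]",
    treated_final: float,
    followup_months: float | None = None,
) -> float:
    """Months of progression delayed: follow-up minus the time at which the
    placebo LS-mean trajectory first reaches the treated arm's final level.

    ``placebo_trajectory`` is (months, lsm_cfb) pairs starting at (0, 0) and
    nondecreasing.  A treated level above placebo's final value means no
    measurable delay (returned as 0 with a warning).
    """
    if isinstance(placebo_trajectory, pd.DataFrame):
        pts = list(zip(placebo_trajectory["visit_months"], placebo_trajectory["lsm"]))
    else:
        pts = list(placebo_trajectory)
    pts = sorted(pts)
    times = np.asarray([p[0] for p in pts], dtype=float)
    values = np.asarray([p[1] for p in pts], dtype=float)
    if times[0] != 0.0 or values[0] != 0.0:
        times = np.insert(times, 0, 0.0)
        values = np.insert(values, 0, 0.0)
    if np.any(np.diff(values) < 0):
        raise ParameterError("placebo trajectory must be nondecreasing")
    followup = followup_months if followup_months is not None else float(times[-1])
    if treated_final > values[-1]:
        warnings.warn("treated final CFB exceeds placebo's; delay set to 0", stacklevel=2)
        return 0.0
    t_star = float(np.interp(treated_final, values, times))
    return followup - t_star


def estimate_effects(
    trial: LongitudinalCohort,
    model: CompositeModel,
    covariance: str = "unstructured",
) -> EffectEstimate:
    """Full effect report: LS means plus progression avoided, d, and delay."""
    est = estimate_lsm(trial, model, covariance)
    a_ref = "placebo" if "placebo" in set(est.lsm["arm"]) else sorted(set(est.lsm["arm"]))[0]
    a_trt = [a for a in sorted(set(est.lsm["arm"])) if a != a_ref][0]
    plb_final = est.final_lsm(a_ref)
    trt_final = est.final_lsm(a_trt)
    frame = trial_cfb_frame(trial, model)
    est.sd_change = pooled_final_sd(frame)
    est.cohens_d = cohens_d(est.difference, est.sd_change)
    if plb_final > 0:
        est.progression_avoided_pct = progression_avoided(plb_final, trt_final)
        traj = est.lsm[est.lsm["arm"] == a_ref][["visit_months", "lsm"]].copy()
        traj = traj.sort_values("visit_months")
        # sampling noise can make the LSM trajectory dip; delay is defined on
        # its monotone (running-maximum) envelope
        traj["lsm"] = np.maximum.accumulate(np.clip(traj["lsm"].to_numpy(), 0.0, None))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.delay_months = delay_in_progression(traj, trt_final)
    return est
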