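"""Synthetic natural-history cohorts and two-arm trials with known progression.

The restricted natural-history registries and the phase-3 trial data cannot
be redistributed, so every downstream stage (composite derivation,
responsiveness, cross-validation, treatment effects) is exercised on
simulated cohorts with a *known* generating model.

Generating model
----------------
Each subject carries a latent disease severity that declines linearly over
the observation window (patients are recruited in the linear phase of an
overall sigmoidal course)::

    z_i(t) = z_i0 + r_i * t + eps_it,    r_i = max(0, r_{g(i)} + eta_i)

with genotype-specific mean rates ``r_g`` (latent units/month), subject-level
rate heterogeneity ``eta_i ~ N(0, subject_rate_sd)``, and visit-level latent
noise ``eps``.  Each ordinal item j maps the latent state through a logistic
link with its own sensitivity ``lambda_j`` and measurement noise, then is
discretized to its scoring grid::

    u_ijt = grid_round( logistic(lambda_j * z_i(t) + e_ijt) )

so items differ in responsiveness (signal-to-noise) — exactly the property
the PLS derivation must detect.  CGI-I rates *change* rather than state: its
unit score is 0.5 (no change) plus a gain times the latent change from
baseline, discretized to the 7-point grid; at baseline it is anchored at the
no-change value.

Defaults emulate the published natural-history descriptives: genotype mix
dominated by SCA3, baseline f-SARA item means around 1.2-1.5 of 4, per-item
responsiveness (MSDR over 24 months) of order 0.2-0.8 with CGI the most
responsive single item.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .scale_data import (
    WEEKS_TO_MONTHS,
    LongitudinalCohort,
    ScaleConfig,
    default_config,
)

__all__ = ["SimulationParams", "TrialParams", "generate_natural_history", "generate_trial"]


DEFAULT_GENOTYPE_MIX = {
    "SCA1": 0.18,
    "SCA2": 0.20,
    "SCA3": 0.36,
    "SCA6": 0.22,
    "SCA8": 0.03,
    "SCA10": 0.01,
}

# Latent units/month; ordering (SCA1 fastest, SCA6 slowest) follows the
# natural-history literature on SARA progression rates.
DEFAULT_RATES = {
    "SCA1": 0.028,
    "SCA2": 0.025,
    "SCA3": 0.022,
    "SCA6": 0.014,
    "SCA7": 0.022,
    "SCA8": 0.018,
    "SCA10": 0.018,
}

DEFAULT_SENSITIVITY = {
    "fsara_gait": 1.10,
    "fsara_stance": 1.00,
    "fsara_speech": 0.80,
    "fsara_sitting": 0.45,
    "fars_func": 0.90,
}

DEFAULT_ITEM_NOISE = {
    "fsara_gait": 0.45,
    "fsara_stance": 0.50,
    "fsara_speech": 0.55,
    "fsara_sitting": 0.60,
    "fars_func": 0.50,
}


@dataclass
class SimulationParams:
    """Natural-history generator settings (see module docstring for the model)."""

    n_subjects: int = 214
    genotype_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GENOTYPE_MIX))
    baseline_severity_mean: float = -0.8
    baseline_severity_sd: float = 0.8
    progression_rate_per_month: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    subject_rate_sd: float = 0.010
    latent_noise_sd: float = 0.12
    item_sensitivity: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SENSITIVITY))
    item_noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ITEM_NOISE))
    cgi_gain: float = 0.55
    cgi_noise_sd: float = 0.12
    visit_schedule_months: list[float] = field(default_factory=lambda: [0.0, 12.0, 24.0])
    dropout_prob_per_visit: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be positive")
        total = sum(self.genotype_mix.values())
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ParameterError(f"genotype proportions must sum to 1 (got {total})")
        if any(p < 0 for p in self.genotype_mix.values()):
            raise ParameterError("genotype proportions must be nonnegative")
        if any(r < 0 for r in self.progression_rate_per_month.values()):
            raise ParameterError("progression rates must be nonnegative")
        if any(s < 0 for s in self.item_noise_sd.values()):
            raise ParameterError("noise SDs must be nonnegative")
        if any(lam <= 0 for lam in self.item_sensitivity.values()):
            raise ParameterError("item sensitivities must be positive")
        if not (0.0 <= self.dropout_prob_per_visit < 1.0):
            raise ParameterError("dropout_prob_per_visit must be in [0, 1)")
        if 0.0 not in self.visit_schedule_months:
            raise ParameterError("visit schedule must include baseline (0)")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=list)


@dataclass
class TrialParams(SimulationParams):
    """Two-arm trial settings.

    The treated arm progresses at ``(1 - slowing_fraction)`` times its
    counterfactual placebo slope.  Trial visits are scheduled in weeks and
    converted to months at 12/52 months per week.  The default genotype mix
    is pure SCA3, matching the subgroup in which treatment effects are
    evaluated.
    """

    n_per_arm: int = 100
    slowing_fraction: float = 0.5
    visit_schedule_weeks: list[float] = field(default_factory=lambda: [0.0, 8.0, 24.0, 48.0])
    genotype_mix: dict[str, float] = field(default_factory=lambda: {"SCA3": 1.0})
    dropout_prob_per_visit: float = 0.05

    def validate(self) -> None:
        super().validate()
        if self.n_per_arm < 2:
            raise ParameterError("n_per_arm must be at least 2")
        if not (0.0 <= self.slowing_fraction <= 1.0):
            raise ParameterError("slowing_fraction must be in [0, 1]")
        if 0.0 not in self.visit_schedule_weeks:
            raise ParameterError("trial schedule must include baseline (week 0)")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _grid_round(unit: np.ndarray, n_steps: int) -> np.ndarray:
    """Snap unit scores to the item's ordinal grid {0, 1/n, ..., 1}."""
    return np.clip(np.round(unit * n_steps), 0, n_steps) / n_steps


def _simulate_subjects(
    params: SimulationParams,
    rng: np.random.Generator,
    n: int,
    rate_multiplier: np.ndarray,
    visit_months: np.ndarray,
    config: ScaleConfig,
    subject_prefix: str,
) -> pd.DataFrame:
    """Core simulation shared by natural-history and trial generators."""
    genos = list(params.genotype_mix)
    probs = np.asarray([params.genotype_mix[g] for g in genos], dtype=float)
    probs = probs / probs.sum()
    genotype = rng.choice(genos, size=n, p=probs)
    missing = set(genotype) - set(params.progression_rate_per_month)
    if missing:
        raise ParameterError(f"no progression rate for genotypes {sorted(missing)}")

    z0 = rng.normal(params.baseline_severity_mean, params.baseline_severity_sd, size=n)
    base_rate = np.asarray([params.progression_rate_per_month[g] for g in genotype])
    rate = np.maximum(0.0, base_rate + rng.normal(0.0, params.subject_rate_sd, size=n))
    rate = rate * rate_multiplier

    n_visits = len(visit_months)
    eps = rng.normal(0.0, params.latent_noise_sd, size=(n, n_visits))
    z = z0[:, None] + rate[:, None] * visit_months[None, :] + eps  # (n, visits)

    # Dropout: baseline always observed; later visits MCAR.
    observed = np.ones((n, n_visits), dtype=bool)
    if params.dropout_prob_per_visit > 0:
        observed[:, 1:] = rng.random((n, n_visits - 1)) >= params.dropout_prob_per_visit

    frames = []
    subject_ids = np.array([f"{subject_prefix}{i:05d}" for i in range(n)])

    for item_id, lam in params.item_sensitivity.items():
        item = config.item(item_id)
        noise = rng.normal(0.0, params.item_noise_sd[item_id], size=(n, n_visits))
        unit = _logistic(lam * z + noise)
        unit = _grid_round(unit, item.max_score - item.min_score)
        frames.append(_long(subject_ids, genotype, visit_months, observed, unit, item_id, item))

    # CGI-I: rates change from baseline, anchored at the no-change midpoint.
    cgi = config.item("cgi")
    cgi_baseline_unit = (config.cgi_baseline_value - cgi.min_score) / (cgi.max_score - cgi.min_score)
    dz = z - z[:, [0]]
    cgi_noise = rng.normal(0.0, params.cgi_noise_sd, size=(n, n_visits))
    cgi_noise[:, 0] = 0.0
    unit = np.clip(cgi_baseline_unit + params.cgi_gain * dz + cgi_noise, 0.0, 1.0)
    unit = _grid_round(unit, cgi.max_score - cgi.min_score)
    frames.append(_long(subject_ids, genotype, visit_months, observed, unit, "cgi", cgi))

    return pd.concat(frames, ignore_index=True)


def _long(subject_ids, genotype, visit_months, observed, unit, item_id, item) -> pd.DataFrame:
    n, n_visits = unit.shape
    mask = observed.ravel()
    raw = item.min_score + unit * (item.max_score - item.min_score)
    if not item.higher_is_worse:
        raw = item.max_score - (raw - item.min_score)
    return pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, n_visits)[mask],
            "genotype": np.repeat(genotype, n_visits)[mask],
            "visit_months": np.tile(visit_months, n)[mask],
            "item_id": item_id,
            "raw_score": np.round(raw.ravel()[mask]).astype(float),
            "unit_score": unit.ravel()[mask],
        }
    )


def generate_natural_history(
    params: SimulationParams, config: ScaleConfig | None = None
) -> LongitudinalCohort:
    """Simulate an observational natural-history cohort.

    Deterministic for a fixed ``params.seed``.
    """
    params.validate()
    config = config or default_config()
    rng = np.random.default_rng(params.seed)
    visit_months = np.asarray(sorted(params.visit_schedule_months), dtype=float)
    df = _simulate_subjects(
        params, rng, params.n_subjects, np.ones(params.n_subjects), visit_months, config, "NH"
    )
    return LongitudinalCohort(df, config, label=f"synthetic-nh-seed{params.seed}")


def generate_trial(
    params: TrialParams, config: ScaleConfig | None = None
) -> LongitudinalCohort:
    """Simulate a balanced two-arm placebo-controlled trial.

    The treated arm's progression slope is ``(1 - slowing_fraction)`` times
    placebo's; arm labels are stored in the cohort's ``arm`` column.
    """
    params.validate()
    config = config or default_config()
    rng = np.random.default_rng(params.seed)
    visit_months = np.asarray(
        sorted(w * WEEKS_TO_MONTHS for w in params.visit_schedule_weeks), dtype=float
    )
    n = 2 * params.n_per_arm
    arms = np.array(["placebo"] * params.n_per_arm + ["treated"] * params.n_per_arm)
    multiplier = np.where(arms == "treated", 1.0 - params.slowing_fraction, 1.0)
    df = _simulate_subjects(params, rng, n, multiplier, visit_months, config, "TR")
    arm_lookup = dict(zip([f"TR{i:05d}" for i in range(n)], arms))
    df["arm"] = df["subject_id"].map(arm_lookup)
    return LongitudinalCohort(df, config, label=f"synthetic-trial-seed{params.seed}")


def with_seed(params: SimulationParams, seed: int):
    """Copy ``params`` with a new seed (dataclass-generic)."""
    return replace(params, seed=seed)
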