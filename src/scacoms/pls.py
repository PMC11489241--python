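"""PLS1 regression of time on unit scores, VIP screening, and composite scoring.

The composite is derived by regressing *time from baseline* (the measure of
disease progression during the linear phase) on the candidate items' unit
scores with single-response partial least squares (PLS1).  PLS balances
explained predictor variation against explained response variation, so the
latent components it extracts are both stable and responsive; the regression
coefficients then serve as item weights, and each retained item's share of
the total weight is its percent contribution to the composite.

Item selection follows Wold's criterion on the Variable Importance in
Projection (VIP): items with VIP <= 0.5 are dropped, unless they are flagged
clinically relevant, their VIP approximates the threshold, and they carry
more than 5% of the composite weight.  Items that acquire a negative
coefficient are removed first (most negative first), one at a time, with a
refit after each removal.

Predictors are mean-centered but not variance-scaled: unit scores already
share the [0, 1] range, and leaving the natural spread in place is what
makes weight shares interpretable as percent contributions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, DerivationError, ParameterError, ScoringError
from .scale_data import LongitudinalCohort

__all__ = [
    "PLSFit",
    "DerivationConfig",
    "CompositeModel",
    "fit_pls1",
    "select_components",
    "compute_vip",
    "derive_composite",
    "percent_contributions",
    "score_composite",
    "score_cohort",
    "composite_design",
]


@dataclass
class PLSFit:
    """A fitted PLS1 model (NIPALS parameterization).

    ``weights`` W (p x A) has unit-norm columns; ``loadings`` P (p x A);
    ``response_loadings`` q (A,); ``score_norms`` holds t_a' t_a.  The
    regression vector ``beta = W (P'W)^-1 q`` acts on centered predictors.
    """

    n_components: int
    weights: np.ndarray
    loadings: np.ndarray
    response_loadings: np.ndarray
    score_norms: np.ndarray
    beta: np.ndarray
    predictor_means: np.ndarray
    response_mean: float
    constant_mask: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.response_mean + (np.asarray(X, float) - self.predictor_means) @ self.beta


def fit_pls1(X: np.ndarray, t: np.ndarray, n_components: int = 1) -> PLSFit:
    """NIPALS PLS1 of response ``t`` on predictor matrix ``X``.

    For a single response the NIPALS inner loop converges in one pass per
    component: w_a ∝ X_a' t_a (unit norm), scores s_a = X_a w_a, loadings
    p_a = X_a' s_a / s_a's_a, q_a = t_a' s_a / s_a's_a, then deflation of
    both blocks.  Constant predictor columns get weight 0.  If the residual
    predictor block is exhausted before ``n_components`` components, the fit
    is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    n, p = X.shape
    if t.shape[0] != n:
        raise ParameterError("X and t have incompatible shapes")
    if not 1 <= n_components <= p:
        raise ParameterError(f"n_components must be in [1, {p}]")
    if n <= n_components:
        raise ParameterError("need more rows than components")

    x_mean = X.mean(axis=0)
    t_mean = float(t.mean())
    Xa = X - x_mean
    ta = t - t_mean
    constant = Xa.std(axis=0) == 0.0
    Xa[:, constant] = 0.0

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    ss = np.zeros(n_components)

    A = n_components
    for a in range(n_components):
        w = Xa.T @ ta
        norm = np.linalg.norm(w)
        if norm < 1e-12 * max(1.0, np.abs(ta).sum()):
            A = a
            warnings.warn(
                f"predictor block exhausted after {A} component(s); "
                f"requested {n_components}",
                stacklevel=2,
            )
            break
        w = w / norm
        s = Xa @ w
        snorm = float(s @ s)
        W[:, a] = w
        P[:, a] = Xa.T @ s / snorm
        q[a] = float(ta @ s) / snorm
        ss[a] = snorm
        Xa = Xa - np.outer(s, P[:, a])
        ta = ta - q[a] * s

    if A == 0:
        raise AnalysisError("degenerate fit: response is uncorrelated with all predictors")
    W, P, q, ss = W[:, :A], P[:, :A], q[:A], ss[:A]
    beta = W @ np.linalg.solve(P.T @ W, q)
    beta[constant] = 0.0
    return PLSFit(
        n_components=A,
        weights=W,
        loadings=P,
        response_loadings=q,
        score_norms=ss,
        beta=beta,
        predictor_means=x_mean,
        response_mean=t_mean,
        constant_mask=constant,
    )


def select_components(X: np.ndarray, t: np.ndarray, a_max: int = 3) -> int:
    """Pick the component count by leave-one-out cross-validated PRESS.

    Returns the smallest A whose PRESS is within 5% of the minimum over
    1..a_max — parsimony over marginal gains.  Falls back to A = 1 with a
    warning when the sample is too small for leave-one-out.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    n, p = X.shape
    a_max = min(a_max, p)
    if n < a_max + 3:
        warnings.warn("sample too small for leave-one-out selection; using A=1", stacklevel=2)
        return 1
    press = np.zeros(a_max)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        for a in range(1, a_max + 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fit = fit_pls1(X[mask], t[mask], a)
                except (AnalysisError, ParameterError):
                    press[a - 1] += np.inf
                    continue
            press[a - 1] += float((t[i] - fit.predict(X[i][None, :])[0]) ** 2)
    best = float(press.min())
    for a in range(1, a_max + 1):
        if press[a - 1] <= 1.05 * best:
            return a
    return a_max  # pragma: no cover


def compute_vip(fit: PLSFit) -> np.ndarray:
    """Variable Importance in Projection for every predictor.

    VIP_j = sqrt( p * sum_a SS_a w_aj^2 / sum_a SS_a ) with
    SS_a = q_a^2 t_a't_a, the response variance explained by component a.
    Satisfies sum_j VIP_j^2 = p.
    """
    ssa = fit.response_loadings**2 * fit.score_norms
    total = ssa.sum()
    if total <= 0:
        raise AnalysisError("VIP undefined: no response variance explained")
    p = fit.weights.shape[0]
    return np.sqrt(p * (fit.weights**2 @ ssa) / total)


def percent_contributions(weights) -> np.ndarray:
    """Each weight's share of the total, in percent (sums to 100)."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ParameterError("percent contributions require strictly positive weights")
    return 100.0 * w / w.sum()


@dataclass
class DerivationConfig:
    """Thresholds and settings for the composite derivation loop.

    ``vip_threshold`` is Wold's criterion; ``vip_near`` operationalizes a
    VIP "approximating" the threshold for the clinical-override rule;
    ``contribution_min`` is the minimum percent weight share an override
    item must carry.  ``n_components=None`` selects A by leave-one-out
    PRESS once on the full design, then holds it fixed.
    """

    vip_threshold: float = 0.5
    vip_near: float = 0.45
    contribution_min: float = 5.0
    n_components: int | None = None
    a_max: int = 3


@dataclass
class CompositeModel:
    """A derived composite: retained items, weights, and the selection audit trail."""

    items: list[str]
    weights: dict[str, float]
    vip: dict[str, float]
    percent_contribution: dict[str, float]
    removal_log: list[tuple[str, str]]
    n_components: int
    config: DerivationConfig = field(default_factory=DerivationConfig)
    label: str = ""

    @property
    def total_weight(self) -> float:
        return float(sum(self.weights.values()))

    def to_json(self) -> str:
        doc = {
            "label": self.label,
            "items": self.items,
            "weights": self.weights,
            "vip": self.vip,
            "percent_contribution": self.percent_contribution,
            "removal_log": [list(r) for r in self.removal_log],
            "n_components": self.n_components,
            "config": {
                "vip_threshold": self.config.vip_threshold,
                "vip_near": self.config.vip_near,
                "contribution_min": self.config.contribution_min,
                "n_components": self.config.n_components,
                "a_max": self.config.a_max,
            },
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CompositeModel":
        doc = json.loads(text)
        return cls(
            items=list(doc["items"]),
            weights={k: float(v) for k, v in doc["weights"].items()},
            vip={k: float(v) for k, v in doc["vip"].items()},
            percent_contribution={k: float(v) for k, v in doc["percent_contribution"].items()},
            removal_log=[tuple(r) for r in doc["removal_log"]],
            n_components=int(doc["n_components"]),
            config=DerivationConfig(**doc.get("config", {})),
            label=doc.get("label", ""),
        )


def composite_design(
    cohort: LongitudinalCohort, candidates: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Build the pooled subject-visit design: X = unit scores, t = months.

    Rows are subject-visits complete on *all* candidates (complete-case per
    visit); every visit including baseline contributes a row.
    """
    wide = cohort.to_wide(candidates).dropna(how="any")
    if wide.empty:
        raise DerivationError("no subject-visit is complete on all candidate items")
    t = wide.index.get_level_values("visit_months").to_numpy(dtype=float)
    return wide.to_numpy(dtype=float), t


def derive_composite(
    cohort: LongitudinalCohort,
    candidates: list[str] | None = None,
    config: DerivationConfig | None = None,
    label: str = "",
) -> CompositeModel:
    """Run the full selection-and-weighting loop on an analytic cohort.

    Iterates: fit PLS1; while any coefficient is negative drop the most
    negative item and refit; apply the VIP screen (with the clinical
    override for near-threshold, clinically relevant, >5%-contributing
    items); repeat until the retained set is stable.  The final weights are
    the coefficients of the last refit.
    """
    config = config or DerivationConfig()
    candidates = list(candidates or cohort.items_present)
    if len(candidates) < 2:
        raise ParameterError("composite derivation needs at least 2 candidate items")

    X_full, t = composite_design(cohort, candidates)
    col = {item: j for j, item in enumerate(candidates)}
    override = {
        item: cohort.config.item(item).clinical_override for item in candidates
    }

    a_sel = config.n_components
    if a_sel is None:
        a_sel = select_components(X_full, t, config.a_max)

    selected = list(candidates)
    removal_log: list[tuple[str, str]] = []
    vip_record: dict[str, float] = {}

    def refit(items: list[str]) -> tuple[PLSFit, np.ndarray]:
        if not items:
            raise DerivationError(f"all candidates removed; log: {removal_log}")
        X = X_full[:, [col[i] for i in items]]
        a = min(a_sel, len(items))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_pls1(X, t, a)
        return fit, fit.beta

    while True:
        fit, beta = refit(selected)

        # One-at-a-time removal of negative coefficients, most negative first.
        while np.any(beta < 0):
            worst = selected[int(np.argmin(beta))]
            vip_here = compute_vip(fit)
            vip_record[worst] = float(vip_here[selected.index(worst)])
            removal_log.append((worst, "negative_coefficient"))
            selected = [i for i in selected if i != worst]
            fit, beta = refit(selected)

        vip = compute_vip(fit)
        for item, v in zip(selected, vip):
            vip_record[item] = float(v)
        contrib = 100.0 * beta / beta.sum() if beta.sum() > 0 else np.zeros_like(beta)

        drop = []
        for j, item in enumerate(selected):
            if vip[j] > config.vip_threshold:
                continue
            kept_by_override = (
                override[item]
                and vip[j] >= config.vip_near
                and contrib[j] > config.contribution_min
            )
            if not kept_by_override:
                drop.append(item)
        if not drop:
            break
        for item in drop:
            removal_log.append((item, "vip_below_threshold"))
        selected = [i for i in selected if i not in drop]
        if not selected:
            raise DerivationError(f"all candidates removed; log: {removal_log}")

    if np.any(beta <= 0):
        # A zero coefficient with VIP above threshold cannot be weighted.
        bad = [selected[j] for j in np.nonzero(beta <= 0)[0]]
        raise DerivationError(f"nonpositive final weights for {bad}")

    shares = percent_contributions(beta)
    return CompositeModel(
        items=list(selected),
        weights={i: float(b) for i, b in zip(selected, beta)},
        vip=vip_record,
        percent_contribution={i: float(c) for i, c in zip(selected, shares)},
        removal_log=removal_log,
        n_components=fit.n_components,
        config=config,
        label=label,
    )


def score_composite(unit_scores: dict[str, float], model: CompositeModel) -> float:
    """Weighted sum of unit scores over the model's retained items."""
    total = 0.0
    for item in model.items:
        if item not in unit_scores or unit_scores[item] is None:
            raise ScoringError(f"missing unit score for retained item {item!r}")
        total += model.weights[item] * float(unit_scores[item])
    return total


def score_cohort(
    cohort: LongitudinalCohort,
    model: CompositeModel,
    weights: dict[str, float] | None = None,
) -> "np.ndarray | object":
    """Composite score per subject-visit (complete-case rows only).

    Returns a pandas Series indexed by (subject_id, visit_months).  An
    alternative ``weights`` mapping (e.g. interchanged foreign weights) may
    override the model's own.
    """
    w = weights or model.weights
    items = list(w)
    wide = cohort.to_wide(items).dropna(how="any")
    if wide.empty:
        raise ScoringError("no subject-visit is complete on the model's items")
    wvec = np.asarray([w[i] for i in items], dtype=float)
    return wide @ wvec
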