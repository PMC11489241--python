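"""Cross-validation of the derived composite.

Two complementary checks of how much responsiveness survives outside the
training data:

* **Weight interchange** — score one cohort with the weights derived on the
  other and compare MSDRs.  When the foreign model contains an item the
  target cohort never measured, either drop that item's weight, or
  re-insert it into the target model's weight set at its original percent
  share (``redistribute_weights``).
* **Repeated k-fold** — randomly partition subjects into k folds, re-derive
  the full composite (selection loop included) on each training set, and
  compare train vs test MSDR; the average percent bias over all
  k x iterations estimates the expected degradation in a new sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, DerivationError, ParameterError, ScoringError
from .pls import CompositeModel, DerivationConfig, derive_composite
from .responsiveness import FollowUpRule, change_from_baseline, msdr
from .scale_data import LongitudinalCohort

__all__ = [
    "InterchangeResult",
    "KFoldResult",
    "interchange_weights",
    "redistribute_weights",
    "kfold_bias",
]


@dataclass
class InterchangeResult:
    source_model: str
    target_cohort: str
    policy: str
    original_msdr: float
    cross_validated_msdr: float
    items_used: list[str] = field(default_factory=list)


def redistribute_weights(
    weights: dict[str, float], new_item: str, new_item_share: float
) -> dict[str, float]:
    """Insert a missing item so it carries exactly ``new_item_share`` of the total.

    With existing total W and target share c, the inserted weight is
    W*c/(1-c); existing weights are untouched, so their relative
    proportions are preserved exactly.
    """
    if not (0.0 < new_item_share < 1.0):
        raise ParameterError("new_item_share must be strictly between 0 and 1")
    if new_item in weights:
        raise ParameterError(f"item {new_item!r} already present in the weight set")
    if any(w <= 0 for w in weights.values()):
        raise ParameterError("existing weights must be positive")
    total = sum(weights.values())
    out = dict(weights)
    out[new_item] = total * new_item_share / (1.0 - new_item_share)
    return out


def _composite_msdr(
    cohort: LongitudinalCohort,
    model: CompositeModel,
    weights: dict[str, float],
    rule: FollowUpRule,
) -> float:
    proxy = CompositeModel(
        items=list(weights),
        weights=dict(weights),
        vip={},
        percent_contribution={},
        removal_log=[],
        n_components=model.n_components,
        config=model.config,
        label=model.label,
    )
    return msdr(change_from_baseline(cohort, proxy, rule))


def interchange_weights(
    model: CompositeModel,
    cohort: LongitudinalCohort,
    policy: str = "drop_item",
    native_model: CompositeModel | None = None,
    redistribute_item: str | None = None,
    redistribute_share: float | None = None,
    follow_up_rule: FollowUpRule | None = None,
) -> InterchangeResult:
    """Score ``cohort`` with a foreign model's weights and compare MSDRs.

    ``original_msdr`` comes from ``native_model`` (the model derived on this
    cohort) when given, else from the foreign model itself — so
    interchanging a model with its own cohort reproduces the original MSDR
    exactly.

    Policies for foreign-model items the cohort lacks:

    * ``drop_item`` — discount them and use the remaining weights;
    * ``redistribute`` — requires ``redistribute_item``/``redistribute_share``
      naming a cohort item absent from the foreign model, inserted at its
      original share via :func:`redistribute_weights`.
    """
    rule = follow_up_rule or FollowUpRule()
    present = set(cohort.items_present)

    if policy == "drop_item":
        weights = {i: w for i, w in model.weights.items() if i in present}
        if not weights:
            raise ScoringError("no model item is measured in the target cohort")
    elif policy == "redistribute":
        if redistribute_item is None or redistribute_share is None:
            raise ParameterError("redistribute policy needs redistribute_item and _share")
        if redistribute_item not in present:
            raise ParameterError(f"{redistribute_item!r} is not measured in the cohort")
        unavailable = [i for i in model.weights if i not in present]
        if len(unavailable) > 1:
            raise ParameterError("redistribute supports at most one unavailable item")
        weights = {i: w for i, w in model.weights.items() if i in present}
        weights = redistribute_weights(weights, redistribute_item, redistribute_share)
    else:
        raise ParameterError(f"unknown interchange policy {policy!r}")

    cross = _composite_msdr(cohort, model, weights, rule)
    if native_model is not None:
        original = _composite_msdr(cohort, native_model, native_model.weights, rule)
    else:
        original = cross if set(weights) == set(model.weights) else _composite_msdr(
            cohort, model, {i: w for i, w in model.weights.items() if i in present}, rule
        )
    return InterchangeResult(
        source_model=model.label,
        target_cohort=cohort.label,
        policy=policy,
        original_msdr=original,
        cross_validated_msdr=cross,
        items_used=list(weights),
    )


@dataclass
class KFoldResult:
    k: int
    iterations: int
    estimates: pd.DataFrame  # iteration, fold, msdr_train, msdr_test, percent_bias
    average_percent_bias: float
    n_failed: int

    @property
    def n_estimates(self) -> int:
        return len(self.estimates)


def kfold_bias(
    cohort: LongitudinalCohort,
    candidates: list[str] | None = None,
    derivation_config: DerivationConfig | None = None,
    k: int = 5,
    iterations: int = 40,
    seed: int = 0,
    follow_up_rule: FollowUpRule | None = None,
) -> KFoldResult:
    """Repeated k-fold estimate of the composite MSDR's out-of-sample bias.

    Subjects (never individual visits) are partitioned; each fold's model is
    derived from scratch on the complementary training set.  Percent bias of
    one estimate is 100*(MSDR_test - MSDR_train)/MSDR_train, so negative
    values mean out-of-sample degradation.  Folds where derivation or an
    MSDR fails are flagged, excluded from the average, and counted.
    """
    if k < 2:
        raise ParameterError("k must be at least 2")
    rule = follow_up_rule or FollowUpRule()
    rng = np.random.default_rng(seed)
    subjects = np.asarray(cohort.subjects)
    if len(subjects) < 2 * k:
        raise ParameterError("cohort too small for the requested k")

    rows = []
    n_failed = 0
    for it in range(iterations):
        perm = rng.permutation(len(subjects))
        folds = np.array_split(perm, k)
        for fold_idx, test_pos in enumerate(folds):
            test_ids = set(subjects[test_pos])
            train = cohort.subset_subjects([s for s in subjects if s not in test_ids])
            test = cohort.subset_subjects(test_ids)
            try:
                model = derive_composite(train, candidates, derivation_config)
                m_train = msdr(change_from_baseline(train, model, rule))
                m_test = msdr(change_from_baseline(test, model, rule))
            except (DerivationError, ScoringError, AnalysisError):
                n_failed += 1
                continue
            rows.append(
                {
                    "iteration": it,
                    "fold": fold_idx,
                    "msdr_train": m_train,
                    "msdr_test": m_test,
                    "percent_bias": 100.0 * (m_test - m_train) / m_train,
                }
            )
    estimates = pd.DataFrame(rows)
    if estimates.empty:
        raise DerivationError("every fold failed during k-fold validation")
    return KFoldResult(
        k=k,
        iterations=iterations,
        estimates=estimates,
        average_percent_bias=float(estimates["percent_bias"].mean()),
        n_failed=n_failed,
    )
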