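"""Change from baseline and MSDR responsiveness for items and composites.

The MSDR (mean-to-standard-deviation ratio) of change from baseline is the
responsiveness index that drives the whole methodology: it is the mean CFB
at follow-up divided by the SD of the CFB, identical in form to the
standardized response mean (SRM).  A scale with higher MSDR needs fewer
subjects to detect a given fractional slowing of progression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, ParameterError
from .pls import CompositeModel, score_cohort
from .scale_data import LongitudinalCohort

__all__ = [
    "FollowUpRule",
    "ResponsivenessReport",
    "change_from_baseline",
    "msdr",
    "responsiveness_report",
]


@dataclass(frozen=True)
class FollowUpRule:
    """Which follow-up visit supplies the CFB for each subject.

    ``visits`` lists the qualifying follow-up times (months).  With
    ``mode="last"`` (default) each subject contributes the last of those
    visits at which they have a value; ``mode="fixed"`` requires the single
    visit in ``visits``.
    """

    visits: tuple[float, ...] = (12.0, 24.0)
    mode: str = "last"

    def pick(self, available: list[float]) -> float | None:
        qualifying = [v for v in self.visits if v in available]
        if not qualifying:
            return None
        if self.mode == "fixed" and len(self.visits) != 1:
            raise ParameterError("fixed follow-up rule requires exactly one visit")
        return qualifying[-1]


def _values_by_visit(
    cohort: LongitudinalCohort, target: "str | CompositeModel"
) -> pd.Series:
    """Per-(subject, visit) value of an item's unit score or a composite."""
    if isinstance(target, CompositeModel):
        return score_cohort(cohort, target)
    wide = cohort.to_wide([target]).dropna()
    return wide[target]


def change_from_baseline(
    cohort: LongitudinalCohort,
    target: "str | CompositeModel",
    follow_up_rule: FollowUpRule | None = None,
) -> pd.Series:
    """Per-subject CFB of an item (unit scale) or composite.

    Subjects lacking a baseline value or any qualifying follow-up are
    skipped (complete-case per visit); the result's ``attrs["n_skipped"]``
    records how many.
    """
    rule = follow_up_rule or FollowUpRule()
    if rule.mode == "fixed" and len(rule.visits) != 1:
        raise ParameterError("fixed follow-up rule requires exactly one visit")
    values = _values_by_visit(cohort, target)
    frame = values.rename("value").reset_index()
    baseline = frame[frame["visit_months"] == 0.0].set_index("subject_id")["value"]
    follow = frame[frame["visit_months"].isin(rule.visits)]
    follow = follow.sort_values("visit_months").groupby("subject_id")["value"].last()
    cfb = (follow - baseline).dropna()
    series = pd.Series(cfb, name="cfb").sort_index()
    series.attrs["n_skipped"] = frame["subject_id"].nunique() - len(series)
    return series


def msdr(cfb_values) -> float:
    """Mean CFB divided by the sample SD (n-1) of the CFB; sign preserved."""
    x = np.asarray(cfb_values, dtype=float)
    if x.size < 2:
        raise AnalysisError(f"MSDR needs at least 2 CFB values (got {x.size})")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise AnalysisError("MSDR undefined: zero SD of change from baseline")
    return float(x.mean()) / sd


@dataclass
class ResponsivenessReport:
    """Per-item and composite MSDRs with the n behind each entry."""

    item_msdr: dict[str, float]
    item_n: dict[str, int]
    composite_msdr: float | None = None
    composite_n: int = 0
    follow_up_rule: FollowUpRule = field(default_factory=FollowUpRule)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"target": item, "msdr": self.item_msdr[item], "n": self.item_n[item]}
            for item in self.item_msdr
        ]
        if self.composite_msdr is not None:
            rows.append(
                {"target": "composite", "msdr": self.composite_msdr, "n": self.composite_n}
            )
        return pd.DataFrame(rows)


def responsiveness_report(
    cohort: LongitudinalCohort,
    model: CompositeModel | None = None,
    items: list[str] | None = None,
    follow_up_rule: FollowUpRule | None = None,
) -> ResponsivenessReport:
    """MSDRs for each item (unit scale) and, if a model is given, the composite."""
    rule = follow_up_rule or FollowUpRule()
    items = items or cohort.items_present
    item_msdr: dict[str, float] = {}
    item_n: dict[str, int] = {}
    for item in items:
        cfb = change_from_baseline(cohort, item, rule)
        item_msdr[item] = msdr(cfb)
        item_n[item] = len(cfb)
    report = ResponsivenessReport(item_msdr=item_msdr, item_n=item_n, follow_up_rule=rule)
    if model is not None:
        cfb = change_from_baseline(cohort, model, rule)
        report.composite_msdr = msdr(cfb)
        report.composite_n = len(cfb)
    return report
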