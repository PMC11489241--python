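"""Scale items, cohort I/O, score standardization, and analytic-sample filtering.

The composite methodology works on *unit scores*: every rating-scale item is
mapped affinely onto [0, 1] with 0 the best possible state and 1 the worst,
so that items from heterogeneous scales (f-SARA 0-4, FARS functional stage
0-6, CGI-I 1-7) are directly comparable and a weighted sum of them is well
defined.

A :class:`LongitudinalCohort` stores long-format observations — one row per
(subject, visit, item) — together with the :class:`ScaleConfig` that defines
the items.  Natural-history SARA axial items can be rescaled to the 5-point
f-SARA grid through a configuration-driven monotone lookup table.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .errors import ConfigError, IntegrityError, ParseError, RangeError

__all__ = [
    "ItemDefinition",
    "ScaleConfig",
    "LongitudinalCohort",
    "SampleFilterReport",
    "standardize_item",
    "unit_to_raw",
    "map_sara_to_fsara",
    "read_cohort",
    "write_cohort",
    "filter_analytic_sample",
    "default_config",
    "proportional_sara_table",
    "load_config",
    "save_config",
]

COHORT_COLUMNS = ["subject_id", "genotype", "visit_months", "item_id", "score"]

WEEKS_TO_MONTHS = 12.0 / 52.0


@dataclass(frozen=True)
class ItemDefinition:
    """One rating-scale item.

    ``higher_is_worse`` states the clinical direction of the raw score;
    ``clinical_override`` marks items eligible for the near-threshold VIP
    retention rule during composite derivation.
    """

    item_id: str
    scale_id: str
    min_score: int
    max_score: int
    higher_is_worse: bool = True
    clinical_override: bool = False

    def __post_init__(self) -> None:
        if self.max_score <= self.min_score:
            raise ConfigError(
                f"item {self.item_id!r}: max_score must exceed min_score "
                f"({self.max_score} <= {self.min_score})"
            )

    @property
    def n_levels(self) -> int:
        return self.max_score - self.min_score + 1


@dataclass
class ScaleConfig:
    """Item inventory plus the SARA-to-f-SARA mapping tables.

    ``sara_to_fsara`` maps f-SARA item_id -> {SARA raw score: f-SARA raw
    score}; each table must be total and monotone nondecreasing over the
    SARA item's range.  ``cgi_baseline_value`` is the raw CGI-I score
    imputed at baseline (the scale rates change, so baseline has no
    observed value; the "no change" midpoint is the conventional anchor).
    """

    items: list[ItemDefinition]
    sara_to_fsara: dict[str, dict[int, int]] = field(default_factory=dict)
    cgi_baseline_value: int = 4

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for item in self.items:
            if item.item_id in seen:
                raise ConfigError(f"duplicate item_id {item.item_id!r} in configuration")
            seen.add(item.item_id)
        for item_id, table in self.sara_to_fsara.items():
            keys = sorted(table)
            if keys != list(range(keys[0], keys[-1] + 1)):
                raise ConfigError(f"sara_to_fsara table for {item_id!r} is not total")
            vals = [table[k] for k in keys]
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ConfigError(f"sara_to_fsara table for {item_id!r} is not monotone")

    def item(self, item_id: str) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise ConfigError(f"unknown item_id {item_id!r}")

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]


def standardize_item(raw_score: float, item: ItemDefinition) -> float:
    """Map a raw score onto the [0, 1] unit scale (0 = best, 1 = worst)."""
    if not (item.min_score <= raw_score <= item.max_score):
        raise RangeError(
            f"raw score {raw_score} outside [{item.min_score}, {item.max_score}] "
            f"for item {item.item_id!r}"
        )
    u = (raw_score - item.min_score) / (item.max_score - item.min_score)
    return u if item.higher_is_worse else 1.0 - u


def unit_to_raw(unit_score: float, item: ItemDefinition) -> float:
    """Inverse of :func:`standardize_item` (continuous; no grid rounding)."""
    u = unit_score if item.higher_is_worse else 1.0 - unit_score
    return item.min_score + u * (item.max_score - item.min_score)


def proportional_sara_table(sara_max: int, fsara_max: int = 4) -> dict[int, int]:
    """Default proportional SARA->f-SARA lookup: round(raw * fsara_max / sara_max).

    A documented stand-in for the scale authors' exact rescaling table; it is
    monotone and maps best-to-best, worst-to-worst.
    """
    return {r: round(r * fsara_max / sara_max) for r in range(sara_max + 1)}


def map_sara_to_fsara(raw_sara: float, item_id: str, config: ScaleConfig) -> int:
    """Rescale a SARA axial-item raw score onto the 5-point f-SARA grid."""
    table = config.sara_to_fsara.get(item_id)
    if table is None:
        raise ConfigError(f"no SARA->f-SARA table for item {item_id!r}")
    key = int(raw_sara)
    if key != raw_sara or key not in table:
        raise ConfigError(
            f"SARA score {raw_sara} has no lookup entry for item {item_id!r}"
        )
    return table[key]


def default_config() -> ScaleConfig:
    """The shipped scale inventory: f-SARA, FARS functional stage, CGI-I.

    f-SARA scores gait, stance, sitting and speech 0-4 (higher = worse);
    FARS-FUNC is a single 0-6 disability stage; CGI-I rates global change
    1-7 (1 = very much improved, 7 = very much worse).  CGI carries the
    clinical override flag: a global-impression item captures changes the
    itemized scales miss and is retained near the VIP threshold.
    """
    items = [
        ItemDefinition("fsara_gait", "fsara", 0, 4),
        ItemDefinition("fsara_stance", "fsara", 0, 4),
        ItemDefinition("fsara_sitting", "fsara", 0, 4),
        ItemDefinition("fsara_speech", "fsara", 0, 4, clinical_override=True),
        ItemDefinition("fars_func", "fars_func", 0, 6, clinical_override=True),
        ItemDefinition("cgi", "cgi", 1, 7, clinical_override=True),
    ]
    sara = {
        "fsara_gait": proportional_sara_table(8),
        "fsara_stance": proportional_sara_table(8),
        "fsara_sitting": proportional_sara_table(6),
        "fsara_speech": proportional_sara_table(6),
    }
    return ScaleConfig(items=items, sara_to_fsara=sara)


class LongitudinalCohort:
    """Long-format (subject x visit x item) observations with unit scores.

    ``df`` columns: subject_id, genotype, visit_months, item_id, raw_score,
    unit_score, and optionally ``arm`` for two-arm trial cohorts.
    """

    def __init__(self, df: pd.DataFrame, config: ScaleConfig, label: str = "") -> None:
        required = {"subject_id", "genotype", "visit_months", "item_id", "raw_score", "unit_score"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigError(f"cohort frame missing columns: {sorted(missing)}")
        unknown = set(df["item_id"]) - set(config.item_ids)
        if unknown:
            raise ConfigError(f"cohort contains unknown item_ids: {sorted(unknown)}")
        dup = df.duplicated(subset=["subject_id", "visit_months", "item_id"])
        if dup.any():
            row = df[dup].iloc[0]
            raise IntegrityError(
                "duplicate observation for "
                f"({row.subject_id!r}, {row.visit_months}, {row.item_id!r})"
            )
        if ((df["unit_score"] < 0) | (df["unit_score"] > 1)).any():
            raise RangeError("unit scores must lie in [0, 1]")
        if (df["visit_months"] < 0).any():
            raise RangeError("visit times must be nonnegative")
        self.df = df.reset_index(drop=True)
        self.config = config
        self.label = label

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_arms(self) -> bool:
        return "arm" in self.df.columns

    @property
    def subjects(self) -> list[str]:
        return sorted(self.df["subject_id"].unique())

    @property
    def items_present(self) -> list[str]:
        present = set(self.df["item_id"])
        return [i for i in self.config.item_ids if i in present]

    @property
    def visit_times(self) -> list[float]:
        return sorted(self.df["visit_months"].unique())

    def to_wide(self, items: list[str] | None = None, values: str = "unit_score") -> pd.DataFrame:
        """Pivot to one row per (subject, visit); columns are item scores.

        Rows with any missing item among ``items`` are retained with NaN —
        complete-case handling is the caller's decision.
        """
        items = items or self.items_present
        sub = self.df[self.df["item_id"].isin(items)]
        wide = sub.pivot_table(
            index=["subject_id", "visit_months"], columns="item_id", values=values,
            aggfunc="first",
        )
        return wide.reindex(columns=items)

    def arm_of(self) -> pd.Series:
        """Subject -> arm lookup for trial cohorts."""
        if not self.has_arms:
            raise ConfigError(f"cohort {self.label!r} has no arm labels")
        return self.df.groupby("subject_id")["arm"].first()

    def subset_subjects(self, subject_ids) -> "LongitudinalCohort":
        keep = self.df[self.df["subject_id"].isin(set(subject_ids))].copy()
        return LongitudinalCohort(keep, self.config, label=self.label)


def read_cohort(path, config: ScaleConfig) -> LongitudinalCohort:
    """Read a delimited cohort file and standardize every score.

    Expected header: ``subject_id,genotype,visit_months,item_id,score``
    (plus an optional trailing ``arm`` column for trial cohorts).
    """
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(COHORT_COLUMNS) <= set(reader.fieldnames):
            raise ParseError(f"{path}: header must contain {COHORT_COLUMNS}")
        has_arm = "arm" in reader.fieldnames
        for lineno, rec in enumerate(reader, start=2):
            try:
                item = config.item(rec["item_id"])
                raw = float(rec["score"])
                row = {
                    "subject_id": rec["subject_id"],
                    "genotype": rec["genotype"],
                    "visit_months": float(rec["visit_months"]),
                    "item_id": item.item_id,
                    "raw_score": raw,
                    "unit_score": standardize_item(raw, item),
                }
            except ConfigError:
                raise
            except (RangeError, KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if has_arm:
                row["arm"] = rec["arm"]
            rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return LongitudinalCohort(df, config, label=str(path))


def write_cohort(cohort: LongitudinalCohort, path) -> None:
    """Write the standard delimited cohort file (raw scores, not unit scores)."""
    cols = COHORT_COLUMNS + (["arm"] if cohort.has_arms else [])
    out = cohort.df.rename(columns={"raw_score": "score"})[cols]
    buf = io.StringIO()
    out.to_csv(buf, index=False, lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


@dataclass
class SampleFilterReport:
    n_input: int
    n_retained: int
    n_dropped_gait: int
    n_dropped_incomplete: int


def filter_analytic_sample(
    cohort: LongitudinalCohort,
    gait_min: int = 1,
    gait_max: int = 7,
    required_visits: set[float] = frozenset({12.0, 24.0}),
    gait_item: str = "fsara_gait",
    items: list[str] | None = None,
) -> tuple[LongitudinalCohort, SampleFilterReport]:
    """Restrict a cohort to the analytic sample used for composite derivation.

    Retains subjects whose baseline gait raw score lies in
    [``gait_min``, ``gait_max``] and who have complete data on ``items``
    (default: every item present anywhere in the cohort) at baseline and at
    one or more of ``required_visits``.
    """
    if gait_item not in cohort.items_present:
        raise ConfigError(f"cohort has no gait item {gait_item!r}")
    items = items or cohort.items_present
    wide = cohort.to_wide(items)
    raw_gait = cohort.to_wide([gait_item], values="raw_score")[gait_item]

    n_gait_dropped = 0
    n_incomplete = 0
    keep: list[str] = []
    for sid, grp in wide.groupby(level="subject_id"):
        visits = grp.droplevel("subject_id")
        if 0.0 not in visits.index:
            n_incomplete += 1
            continue
        g = raw_gait.get((sid, 0.0))
        if g is None or pd.isna(g) or not (gait_min <= g <= gait_max):
            n_gait_dropped += 1
            continue
        complete = visits.dropna(how="any").index
        if 0.0 not in complete:
            n_incomplete += 1
            continue
        if not any(v in complete for v in required_visits):
            n_incomplete += 1
            continue
        keep.append(sid)

    report = SampleFilterReport(
        n_input=len(wide.index.get_level_values("subject_id").unique()),
        n_retained=len(keep),
        n_dropped_gait=n_gait_dropped,
        n_dropped_incomplete=n_incomplete,
    )
    return cohort.subset_subjects(keep), report


def save_config(config: ScaleConfig, path) -> None:
    doc = {
        "items": [
            {
                "item_id": it.item_id,
                "scale_id": it.scale_id,
                "min_score": it.min_score,
                "max_score": it.max_score,
                "higher_is_worse": it.higher_is_worse,
                "clinical_override": it.clinical_override,
            }
            for it in config.items
        ],
        "sara_to_fsara": {k: dict(v) for k, v in config.sara_to_fsara.items()},
        "cgi_baseline_value": config.cgi_baseline_value,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> ScaleConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    try:
        items = [ItemDefinition(**rec) for rec in doc["items"]]
        tables = {
            k: {int(a): int(b) for a, b in v.items()}
            for k, v in doc.get("sara_to_fsara", {}).items()
        }
        return ScaleConfig(
            items=items,
            sara_to_fsara=tables,
            cgi_baseline_value=int(doc.get("cgi_baseline_value", 4)),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: malformed scale configuration: {exc}") from exc
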