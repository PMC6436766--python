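"""Dataset validation: per-table invariants and referential integrity.

Validation is report-based: :func:`validate_dataset` never raises, it returns
a :class:`ValidationReport` listing every violation found, so a messy field
dataset can be triaged in one pass.  Callers that want fail-fast behaviour
(e.g. the reader) use :meth:`ValidationReport.raise_if_violations`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Dataset, ENUM_VALUES, ReferentialError, TABLE_SCHEMAS


@dataclass(frozen=True)
class Violation:
    table: str
    rule: str
    message: str
    rows: tuple = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" (rows {list(self.rows)})" if self.rows else ""
        return f"[{self.table}] {self.rule}: {self.message}{loc}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, table: str, rule: str, message: str, rows=()) -> None:
        self.violations.append(Violation(table, rule, message, tuple(rows)))

    def raise_if_violations(self) -> None:
        if self.ok:
            return
        first = self.violations[0]
        summary = "; ".join(str(v) for v in self.violations[:5])
        if len(self.violations) > 5:
            summary += f"; ... {len(self.violations) - 5} more"
        exc_type = ReferentialError if first.rule == "foreign_key" else ValueError
        raise exc_type(f"dataset failed validation: {summary}")


def _check_enum(report, table, df, column, enum_name):
    allowed = set(ENUM_VALUES[enum_name])
    bad = ~df[column].isin(allowed)
    if bad.any():
        report.add(
            table,
            "enum",
            f"column {column!r} has token(s) outside {sorted(allowed)}: "
            f"{sorted(df.loc[bad, column].unique())}",
            df.index[bad],
        )


def _check_unique(report, table, df, columns, rule="unique"):
    dup = df.duplicated(subset=columns, keep=False)
    if dup.any():
        report.add(
            table,
            rule,
            f"duplicate value(s) of {columns}",
            df.index[dup],
        )


def _check_fk(report, table, df, column, valid, target):
    bad = ~df[column].isin(valid)
    if bad.any():
        report.add(
            table,
            "foreign_key",
            f"column {column!r} references {target} absent from the dataset: "
            f"{sorted(df.loc[bad, column].unique())[:10]}",
            df.index[bad],
        )


def validate_dataset(dataset: Dataset) -> ValidationReport:
    """Check every table invariant and all foreign keys; return the report."""
    report = ValidationReport()

    islands = dataset.islands
    _check_unique(report, "islands", islands, ["island_id"])
    if (islands["area_ha"] < 0).any():
        report.add("islands", "non_negative", "area_ha must be >= 0",
                   islands.index[islands["area_ha"] < 0])
    if (islands["human_population"] < 0).any():
        report.add("islands", "non_negative", "human_population must be >= 0",
                   islands.index[islands["human_population"] < 0])

    species = dataset.species
    _check_unique(report, "species", species, ["species_id"])
    _check_enum(report, "species", species, "taxon_class", "taxon_class")
    _check_enum(report, "species", species, "iucn_category", "iucn_category")
    _check_enum(report, "species", species, "insularity", "insularity")
    blank_family = species["family"].astype(str).str.strip() == ""
    if blank_family.any():
        report.add("species", "family_nonempty",
                   "family must be non-empty (it drives impact imputation)",
                   species.index[blank_family])
    seabird_nonbird = species["seabird_flag"].astype(bool) & (species["taxon_class"] != "bird")
    if seabird_nonbird.any():
        report.add("species", "seabird_flag_birds_only",
                   "seabird_flag set on a non-bird", species.index[seabird_nonbird])

    island_ids = set(islands["island_id"])
    species_ids = set(species["species_id"])

    breeding = dataset.breeding
    _check_enum(report, "breeding", breeding, "breeding_status", "breeding_status")
    _check_unique(report, "breeding", breeding, ["species_id", "island_id"])
    _check_fk(report, "breeding", breeding, "species_id", species_ids, "species")
    _check_fk(report, "breeding", breeding, "island_id", island_ids, "islands")

    pops = dataset.invasive_populations
    _check_enum(report, "invasive_populations", pops, "presence", "presence")
    _check_enum(report, "invasive_populations", pops, "feral_status", "feral_status")
    _check_unique(report, "invasive_populations", pops, ["invasive_id", "island_id"])
    _check_fk(report, "invasive_populations", pops, "island_id", island_ids, "islands")

    inter = dataset.interactions
    _check_enum(report, "interactions", inter, "impact_class", "impact_class")
    _check_unique(report, "interactions", inter, ["invasive_id", "species_id", "island_id"])
    _check_fk(report, "interactions", inter, "species_id", species_ids, "species")
    _check_fk(report, "interactions", inter, "island_id", island_ids, "islands")
    pop_keys = set(zip(pops["invasive_id"], pops["island_id"]))
    orphan = [
        idx
        for idx, (v, i) in zip(inter.index, zip(inter["invasive_id"], inter["island_id"]))
        if (v, i) not in pop_keys
    ]
    if orphan:
        report.add("interactions", "foreign_key",
                   "impact record for an invasive population not in the dataset", orphan)

    rules = dataset.feasibility_rules
    _check_unique(report, "feasibility_rules", rules, ["invasive_group"],
                  rule="one_rule_per_group")
    if (rules["max_area_ha"] <= 0).any():
        report.add("feasibility_rules", "positive",
                   "max_area_ha must be > 0 (or 'inf')",
                   rules.index[rules["max_area_ha"] <= 0])
    if (rules["max_human_population"] < 0).any():
        report.add("feasibility_rules", "non_negative",
                   "max_human_population must be >= 0 (or 'inf')",
                   rules.index[rules["max_human_population"] < 0])

    experts = dataset.expert_assessments
    _check_enum(report, "expert_assessments", experts, "timeframe", "timeframe")
    _check_fk(report, "expert_assessments", experts, "island_id", island_ids, "islands")
    if (experts["years_experience"] < 0).any():
        report.add("expert_assessments", "non_negative",
                   "years_experience must be >= 0",
                   experts.index[experts["years_experience"] < 0])

    return report
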