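"""Benefit summaries, sensitivity scenarios, masking and formatting.

A (species, island) pair "benefits" from eradication when removing the
technically feasible invasive populations lowers the species' maximum impact
severity on that island.  Summaries count benefiting populations (pairs),
distinct species, islands and countries, with birds split into seabirds and
landbirds for reporting (the split never affects scores).

Island names flagged sensitive — or small (<100 ha) islands holding a
breeding reptile — are masked in outputs to avoid aiding wildlife
trafficking; masking changes names only, never counts or scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .impacts import enumerate_interactions, impute_impacts, severity_matrix
from .model import Dataset

MASKED_NAME = "unknown"

#: Area below which an island counts as small, both for the reptile masking
#: rule and the low-complexity (low-cost) flag.  Strictly below.
SMALL_ISLAND_HA = 100.0


@dataclass(frozen=True)
class BenefitSummary:
    """Counts of what a set of islands' eradications would protect."""

    label: str
    n_islands: int
    n_populations: int  # species x island pairs
    n_species: int  # distinct species
    n_countries: int
    by_taxon_populations: dict
    by_taxon_species: dict

    def as_row(self) -> dict:
        row = {
            "label": self.label,
            "n_islands": self.n_islands,
            "n_populations": self.n_populations,
            "n_species": self.n_species,
            "n_countries": self.n_countries,
        }
        for taxon in sorted(self.by_taxon_populations):
            row[f"populations_{taxon}"] = self.by_taxon_populations[taxon]
            row[f"species_{taxon}"] = self.by_taxon_species[taxon]
        return row


def _infeasible_keys(feasibility_flags: pd.DataFrame) -> set:
    infeasible = feasibility_flags.loc[~feasibility_flags["feasible"].astype(bool)]
    return set(zip(infeasible["invasive_id"], infeasible["island_id"]))


def benefit_records(
    dataset: Dataset, feasibility_flags: pd.DataFrame, island_set
) -> pd.DataFrame:
    """(species, island) pairs whose severity drops when feasible populations
    are removed, restricted to islands in *island_set*."""
    islands = set(island_set)
    z_all = severity_matrix(dataset, None).set_index(["species_id", "island_id"])["z"]
    z_inf = severity_matrix(dataset, _infeasible_keys(feasibility_flags)).set_index(
        ["species_id", "island_id"]
    )["z"]
    z_inf = z_inf.reindex(z_all.index, fill_value=0)
    pairs = z_all.index[(z_all > z_inf)].to_frame(index=False)
    pairs = pairs[pairs["island_id"].isin(islands)]
    return pairs.sort_values(["island_id", "species_id"]).reset_index(drop=True)


def _taxon_label(row) -> str:
    if row["taxon_class"] == "bird":
        return "seabird" if row["seabird_flag"] else "landbird"
    return row["taxon_class"]


def summarize(pairs: pd.DataFrame, dataset: Dataset, label: str) -> BenefitSummary:
    """Summarize benefiting pairs: population, species, island and country
    counts plus a per-taxon breakdown (birds split seabird/landbird)."""
    species = dataset.species.set_index("species_id")
    taxa = [
        _taxon_label(species.loc[s]) for s in pairs["species_id"]
    ]
    tagged = pairs.assign(taxon=taxa)
    by_pop = tagged.groupby("taxon").size().to_dict()
    by_sp = tagged.groupby("taxon")["species_id"].nunique().to_dict()
    countries = dataset.islands.set_index("island_id")["country"]
    return BenefitSummary(
        label=label,
        n_islands=int(pairs["island_id"].nunique()),
        n_populations=int(len(pairs)),
        n_species=int(pairs["species_id"].nunique()),
        n_countries=int(pairs["island_id"].map(countries).nunique()),
        by_taxon_populations=by_pop,
        by_taxon_species=by_sp,
    )


def summaries_table(summaries) -> pd.DataFrame:
    """Stack BenefitSummary rows into one DataFrame with a stable column order."""
    rows = [s.as_row() for s in summaries]
    df = pd.DataFrame(rows)
    fixed = ["label", "n_islands", "n_populations", "n_species", "n_countries"]
    extra = sorted(c for c in df.columns if c not in fixed)
    return df.loc[:, fixed + extra].fillna(0)


def low_complexity_flags(
    dataset: Dataset, feasibility_flags: pd.DataFrame, island_set
) -> pd.Series:
    """Flag islands whose eradication project should be comparatively cheap:
    small (<100 ha, strictly), uninhabited, and needing only one or two
    invasive mammal species removed to deliver a benefit.

    Counted are distinct feasible invasive species with a positive (recorded
    or imputed) impact on at least one breeding highly threatened vertebrate.
    Returns a boolean Series indexed by island_id over *island_set*.
    """
    islands = sorted(set(island_set))
    cand = impute_impacts(enumerate_interactions(dataset), dataset)
    feasible_keys = set(
        zip(
            feasibility_flags.loc[feasibility_flags["feasible"].astype(bool), "invasive_id"],
            feasibility_flags.loc[feasibility_flags["feasible"].astype(bool), "island_id"],
        )
    )
    in_feasible = np.fromiter(
        ((v, i) in feasible_keys for v, i in zip(cand["invasive_id"], cand["island_id"])),
        dtype=bool,
        count=len(cand),
    )
    harmful = cand[(cand["z"] > 0).to_numpy() & in_feasible]
    n_beneficial = harmful.groupby("island_id")["invasive_id"].nunique()
    meta = dataset.islands.set_index("island_id")
    out = {}
    for island_id in islands:
        row = meta.loc[island_id]
        k = int(n_beneficial.get(island_id, 0))
        out[island_id] = bool(
            row["area_ha"] < SMALL_ISLAND_HA
            and row["human_population"] == 0
            and k in (1, 2)
        )
    return pd.Series(out, name="low_complexity", dtype=bool)


def sensitive_island_ids(dataset: Dataset) -> set:
    """Islands whose names must be masked: expert-flagged sensitive locations,
    or <100 ha with at least one breeding reptile."""
    islands = dataset.islands
    reptiles = set(
        dataset.species.loc[dataset.species["taxon_class"] == "reptile", "species_id"]
    )
    reptile_islands = set(
        dataset.breeding.loc[dataset.breeding["species_id"].isin(reptiles), "island_id"]
    )
    flagged = islands["sensitive"].astype(bool) | (
        (islands["area_ha"] < SMALL_ISLAND_HA)
        & islands["island_id"].isin(reptile_islands)
    )
    return set(islands.loc[flagged, "island_id"])


def mask_sensitive(rows: pd.DataFrame, dataset: Dataset) -> pd.DataFrame:
    """Replace the ``name`` of sensitive islands with "unknown" in an output
    table keyed by ``island_id``.  Ids are retained (counts key on ids), so no
    summary changes — only the printable name."""
    masked = rows.copy()
    if "name" not in masked.columns:
        return masked
    to_mask = masked["island_id"].isin(sensitive_island_ids(dataset))
    masked.loc[to_mask, "name"] = MASKED_NAME
    return masked


def rodent_scenario(dataset: Dataset) -> Dataset:
    """Sensitivity scenario: assume rodents are present wherever their status
    is unknown.

    Rodent populations flagged ``rodent_status_unknown`` are excluded from the
    base analysis; the scenario marks them confirmed present (clearing the
    flag), which brings them into scoring.  Returns a new dataset; the input
    is never mutated.  Idempotent, and island risk can only rise because a
    maximum over a superset never decreases.
    """
    out = dataset.copy()
    pops = out.invasive_populations
    flip = (pops["invasive_group"] == "rodent") & pops["rodent_status_unknown"].astype(bool)
    pops.loc[flip, "presence"] = "confirmed"
    pops.loc[flip, "rodent_status_unknown"] = False
    return out


def round_percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """100 * numerator / denominator, rounded half-away-from-zero.

    Half-away-from-zero matches how the headline percentages are conventionally
    printed (e.g. 111/1184 -> 9.4 at one decimal); banker's rounding would
    disagree on exact halves.
    """
    if denominator == 0:
        raise ValueError("round_percent: zero denominator")
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))
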