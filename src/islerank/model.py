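"""Domain model for island eradication prioritization.

The analysis operates on seven linked tables describing islands, the highly
threatened vertebrates (IUCN Critically Endangered or Endangered) breeding on
them, the non-native mammal populations present, recorded invasive-native
impact interactions, per-invasive-group eradication feasibility thresholds,
and expert assessments of the socio-political timeframe for starting an
eradication project.

Tables are held as :class:`pandas.DataFrame` objects inside a :class:`Dataset`
container.  Enumerated columns use lower-case canonical tokens, except IUCN
categories which keep their conventional upper-case codes (``CR``, ``EN``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Errors


class SchemaError(ValueError):
    """A table is missing a required column or has a malformed value."""


class ReferentialError(ValueError):
    """A record references an island, species or invasive that does not exist."""


class ConfigurationError(ValueError):
    """A required configuration entry (e.g. a feasibility rule) is absent."""


# ---------------------------------------------------------------------------
# Enumerated vocabularies

TAXON_CLASSES = ("amphibian", "reptile", "bird", "mammal")
IUCN_CATEGORIES = ("CR", "EN")
INSULARITY = ("insular", "insular_and_continental")
BREEDING_STATUSES = ("confirmed", "probable", "potential")
PRESENCE = ("confirmed", "suspected")
FERAL_STATUSES = ("feral", "domestic", "unknown")
IMPACT_CLASSES = ("confirmed", "suspected", "none", "unknown")
TIMEFRAMES = ("by2020", "by2030", "never", "unknown")

#: Severity score for each recorded impact class; ``unknown`` has no score and
#: is resolved by family-level imputation.
IMPACT_SCORES = {"confirmed": 2, "suspected": 1, "none": 0}

#: Ordering used when taking the most conservative (latest) timeframe.
TIMEFRAME_ORDER = {"by2020": 0, "by2030": 1, "never": 2}

#: Sentinel accepted in the feasibility-rules table for an unbounded threshold.
UNBOUNDED_TOKEN = "inf"


# ---------------------------------------------------------------------------
# Table schemas: column -> kind
# kinds: id, text, real, int, bool, enum:<name>

TABLE_SCHEMAS: dict[str, dict[str, str]] = {
    "islands": {
        "island_id": "id",
        "name": "text",
        "country": "text",
        "area_ha": "real",
        "human_population": "int",
        "sensitive": "bool",
    },
    "species": {
        "species_id": "id",
        "name": "text",
        "taxon_class": "enum:taxon_class",
        "seabird_flag": "bool",
        "family": "text",
        "iucn_category": "enum:iucn_category",
        "insularity": "enum:insularity",
    },
    "breeding": {
        "species_id": "id",
        "island_id": "id",
        "breeding_status": "enum:breeding_status",
    },
    "invasive_populations": {
        "invasive_id": "id",
        "invasive_group": "text",
        "island_id": "id",
        "presence": "enum:presence",
        "feral_status": "enum:feral_status",
        "rodent_status_unknown": "bool",
        "under_eradication": "bool",
    },
    "interactions": {
        "invasive_id": "id",
        "species_id": "id",
        "island_id": "id",
        "impact_class": "enum:impact_class",
    },
    "feasibility_rules": {
        "invasive_group": "text",
        "max_area_ha": "real_or_inf",
        "max_human_population": "real_or_inf",
    },
    "expert_assessments": {
        "island_id": "id",
        "expert_id": "id",
        "timeframe": "enum:timeframe",
        "years_experience": "int",
    },
}

ENUM_VALUES = {
    "taxon_class": TAXON_CLASSES,
    "iucn_category": IUCN_CATEGORIES,
    "insularity": INSULARITY,
    "breeding_status": BREEDING_STATUSES,
    "presence": PRESENCE,
    "feral_status": FERAL_STATUSES,
    "impact_class": IMPACT_CLASSES,
    "timeframe": TIMEFRAMES,
}


def empty_table(name: str) -> pd.DataFrame:
    """Return an empty, correctly-typed DataFrame for table *name*."""
    schema = TABLE_SCHEMAS[name]
    data: dict[str, pd.Series] = {}
    for col, kind in schema.items():
        if kind in ("real", "real_or_inf"):
            dtype = float
        elif kind == "int":
            dtype = np.int64
        elif kind == "bool":
            dtype = bool
        else:
            dtype = object
        data[col] = pd.Series([], dtype=dtype)
    return pd.DataFrame(data)


@dataclass
class Dataset:
    """Container for the seven analysis tables.

    All tables default to empty.  Foreign-key integrity and per-table
    invariants are checked by :func:`islerank.validate.validate_dataset`,
    not at construction time, so partially built datasets can be assembled
    incrementally (e.g. by the synthetic generator or in tests).
    """

    islands: pd.DataFrame = field(default_factory=lambda: empty_table("islands"))
    species: pd.DataFrame = field(default_factory=lambda: empty_table("species"))
    breeding: pd.DataFrame = field(default_factory=lambda: empty_table("breeding"))
    invasive_populations: pd.DataFrame = field(
        default_factory=lambda: empty_table("invasive_populations")
    )
    interactions: pd.DataFrame = field(default_factory=lambda: empty_table("interactions"))
    feasibility_rules: pd.DataFrame = field(
        default_factory=lambda: empty_table("feasibility_rules")
    )
    expert_assessments: pd.DataFrame = field(
        default_factory=lambda: empty_table("expert_assessments")
    )

    TABLE_NAMES = tuple(TABLE_SCHEMAS)

    def table(self, name: str) -> pd.DataFrame:
        if name not in TABLE_SCHEMAS:
            raise KeyError(f"unknown table {name!r}")
        return getattr(self, name)

    def copy(self) -> "Dataset":
        """Deep copy; scenario transforms use this to keep inputs immutable."""
        return Dataset(**{f.name: getattr(self, f.name).copy() for f in fields(self)})


def population_included(invasive_populations: pd.DataFrame) -> pd.Series:
    """Boolean mask of invasive populations contributing to scoring.

    Excluded are populations that are entirely domestic (farmed stock poses no
    threatening process) and rodent populations whose presence is unknown; the
    conservative feral assumption keeps ``feral_status`` in {feral, unknown}
    in.  Populations under ongoing eradication remain included because removal
    is not yet assured.  Excluded rows are retained in the table (audit trail)
    and merely masked out here.
    """
    df = invasive_populations
    return (df["feral_status"] != "domestic") & (~df["rodent_status_unknown"].astype(bool))
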