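"""Invasive-native interaction handling and the severity-of-impact matrix Z.

Every co-occurrence of an included invasive mammal population and a highly
threatened vertebrate breeding on the same island is an interaction candidate.
Candidates with a recorded impact keep that record (confirmed -> 2,
suspected -> 1, none -> 0).  Candidates with no record are filled by
family-level imputation: the invasive species is assumed to affect the native
species like the worst impact it has anywhere on any member of the same
taxonomic family; with no family evidence at all the impact is assumed zero.

The severity matrix Z holds, per (species, island), the maximum impact score
over the contributing invasive populations — "the most harmful invasive
species on a given island".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import Dataset, IMPACT_SCORES, population_included

#: Provenance labels, in tie-break priority order for the matrix entries.
PROVENANCE_PRIORITY = {"direct": 0, "imputed": 1, "assumed_zero": 2}

_CANDIDATE_COLUMNS = [
    "invasive_id",
    "invasive_group",
    "species_id",
    "island_id",
    "impact_class",
    "z",
    "provenance",
]


def _empty_candidates() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series([], dtype=object) for c in _CANDIDATE_COLUMNS})


def enumerate_interactions(dataset: Dataset) -> pd.DataFrame:
    """Cross every included invasive population with every breeding record on
    the same island; attach recorded impact classes where they exist.

    Excluded populations (entirely domestic, or rodents whose presence is
    unknown) produce no candidates.  Suspected presence counts the same as
    confirmed.  Returns a DataFrame with one row per candidate; ``z`` is the
    recorded score or NaN where the impact class is ``unknown`` or absent.
    """
    pops = dataset.invasive_populations
    pops = pops.loc[population_included(pops), ["invasive_id", "invasive_group", "island_id"]]
    breeding = dataset.breeding[["species_id", "island_id"]]
    cand = pops.merge(breeding, on="island_id", how="inner")
    if cand.empty:
        return _empty_candidates()
    cand = cand.merge(
        dataset.interactions[["invasive_id", "species_id", "island_id", "impact_class"]],
        on=["invasive_id", "species_id", "island_id"],
        how="left",
    )
    cand["impact_class"] = cand["impact_class"].fillna("unknown")
    cand["z"] = cand["impact_class"].map(IMPACT_SCORES).astype(float)
    cand["provenance"] = np.where(cand["z"].notna(), "direct", None)
    return cand.loc[:, _CANDIDATE_COLUMNS].reset_index(drop=True)


def family_impact_table(dataset: Dataset) -> pd.DataFrame:
    """Maximum recorded impact score per (invasive species, native family).

    Built from explicit interaction records only (unknown classes contribute
    nothing), maximizing over all islands globally: the imputation rule is
    taxonomic, not spatial.
    """
    inter = dataset.interactions
    inter = inter[inter["impact_class"].isin(IMPACT_SCORES)]
    if inter.empty:
        return pd.DataFrame({
            "invasive_id": pd.Series([], dtype=object),
            "family": pd.Series([], dtype=object),
            "family_z": pd.Series([], dtype=float),
        })
    scored = inter.assign(family_z=inter["impact_class"].map(IMPACT_SCORES).astype(float))
    scored = scored.merge(
        dataset.species[["species_id", "family"]], on="species_id", how="inner"
    )
    return (
        scored.groupby(["invasive_id", "family"], as_index=False)["family_z"].max()
    )


def impute_impacts(candidates: pd.DataFrame, dataset: Dataset) -> pd.DataFrame:
    """Fill unknown candidate impacts from the family impact table.

    Explicit records always win, including explicit "none"; only candidates
    whose ``z`` is still NaN are touched, so the operation is idempotent.
    Unknowns with no family evidence score 0 with provenance ``assumed_zero``.
    """
    out = candidates.copy()
    open_mask = out["z"].isna()
    if not open_mask.any():
        return out
    fam = out.loc[open_mask, ["invasive_id", "species_id"]].merge(
        dataset.species[["species_id", "family"]], on="species_id", how="left"
    )
    fam = fam.merge(family_impact_table(dataset), on=["invasive_id", "family"], how="left")
    imputed_z = fam["family_z"].to_numpy()
    out.loc[open_mask, "z"] = np.where(np.isnan(imputed_z), 0.0, imputed_z)
    out.loc[open_mask, "provenance"] = np.where(
        np.isnan(imputed_z), "assumed_zero", "imputed"
    )
    return out


def severity_matrix(dataset: Dataset, invasive_filter=None) -> pd.DataFrame:
    """Z matrix: per (species, island), the maximum impact over contributing
    invasive populations.

    ``invasive_filter`` selects which populations contribute: ``None`` means
    all included populations (current-risk scoring); a set of
    ``(invasive_id, island_id)`` keys restricts to those populations (e.g. the
    infeasible-to-eradicate ones for potential-risk scoring).  Pairs absent
    from the matrix are zero downstream.

    Returns a DataFrame with columns species_id, island_id, z (int), provenance;
    provenance is that of a candidate achieving the maximum (direct preferred
    over imputed over assumed_zero).
    """
    cand = impute_impacts(enumerate_interactions(dataset), dataset)
    if invasive_filter is not None:
        keys = set(invasive_filter)
        keep = [
            (v, i) in keys
            for v, i in zip(cand["invasive_id"], cand["island_id"])
        ]
        cand = cand.loc[keep]
    if cand.empty:
        return pd.DataFrame({
            "species_id": pd.Series([], dtype=object),
            "island_id": pd.Series([], dtype=object),
            "z": pd.Series([], dtype=np.int64),
            "provenance": pd.Series([], dtype=object),
        })
    cand = cand.assign(_prio=cand["provenance"].map(PROVENANCE_PRIORITY))
    cand = cand.sort_values(
        ["species_id", "island_id", "z", "_prio"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = cand.drop_duplicates(subset=["species_id", "island_id"], keep="first")
    out = best.loc[:, ["species_id", "island_id", "z", "provenance"]].reset_index(drop=True)
    out["z"] = out["z"].astype(np.int64)
    return out
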