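"""Conservation-risk scoring and island ranking.

Current Conservation Risk of island i is

    CCR_i = sum_s  E_s * I_s * Z_{s,i}

over the highly threatened vertebrates s breeding on i, where E is the
extinction-risk weight of the species' IUCN category, I its irreplaceability
(the reciprocal of the number of islands it breeds on) and Z the maximum
severity of impact of any invasive mammal on that island (2 confirmed,
1 suspected, 0 none).

Potential Conservation Risk (PCR) is the same sum with Z recomputed as if
every technically feasible invasive population had been eradicated — only
infeasible populations contribute.  Eradication Benefit EB = CCR - PCR is the
primary ranking statistic; islands with EB = 0 gain nothing from feasible
eradications and are reported separately, unranked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .impacts import severity_matrix
from .model import Dataset

#: EB values at or below this are treated as exactly zero (floating-point
#: noise absorption); everything above is a strictly positive benefit.
EB_TOLERANCE = 1e-12


@dataclass(frozen=True)
class ExtinctionRiskScheme:
    """Extinction-risk weights per IUCN category.

    The default scheme (0.5 CR / 0.05 EN) reflects the relative extinction
    risk implied by the quantitative Red List criteria thresholds; the linear
    scheme (4 / 3) is an ordinal alternative used for sensitivity analysis.
    """

    scheme_name: str
    cr_score: float
    en_score: float

    def score(self, iucn_category: str) -> float:
        if iucn_category == "CR":
            return self.cr_score
        if iucn_category == "EN":
            return self.en_score
        raise ValueError(
            f"no extinction-risk score for category {iucn_category!r}: "
            "only CR and EN species are in scope"
        )


SCHEMES = {
    "default": ExtinctionRiskScheme("default", 0.5, 0.05),
    "linear": ExtinctionRiskScheme("linear", 4.0, 3.0),
}


def get_scheme(scheme) -> ExtinctionRiskScheme:
    """Resolve a scheme name or pass an :class:`ExtinctionRiskScheme` through."""
    if isinstance(scheme, ExtinctionRiskScheme):
        return scheme
    try:
        return SCHEMES[scheme]
    except KeyError:
        raise ValueError(
            f"unknown extinction-risk scheme {scheme!r}; known: {sorted(SCHEMES)}"
        ) from None


def extinction_risk(iucn_category: str, scheme="default") -> float:
    """E score for one species category under the given scheme."""
    return get_scheme(scheme).score(iucn_category)


def irreplaceability(species_id: str, breeding: pd.DataFrame) -> float:
    """I = 1 / number of distinct islands the species breeds on.

    Continental populations are never counted — the breeding table only holds
    island records, so a species breeding both on islands and continents is
    scored from its island occurrences alone.
    """
    n = breeding.loc[breeding["species_id"] == species_id, "island_id"].nunique()
    if n == 0:
        raise ValueError(
            f"species {species_id!r} has no island breeding record; "
            "irreplaceability is undefined (species out of scope)"
        )
    return 1.0 / n


def irreplaceability_table(breeding: pd.DataFrame) -> pd.Series:
    """I for every species with at least one breeding record, as a Series."""
    counts = breeding.groupby("species_id")["island_id"].nunique()
    return 1.0 / counts


def _risk_sum(dataset: Dataset, scheme, invasive_filter) -> pd.Series:
    """Sum E*I*z per island over the given contributing populations; every
    island in the dataset appears, zero where nothing contributes."""
    scheme = get_scheme(scheme)
    zmat = severity_matrix(dataset, invasive_filter)
    islands = dataset.islands["island_id"]
    totals = pd.Series(0.0, index=pd.Index(islands, name="island_id"))
    if zmat.empty:
        return totals
    e_by_species = dataset.species.set_index("species_id")["iucn_category"].map(
        {"CR": scheme.cr_score, "EN": scheme.en_score}
    )
    i_by_species = irreplaceability_table(dataset.breeding)
    contrib = (
        zmat["species_id"].map(e_by_species).to_numpy()
        * zmat["species_id"].map(i_by_species).to_numpy()
        * zmat["z"].to_numpy()
    )
    per_island = pd.Series(contrib, index=zmat["island_id"]).groupby(level=0).sum()
    totals.loc[per_island.index] = per_island
    return totals


def compute_ccr(dataset: Dataset, scheme="default") -> pd.Series:
    """Current Conservation Risk per island (all included invasives contribute)."""
    return _risk_sum(dataset, scheme, invasive_filter=None)


def compute_pcr(dataset: Dataset, scheme="default", feasibility_flags=None) -> pd.Series:
    """Potential Conservation Risk per island.

    ``feasibility_flags`` is a DataFrame with columns invasive_id, island_id,
    feasible (see :func:`islerank.feasibility.assess_feasibility`).  All
    feasible populations on an island are removed concurrently; Z is the
    maximum over the remaining (infeasible) populations only.  If an island
    has no feasible population its PCR equals its CCR.
    """
    if feasibility_flags is None:
        raise ValueError("compute_pcr requires feasibility flags")
    infeasible = feasibility_flags.loc[~feasibility_flags["feasible"].astype(bool)]
    keys = set(zip(infeasible["invasive_id"], infeasible["island_id"]))
    return _risk_sum(dataset, scheme, invasive_filter=keys)


def eradication_benefit(ccr: pd.Series, pcr: pd.Series) -> pd.Series:
    """EB = CCR - PCR, per island; the island sets must match exactly."""
    if set(ccr.index) != set(pcr.index):
        raise KeyError("CCR and PCR cover different island sets")
    return ccr - pcr.reindex(ccr.index)


def score_islands(dataset: Dataset, scheme="default", feasibility_flags=None) -> pd.DataFrame:
    """Compute CCR, PCR, EB and the reduced-species count for every island.

    ``n_reduced`` counts the species on the island whose maximum impact
    severity drops when feasible populations are removed; it is used as a
    ranking tie-break and to enumerate benefiting populations.
    """
    ccr = compute_ccr(dataset, scheme)
    pcr = compute_pcr(dataset, scheme, feasibility_flags)
    eb = eradication_benefit(ccr, pcr)
    z_all = severity_matrix(dataset, None).set_index(["species_id", "island_id"])["z"]
    infeasible = feasibility_flags.loc[~feasibility_flags["feasible"].astype(bool)]
    keys = set(zip(infeasible["invasive_id"], infeasible["island_id"]))
    z_inf = severity_matrix(dataset, keys).set_index(["species_id", "island_id"])["z"]
    z_inf = z_inf.reindex(z_all.index, fill_value=0)
    reduced = (z_all > z_inf)
    n_reduced = (
        reduced[reduced]
        .reset_index()
        .groupby("island_id")
        .size()
        .reindex(ccr.index, fill_value=0)
        if reduced.any()
        else pd.Series(0, index=ccr.index)
    )
    return pd.DataFrame(
        {
            "island_id": ccr.index,
            "ccr": ccr.to_numpy(),
            "pcr": pcr.reindex(ccr.index).to_numpy(),
            "eb": eb.to_numpy(),
            "n_reduced": n_reduced.reindex(ccr.index).astype(int).to_numpy(),
        }
    ).reset_index(drop=True)


def rank_islands(scores: pd.DataFrame) -> pd.DataFrame:
    """Rank islands by descending EB.

    Ties break by higher CCR, then by more species with reduced severity,
    then island_id lexicographically (for reproducibility; the ranking rule
    beyond EB is a deterministic convention, not a biological statement).
    Islands whose EB is zero (within :data:`EB_TOLERANCE`) are excluded from
    the ranked list — their ``rank`` is null — and sorted after the ranked
    islands by id.
    """
    df = scores.copy()
    if "n_reduced" not in df.columns:
        df["n_reduced"] = 0
    positive = df["eb"] > EB_TOLERANCE
    ranked = df.loc[positive].sort_values(
        ["eb", "ccr", "n_reduced", "island_id"],
        ascending=[False, False, False, True],
        kind="mergesort",
    )
    ranked = ranked.assign(rank=np.arange(1, len(ranked) + 1))
    zero = df.loc[~positive].sort_values("island_id", kind="mergesort")
    zero = zero.assign(rank=pd.NA)
    out = pd.concat([ranked, zero], ignore_index=True)
    out["rank"] = out["rank"].astype("Int64")
    return out
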