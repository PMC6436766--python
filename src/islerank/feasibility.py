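"""Technical eradication feasibility and socio-political timeframe aggregation.

Technical feasibility is a coarse screen suitable for global comparisons:
an invasive population can be removed if its island falls at or below the
area and human-population thresholds of the population's invasive group
(rodent, cat, ungulate, ...).  Thresholds derive from the track record of
completed and in-progress eradications and are supplied as configuration —
there is no authoritative built-in table.

Socio-political feasibility is an expert judgement of when an eradication
project could be initiated: by 2020, by 2030, or not in the foreseeable
future.  Multiple experts may assess one island; agreement is taken as
consensus, disagreement resolves to the most conservative (latest) timeframe,
and islands with no informative assessment are an explicit data gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .model import ConfigurationError, Dataset, TIMEFRAME_ORDER
from .scoring import EB_TOLERANCE


@dataclass(frozen=True)
class TimeframeDecision:
    island_id: str
    timeframe: str  # by2020 | by2030 | never | unknown
    basis: str  # consensus | most_conservative | single_expert | no_response


def technically_feasible(population, island, rules: pd.DataFrame) -> bool:
    """True iff the island is within the population group's thresholds.

    ``population`` and ``island`` are mappings (e.g. DataFrame rows) carrying
    ``invasive_group`` and ``area_ha``/``human_population`` respectively.
    A missing rule for the group is a configuration error — no silent default.
    """
    group = population["invasive_group"]
    match = rules.loc[rules["invasive_group"] == group]
    if match.empty:
        raise ConfigurationError(
            f"no feasibility rule for invasive group {group!r}; "
            "every group present in the data needs a rule"
        )
    rule = match.iloc[0]
    return bool(
        island["area_ha"] <= rule["max_area_ha"]
        and island["human_population"] <= rule["max_human_population"]
    )


def assess_feasibility(dataset: Dataset) -> pd.DataFrame:
    """Apply the group rules to every invasive population.

    Returns the populations table plus a boolean ``feasible`` column.  All
    populations are assessed, including excluded (domestic) ones, since the
    flag is a property of island and group alone; scoring decides which
    populations matter.
    """
    pops = dataset.invasive_populations.copy()
    groups = set(pops["invasive_group"])
    known = set(dataset.feasibility_rules["invasive_group"])
    missing = sorted(groups - known)
    if missing:
        raise ConfigurationError(
            f"no feasibility rule for invasive group(s) {missing}; "
            "every group present in the data needs a rule"
        )
    merged = pops.merge(dataset.feasibility_rules, on="invasive_group", how="left")
    merged = merged.merge(
        dataset.islands[["island_id", "area_ha", "human_population"]],
        on="island_id",
        how="left",
    )
    pops["feasible"] = (
        (merged["area_ha"] <= merged["max_area_ha"])
        & (merged["human_population"] <= merged["max_human_population"])
    ).to_numpy()
    return pops


def aggregate_timeframes(assessments, island_id: str | None = None) -> TimeframeDecision:
    """Aggregate one island's expert timeframes into a single decision.

    ``assessments`` is an iterable of timeframe tokens (or a DataFrame slice
    with a ``timeframe`` column).  Unknown votes are ignored whenever at least
    one informative vote exists; no informative vote at all yields
    ``unknown`` / ``no_response``.  The result is independent of input order
    and idempotent (feeding the decision back in reproduces it).
    """
    if isinstance(assessments, pd.DataFrame):
        if island_id is None and "island_id" in assessments.columns and len(assessments):
            island_id = assessments["island_id"].iloc[0]
        tokens = list(assessments["timeframe"])
    else:
        tokens = list(assessments)
    informative = [t for t in tokens if t in TIMEFRAME_ORDER]
    if not informative:
        return TimeframeDecision(island_id, "unknown", "no_response")
    distinct = set(informative)
    if len(informative) == 1:
        return TimeframeDecision(island_id, informative[0], "single_expert")
    if len(distinct) == 1:
        return TimeframeDecision(island_id, informative[0], "consensus")
    latest = max(distinct, key=TIMEFRAME_ORDER.__getitem__)
    return TimeframeDecision(island_id, latest, "most_conservative")


def assign_timeframes(dataset: Dataset, ranked: pd.DataFrame):
    """Timeframe decisions for every island with positive eradication benefit.

    Only islands where EB > 0 are assessed (there is nothing to initiate
    elsewhere).  Returns ``(decisions, sets)`` where ``decisions`` is a list of
    :class:`TimeframeDecision` and ``sets`` maps each timeframe to the sorted
    list of island ids; the four sets partition the EB > 0 islands exactly.
    Islands in the ``unknown`` set are a priority data gap: they are excluded
    from headline results but must be reported.
    """
    beneficial = ranked.loc[ranked["eb"] > EB_TOLERANCE, "island_id"]
    by_island = dict(iter(dataset.expert_assessments.groupby("island_id")))
    decisions = []
    sets: dict[str, list[str]] = {"by2020": [], "by2030": [], "never": [], "unknown": []}
    for island_id in beneficial:
        votes = by_island.get(island_id)
        if votes is None:
            decision = TimeframeDecision(island_id, "unknown", "no_response")
        else:
            decision = aggregate_timeframes(votes, island_id)
        decisions.append(decision)
        sets[decision.timeframe].append(island_id)
    for key in sets:
        sets[key] = sorted(sets[key])
    return decisions, sets
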