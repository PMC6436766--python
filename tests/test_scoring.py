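"""E, I, CCR/PCR/EB and ranking."""

import numpy as np
import pandas as pd
import pytest

from islerank import (
    assess_feasibility,
    compute_ccr,
    compute_pcr,
    eradication_benefit,
    extinction_risk,
    generate_dataset,
    irreplaceability,
    oracle_scores,
    rank_islands,
    score_islands,
)

from conftest import (
    breeding,
    interaction,
    invasive,
    island,
    make_dataset,
    rule,
    small_params,
    species,
)


@pytest.mark.parametrize(
    "category,scheme,expected",
    [("CR", "default", 0.5), ("EN", "default", 0.05),
     ("CR", "linear", 4.0), ("EN", "linear", 3.0)],
)
def test_extinction_risk_weights(category, scheme, expected):
    assert extinction_risk(category, scheme) == expected


def test_extinction_risk_rejects_other_categories():
    with pytest.raises(ValueError):
        extinction_risk("VU", "default")


def test_irreplaceability_is_reciprocal_island_count():
    b = pd.DataFrame([breeding("s1", "a")] + [breeding("s2", i) for i in "abcd"])
    assert irreplaceability("s1", b) == 1.0
    assert irreplaceability("s2", b) == 0.25
    with pytest.raises(ValueError):
        irreplaceability("ghost", b)


def test_continental_population_ignored_in_irreplaceability():
    # a species also breeding on continents is scored from islands alone
    ds = make_dataset(
        islands=[island("a"), island("b")],
        species=[species("s1", insularity="insular_and_continental")],
        breeding=[breeding("s1", "a"), breeding("s1", "b")],
    )
    assert irreplaceability("s1", ds.breeding) == 0.5


def _one_triple(iucn="CR", impact="confirmed", n_islands=1):
    islands = [island(chr(ord("a") + k)) for k in range(n_islands)]
    return make_dataset(
        islands=islands,
        species=[species("s1", iucn_category=iucn)],
        breeding=[breeding("s1", isl["island_id"]) for isl in islands],
        invasive_populations=[invasive("rat", "a")],
        interactions=[interaction("rat", "s1", "a", impact)],
        feasibility_rules=[rule("rodent")],
    )


def test_ccr_hand_arithmetic():
    # CR single-island endemic with a confirmed impact: 0.5 * 1 * 2
    assert compute_ccr(_one_triple())["a"] == pytest.approx(1.0, abs=1e-15)
    # EN species on two islands, suspected impact: 0.05 * 0.5 * 1
    ds = _one_triple(iucn="EN", impact="suspected", n_islands=2)
    assert compute_ccr(ds)["a"] == pytest.approx(0.025, abs=1e-15)
    assert compute_ccr(ds)["b"] == 0.0


def test_island_with_no_impacts_scores_zero():
    ds = _one_triple(impact="none")
    assert compute_ccr(ds)["a"] == 0.0


def test_pcr_zero_when_everything_feasible():
    ds = _one_triple()
    flags = assess_feasibility(ds)  # unbounded rule -> feasible
    assert compute_pcr(ds, "default", flags)["a"] == 0.0


def test_pcr_equals_ccr_when_nothing_feasible():
    ds = _one_triple()
    ds.feasibility_rules.loc[0, ["max_area_ha", "max_human_population"]] = [1.0, 0.0]
    flags = assess_feasibility(ds)
    ccr = compute_ccr(ds)
    pcr = compute_pcr(ds, "default", flags)
    assert pcr["a"] == ccr["a"]
    assert eradication_benefit(ccr, pcr)["a"] == 0.0


def test_infeasible_invasive_keeps_severity_up():
    # feasible rat (z=2) plus infeasible cat (z=2): removing the rat changes
    # nothing, the island's PCR stays at CCR and EB is zero
    ds = make_dataset(
        islands=[island("a")],
        species=[species("s1")],
        breeding=[breeding("s1", "a")],
        invasive_populations=[invasive("rat", "a"),
                              invasive("cat", "a", invasive_group="cat")],
        interactions=[interaction("rat", "s1", "a", "confirmed"),
                      interaction("cat", "s1", "a", "confirmed")],
        feasibility_rules=[rule("rodent"),
                           rule("cat", max_area_ha=1.0, max_human_population=0)],
    )
    flags = assess_feasibility(ds)
    scores = score_islands(ds, "default", flags)
    assert scores.loc[0, "pcr"] == scores.loc[0, "ccr"] == 1.0
    assert scores.loc[0, "eb"] == 0.0


def test_eradication_benefit_requires_matching_islands():
    with pytest.raises(KeyError):
        eradication_benefit(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))


def test_ranking_descends_and_breaks_ties_by_ccr():
    scores = pd.DataFrame(
        {"island_id": ["b", "a", "c"], "ccr": [2.0, 3.0, 5.0],
         "pcr": [1.0, 2.0, 5.0], "eb": [1.0, 1.0, 0.0], "n_reduced": [1, 1, 0]}
    )
    ranked = rank_islands(scores)
    ordered = ranked.loc[ranked["rank"].notna()].sort_values("rank")
    assert list(ordered["island_id"]) == ["a", "b"]  # EB tie -> higher CCR first
    assert ranked.loc[ranked["island_id"] == "c", "rank"].isna().all()


def test_all_zero_benefit_means_empty_ranking():
    scores = pd.DataFrame(
        {"island_id": ["a", "b"], "ccr": [1.0, 0.0], "pcr": [1.0, 0.0],
         "eb": [0.0, 0.0], "n_reduced": [0, 0]}
    )
    ranked = rank_islands(scores)
    assert ranked["rank"].isna().all()


@pytest.mark.parametrize("seed", range(20))
@pytest.mark.parametrize("scheme", ["default", "linear"])
def test_pipeline_matches_bruteforce_oracle(seed, scheme):
    ds = generate_dataset(small_params(seed))
    flags = assess_feasibility(ds)
    got = score_islands(ds, scheme, flags)
    want = oracle_scores(ds, scheme, flags)
    m = got.merge(want, on="island_id", suffixes=("", "_oracle"))
    for col in ("ccr", "pcr", "eb"):
        assert np.allclose(m[col], m[f"{col}_oracle"], rtol=1e-12, atol=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_score_bounds_hold_for_both_schemes(seed):
    ds = generate_dataset(small_params(seed, n_islands=20))
    flags = assess_feasibility(ds)
    n_species = ds.breeding.groupby("island_id")["species_id"].nunique()
    for scheme, cr in (("default", 0.5), ("linear", 4.0)):
        s = score_islands(ds, scheme, flags)
        assert (s["pcr"] >= 0).all()
        assert (s["pcr"] <= s["ccr"] + 1e-12).all()
        assert (s["eb"] >= -1e-12).all()
        bound = s["island_id"].map(n_species).fillna(0) * 2 * cr
        assert (s["ccr"] <= bound + 1e-12).all()


@pytest.mark.parametrize("seed", range(10))
def test_scheme_change_preserves_zero_benefit_pattern(seed):
    # feasibility, not the E weights, decides which islands gain nothing
    ds = generate_dataset(small_params(seed, n_islands=20))
    flags = assess_feasibility(ds)
    a = score_islands(ds, "default", flags)
    b = score_islands(ds, "linear", flags)
    assert ((a["eb"] > 1e-12) == (b["eb"] > 1e-12)).all()


@pytest.mark.parametrize("seed", range(5))
def test_adding_an_impact_never_decreases_ccr(seed):
    ds = generate_dataset(small_params(seed, n_islands=15))
    before = compute_ccr(ds)
    from islerank import enumerate_interactions

    cand = enumerate_interactions(ds)
    unknown = cand[cand["impact_class"] == "unknown"]
    if unknown.empty:
        pytest.skip("no unknown candidate to upgrade in this draw")
    row = unknown.iloc[0]
    ds.interactions.loc[len(ds.interactions)] = {
        "invasive_id": row["invasive_id"], "species_id": row["species_id"],
        "island_id": row["island_id"], "impact_class": "confirmed",
    }
    after = compute_ccr(ds)
    assert (after >= before - 1e-12).all()


@pytest.mark.parametrize("seed", range(5))
def test_marking_one_more_population_feasible_never_raises_pcr(seed):
    ds = generate_dataset(small_params(seed, n_islands=15))
    flags = assess_feasibility(ds)
    infeasible_idx = flags.index[~flags["feasible"]]
    if infeasible_idx.empty:
        pytest.skip("every population already feasible in this draw")
    before = compute_pcr(ds, "default", flags)
    flags.loc[infeasible_idx[0], "feasible"] = True
    after = compute_pcr(ds, "default", flags)
    assert (after <= before + 1e-12).all()
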