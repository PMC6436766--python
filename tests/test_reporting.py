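"""Benefit summaries, masking, scenarios and percentage formatting."""

import pandas as pd
import pytest

from islerank import (
    assess_feasibility,
    benefit_records,
    compute_ccr,
    generate_dataset,
    low_complexity_flags,
    mask_sensitive,
    rodent_scenario,
    round_percent,
    summarize,
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


def test_fixture_benefit_pairs_count(fixture_dataset):
    flags = assess_feasibility(fixture_dataset)
    pairs = benefit_records(fixture_dataset, flags, set(fixture_dataset.islands["island_id"]))
    assert len(pairs) == 24
    assert pairs["species_id"].nunique() == 23
    # the one species counted twice breeds on both its islands
    twice = pairs["species_id"].value_counts()
    assert twice.idxmax() == "phoebetria_fusca" and twice.max() == 2


def test_empty_island_set_gives_no_pairs(fixture_dataset):
    flags = assess_feasibility(fixture_dataset)
    assert benefit_records(fixture_dataset, flags, set()).empty


def test_summary_counts_and_breakdown(fixture_dataset):
    flags = assess_feasibility(fixture_dataset)
    pairs = benefit_records(fixture_dataset, flags, set(fixture_dataset.islands["island_id"]))
    s = summarize(pairs, fixture_dataset, "by2020")
    assert (s.n_islands, s.n_populations, s.n_species) == (8, 24, 23)
    assert s.n_species <= s.n_populations
    assert sum(s.by_taxon_populations.values()) == s.n_populations
    assert sum(s.by_taxon_species.values()) == s.n_species
    assert s.n_countries == 7  # Socorro and San José share Mexico


def test_single_species_summary(fixture_dataset):
    pairs = pd.DataFrame(
        {"species_id": ["phoebetria_fusca", "phoebetria_fusca"],
         "island_id": ["gough", "amsterdam"]}
    )
    s = summarize(pairs, fixture_dataset, "x")
    assert s.n_species == 1 and s.n_populations == 2


def _cheap_island_dataset(area=50.0, pop=0, n_invasives=1):
    invs = [invasive(f"inv{k}", "a") for k in range(n_invasives)]
    return make_dataset(
        islands=[island("a", area_ha=area, human_population=pop)],
        species=[species("s1")],
        breeding=[breeding("s1", "a")],
        invasive_populations=invs,
        interactions=[interaction(f"inv{k}", "s1", "a", "confirmed")
                      for k in range(n_invasives)],
        feasibility_rules=[rule("rodent")],
    )


@pytest.mark.parametrize(
    "area,pop,n_inv,expected",
    [
        (50.0, 0, 1, True),
        (50.0, 0, 2, True),
        (50.0, 0, 3, False),  # too many species to remove
        (100.0, 0, 1, False),  # the 100 ha cutoff is strict
        (50.0, 5, 1, False),  # inhabited
    ],
)
def test_low_complexity_boundaries(area, pop, n_inv, expected):
    ds = _cheap_island_dataset(area, pop, n_inv)
    flags = assess_feasibility(ds)
    out = low_complexity_flags(ds, flags, {"a"})
    assert bool(out["a"]) is expected


def test_masking_small_reptile_island_and_flagged_islands():
    ds = make_dataset(
        islands=[island("tiny", area_ha=50.0), island("big", area_ha=500.0),
                 island("secret", sensitive=True)],
        species=[species("iguana", taxon_class="reptile")],
        breeding=[breeding("iguana", "tiny"), breeding("iguana", "big")],
    )
    rows = ds.islands[["island_id", "name"]].copy()
    masked = mask_sensitive(rows, ds)
    by_id = masked.set_index("island_id")["name"]
    assert by_id["tiny"] == "unknown"  # <100 ha with a breeding reptile
    assert by_id["secret"] == "unknown"  # expert-flagged sensitive location
    assert by_id["big"] == "Big"  # large reptile island stays visible


@pytest.mark.parametrize("seed", range(3))
def test_masking_changes_names_only(seed):
    ds = generate_dataset(small_params(seed, n_islands=30))
    rows = ds.islands[["island_id", "name", "area_ha"]].copy()
    masked = mask_sensitive(rows, ds)
    assert len(masked) == len(rows)
    assert masked["island_id"].equals(rows["island_id"])
    assert masked["area_ha"].equals(rows["area_ha"])


def test_rodent_scenario_noop_without_unknown_rodents(fixture_dataset):
    out = rodent_scenario(fixture_dataset)
    pd.testing.assert_frame_equal(out.invasive_populations,
                                  fixture_dataset.invasive_populations)


def test_rodent_scenario_flips_unknowns_and_never_lowers_risk():
    ds = make_dataset(
        islands=[island("a")],
        species=[species("s1")],
        breeding=[breeding("s1", "a")],
        invasive_populations=[invasive("rat", "a", rodent_status_unknown=True)],
        interactions=[interaction("rat", "s1", "a", "confirmed")],
        feasibility_rules=[rule("rodent")],
    )
    before = compute_ccr(ds)
    out = rodent_scenario(ds)
    after = compute_ccr(out)
    assert before["a"] == 0.0  # unknown-status rodent excluded from base run
    assert after["a"] == 1.0  # assumed present: 0.5 * 1 * 2
    assert (after >= before).all()
    # input untouched, and the scenario is idempotent
    assert ds.invasive_populations["rodent_status_unknown"].iloc[0]
    pd.testing.assert_frame_equal(
        rodent_scenario(out).invasive_populations, out.invasive_populations
    )


@pytest.mark.parametrize(
    "num,den,dec,expected",
    [(111, 1184, 1, 9.4), (94, 260, 0, 36.0), (260, 1279, 0, 20.0),
     (47, 184, 0, 26.0), (25, 200, 0, 13.0)],  # 12.5 rounds away from zero
)
def test_round_percent_half_away_from_zero(num, den, dec, expected):
    assert round_percent(num, den, dec) == expected


def test_round_percent_rejects_zero_denominator():
    with pytest.raises(ValueError):
        round_percent(1, 0)
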