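"""Interaction enumeration, family-level imputation and the Z matrix."""

import numpy as np
import pytest

from islerank import (
    enumerate_interactions,
    generate_dataset,
    impute_impacts,
    severity_matrix,
)
from islerank.model import population_included

from conftest import (
    breeding,
    interaction,
    invasive,
    island,
    make_dataset,
    small_params,
    species,
)


def _base(n_species=2, invasives=("rat", "cat", "goat")):
    groups = {"rat": "rodent", "cat": "cat", "goat": "ungulate"}
    return make_dataset(
        islands=[island("a")],
        species=[species(f"s{i}") for i in range(n_species)],
        breeding=[breeding(f"s{i}", "a") for i in range(n_species)],
        invasive_populations=[
            invasive(v, "a", invasive_group=groups.get(v, "other")) for v in invasives
        ],
    )


def test_candidates_are_the_island_cross_product():
    cand = enumerate_interactions(_base())
    assert len(cand) == 6  # 2 species x 3 invasives on one shared island
    assert set(cand["impact_class"]) == {"unknown"}


def test_domestic_only_island_yields_no_candidates():
    ds = make_dataset(
        islands=[island("a")],
        species=[species("s0")],
        breeding=[breeding("s0", "a")],
        invasive_populations=[
            invasive("cattle", "a", invasive_group="ungulate", feral_status="domestic")
        ],
    )
    assert enumerate_interactions(ds).empty


def test_candidate_count_equals_per_island_product_sum():
    ds = generate_dataset(small_params(5, n_islands=40))
    cand = enumerate_interactions(ds)
    pops = ds.invasive_populations[population_included(ds.invasive_populations)]
    expected = sum(
        (ds.breeding["island_id"] == iid).sum() * (pops["island_id"] == iid).sum()
        for iid in ds.islands["island_id"]
    )
    assert len(cand) == expected


def test_unknown_impact_imputed_from_family_maximum():
    # the rat's confirmed impact on petrel B (same family) carries to petrel A
    ds = make_dataset(
        islands=[island("a"), island("b")],
        species=[species("petrelA", family="Procellariidae"),
                 species("petrelB", family="Procellariidae")],
        breeding=[breeding("petrelA", "a"), breeding("petrelB", "b")],
        invasive_populations=[invasive("rat", "a"), invasive("rat", "b")],
        interactions=[interaction("rat", "petrelB", "b", "confirmed")],
    )
    cand = impute_impacts(enumerate_interactions(ds), ds)
    row = cand[(cand["species_id"] == "petrelA")].iloc[0]
    assert row["z"] == 2 and row["provenance"] == "imputed"


def test_no_family_evidence_scores_zero():
    cand = impute_impacts(enumerate_interactions(_base()), _base())
    assert (cand["z"] == 0).all()
    assert set(cand["provenance"]) == {"assumed_zero"}


def test_explicit_none_record_beats_imputation():
    ds = make_dataset(
        islands=[island("a"), island("b")],
        species=[species("x1", family="F"), species("x2", family="F")],
        breeding=[breeding("x1", "a"), breeding("x2", "b")],
        invasive_populations=[invasive("rat", "a"), invasive("rat", "b")],
        interactions=[interaction("rat", "x2", "b", "confirmed"),
                      interaction("rat", "x1", "a", "none")],
    )
    cand = impute_impacts(enumerate_interactions(ds), ds)
    row = cand[cand["species_id"] == "x1"].iloc[0]
    assert row["z"] == 0 and row["provenance"] == "direct"


@pytest.mark.parametrize("seed", range(5))
def test_imputation_is_idempotent(seed):
    ds = generate_dataset(small_params(seed, n_islands=20))
    once = impute_impacts(enumerate_interactions(ds), ds)
    twice = impute_impacts(once, ds)
    assert once.equals(twice)


def test_severity_takes_maximum_over_invasives():
    ds = make_dataset(
        islands=[island("a")],
        species=[species("s0")],
        breeding=[breeding("s0", "a")],
        invasive_populations=[invasive("cat", "a", invasive_group="cat"),
                              invasive("rat", "a")],
        interactions=[interaction("cat", "s0", "a", "confirmed"),
                      interaction("rat", "s0", "a", "suspected")],
    )
    zmat = severity_matrix(ds)
    assert zmat.loc[0, "z"] == 2 and zmat.loc[0, "provenance"] == "direct"


def test_empty_invasive_filter_gives_empty_matrix():
    assert severity_matrix(_base(), invasive_filter=set()).empty


@pytest.mark.parametrize("seed", range(5))
def test_severity_values_and_provenance_partition(seed):
    ds = generate_dataset(small_params(seed, n_islands=25))
    zmat = severity_matrix(ds)
    assert zmat["z"].isin([0, 1, 2]).all()
    assert zmat["provenance"].isin(["direct", "imputed", "assumed_zero"]).all()
    assert not zmat.duplicated(subset=["species_id", "island_id"]).any()


@pytest.mark.parametrize("seed", range(5))
def test_enlarging_the_filter_never_decreases_z(seed):
    ds = generate_dataset(small_params(seed, n_islands=25))
    pops = ds.invasive_populations
    keys = sorted(set(zip(pops["invasive_id"], pops["island_id"])))
    rng = np.random.default_rng(seed)
    subset = {k for k in keys if rng.random() < 0.5}
    z_small = severity_matrix(ds, subset).set_index(["species_id", "island_id"])["z"]
    z_full = severity_matrix(ds, set(keys)).set_index(["species_id", "island_id"])["z"]
    aligned = z_small.reindex(z_full.index, fill_value=0)
    assert (z_full >= aligned).all()
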