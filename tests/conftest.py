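import pandas as pd
import pytest

from islerank import Dataset, GeneratorParams, generate_dataset, table1_fixture
from islerank.model import empty_table


def make_dataset(**tables) -> Dataset:
    """Build a Dataset from lists of row dicts; unmentioned tables are empty."""
    kwargs = {}
    for name, rows in tables.items():
        kwargs[name] = pd.DataFrame(rows) if rows else empty_table(name)
    return Dataset(**kwargs)


def island(island_id, area_ha=1000.0, human_population=0, sensitive=False, **kw):
    return {
        "island_id": island_id,
        "name": kw.get("name", island_id.title()),
        "country": kw.get("country", "atlantis"),
        "area_ha": area_ha,
        "human_population": human_population,
        "sensitive": sensitive,
    }


def species(species_id, iucn_category="CR", taxon_class="bird", family="famA",
            seabird_flag=False, insularity="insular"):
    return {
        "species_id": species_id,
        "name": species_id,
        "taxon_class": taxon_class,
        "seabird_flag": seabird_flag,
        "family": family,
        "iucn_category": iucn_category,
        "insularity": insularity,
    }


def breeding(species_id, island_id, breeding_status="confirmed"):
    return {"species_id": species_id, "island_id": island_id,
            "breeding_status": breeding_status}


def invasive(invasive_id, island_id, invasive_group="rodent", presence="confirmed",
             feral_status="feral", rodent_status_unknown=False, under_eradication=False):
    return {
        "invasive_id": invasive_id,
        "invasive_group": invasive_group,
        "island_id": island_id,
        "presence": presence,
        "feral_status": feral_status,
        "rodent_status_unknown": rodent_status_unknown,
        "under_eradication": under_eradication,
    }


def interaction(invasive_id, species_id, island_id, impact_class="confirmed"):
    return {"invasive_id": invasive_id, "species_id": species_id,
            "island_id": island_id, "impact_class": impact_class}


def rule(invasive_group, max_area_ha=float("inf"), max_human_population=float("inf")):
    return {"invasive_group": invasive_group, "max_area_ha": max_area_ha,
            "max_human_population": max_human_population}


def assessment(island_id, expert_id, timeframe, years_experience=20):
    return {"island_id": island_id, "expert_id": expert_id,
            "timeframe": timeframe, "years_experience": years_experience}


@pytest.fixture
def fixture_dataset() -> Dataset:
    """The eight-island worked-example dataset."""
    return table1_fixture()


@pytest.fixture
def small_dataset() -> Dataset:
    """A small generated dataset for structural tests."""
    return generate_dataset(GeneratorParams(n_islands=40, seed=11))


def small_params(seed: int, n_islands: int = 10) -> GeneratorParams:
    return GeneratorParams(n_islands=n_islands, seed=seed)
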