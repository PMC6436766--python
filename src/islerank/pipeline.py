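"""End-to-end prioritization pipeline.

Stages: read -> validate -> (optional rodent scenario) -> technical
feasibility -> CCR/PCR/EB scoring -> ranking -> socio-political timeframes ->
benefit summaries -> sensitive-name masking -> write.  Every stage logs its
record counts; any failure is re-raised wrapped with the stage name.  Given
the same inputs the run is fully deterministic, so repeated runs produce
byte-identical output files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .feasibility import assess_feasibility, assign_timeframes
from .io import read_dataset, write_results
from .model import Dataset
from .reporting import (
    benefit_records,
    low_complexity_flags,
    mask_sensitive,
    rodent_scenario,
    summaries_table,
    summarize,
)
from .scoring import rank_islands, score_islands
from .validate import validate_dataset

log = logging.getLogger("islerank")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage {stage!r} failed: {original}")


DEFAULT_CONFIG = {
    "input_dir": None,
    "scheme": "default",
    "rodent_scenario": False,
    "mask": True,
    "output_dir": None,
    "seed": 0,
}


def load_config(path) -> dict:
    """Read a YAML run configuration, filling defaults for absent keys."""
    with open(path, "r", encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh) or {}
    config = dict(DEFAULT_CONFIG)
    unknown = set(loaded) - set(config)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    config.update(loaded)
    return config


def _stage(name):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(name, exc) from exc
            log.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(config: dict | None = None, dataset: Dataset | None = None) -> dict:
    """Execute the full analysis and return a result bundle.

    ``config`` follows :data:`DEFAULT_CONFIG`; ``dataset`` may be passed
    directly for in-memory use (then ``input_dir`` is ignored).  The bundle
    holds the dataset actually scored, feasibility flags, the ranked score
    table (masked if configured), timeframe decisions and sets, per-set
    benefit summaries, the low-complexity flags for the earliest set, the
    data-gap listing, and any file paths written.
    """
    config = {**DEFAULT_CONFIG, **(config or {})}

    with _stage("read"):
        if dataset is None:
            if not config["input_dir"]:
                raise ValueError("config must name input_dir when no dataset is given")
            dataset = read_dataset(config["input_dir"], validate=False)
        log.info(
            "read: %d islands, %d species, %d breeding records, %d invasive populations",
            len(dataset.islands), len(dataset.species),
            len(dataset.breeding), len(dataset.invasive_populations),
        )

    with _stage("validate"):
        validate_dataset(dataset).raise_if_violations()

    if config["rodent_scenario"]:
        with _stage("rodent_scenario"):
            dataset = rodent_scenario(dataset)

    with _stage("feasibility"):
        flags = assess_feasibility(dataset)
        log.info("feasibility: %d/%d populations feasible",
                 int(flags["feasible"].sum()), len(flags))

    with _stage("scoring"):
        scores = score_islands(dataset, config["scheme"], flags)

    with _stage("ranking"):
        ranked = rank_islands(scores)
        log.info("ranking: %d islands with positive eradication benefit",
                 int(ranked["rank"].notna().sum()))

    with _stage("timeframes"):
        decisions, sets = assign_timeframes(dataset, ranked)

    with _stage("summaries"):
        pairs = {
            label: benefit_records(dataset, flags, island_set)
            for label, island_set in sets.items()
        }
        summaries = summaries_table(
            [summarize(pairs[label], dataset, label) for label in sets]
        )
        low_cost = low_complexity_flags(dataset, flags, sets["by2020"])

    with _stage("masking"):
        meta = dataset.islands[["island_id", "name", "country"]]
        score_table = ranked.merge(meta, on="island_id", how="left")
        data_gap = meta[meta["island_id"].isin(sets["unknown"])].copy()
        if config["mask"]:
            score_table = mask_sensitive(score_table, dataset)
            data_gap = mask_sensitive(data_gap, dataset)

    decisions_table = pd.DataFrame(
        [
            {"island_id": d.island_id, "timeframe": d.timeframe, "basis": d.basis}
            for d in decisions
        ],
        columns=["island_id", "timeframe", "basis"],
    )

    paths: dict[str, Path] = {}
    if config["output_dir"]:
        with _stage("write"):
            out = Path(config["output_dir"])
            paths = write_results(score_table, summaries, out)
            decisions_table.to_csv(out / "timeframe_decisions.csv", index=False)
            data_gap.to_csv(out / "data_gap_islands.csv", index=False)
            paths["decisions"] = out / "timeframe_decisions.csv"
            paths["data_gap"] = out / "data_gap_islands.csv"

    return {
        "config": config,
        "dataset": dataset,
        "feasibility": flags,
        "scores": score_table,
        "decisions": decisions,
        "decisions_table": decisions_table,
        "sets": sets,
        "benefit_pairs": pairs,
        "summaries": summaries,
        "low_complexity": low_cost,
        "data_gap": data_gap,
        "paths": paths,
    }
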