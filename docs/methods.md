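# Methods notes

## Model

The unit of analysis is the island. Each island's Current Conservation Risk
is the sum, over the Critically Endangered (CR) and Endangered (EN)
vertebrates breeding there, of extinction risk × irreplaceability × severity
of impact:

```
CCR_i = Σ_s E_s · I_s · Z_s,i
```

Potential Conservation Risk (PCR) is the same quantity computed as if every
technically feasible invasive population had already been removed: Z is
re-maximized over the infeasible populations only, all feasible populations
being removed concurrently. Eradication Benefit EB = CCR − PCR is the primary
ranking statistic. Because Z is a maximum over a set and PCR shrinks that
set, 0 ≤ PCR ≤ CCR and EB ≥ 0 hold identically; both are asserted as
invariants in the test suite.

Assumptions worth making explicit:

- **All breeding statuses are equal.** Confirmed, probable and potential
  breeding records enter identically. This is deliberately inclusive: a
  potential breeding population is still an opportunity to protect.
- **Suspected presence = confirmed presence** for invasive populations, and
  populations under ongoing eradication still count (removal is not assured
  until confirmed).
- **Conservative feral assumption.** Populations of unknown feral status are
  treated as feral and threatening; only entirely domestic/farmed populations
  are excluded from scoring. Excluded rows stay in the table with their
  status, so audits and scenario re-runs see the full record.
- **Rodents of unknown presence** are excluded from the base analysis. The
  `rodent_scenario` transform flips them to confirmed presence (clearing the
  flag) so a re-run bounds their potential contribution; by monotonicity of
  the maximum this can only raise island risk. The transform is pure and
  idempotent.
- **No interactions among invasives.** Removing a subset of invasive mammals
  can release others (mesopredator/competitor release); this is out of scope
  for a global screen and belongs to island-scale feasibility work.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| E (CR, EN), `default` scheme | 0.5, 0.05 | relative extinction risk implied by Red List criteria thresholds |
| E (CR, EN), `linear` scheme | 4, 3 | ordinal alternative for sensitivity analysis |
| Z scores | 2 / 1 / 0 | confirmed / suspected / no impact |
| EB zero tolerance | 1e-12 | EB at or below this counts as "no benefit" (float-noise absorption) |
| Small-island cutoff | 100 ha, strict `<` | used by both the reptile masking rule and the low-complexity flag |

Irreplaceability is computed from the dataset's own breeding table:
I(s) = 1 / (distinct islands with a breeding record for s). **This means a
subsetted dataset rescales I** relative to an analysis of the full global
inventory; it keeps any dataset self-consistent, but comparisons across
datasets must use the same island universe. Continental populations are never
counted (the table holds island records only): islands may be the only
realistic invader-free refuge for species that also breed on continents.

Impact imputation is keyed by (invasive species × native taxonomic family)
and maximizes over all islands globally — the rule is taxonomic, not spatial.
Explicit records always win, including explicit "none"; imputation fills only
true unknowns, and unknowns with no family evidence score 0 with provenance
`assumed_zero`. Imputation does not cross invasive congeners (e.g. evidence
for one *Rattus* species is not applied to another); the evidence base is
per invasive species.

Technical feasibility thresholds (max island area, max human population per
invasive group) are **required configuration**. The bundled table in
`islerank.synthetic.ILLUSTRATIVE_FEASIBILITY_RULES` is illustrative only —
plausible orders of magnitude for rodents, cats, dogs, mongooses and
ungulates — and is not an authoritative reproduction of any published
threshold set. Thresholds are inclusive (`≤`): an island exactly at the limit
is feasible. A population whose group has no rule raises a configuration
error rather than defaulting silently.

Timeframe aggregation: unknown votes are ignored whenever at least one
informative vote exists; a single informative vote decides with basis
`single_expert`; unanimity is `consensus`; disagreement resolves to the
latest timeframe (`by2020 < by2030 < never`) with basis `most_conservative`.
Only islands with EB > 0 are assessed — there is nothing to initiate
elsewhere — and the four resulting sets (by2020 / by2030 / never / unknown)
partition those islands exactly; the unknown set is emitted as a data-gap
listing rather than dropped silently. Expert experience years are recorded
as metadata only and never weight the votes.

Ranking ties (equal EB) break by higher CCR, then by more species whose
severity would drop, then island id. The rule beyond EB is a reproducibility
convention, not a biological statement.

Percentages are rounded half-away-from-zero (`decimal`-based, not float
banker's rounding), matching how headline fractions such as 111/1184 → 9.4%
are conventionally printed.

## Synthetic data generator

`generate_dataset` draws a seven-table dataset calibrated to the *marginal*
structure of the global threatened-island inventory this method targets:

- species per island: zipf(a = 2.5) truncated to [1, 155] — median 1 with a
  heavy right tail. The zipf family is a documented modelling choice; only
  the median/range targets are taken from published summaries.
- 58% of islands carry invasive mammals; per invaded island the species
  count is a discretized lognormal (median 4, capped at 34) drawn from a
  twelve-species pool weighted so cats and rats dominate.
- island areas: lognormal, median 430 ha, σ = 2.5 log-units (sub-0.1 ha
  rockstacks to very large islands); 69% of islands uninhabited, inhabited
  populations lognormal around ~120 people.
- explicit impact records drawn per co-occurrence with mixture
  confirmed/suspected/none/unknown = 0.10/0.10/0.15/0.65; "unknown" writes no
  record and is later resolved by imputation.
- CR fraction 0.4; taxon mixture ≈ equal across amphibians, reptiles, birds
  and mammals; 8% of species also have continental populations; expert
  response rate 0.75 with timeframe mixture 0.45/0.25/0.20/0.10.

What the generator does **not** emulate: the joint distribution of area ×
human population × invader richness (unpublished), spatial/archipelago
structure, island-specific invader communities, and any correlation between
threat category and range size. Tests passing on synthetic data therefore
demonstrate the *computational* correctness of the pipeline (score algebra,
filters, aggregation, determinism), not that real-world rankings would be
recovered — the worked-example fixture covers the published counts instead.

The worked-example fixture (`table1_fixture`) encodes only what the published
eight-island table prints: island names/countries, invasive lists, benefiting
species lists and the under-eradication marks. Areas, human populations,
IUCN categories, families and expert identities are illustrative filler
(flagged synthetic in the docstring) chosen so the fixture is self-consistent
and all listed populations are feasible.

## Verification

The central correctness property is exact agreement (1e-12 relative) between
the vectorized pipeline and `oracle_scores`, a deliberately naive nested-loop
re-implementation sharing no code with the pipeline, across 100+ seeded
random datasets and both E schemes. Property tests (hypothesis, derandomized)
cover threshold monotonicity and timeframe-aggregation order invariance;
further invariants (score bounds, CCR/PCR monotonicity under added impacts
and grown feasible sets, masking count-preservation, byte-identical reruns)
are asserted across seeds. Oracle-equivalence runs use 10-island datasets and
the wider suites 15–40 islands with 100–500-island draws for calibration
checks — small enough to keep the full suite well under a minute while
exercising every code path.

## Known limitations

- No cost model: the low-complexity flag (<100 ha, uninhabited, ≤2 invasive
  species to remove) is a coarse proxy, not an estimate.
- No re-invasion risk, biosecurity, or optimization/complementarity across
  islands; the ranking is independent per island by design and meant as a
  global screen preceding island-scale feasibility studies.
- Degenerate inputs: an empty dataset scores an empty table; islands with no
  breeding species or no included invasives score 0 and are reported,
  unranked, alongside the ranked list.
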