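# islerank

Prioritize islands for invasive-mammal eradication by the conservation risk
it would remove.

Invasive mammals — above all cats and rats — are the leading driver of
vertebrate extinctions on islands, and whole-island eradication is one of the
few conservation actions with a long track record of success. Given a global
inventory of islands, the Critically Endangered (CR) and Endangered (EN)
vertebrates breeding on them, and the non-native mammal populations present,
`islerank` identifies and ranks the islands where eradication would do the
most good, and filters them by whether a project could realistically be
started. It is aimed at conservation planners and analysts working with
island/species/invader occurrence tables.

## The scoring model

For island *i*, **Current Conservation Risk** sums over the highly threatened
vertebrates *s* breeding there:

```
CCR_i = Σ_s  E_s · I_s · Z_s,i
```

- **E** — extinction-risk weight of the species' IUCN category: 0.5 (CR) and
  0.05 (EN) by default, reflecting the relative risk implied by the Red List
  criteria thresholds; an alternative linear scheme (4/3) is available for
  sensitivity analysis.
- **I** — irreplaceability: 1 / (number of islands the species breeds on).
  A single-island endemic scores 1. Continental populations are not counted.
- **Z** — severity of impact: the maximum over the invasive mammal
  populations on the island, scored 2 (confirmed impact), 1 (suspected),
  0 (none). Species×invader pairs with no impact record are imputed from the
  worst impact that invasive species has on any member of the same taxonomic
  family; entirely domestic (farmed) populations are excluded.

**Potential Conservation Risk** (PCR) recomputes the same sum assuming every
*technically feasible* invasive population (island area and human population
within per-group thresholds derived from eradication precedent) has been
removed; only infeasible populations keep contributing to Z. The
**Eradication Benefit**

```
EB_i = CCR_i − PCR_i  ≥ 0
```

is the primary ranking statistic. Islands with EB > 0 are then assigned an
expert-assessed socio-political timeframe — feasible to initiate **by 2020**,
**by 2030**, or **not in the foreseeable future** — by consensus where experts
agree and by the most conservative (latest) vote where they do not; islands
with no usable assessment are reported as a data gap. Sensitive island names
(expert-flagged, or <100 ha with a breeding reptile) are masked in outputs to
avoid aiding wildlife trafficking.

## Worked example

The package ships the eight-island worked example (Socorro, San José, Gough,
Mona, Floreana, Amsterdam, Alejandro Selkirk, Niau) with their published
invasive-mammal and benefiting-species lists:

```python
from islerank import run_pipeline, table1_fixture

bundle = run_pipeline(dataset=table1_fixture())
print(bundle["scores"][["island_id", "name", "ccr", "pcr", "eb", "rank"]].to_string(index=False))
```

```
        island_id              name  ccr  pcr   eb  rank
          socorro           Socorro 3.00  0.0 3.00     1
             mona              Mona 2.30  0.0 2.30     2
            gough             Gough 2.25  0.0 2.25     3
         floreana          Floreana 2.10  0.0 2.10     4
         san_jose          San José 2.00  0.0 2.00     5
alejandro_selkirk Alejandro Selkirk 1.00  0.0 1.00     6
             niau              Niau 1.00  0.0 1.00     7
        amsterdam         Amsterdam 0.35  0.0 0.35     8
```

Every listed invasive population is technically feasible to remove, so PCR is
0 everywhere and EB equals CCR. Socorro ranks first: three single-island
endemics (I = 1) with confirmed impacts, two of them CR
(0.5·1·2 + 0.5·1·2 + 0.5·1·2 = 3.0). Amsterdam's four benefiting seabirds are
all EN — and the sooty albatross *Phoebetria fusca* also breeds on Gough
(I = 0.5) — giving the low but positive 0.35. The per-timeframe summary:

```
  label  n_islands  n_populations  n_species  n_countries
 by2020          8             24         23            7
```

24 benefiting populations of 23 distinct species (*P. fusca* counted once) on
8 islands in 7 countries — the published counts for this example.

## Command line

```sh
islerank simulate --n-islands 200 --seed 42 --out data/   # synthetic dataset
islerank validate data/
islerank rank data/ --top 20
islerank summarize data/ --scheme linear --rodent-scenario
islerank run --config run.yaml                            # full pipeline
```

Inputs are seven CSV tables (islands, species, breeding, invasive
populations, interactions, feasibility rules, expert assessments); see
`docs/methods.md` for the schema and modelling notes. Feasibility thresholds
are required configuration — the bundled defaults are illustrative only.

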