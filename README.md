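# pairspace

Spatial and social analysis of **dyadic animal telemetry** — built for
studies of pair-living nocturnal primates (and similar "dispersed pair"
mammals) in which a male and a female share a home range but may rarely
associate. Two observers follow the pair partners simultaneously from dusk
to dawn; the question is whether the partners attract each other, avoid
each other, or move independently, and how their ranges and social
interactions are structured.

The package provides, as composable library modules and a thin CLI:

* **Kernel home ranges** — fixed bivariate Gaussian kernel utilization
  distributions with the reference-rule bandwidth
  `h_ref = sqrt((s_x² + s_y²)/2) · n^(−1/6)` and optional *ad hoc* stepwise
  reduction (smallest multiplier in {1.0, …, 0.1} of `h_ref` whose 95%
  isopleth stays in one piece); isopleth polygons with areas in hectares,
  minimum-convex-polygon fallback for sparse nights.
* **Directional percent overlap** — `100 · area(A∩B) / area(A)` between
  range polygons, for pair partners and same-sex neighbors.
* **Dynamic-interaction tests** for a simultaneously followed dyad:
  * random gas model, expected encounter rate `f = (4ρv/π)(2d + s)`;
  * Hutchinson's instantaneous-sampling correction, `f = Nρπd²`;
  * Doncaster's contingency test — the N observed simultaneous
    inter-partner distances vs. all N² cross-pairings, classified
    below/above the distance criterion `d` in a 2×2 χ² table (df = 1),
  plus the share of aligned time spent within a given distance.
* **Exact small-sample rank tests** — Wilcoxon signed-rank and rank-sum
  with the full enumeration null distribution (essential at n = 7 dyads),
  and the 2×2 χ² independence test.
* **Social metrics** — interaction classification
  (agonistic / affiliative ≤1 m / neutral ≤5 m), hourly rates per in-sight
  observation time, and sleeping-tree tallies (exclusive, shared,
  simultaneously used).
* **A synthetic study generator** — coupled Ornstein–Uhlenbeck walks with a
  tunable attraction/avoidance coupling, plus sleeping-site and
  interaction-event generators, so that every stage is testable end to end
  without field data.

## Worked example

Simulate a seven-dyad study in the "paper" preset (avoiding pairs, female
ranges ≈ 0.2 ha inside male ranges ≈ 0.35 ha) and run the full analysis:

```sh
pairspace simulate --preset paper --seed 1 --out data/
pairspace analyze --data data/ --out report/
```

`report/range_areas.tsv` then starts

```
individual_id  area_ha  bandwidth_m  method
f1             0.2017   2.377        kde
f2             0.1938   1.689        kde
```

— per-individual 95% kernel range areas (ha) with the ad hoc bandwidth
used. `report/pair_overlap.tsv` shows the directional asymmetry typical of
nested pair ranges (the smaller female range lies almost entirely inside
the male's, so her percentage is the larger one):

```
id_a  id_b  pct_a_in_b  pct_b_in_a  area_a_ha  area_b_ha
f1    m1    100.0       57.42       0.2017     0.3513
```

`report/dynamic_interaction.json` holds one block per dyad; for `m1–f1`:

```json
"doncaster": {"observed": 130, "expected": 291.87, "statistic": 125.87,
              "df": 1, "p": 3.3e-29, "direction": "avoidance"},
"hutchinson": {"observed": 130, "expected": 204.44},
"proximity_pct": {"d10": 4.33, "d15": 12.80, "d20": 25.30}
```

The pair was within 15 m at 130 of its aligned 5-min fixes, far fewer than
the 292 expected from the N² cross-pairings — active avoidance — and spent
only ~4% of its time within 10 m. The across-pairs block applies the exact
signed-rank test to observed minus expected over the seven dyads; with all
seven differences negative the statistic is V = 0 and the exact two-sided
p is 2/2⁷ = 0.015625 (printed as p = 0.02). `sleeping_tally.tsv` shows
shared sleeping trees but zero days of simultaneous use in this preset.

Each stage (`homerange`, `overlap`, `interact`, `social`) can also be run
separately on intermediate files; `pairspace COMMAND --help` lists the
knobs (distance criterion `--d`, grid cell, isopleth level, α, …).

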