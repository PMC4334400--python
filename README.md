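# assaydesign

Cost-effectiveness planning for genetic assay choice in rare-disease
gene-discovery studies.

Rare-disease projects are usually limited by assay cost, not by case
availability: a fixed budget must be split between assaying a few cases
deeply (WGS, WES) or many cases shallowly (genotyping chips). This package
implements a small decision framework for that choice, aimed at researchers
designing or extending trio/singleton sequencing studies.

## Model

Each case is assumed to carry *c* private risk mutations (the disease
**complexity**), with no overlap in causal mutations across cases. An assay
covers any one risk mutation with probability *v* (its **hit rate**), so a
case's complete causal mechanism is observed with probability

&nbsp;&nbsp;&nbsp;&nbsp;*d* = *v*ᶜ

and the number of completely observed mechanisms among *n* assayed case-units
is *m* ~ Bin(*n*, *d*), with mean E[*m*] = *n·v*ᶜ. Dividing by total cost
gives the assay's utility *U* = *v*ᶜ/*P* (expected complete mechanisms per
currency unit), the criterion for ranking assays under a fixed budget. Two
assays are equally cost-effective when *P₂/P₁* = (*v₂/v₁*)ᶜ.

For **extending** an existing study of *n* case-units, two equal-budget
strategies compete: assay new cases with the original assay (strategy A) or
re-assay the existing cases with an additional assay (strategy B). They tie
exactly when

&nbsp;&nbsp;&nbsp;&nbsp;*v_B*/*v* = (*P_B*/*P_A* + 1)^(1/*c*)

independently of *n*, which partitions the (price-ratio, hit-rate-ratio)
plane into regions favouring each strategy. A seeded Monte-Carlo simulator of
the generative assumptions provides an independent check on every closed form.

## Worked example

A budget of 16 chip-units buys 4 WES trios (*v* = 0.27, price 4) or 16 chip
trios (*v* = 0.12, price 1). At complexity *c* = 2:

```sh
$ assaydesign design --budget 16 -c 2 --format text
...
  expected_yield: 0.29 (full: 0.2916)   # WES, n = 4
...
  expected_yield: 0.23 (full: 0.2304)   # chip-CNV, n = 16
...
  yield_ratio_display: 1.26 (full: 1.26)
```

WES yields 0.29 expected completely observed disease mechanisms against 0.23
for chip genotyping — 26% better for the same money (0.29/0.23 = 1.26).

Extending that 4-trio WES study with the price of one more trio:

```sh
$ assaydesign extend --n 4 --hit-rate 0.27 --added-hit-rate 0.12 \
    --price-a 4 --price-b 1 -c 2 --budget 4 --format text
verdict:
  yield_A: 0.36 (full: 0.36450000000000005)
  yield_B: 0.61 (full: 0.6084)
  n_A: 5
  favoured: B
  breakeven_delta:
    value: 0.03 (full: 0.03186917696247163)
    feasible: True
  breakeven_base_hit_rate:
    value: 1.02 (full: 1.016656314599949)
    feasible: False
```

A fifth WES trio raises the expected yield to 0.365, but chip-genotyping the
existing four trios (additive hit rates, no overlap: *v_B* = 0.39) raises it
to 0.61 — strategy B wins decisively. The chip assay only needed to add a
0.032 hit-rate increment to break even, while the base assay would need an
impossible hit rate of 1.02 for strategy A to tie.

`assaydesign partition` exports the favoured-strategy map over
(*P_B*/*P_A*, *v_B*/*v*) space as TSV and optionally a figure;
`assaydesign simulate` runs the Monte-Carlo check.

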