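# Methods

## Model and assumptions

The framework models a rare-disease gene-discovery study in which each
affected case carries its own private set of exactly *c* causal risk
mutations (*c* is the disease complexity, in the sense of component causes of
a sufficient cause), with no overlap in causal mutations across cases. An
assay captures any single risk mutation independently with probability *v*,
its hit rate. A case's disease mechanism is *completely observed* — the
prerequisite for it being identifiable downstream — only if all *c* mutations
are captured, which happens with probability *d* = *v*ᶜ. Across *n*
independent case-units the number of completely observed mechanisms is
binomial, *m* ~ Bin(*n*, *d*), so E[*m*] = *n·v*ᶜ and
Var[*m*] = *n·d·*(1 − *d*).

*d* = *v*ᶜ is treated as exact. It is strictly an approximation when some
cases carry more than *c* causal mutations, but for rare disease that
fraction is negligible; the simulator's `extra_mutation_prob` option exists
to probe how the closed form degrades when the assumption is relaxed, and is
off by default.

Assays are ranked for a new study by utility *U* = *v*ᶜ/*P*, the expected
completely observed mechanisms per currency unit. Currency is an abstract
positive unit — every decision in the framework depends on price ratios only.
Likewise "case-unit" is whatever unit is priced (a parent–offspring trio in
the worked examples, a singleton elsewhere); the library never assumes family
structure.

For extending an existing study of *n* case-units at hit rate *v*, the two
equal-budget strategies are A (spend the budget on `floor(budget/P_A)` more
case-units with the original assay, raising *n* to *n_A*) and B (re-assay the
existing case-units with an additional assay, raising *v* to *v_B*). Their
yields are E[*m_A*] = *n_A·v*ᶜ and E[*m_B*] = *n·v_B*ᶜ. Under the equal-budget
constraint (*n_A* − *n*)·*P_A* = *n·P_B*, combining the matching condition
*n_A*/*n* = (*v_B*/*v*)ᶜ with the budget constraint gives the tie locus

    v_B / v = (P_B / P_A + 1)^(1/c)

which is independent of *n*. Rearrangements give the minimum hit-rate
increment Δ = *v*·[(*P_B*/*P_A* + 1)^(1/*c*) − 1] strategy B must confer, and
its algebraic inverse, the base hit rate *v* = Δ/[(*P_B*/*P_A* + 1)^(1/*c*) − 1]
at which strategy A ties a given increment. Both are reported with a
feasibility flag: values implying a hit rate above 1 mean no real assay can
reach the tie, so the other strategy dominates over the whole attainable
range.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| `hit_rate` (*v*) | probability a risk mutation lies in the assayed loci | probability | per-assay; catalog ships 0.12 / 0.27 / 0.62 |
| `price` (*P*) | cost per case-unit | abstract currency > 0 | per-assay; catalog ships 1 / 4 / 16 |
| `complexity` (*c*) | risk mutations per causal mechanism | count, real ≥ 1 | 2 in the CLI |
| `overlap` | probability mass covered by more than one combined assay | probability | 0 |
| `n_replicates` | Monte-Carlo replicates | count | 100 000 |

Complexity is accepted as any real ≥ 1, not just an integer: every closed
form is well defined for real exponents and the decision boundaries are
naturally swept continuously, including `c = inf`, which is handled
analytically (the tie locus degenerates to the constant line *v_B*/*v* = 1 —
an additional assay that adds nothing can never be worth paying for).
Integer *c* remains the typical use, and the simulator requires it (it draws
actual mutation capture events).

The default catalog's hit rates are the diagnostic rates observed when a
large severe-intellectual-disability cohort was successively chip-genotyped
for CNVs (12%), exome sequenced (27%) and genome sequenced (62%). Since a
mutation can be covered by an assay without yielding a diagnosis, these are
lower bounds on the true hit rates, and the catalog is labelled accordingly.
Default prices follow the conventional cost ladder of chip : WES : WGS =
1 : 4 : 16.

`combine_assays` models applying several assays jointly as one synthetic
assay: hit rates add (minus a single scalar `overlap` mass counted more than
once, default 0) and prices add. The zero-overlap default is the assumption
under which the worked extension example holds; a richer overlap model (per
pair, per mutation class) would need data the framework does not ask for, so
the scalar is the deliberate minimal generalisation.

## Numerical choices

- All computation is full precision; display rounds to 2 decimal places by
  default (`--precision` on the CLI). Ranking reports quote yield ratios both
  at full precision and from 2-dp-rounded intermediate yields (0.29/0.23 =
  1.26), because that is how such comparisons are quoted in practice; the two
  can differ in the last digit (full precision gives ≈ 1.27 here).
- Sample sizes are integral: `affordable_sample_size` floors `budget/price`
  and the leftover budget is reported. `extension_yields` also supports a
  continuous-*n_A* convention (`continuous_n=True`), the convention under
  which the breakeven algebra is exact; the floor convention is used for
  concrete advice. With floors, the utility ranking and the expected-yield
  ranking can disagree when budgets do not divide evenly — `ranking_report`
  reports both orders and flags disagreement.
- Strategy classification uses a relative tolerance of 1e-9 so that grid
  cells lying exactly on a decision boundary label deterministically as
  "equivalent" instead of flipping on floating-point noise.
- Ties in utility break on lower price, then name, so output ordering is
  deterministic.
- If strategy B's fixed cost *n·P_B* exceeds the extension budget the verdict
  is flagged `infeasible` rather than compared on yields it cannot fund.
- Degenerate inputs: *v* = 0 or *n* = 0 give zero yield; *v* = 1 gives
  certain capture at any complexity; a zero base hit rate is rejected
  wherever a ratio over it would be formed.

## Simulation oracle

`simulate_study` implements the generative assumptions directly: each case
carries *c* private mutations, each captured by an independent Bernoulli(*v*)
draw, and counts toward *m* only if all are captured. It never calls the
closed forms or the binomial distribution of *d*, so its empirical mean,
variance and full count distribution are independent checks on them (the test
suite verifies the mean to within 3 standard errors, the variance against
*n·d·*(1 − *d*), and the count distribution by a chi-square fit).
`simulate_extension` runs both extension strategies on deterministic child
streams of one seed. Identical seeds reproduce output exactly.

The default 100 000 replicates resolve example-scale yield differences
(standard errors ≈ 0.002 at the worked example's size) in about a second;
this is the problem size used throughout the tests and the reproduction
script.

What the simulator emulates is exactly the model's idealised world — exact
complexity per case, independent capture, no shared causal mutations, no
assay error. Real studies violate all four to some degree (notably: hit rates
are themselves uncertain estimates, assays have error rates, and candidate
mechanisms need validation). Passing tests therefore show internal
consistency of the framework, not that a particular real study will achieve
the predicted yield.

## Design choices

- One tie-locus derivation path: the equivalence condition is obtained by
  combining the equal-budget constraint with the sample-ratio matching
  condition *n_A*/*n* = (*v_B*/*v*)ᶜ; that is the algebra the implementation
  and its tests follow.
- The partition grid's axes are the two scale-free ratios *P_B*/*P_A* and
  *v_B*/*v*, so one grid serves any absolute price/hit-rate scale. Cells with
  *v_B*/*v* < 1 are labelled infeasible (an additional assay cannot lower the
  combined hit rate). Default CLI ranges (0.05–2 in price ratio, 0.5–2.5 in
  hit ratio) bracket the worked example's point and all four boundary curves;
  the reproduction is structural (region labels and equivalence curves), not
  a pixel-level copy of any particular figure.
- A thin `click` CLI (`design`, `extend`, `partition`, `simulate`) wraps the
  library; every JSON result embeds a provenance record (package version,
  seed, input parameters) and identical invocations are byte-identical.

## Limitations

- No modelling of assay error rates, candidate-mechanism counts per case, or
  validation costs; no clinical-utility evaluation.
- No mixed portfolios (splitting one budget across different assays on
  different cases) beyond evaluating a `combine_assays` composite applied to
  every case.
- No sequential-analysis correction for re-analysing an augmented dataset;
  the yield comparison says which extension buys more completely observed
  mechanisms, not how to analyse the combined data.
- Hit rates and complexity are inputs, not estimates: the framework
  propagates them, it cannot justify them.
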