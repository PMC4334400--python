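"""Cost-effectiveness planning for genetic assay choice in rare-disease studies.

Rare-disease gene-discovery projects are usually limited by assay cost, not by
case availability.  This module implements a small decision framework for that
setting.  The model assumes each case carries ``c`` private risk mutations
(the disease *complexity*), none shared across cases, and that an assay
captures any one risk mutation with probability ``v`` (its *hit rate*).  The
probability that a case's complete causal mechanism is observed is then

    d = v**c                        (discoverability)

and the number of cases with a completely observed mechanism among ``n``
assayed cases is binomial, ``m ~ Bin(n, d)``, with mean ``E[m] = n * v**c``.
Dividing by total cost gives the assay's utility ``U = v**c / P`` (expected
complete mechanisms per currency unit), the ranking criterion for a new study.

For extending an existing study of ``n`` cases, two strategies compete under
one budget: assay new cases with the original assay (strategy A, raising ``n``
to ``n_A``) or re-assay the existing cases with an additional assay (strategy
B, raising ``v`` to ``v_B``).  The strategies tie exactly when

    v_B / v = (P_B / P_A + 1) ** (1 / c)

which is independent of ``n`` and partitions the (price-ratio, hit-rate-ratio)
plane into regions favouring A or B per complexity.

Layout of this file, in the order the method runs:

  1. configuration constants and logging
  2. domain types (Assay, DiseaseModel, distributions, scenarios)
  3. closed-form core model (discoverability, yields, utility, price ratio)
  4. scenario 1 -- ranking candidate assays for a new study
  5. scenario 2 -- extension strategies, breakeven formulas, partition grid
  6. Monte-Carlo simulation oracle
  7. catalog I/O and report rendering

All prices are abstract positive currency units (only ratios matter) and a
"case-unit" is whatever unit is priced -- a singleton case or a full trio.
"""

from __future__ import annotations

import io
import json
import logging
import math
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterable, NamedTuple, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "Assay",
    "DiseaseModel",
    "MechanismCountDistribution",
    "DesignEvaluation",
    "ExtensionScenario",
    "StrategyVerdict",
    "Breakeven",
    "PartitionGrid",
    "SimulationConfig",
    "SimulationResult",
    "ExtensionSimulation",
    "InvalidParameterError",
    "InfeasibleCombinationError",
    "CatalogError",
    "DEFAULT_CATALOG",
    "DISPLAY_DIGITS",
    "EQUIVALENCE_RTOL",
    "discoverability",
    "expected_complete_mechanisms",
    "mechanism_count_distribution",
    "assay_utility",
    "equivalent_price_ratio",
    "combine_assays",
    "affordable_sample_size",
    "evaluate_design",
    "rank_assays",
    "ranking_report",
    "extension_yields",
    "extension_sample_ratio",
    "equivalence_hit_ratio",
    "min_extra_hit_rate",
    "required_base_hit_rate",
    "partition_parameter_space",
    "simulate_study",
    "simulate_extension",
    "load_catalog",
    "render_report",
    "provenance",
]

__version__ = "1.0.0"

# ----------------------------------------------------------------------------
# 1. configuration
# ----------------------------------------------------------------------------

#: Decimal places used for display rounding (full precision is always kept).
DISPLAY_DIGITS = 2

#: Relative tolerance when classifying two strategies as equivalent.  Cells on
#: a decision boundary must not flip label under floating-point noise.
EQUIVALENCE_RTOL = 1e-9

#: Default Monte-Carlo replicate count: small enough for seconds on one CPU,
#: large enough that the standard error resolves example-scale differences.
DEFAULT_REPLICATES = 100_000

logger = logging.getLogger("assaydesign")


class InvalidParameterError(ValueError):
    """A model parameter is outside its valid domain."""


class InfeasibleCombinationError(ValueError):
    """A combined assay would have a hit rate outside [0, 1]."""


class CatalogError(ValueError):
    """An assay catalog file fails schema validation."""


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise InvalidParameterError(message)


# ----------------------------------------------------------------------------
# 2. domain types
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class Assay:
    """A named assay with a hit rate and a price per case-unit.

    Parameters
    ----------
    name:
        Label used in reports ("WES", "chip-CNV", ...).
    hit_rate:
        Probability ``v`` in [0, 1] that a disease risk mutation lies within
        the loci the assay covers.
    price:
        Cost ``P`` per case-unit in arbitrary positive currency units; only
        price ratios enter any decision.
    """

    name: str
    hit_rate: float
    price: float

    def __post_init__(self) -> None:
        _require(0.0 <= self.hit_rate <= 1.0,
                 f"hit_rate must be in [0, 1], got {self.hit_rate}")
        _require(self.price > 0, f"price must be > 0, got {self.price}")


@dataclass(frozen=True)
class DiseaseModel:
    """Disease complexity: the number of risk mutations per causal mechanism.

    ``complexity`` is any real number >= 1 (the closed forms are well defined
    for real exponents and the decision boundaries are often swept
    continuously); integer values are the typical use.  ``math.inf`` is
    accepted and handled analytically where it appears.
    """

    complexity: float

    def __post_init__(self) -> None:
        _require(self.complexity >= 1,
                 f"complexity must be >= 1, got {self.complexity}")


@dataclass(frozen=True)
class MechanismCountDistribution:
    """Binomial distribution of the number of completely observed mechanisms.

    ``m ~ Bin(n, d)`` where ``d = v**c`` is the per-case discoverability.
    Thin wrapper around :mod:`scipy.stats` exposing the mass function,
    cumulative mass and upper tail.
    """

    n: int
    d: float
    _dist: Any = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        _require(self.n >= 0, f"n must be >= 0, got {self.n}")
        _require(0.0 <= self.d <= 1.0, f"d must be in [0, 1], got {self.d}")
        object.__setattr__(self, "_dist", stats.binom(self.n, self.d))

    @property
    def mean(self) -> float:
        return self.n * self.d

    @property
    def variance(self) -> float:
        return self.n * self.d * (1.0 - self.d)

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.n + 1)

    def pmf(self, k: int | np.ndarray) -> float | np.ndarray:
        """P(m = k)."""
        return self._dist.pmf(k)

    def cdf(self, k: int | np.ndarray) -> float | np.ndarray:
        """P(m <= k)."""
        return self._dist.cdf(k)

    def tail(self, k: int | np.ndarray) -> float | np.ndarray:
        """P(m >= k) -- the chance of seeing at least ``k`` complete mechanisms."""
        return self._dist.sf(np.asarray(k) - 1)


@dataclass(frozen=True)
class DesignEvaluation:
    """One assay resolved against a budget and a disease model."""

    assay: Assay
    n: int
    discoverability: float
    expected_yield: float
    utility: float
    budget_spent: float
    budget_left: float


class Breakeven(NamedTuple):
    """A breakeven quantity with a feasibility flag (hit rates must stay <= 1)."""

    value: float
    feasible: bool


@dataclass(frozen=True)
class ExtensionScenario:
    """An existing study plus the parameters of the two extension strategies.

    ``n`` existing case-units were assayed at hit rate ``base_hit_rate`` (price
    ``price_A`` per case-unit).  Strategy A spends ``budget`` on more
    case-units with the same assay; strategy B spends it re-assaying the
    existing ``n`` case-units with an additional assay priced at ``price_B``,
    lifting the combined hit rate to ``augmented_hit_rate``.
    """

    n: int
    base_hit_rate: float
    augmented_hit_rate: float
    complexity: float
    price_A: float
    price_B: float
    budget: float

    def __post_init__(self) -> None:
        _require(self.n >= 1, f"n must be >= 1, got {self.n}")
        _require(0.0 <= self.base_hit_rate <= self.augmented_hit_rate <= 1.0,
                 "need 0 <= base_hit_rate <= augmented_hit_rate <= 1, got "
                 f"v={self.base_hit_rate}, v_B={self.augmented_hit_rate}")
        _require(self.complexity >= 1,
                 f"complexity must be >= 1, got {self.complexity}")
        _require(self.price_A > 0 and self.price_B > 0,
                 "prices must be > 0")
        _require(self.budget >= 0, f"budget must be >= 0, got {self.budget}")

    @classmethod
    def from_added_assay(cls, n: int, base: Assay, added: Assay,
                         complexity: float, budget: float,
                         overlap: float = 0.0) -> "ExtensionScenario":
        """Build a scenario where strategy B applies ``added`` on top of ``base``.

        The augmented hit rate is the no-overlap sum ``v + v_added`` minus the
        ``overlap`` probability mass covered by both assays.
        """
        combined = combine_assays([base, added], overlap=overlap)
        return cls(n=n, base_hit_rate=base.hit_rate,
                   augmented_hit_rate=combined.hit_rate,
                   complexity=complexity, price_A=base.price,
                   price_B=added.price, budget=budget)


@dataclass(frozen=True)
class StrategyVerdict:
    """Outcome of comparing extension strategies A and B at equal budget."""

    yield_A: float
    yield_B: float
    n_A: int | float
    favoured: str  # one of "A", "B", "equivalent", "infeasible"
    breakeven_delta: Breakeven
    breakeven_base_hit_rate: Breakeven
    feasibility_notes: str = ""


@dataclass(frozen=True)
class PartitionGrid:
    """Favoured-strategy labels over (price-ratio, hit-rate-ratio) space.

    ``labels[c]`` is a (hit-ratio x price-ratio) array of strings in
    {"A", "B", "equivalent", "infeasible"}; ``boundary_curves[c]`` gives the
    equivalence locus v_B/v over ``price_ratios`` for complexity ``c``
    (``math.inf`` allowed: its boundary is the constant line 1).
    """

    price_ratios: np.ndarray
    hit_ratios: np.ndarray
    labels: dict[float, np.ndarray]
    boundary_curves: dict[float, np.ndarray]

    def to_records(self) -> list[dict[str, Any]]:
        """Flatten to one record per (cell, complexity) for TSV export."""
        out = []
        for c, lab in self.labels.items():
            for i, r in enumerate(self.hit_ratios):
                for j, p in enumerate(self.price_ratios):
                    out.append({"price_ratio": float(p), "hit_ratio": float(r),
                                "complexity": c, "label": str(lab[i, j])})
        return out


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for the generative Monte-Carlo model.

    Each simulated case carries ``complexity`` private risk mutations, each
    captured independently with probability ``hit_rate``; the case counts
    toward ``m`` only if all are captured.  ``extra_mutation_prob`` optionally
    gives some cases ``extra_mutation_count`` additional causal mutations, to
    probe how the closed form degrades when complexity is not exact; it is 0
    by default, matching the model's assumption.
    """

    n_cases: int
    complexity: int
    hit_rate: float
    n_replicates: int = DEFAULT_REPLICATES
    seed: int = 0
    extra_mutation_prob: float = 0.0
    extra_mutation_count: int = 1

    def __post_init__(self) -> None:
        _require(self.n_cases >= 0, "n_cases must be >= 0")
        _require(int(self.complexity) == self.complexity and self.complexity >= 1,
                 "simulation requires integer complexity >= 1")
        _require(0.0 <= self.hit_rate <= 1.0, "hit_rate must be in [0, 1]")
        _require(self.n_replicates >= 1, "n_replicates must be >= 1")
        _require(0.0 <= self.extra_mutation_prob <= 1.0,
                 "extra_mutation_prob must be in [0, 1]")
        _require(self.extra_mutation_count >= 0,
                 "extra_mutation_count must be >= 0")


@dataclass(frozen=True)
class SimulationResult:
    """Per-replicate counts of completely observed mechanisms, summarised."""

    counts: np.ndarray
    mean: float
    variance: float
    sem: float


@dataclass(frozen=True)
class ExtensionSimulation:
    """Paired simulation of the two extension strategies."""

    strategy_A: SimulationResult
    strategy_B: SimulationResult
    yield_difference: float
    difference_sem: float


# ----------------------------------------------------------------------------
# 3. closed-form core model
# ----------------------------------------------------------------------------


def discoverability(hit_rate: float, complexity: float) -> float:
    """Probability ``d = v**c`` that a case's complete mechanism is observed.

    Treated as exact: the correction for cases carrying more than ``c``
    causal mutations is negligible for rare diseases and is not applied.
    """
    _require(0.0 <= hit_rate <= 1.0,
             f"hit_rate must be in [0, 1], got {hit_rate}")
    _require(complexity >= 1, f"complexity must be >= 1, got {complexity}")
    if math.isinf(complexity):
        return 1.0 if hit_rate == 1.0 else 0.0
    return hit_rate ** complexity


def expected_complete_mechanisms(n: float, hit_rate: float,
                                 complexity: float) -> float:
    """Expected number of completely observed mechanisms, ``E[m] = n * v**c``."""
    _require(n >= 0, f"n must be >= 0, got {n}")
    return n * discoverability(hit_rate, complexity)


def mechanism_count_distribution(n: int, hit_rate: float,
                                 complexity: float) -> MechanismCountDistribution:
    """Full distribution of ``m``: binomial over ``n`` cases at ``d = v**c``."""
    _require(isinstance(n, (int, np.integer)) and not isinstance(n, bool),
             f"n must be an integer, got {n!r}")
    return MechanismCountDistribution(n=int(n),
                                      d=discoverability(hit_rate, complexity))


def assay_utility(assay: Assay, disease: DiseaseModel) -> float:
    """Cost effectiveness ``U = v**c / P``: expected complete mechanisms per
    currency unit.  Independent of how many case-units are bought."""
    return discoverability(assay.hit_rate, disease.complexity) / assay.price


def equivalent_price_ratio(hit_rate_1: float, hit_rate_2: float,
                           complexity: float) -> float:
    """Maximum price multiple ``P2/P1 = (v2/v1)**c`` at which assay 2 stays
    at least as cost-effective as assay 1."""
    _require(hit_rate_1 > 0, "hit_rate_1 must be > 0 to form the ratio")
    _require(0.0 <= hit_rate_2 <= 1.0,
             f"hit_rate_2 must be in [0, 1], got {hit_rate_2}")
    _require(complexity >= 1, f"complexity must be >= 1, got {complexity}")
    return (hit_rate_2 / hit_rate_1) ** complexity


def combine_assays(assays: Sequence[Assay], overlap: float = 0.0) -> Assay:
    """Treat a set of assays applied jointly as one synthetic assay.

    With the default ``overlap = 0`` the combined hit rate is the plain sum of
    the component hit rates -- the no-overlap assumption under which risk
    mutations detectable by one assay are invisible to the others.  A positive
    ``overlap`` subtracts the probability mass covered more than once.  The
    combined price is always the sum of prices.
    """
    if not assays:
        raise InvalidParameterError("need at least one assay to combine")
    _require(overlap >= 0, f"overlap must be >= 0, got {overlap}")
    hit = sum(a.hit_rate for a in assays) - overlap
    if not 0.0 <= hit <= 1.0:
        raise InfeasibleCombinationError(
            f"combined hit rate {hit:.4g} is outside [0, 1]")
    if len(assays) == 1 and overlap == 0.0:
        return assays[0]
    return Assay(name="+".join(a.name for a in assays),
                 hit_rate=hit, price=sum(a.price for a in assays))


# ----------------------------------------------------------------------------
# 4. scenario 1 -- assay choice for a new study
# ----------------------------------------------------------------------------


def affordable_sample_size(budget: float, price: float) -> int:
    """Whole case-units affordable: ``floor(budget / price)``."""
    _require(budget >= 0, f"budget must be >= 0, got {budget}")
    _require(price > 0, f"price must be > 0, got {price}")
    return int(math.floor(budget / price))


def evaluate_design(budget: float, assay: Assay,
                    disease: DiseaseModel) -> DesignEvaluation:
    """Resolve one assay against a budget: sample size, yield, utility."""
    n = affordable_sample_size(budget, assay.price)
    d = discoverability(assay.hit_rate, disease.complexity)
    spent = n * assay.price
    return DesignEvaluation(
        assay=assay, n=n, discoverability=d,
        expected_yield=expected_complete_mechanisms(
            n, assay.hit_rate, disease.complexity),
        utility=assay_utility(assay, disease),
        budget_spent=spent, budget_left=budget - spent)


def rank_assays(budget: float, catalog: Sequence[Assay],
                disease: DiseaseModel) -> list[DesignEvaluation]:
    """Evaluate every assay in the catalog and sort by utility, descending.

    Ties break on lower price, then name, so output is deterministic.  With
    integer sample sizes the utility order can differ from the expected-yield
    order when budgets do not divide evenly; :func:`ranking_report` flags that.
    """
    if not catalog:
        raise InvalidParameterError("catalog must contain at least one assay")
    evals = [evaluate_design(budget, a, disease) for a in catalog]
    evals.sort(key=lambda e: (-e.utility, e.assay.price, e.assay.name))
    return evals


def ranking_report(budget: float, catalog: Sequence[Assay],
                   disease: DiseaseModel,
                   ndigits: int = DISPLAY_DIGITS) -> dict[str, Any]:
    """Ranking plus pairwise yield ratios at full and display precision.

    The display-precision ratio is formed from rounded intermediate yields
    (e.g. 0.29 / 0.23 = 1.26), matching how such comparisons are quoted in
    practice; the full-precision ratio is reported alongside.
    """
    evals = rank_assays(budget, catalog, disease)
    by_yield = sorted(evals, key=lambda e: (-e.expected_yield,
                                            e.assay.price, e.assay.name))
    ratios = []
    for i, hi in enumerate(evals):
        for lo in evals[i + 1:]:
            full = (hi.expected_yield / lo.expected_yield
                    if lo.expected_yield > 0 else math.inf)
            r_hi = round(hi.expected_yield, ndigits)
            r_lo = round(lo.expected_yield, ndigits)
            ratios.append({
                "numerator": hi.assay.name, "denominator": lo.assay.name,
                "yield_ratio": full,
                "yield_ratio_display": (round(r_hi / r_lo, ndigits)
                                        if r_lo > 0 else math.inf),
            })
    return {
        "ranking": evals,
        "yield_order": [e.assay.name for e in by_yield],
        "utility_order": [e.assay.name for e in evals],
        "order_disagreement": [e.assay.name for e in evals]
                              != [e.assay.name for e in by_yield],
        "pairwise_yield_ratios": ratios,
    }


# ----------------------------------------------------------------------------
# 5. scenario 2 -- extending an existing study
# ----------------------------------------------------------------------------


def extension_sample_ratio(base_hit_rate: float, augmented_hit_rate: float,
                           complexity: float) -> float:
    """Sample-size multiple ``n_A/n = (v_B/v)**c`` strategy A needs to match
    strategy B's yield."""
    _require(base_hit_rate > 0, "base_hit_rate must be > 0 to form the ratio")
    _require(0.0 <= augmented_hit_rate <= 1.0,
             "augmented_hit_rate must be in [0, 1]")
    _require(complexity >= 1, f"complexity must be >= 1, got {complexity}")
    return (augmented_hit_rate / base_hit_rate) ** complexity


def equivalence_hit_ratio(price_B: float, price_A: float,
                          complexity: float) -> float:
    """Hit-rate ratio ``v_B/v = (P_B/P_A + 1)**(1/c)`` at which the two
    equal-budget strategies tie.

    Strictly decreasing in ``c``; for ``c = math.inf`` it is exactly 1 (the
    additional assay must add *something* for strategy B ever to win).
    """
    _require(price_A > 0 and price_B > 0, "prices must be > 0")
    _require(complexity >= 1, f"complexity must be >= 1, got {complexity}")
    if math.isinf(complexity):
        return 1.0
    return (price_B / price_A + 1.0) ** (1.0 / complexity)


def min_extra_hit_rate(base_hit_rate: float, price_B: float, price_A: float,
                       complexity: float) -> Breakeven:
    """Minimum hit-rate increment strategy B's extra assay must contribute to
    match strategy A: ``delta = v * [(P_B/P_A + 1)**(1/c) - 1]``.

    Flagged infeasible when ``v + delta`` exceeds 1: no real assay can confer
    that much, so strategy A wins at any attainable hit rate.
    """
    _require(0.0 <= base_hit_rate <= 1.0, "base_hit_rate must be in [0, 1]")
    delta = base_hit_rate * (equivalence_hit_ratio(price_B, price_A,
                                                   complexity) - 1.0)
    return Breakeven(value=delta, feasible=base_hit_rate + delta <= 1.0)


def required_base_hit_rate(delta: float, price_B: float, price_A: float,
                           complexity: float) -> Breakeven:
    """Base hit rate at which strategy A ties strategy B that confers an extra
    hit rate ``delta``: ``v = delta / [(P_B/P_A + 1)**(1/c) - 1]``.

    The algebraic inverse of :func:`min_extra_hit_rate`.  Values above 1 are
    returned with ``feasible=False`` -- an impossibly high hit rate, meaning
    strategy B dominates for every attainable ``v``.
    """
    _require(delta >= 0, f"delta must be >= 0, got {delta}")
    denom = equivalence_hit_ratio(price_B, price_A, complexity) - 1.0
    if denom == 0.0:  # c = inf: any positive delta favours B outright
        v = 0.0 if delta == 0.0 else math.inf
    else:
        v = delta / denom
    return Breakeven(value=v, feasible=v <= 1.0)


def _classify(yield_A: float, yield_B: float,
              rtol: float = EQUIVALENCE_RTOL) -> str:
    scale = max(abs(yield_A), abs(yield_B), 1e-300)
    if abs(yield_A - yield_B) <= rtol * scale:
        return "equivalent"
    return "A" if yield_A > yield_B else "B"


def extension_yields(scenario: ExtensionScenario, *,
                     continuous_n: bool = False) -> StrategyVerdict:
    """Compare the two extension strategies at equal budget.

    Strategy A buys ``floor(budget / price_A)`` additional case-units (or the
    continuous fraction when ``continuous_n=True``, the convention under which
    the breakeven formulas are exact).  Strategy B costs ``n * price_B``; if
    that exceeds the budget the verdict is flagged infeasible rather than
    compared on yields it cannot fund.
    """
    sc = scenario
    extra = (sc.budget / sc.price_A if continuous_n
             else affordable_sample_size(sc.budget, sc.price_A))
    n_A = sc.n + extra
    yield_A = expected_complete_mechanisms(n_A, sc.base_hit_rate,
                                           sc.complexity)
    yield_B = expected_complete_mechanisms(sc.n, sc.augmented_hit_rate,
                                           sc.complexity)
    cost_B = sc.n * sc.price_B
    notes = []
    if extra == 0:
        notes.append("budget buys no additional case-unit for strategy A")
    if cost_B > sc.budget:
        notes.append(f"strategy B needs {cost_B:g} but budget is "
                     f"{sc.budget:g}: infeasible")
        favoured = "infeasible"
    else:
        favoured = _classify(yield_A, yield_B)
    return StrategyVerdict(
        yield_A=yield_A, yield_B=yield_B, n_A=n_A, favoured=favoured,
        breakeven_delta=min_extra_hit_rate(
            sc.base_hit_rate, sc.price_B, sc.price_A, sc.complexity),
        breakeven_base_hit_rate=required_base_hit_rate(
            sc.augmented_hit_rate - sc.base_hit_rate,
            sc.price_B, sc.price_A, sc.complexity),
        feasibility_notes="; ".join(notes))


def partition_parameter_space(price_ratio_range: tuple[float, float],
                              hit_ratio_range: tuple[float, float],
                              complexities: Sequence[float],
                              resolution: int = 101) -> PartitionGrid:
    """Label a grid over (P_B/P_A, v_B/v) by the favoured extension strategy.

    A cell favours strategy B when its hit-rate ratio exceeds the equivalence
    locus ``(P_B/P_A + 1)**(1/c)`` at its price ratio, strategy A when below,
    and is "infeasible" where v_B/v < 1 (the additional assay cannot lower the
    combined hit rate).  The grid is scale-free: only the two ratios matter,
    never the absolute prices, hit rates or sample size.
    """
    p_lo, p_hi = price_ratio_range
    r_lo, r_hi = hit_ratio_range
    _require(0 < p_lo < p_hi, "price_ratio_range must be increasing, > 0")
    _require(0 < r_lo < r_hi, "hit_ratio_range must be increasing, > 0")
    _require(resolution >= 2, "resolution must be >= 2")
    _require(len(complexities) > 0, "need at least one complexity")
    price_ratios = np.linspace(p_lo, p_hi, resolution)
    hit_ratios = np.linspace(r_lo, r_hi, resolution)
    labels: dict[float, np.ndarray] = {}
    boundaries: dict[float, np.ndarray] = {}
    for c in complexities:
        _require(c >= 1, f"complexity must be >= 1, got {c}")
        boundary = np.array([equivalence_hit_ratio(p, 1.0, c)
                             for p in price_ratios])
        lab = np.empty((resolution, resolution), dtype=object)
        for i, r in enumerate(hit_ratios):
            for j in range(resolution):
                if r < 1.0:
                    lab[i, j] = "infeasible"
                    continue
                b = boundary[j]
                if abs(r - b) <= EQUIVALENCE_RTOL * max(r, b):
                    lab[i, j] = "equivalent"
                else:
                    lab[i, j] = "B" if r > b else "A"
        labels[c] = lab
        boundaries[c] = boundary
    return PartitionGrid(price_ratios=price_ratios, hit_ratios=hit_ratios,
                         labels=labels, boundary_curves=boundaries)


def plot_partition(grid: PartitionGrid, complexity: float, path: str | Path,
                   boundary_complexities: Sequence[float] = ()) -> None:
    """Render a partition grid as a raster figure.

    Shades the favoured-strategy regions for ``complexity`` and overlays the
    equivalence boundary of every complexity in the grid.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lab = grid.labels[complexity]
    code = np.zeros(lab.shape)
    code[lab == "A"] = 1.0
    code[lab == "B"] = 2.0
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.pcolormesh(grid.price_ratios, grid.hit_ratios, code,
                  cmap="Greys", vmin=0, vmax=3, shading="nearest")
    for c in (boundary_complexities or grid.boundary_curves):
        ax.plot(grid.price_ratios, grid.boundary_curves[c], ls=":",
                label=f"c = {c:g}" if not math.isinf(c) else "c = inf")
    ax.set_xlabel("price ratio  $P_B / P_A$")
    ax.set_ylabel("hit-rate ratio  $v_B / v$")
    ax.set_title(f"Favoured extension strategy (shaded for c = {complexity:g})")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ----------------------------------------------------------------------------
# 6. Monte-Carlo simulation oracle
# ----------------------------------------------------------------------------


def _simulate_counts(rng: np.random.Generator,
                     cfg: SimulationConfig) -> np.ndarray:
    """Draw per-replicate counts of completely observed mechanisms.

    Simulates the generative assumptions directly -- each case carries its own
    private mutations, each captured independently with probability
    ``hit_rate`` -- never the derived closed forms, so the result is an
    independent check on them.
    """
    shape = (cfg.n_replicates, cfg.n_cases)
    if cfg.n_cases == 0:
        return np.zeros(cfg.n_replicates, dtype=np.int64)
    muts = np.full(shape, int(cfg.complexity), dtype=np.int64)
    if cfg.extra_mutation_prob > 0.0:
        muts += cfg.extra_mutation_count * (
            rng.random(shape) < cfg.extra_mutation_prob)
    # per-case capture events: all `muts` independent Bernoulli(v) must hit
    captured = rng.binomial(muts, cfg.hit_rate)
    return (captured == muts).sum(axis=1).astype(np.int64)


def _summarise(counts: np.ndarray) -> SimulationResult:
    var = float(counts.var(ddof=1)) if counts.size > 1 else 0.0
    return SimulationResult(counts=counts, mean=float(counts.mean()),
                            variance=var,
                            sem=math.sqrt(var / counts.size))


def simulate_study(config: SimulationConfig) -> SimulationResult:
    """Monte-Carlo replicate counts of completely observed mechanisms.

    The empirical mean converges to ``n * v**c`` and the variance to the
    binomial ``n * d * (1 - d)``; both are checked in the test suite against
    the closed forms.  Identical seeds reproduce the full output stream.
    """
    rng = np.random.default_rng(config.seed)
    return _summarise(_simulate_counts(rng, config))


def simulate_extension(scenario: ExtensionScenario,
                       config: SimulationConfig) -> ExtensionSimulation:
    """Simulate both extension strategies and their yield difference.

    Strategy A runs ``n_A`` cases at the base hit rate; strategy B runs the
    original ``n`` cases at the augmented hit rate.  Both use deterministic
    child streams of ``config.seed`` so results are reproducible.
    """
    verdict = extension_yields(scenario)
    seed_A, seed_B = np.random.SeedSequence(config.seed).spawn(2)
    cfg_A = SimulationConfig(
        n_cases=int(verdict.n_A), complexity=config.complexity,
        hit_rate=scenario.base_hit_rate, n_replicates=config.n_replicates)
    cfg_B = SimulationConfig(
        n_cases=scenario.n, complexity=config.complexity,
        hit_rate=scenario.augmented_hit_rate,
        n_replicates=config.n_replicates)
    res_A = _summarise(_simulate_counts(np.random.default_rng(seed_A), cfg_A))
    res_B = _summarise(_simulate_counts(np.random.default_rng(seed_B), cfg_B))
    diff = res_B.counts - res_A.counts
    return ExtensionSimulation(
        strategy_A=res_A, strategy_B=res_B,
        yield_difference=float(diff.mean()),
        difference_sem=math.sqrt(diff.var(ddof=1) / diff.size))


# ----------------------------------------------------------------------------
# 7. catalog I/O and report rendering
# ----------------------------------------------------------------------------

#: Default assay catalog.  Hit rates are the diagnostic rates observed for the
#: three assays in a large severe-intellectual-disability cohort (12% for
#: chip-based CNV detection, 27% for WES, 62% for WGS) -- lower bounds on the
#: true hit rates, since a mutation can be covered without yielding a
#: diagnosis.  Prices are in chip-units: WES at 4x chip price, WGS at 4x WES.
DEFAULT_CATALOG: tuple[Assay, ...] = (
    Assay(name="chip-CNV", hit_rate=0.12, price=1.0),
    Assay(name="WES", hit_rate=0.27, price=4.0),
    Assay(name="WGS", hit_rate=0.62, price=16.0),
)


def load_catalog(path: str | Path) -> list[Assay]:
    """Load and validate an assay catalog from a YAML or JSON file.

    The file must contain a list of records ``{name, hit_rate, price}``.
    Validation failures raise :class:`CatalogError` naming the offending
    record and field; duplicate assay names are rejected.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise CatalogError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(raw, list) or not raw:
        raise CatalogError(f"{path}: catalog must be a non-empty list of "
                           "{name, hit_rate, price} records")
    assays: list[Assay] = []
    seen: set[str] = set()
    for idx, rec in enumerate(raw):
        if not isinstance(rec, dict):
            raise CatalogError(f"{path}: record {idx} is not a mapping")
        missing = {"name", "hit_rate", "price"} - rec.keys()
        if missing:
            raise CatalogError(
                f"{path}: record {idx} is missing {sorted(missing)}")
        extra = rec.keys() - {"name", "hit_rate", "price"}
        if extra:
            raise CatalogError(
                f"{path}: record {idx} has unknown fields {sorted(extra)}")
        try:
            assay = Assay(name=str(rec["name"]),
                          hit_rate=float(rec["hit_rate"]),
                          price=float(rec["price"]))
        except (TypeError, ValueError) as exc:
            raise CatalogError(f"{path}: record {idx} "
                               f"({rec.get('name', '?')}): {exc}") from exc
        if assay.name in seen:
            raise CatalogError(f"{path}: duplicate assay name {assay.name!r}")
        seen.add(assay.name)
        assays.append(assay)
    return assays


def provenance(seed: int | None = None, **params: Any) -> dict[str, Any]:
    """Provenance record written alongside every result: version, seed, inputs."""
    return {"package": "assaydesign", "version": __version__,
            "seed": seed, "parameters": params}


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Breakeven):
        return {"value": obj.value, "feasible": obj.feasible}
    if isinstance(obj, (Assay, DesignEvaluation, StrategyVerdict,
                        DiseaseModel, ExtensionScenario)):
        return _jsonable(asdict(obj))
    if isinstance(obj, MechanismCountDistribution):
        return {"n": obj.n, "d": obj.d, "mean": obj.mean,
                "pmf": [float(x) for x in obj.pmf(obj.support)]}
    if isinstance(obj, SimulationResult):
        return {"mean": obj.mean, "variance": obj.variance, "sem": obj.sem,
                "n_replicates": int(obj.counts.size)}
    if isinstance(obj, ExtensionSimulation):
        return {"strategy_A": _jsonable(obj.strategy_A),
                "strategy_B": _jsonable(obj.strategy_B),
                "yield_difference": obj.yield_difference,
                "difference_sem": obj.difference_sem}
    if isinstance(obj, PartitionGrid):
        return {"records": obj.to_records()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    return obj


def _with_display(obj: Any, ndigits: int) -> Any:
    """Pair every float with its display rounding, recursively."""
    if isinstance(obj, dict):
        out = {}
        for k, v in obj.items():
            out[k] = _with_display(v, ndigits)
            if isinstance(v, float) and math.isfinite(v):
                out[f"{k}_display"] = round(v, ndigits)
        return out
    if isinstance(obj, list):
        return [_with_display(v, ndigits) for v in obj]
    return obj


def render_report(results: Any, format: str = "json",
                  ndigits: int = DISPLAY_DIGITS) -> str:
    """Serialize a result object deterministically.

    ``json`` carries full precision plus ``*_display`` fields rounded to
    ``ndigits``; ``tsv`` flattens lists of records; ``text`` gives a
    human-readable summary.  Identical inputs give byte-identical output.
    """
    data = _jsonable(results)
    if format == "json":
        return json.dumps(_with_display(data, ndigits), indent=2,
                          sort_keys=True) + "\n"
    if format == "tsv":
        records = _flatten_records(data)
        buf = io.StringIO()
        if records:
            cols = list(records[0])
            buf.write("\t".join(cols) + "\n")
            for rec in records:
                buf.write("\t".join(_cell(rec.get(c)) for c in cols) + "\n")
        return buf.getvalue()
    if format == "text":
        return _text_report(data, ndigits) + "\n"
    raise InvalidParameterError(f"unknown report format: {format!r}")


def _cell(v: Any) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _flatten_records(data: Any) -> list[dict[str, Any]]:
    if isinstance(data, dict):
        for key in ("records", "ranking"):
            if key in data and isinstance(data[key], list):
                return _flatten_records(data[key])
        return [_flatten_one(data)]
    if isinstance(data, list):
        return [_flatten_one(r) for r in data]
    return [{"value": data}]


def _flatten_one(rec: Any, prefix: str = "") -> dict[str, Any]:
    if not isinstance(rec, dict):
        return {prefix or "value": rec}
    flat: dict[str, Any] = {}
    for k, v in rec.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            flat.update(_flatten_one(v, prefix=f"{key}."))
        elif isinstance(v, list):
            flat[key] = json.dumps(v)
        else:
            flat[key] = v
    return flat


def _text_report(data: Any, ndigits: int, indent: int = 0) -> str:
    pad = "  " * indent
    lines: list[str] = []
    if isinstance(data, dict):
        for k, v in data.items():
            if isinstance(v, (dict, list)):
                lines.append(f"{pad}{k}:")
                lines.append(_text_report(v, ndigits, indent + 1))
            elif isinstance(v, float):
                lines.append(f"{pad}{k}: {round(v, ndigits)} "
                             f"(full: {v!r})")
            else:
                lines.append(f"{pad}{k}: {v}")
    elif isinstance(data, list):
        for item in data:
            lines.append(_text_report(item, ndigits, indent))
    else:
        lines.append(f"{pad}{data}")
    return "\n".join(line for line in lines if line)
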