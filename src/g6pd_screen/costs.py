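"""Testing-cost accounting per strategy and cost sensitivity analysis.

Costs are per administered test and strategy-independent: total cost is
``n_activity_tests * activity_cost + n_genotyping_tests *
genotyping_cost`` and cost per diagnosed case divides by the number of
diagnosed carriers (half-up to 2 decimals at presentation).  Default
prices are the median self-pay charges used in the source cost model:
$3 per activity test, $50 per targeted genotyping.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

__all__ = [
    "CostSchedule",
    "CostResult",
    "strategy_cost",
    "cost_sensitivity",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CostSchedule:
    """Per-test prices in USD; the CNY rate is informational only."""

    activity_cost: float = 3.0
    genotyping_cost: float = 50.0
    cny_per_usd: float = 6.8

    def __post_init__(self) -> None:
        if self.activity_cost < 0 or self.genotyping_cost < 0:
            raise ValueError("test costs must be nonnegative")
        if self.cny_per_usd <= 0:
            raise ValueError("exchange rate must be positive")


@dataclass(frozen=True)
class CostResult:
    total_cost: float  # USD
    cost_per_diagnosed: float | None  # USD, half-up to 2 decimals; None if 0 dx
    diagnosed: float

    def total_cny(self, schedule: CostSchedule) -> float:
        return self.total_cost * schedule.cny_per_usd


def strategy_cost(outcome, schedule: CostSchedule = CostSchedule()) -> CostResult:
    """Price a strategy outcome (exact counts or analytic expectations).

    ``outcome`` needs ``n_activity_tests``, ``n_genotyping_tests`` and
    ``diagnosed`` attributes, so both empirical and expected outcomes
    are accepted.
    """
    total = (
        outcome.n_activity_tests * schedule.activity_cost
        + outcome.n_genotyping_tests * schedule.genotyping_cost
    )
    per = (
        round_half_up(total / outcome.diagnosed, 2) if outcome.diagnosed > 0 else None
    )
    return CostResult(
        total_cost=total, cost_per_diagnosed=per, diagnosed=outcome.diagnosed
    )


def cost_sensitivity(
    strategy,
    config,
    activity_costs: Sequence[float] = (3.0,),
    genotyping_costs: Sequence[float] = (50.0,),
    female_fractions: Sequence[float] = (118 / 555,),
    n: int = 10_000,
) -> pd.DataFrame:
    """Expected cost per diagnosed case over a price/composition grid.

    For each grid point the cohort model's analytic class probabilities
    (not a Monte-Carlo draw) give the expected test counts and diagnoses
    for a hypothetical cohort of ``n`` infants, so the reported costs
    are smooth in every grid variable.
    """
    from dataclasses import replace

    from .simulate import expected_strategy_outcome

    if not (activity_costs and genotyping_costs and female_fractions):
        raise ValueError("cost sensitivity grid must be nonempty")
    rows = []
    for ff in female_fractions:
        if not 0 <= ff <= 1:
            raise ValueError(f"female_fraction {ff} outside [0, 1]")
        cfg = replace(config, female_fraction=float(ff))
        expected = expected_strategy_outcome(strategy, cfg, n=n)
        for ac in activity_costs:
            for gc in genotyping_costs:
                schedule = CostSchedule(activity_cost=ac, genotyping_cost=gc)
                cost = strategy_cost(expected, schedule)
                rows.append(
                    {
                        "strategy": strategy.name,
                        "female_fraction": ff,
                        "activity_cost": ac,
                        "genotyping_cost": gc,
                        "expected_activity_tests": expected.n_activity_tests,
                        "expected_genotyping_tests": expected.n_genotyping_tests,
                        "expected_diagnosed": expected.diagnosed,
                        "expected_total_cost": cost.total_cost,
                        "expected_cost_per_diagnosed": cost.cost_per_diagnosed,
                    }
                )
    return pd.DataFrame(rows)
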