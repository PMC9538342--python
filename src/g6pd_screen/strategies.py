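"""Sequential diagnostic strategies and their evaluation on a cohort.

A :class:`Strategy` is an ordered list of stages; each stage administers
one test (activity or panel genotyping) to the sub-population selected
by a filter over sex and earlier-stage results.  An infant is diagnosed
if any administered test is positive and the infant truly carries a
pathogenic variant.  The five built-in strategies are the standard
isolated and reflex combinations used in Chinese NBS follow-up:

1. activity for everyone;
2. panel genotyping for everyone;
3. activity for everyone, then genotyping for females with normal activity;
4. genotyping for everyone, then activity for panel-negative infants;
5. both tests for everyone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

from .assays import classify_activity, cohort_truths, panel_call
from .cohort import (
    CarrierStatus,
    CohortTable,
    DEFAULT_PANEL,
    PanelDefinition,
    Sex,
)
from .performance import MetricValue

__all__ = [
    "StageFilter",
    "Stage",
    "Strategy",
    "StrategyOutcome",
    "StrategyConfigError",
    "builtin_strategies",
    "apply_strategy",
    "evaluate_all",
    "load_strategies",
]

TESTS = ("activity", "panel")


class StrategyConfigError(ValueError):
    """A strategy is structurally invalid (bad filter or repeated test)."""


@dataclass(frozen=True)
class StageFilter:
    """Predicate over sex and the results of earlier stages.

    ``activity``/``panel`` constrain the result of an earlier
    administration of that test; ``untested`` selects infants who have
    not yet received it; ``any`` is unconstrained.
    """

    sex: str = "any"  # male | female | any
    activity: str = "any"  # deficient | normal | any | untested
    panel: str = "any"  # positive | negative | any | untested

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "any"):
            raise StrategyConfigError(f"bad sex filter {self.sex!r}")
        if self.activity not in ("deficient", "normal", "any", "untested"):
            raise StrategyConfigError(f"bad activity filter {self.activity!r}")
        if self.panel not in ("positive", "negative", "any", "untested"):
            raise StrategyConfigError(f"bad panel filter {self.panel!r}")

    def matches(self, sex: Sex, results: dict[str, bool]) -> bool:
        # results maps test name -> positive flag for administered tests
        if self.sex != "any" and sex.value != self.sex:
            return False
        for test, want in (("activity", self.activity), ("panel", self.panel)):
            if want == "any":
                continue
            if want == "untested":
                if test in results:
                    return False
            elif test not in results:
                return False
            elif test == "activity":
                if (want == "deficient") != results[test]:
                    return False
            else:
                if (want == "positive") != results[test]:
                    return False
        return True


@dataclass(frozen=True)
class Stage:
    test: str  # "activity" | "panel"
    filter: StageFilter = field(default_factory=StageFilter)

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise StrategyConfigError(f"unknown test {self.test!r}")


@dataclass(frozen=True)
class Strategy:
    name: str
    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for i, stage in enumerate(self.stages, start=1):
            for test, want in (
                ("activity", stage.filter.activity),
                ("panel", stage.filter.panel),
            ):
                if want in ("any", "untested"):
                    continue
                if test not in seen:
                    raise StrategyConfigError(
                        f"strategy {self.name!r} stage {i}: filter references "
                        f"{test} results but no earlier stage administers it"
                    )
            seen.add(stage.test)

    def uses(self, test: str) -> bool:
        return any(s.test == test for s in self.stages)


@dataclass(frozen=True)
class StrategyOutcome:
    """Evaluation of one strategy on one cohort."""

    strategy: str
    diagnosed: int
    undiagnosed: int
    sensitivity: MetricValue
    n_activity_tests: int
    n_genotyping_tests: int
    allele_frequency_info: bool
    genotype_phenotype_info: bool
    diagnosed_ids: tuple[str, ...] = ()


def builtin_strategies() -> list[Strategy]:
    """The five standard confirmation strategies (see module docstring)."""
    everyone = StageFilter()
    return [
        Strategy("S1", (Stage("activity", everyone),)),
        Strategy("S2", (Stage("panel", everyone),)),
        Strategy(
            "S3",
            (
                Stage("activity", everyone),
                Stage("panel", StageFilter(sex="female", activity="normal")),
            ),
        ),
        Strategy(
            "S4",
            (
                Stage("panel", everyone),
                Stage("activity", StageFilter(panel="negative")),
            ),
        ),
        Strategy("S5", (Stage("activity", everyone), Stage("panel", everyone))),
    ]


def apply_strategy(
    cohort: CohortTable,
    strategy: Strategy,
    cutoff: float = 1.0,
    panel: PanelDefinition = DEFAULT_PANEL,
) -> StrategyOutcome:
    """Run a strategy's stages over every record and tally the outcome.

    Carriers are the sensitivity denominator regardless of which branch
    tested them.  Records with unresolvable truth abort the evaluation.
    """
    truths = cohort_truths(cohort)
    n_activity = n_panel = 0
    diagnosed_ids: list[str] = []
    n_carriers = sum(1 for t in truths.values() if t is CarrierStatus.CARRIER)
    for record in cohort:
        results: dict[str, bool] = {}
        for i, stage in enumerate(strategy.stages, start=1):
            if not stage.filter.matches(record.sex, results):
                continue
            if stage.test in results:
                raise StrategyConfigError(
                    f"strategy {strategy.name!r} stage {i} would administer "
                    f"{stage.test} twice to record {record.id}"
                )
            if stage.test == "activity":
                results["activity"] = classify_activity(
                    record.activity_ratio, cutoff
                ).deficient
                n_activity += 1
            else:
                results["panel"] = panel_call(record.panel_result, panel).positive
                n_panel += 1
        any_positive = any(results.values())
        if any_positive and truths[record.id] is CarrierStatus.CARRIER:
            diagnosed_ids.append(record.id)
    diagnosed = len(diagnosed_ids)
    return StrategyOutcome(
        strategy=strategy.name,
        diagnosed=diagnosed,
        undiagnosed=n_carriers - diagnosed,
        sensitivity=MetricValue(diagnosed, n_carriers),
        n_activity_tests=n_activity,
        n_genotyping_tests=n_panel,
        allele_frequency_info=n_panel == len(cohort) and len(cohort) > 0,
        genotype_phenotype_info=(
            len(cohort) > 0 and n_panel == len(cohort) and n_activity == len(cohort)
        ),
        diagnosed_ids=tuple(diagnosed_ids),
    )


def evaluate_all(
    cohort: CohortTable,
    strategies: Iterable[Strategy] | None = None,
    schedule=None,
    cutoff: float = 1.0,
    panel: PanelDefinition = DEFAULT_PANEL,
):
    """Evaluate strategies and join testing costs; one row per strategy.

    Returns a DataFrame mirroring the standard cost-analysis layout:
    diagnosed/undiagnosed, sensitivity, per-test counts, information
    flags, total cost and cost per diagnosed case.
    """
    import pandas as pd

    from .costs import CostSchedule, strategy_cost

    if strategies is None:
        strategies = builtin_strategies()
    if schedule is None:
        schedule = CostSchedule()
    rows = []
    for strategy in strategies:
        out = apply_strategy(cohort, strategy, cutoff=cutoff, panel=panel)
        cost = strategy_cost(out, schedule)
        rows.append(
            {
                "strategy": out.strategy,
                "diagnosed": out.diagnosed,
                "undiagnosed": out.undiagnosed,
                "sensitivity_pct": out.sensitivity.percent,
                "n_activity_tests": out.n_activity_tests,
                "n_genotyping_tests": out.n_genotyping_tests,
                "allele_frequency_info": out.allele_frequency_info,
                "genotype_phenotype_info": out.genotype_phenotype_info,
                "total_cost_usd": cost.total_cost,
                "cost_per_diagnosed_usd": cost.cost_per_diagnosed,
                "diagnosed_ids": ";".join(out.diagnosed_ids),
            }
        )
    return pd.DataFrame(rows)


def _stage_from_dict(d: dict) -> Stage:
    filt = d.get("filter", {}) or {}
    prior = filt.get("prior", {}) or {}
    return Stage(
        test={"activity": "activity", "panel": "panel"}[d["test"]],
        filter=StageFilter(
            sex=filt.get("sex", "any"),
            activity=prior.get("activity", "any"),
            panel=prior.get("panel", "any"),
        ),
    )


def load_strategies(path: str | Path) -> list[Strategy]:
    """Load custom strategies from a YAML/JSON file.

    Expected layout::

        - name: my-strategy
          stages:
            - {test: activity, filter: {sex: any}}
            - {test: panel,
               filter: {sex: female, prior: {activity: normal}}}
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, list):
        raise StrategyConfigError("strategy config must be a list of strategies")
    strategies = []
    for entry in doc:
        strategies.append(
            Strategy(
                name=str(entry["name"]),
                stages=tuple(_stage_from_dict(s) for s in entry["stages"]),
            )
        )
    return strategies
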