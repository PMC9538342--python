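"""Sequential-strategy evaluation against explicit enumeration oracles."""

import pytest
from hypothesis import given, settings, strategies as st

from g6pd_screen.cohort import CohortTable, Sex
from g6pd_screen.strategies import (
    Stage,
    StageFilter,
    Strategy,
    StrategyConfigError,
    apply_strategy,
    builtin_strategies,
    evaluate_all,
    load_strategies,
)

from conftest import make_cohort, make_record


# ---------------------------------------------------------------------------
# Independent oracle: explicit record x stage enumeration with inline
# filter logic, kept free of the engine's StageFilter.matches machinery.


def oracle_apply(cohort: CohortTable, strategy: Strategy, cutoff: float = 1.0):
    administered = {r.id: {} for r in cohort}
    for stage in strategy.stages:
        for r in cohort:
            res = administered[r.id]
            f = stage.filter
            if f.sex == "male" and r.sex is not Sex.MALE:
                continue
            if f.sex == "female" and r.sex is not Sex.FEMALE:
                continue
            if f.activity == "deficient" and res.get("activity") != "deficient":
                continue
            if f.activity == "normal" and res.get("activity") != "normal":
                continue
            if f.activity == "untested" and "activity" in res:
                continue
            if f.panel == "positive" and res.get("panel") != "positive":
                continue
            if f.panel == "negative" and res.get("panel") != "negative":
                continue
            if f.panel == "untested" and "panel" in res:
                continue
            if stage.test == "activity":
                res["activity"] = (
                    "deficient" if r.activity_ratio < cutoff else "normal"
                )
            else:
                res["panel"] = "positive" if r.panel_positive else "negative"
    diagnosed_ids = []
    carriers = 0
    n_act = sum(1 for r in cohort if "activity" in administered[r.id])
    n_pan = sum(1 for r in cohort if "panel" in administered[r.id])
    for r in cohort:
        is_carrier = r.panel_positive or r.sanger_positive
        carriers += is_carrier
        res = administered[r.id]
        positive = res.get("activity") == "deficient" or res.get("panel") == "positive"
        if positive and is_carrier:
            diagnosed_ids.append(r.id)
    return {
        "diagnosed": len(diagnosed_ids),
        "undiagnosed": carriers - len(diagnosed_ids),
        "n_activity_tests": n_act,
        "n_genotyping_tests": n_pan,
        "diagnosed_ids": tuple(diagnosed_ids),
    }


# ---------------------------------------------------------------------------
# Random truth-resolvable cohorts (small) for property tests.

_PANEL_VARIANTS = ("c.95A>G", "c.1024C>T", "c.1376G>T", "c.1388G>A")
_OOP_VARIANTS = ("c.305T>C", "c.835A>T")


@st.composite
def small_cohorts(draw, max_size: int = 20):
    n = draw(st.integers(min_value=0, max_value=max_size))
    records = []
    for i in range(n):
        sex = draw(st.sampled_from(["male", "female"]))
        ratio = draw(
            st.floats(0, 2, allow_nan=False, allow_infinity=False).map(
                lambda x: round(x, 3)
            )
        )
        kind = draw(st.sampled_from(["panel_carrier", "oop_carrier", "non_carrier"]))
        if kind == "panel_carrier":
            rec = make_record(
                f"r{i}", sex=sex, ratio=ratio,
                panel_variant=draw(st.sampled_from(_PANEL_VARIANTS)),
            )
        elif kind == "oop_carrier":
            rec = make_record(
                f"r{i}", sex=sex, ratio=ratio, panel_variant=None,
                sanger=draw(st.sampled_from(_OOP_VARIANTS)),
            )
        else:
            rec = make_record(
                f"r{i}", sex=sex, ratio=ratio, panel_variant=None,
                sanger_negative=True,
            )
        records.append(rec)
    return make_cohort(*records)


_EXTRA_STAGES = [
    Stage("activity", StageFilter(activity="untested")),
    Stage("panel", StageFilter(panel="untested")),
    Stage("panel", StageFilter(sex="female", panel="untested")),
    Stage("activity", StageFilter(sex="male", activity="untested")),
]


class TestBuiltins:
    def test_five_builtins_shapes(self):
        s = {x.name: x for x in builtin_strategies()}
        assert len(s) == 5
        assert len(s["S1"].stages) == 1 and s["S1"].stages[0].test == "activity"
        assert len(s["S2"].stages) == 1 and s["S2"].stages[0].test == "panel"
        f3 = s["S3"].stages[1].filter
        assert (f3.sex, f3.activity) == ("female", "normal")
        f4 = s["S4"].stages[1].filter
        assert f4.panel == "negative" and f4.sex == "any"
        assert [st_.test for st_ in s["S5"].stages] == ["activity", "panel"]

    def test_filter_referencing_unadministered_test_rejected(self):
        with pytest.raises(StrategyConfigError, match="no earlier stage"):
            Strategy("bad", (Stage("panel", StageFilter(activity="normal")),))


class TestApplyStrategy:
    @pytest.mark.parametrize(
        "name,diagnosed,undiagnosed,n_act,n_pan",
        [
            ("S1", 480, 37, 555, 0),
            ("S2", 508, 9, 0, 555),
            ("S3", 516, 1, 555, 58),
            ("S4", 517, 0, 47, 555),
            ("S5", 517, 0, 555, 555),
        ],
    )
    def test_reference_branch_counts(self, ref_cohort, name, diagnosed,
                                     undiagnosed, n_act, n_pan):
        strategy = {s.name: s for s in builtin_strategies()}[name]
        out = apply_strategy(ref_cohort, strategy)
        assert out.diagnosed == diagnosed
        assert out.undiagnosed == undiagnosed
        assert out.n_activity_tests == n_act
        assert out.n_genotyping_tests == n_pan

    def test_empty_cohort(self):
        out = apply_strategy(make_cohort(), builtin_strategies()[0])
        assert out.diagnosed == out.undiagnosed == 0
        assert not out.sensitivity.defined

    @settings(deadline=None, derandomize=True)
    @given(cohort=small_cohorts())
    def test_engine_matches_enumeration_oracle(self, cohort):
        """All outcome fields agree with brute-force enumeration, for
        every built-in strategy on random small cohorts."""
        for strategy in builtin_strategies():
            out = apply_strategy(cohort, strategy)
            exp = oracle_apply(cohort, strategy)
            assert out.diagnosed == exp["diagnosed"]
            assert out.undiagnosed == exp["undiagnosed"]
            assert out.n_activity_tests == exp["n_activity_tests"]
            assert out.n_genotyping_tests == exp["n_genotyping_tests"]
            assert out.diagnosed_ids == exp["diagnosed_ids"]

    @settings(deadline=None, derandomize=True)
    @given(cohort=small_cohorts(), base=st.sampled_from(builtin_strategies()),
           extra=st.sampled_from(_EXTRA_STAGES))
    def test_appending_a_stage_never_reduces_diagnoses(self, cohort, base, extra):
        extended = Strategy(base.name + "+", base.stages + (extra,))
        assert (
            apply_strategy(cohort, extended).diagnosed
            >= apply_strategy(cohort, base).diagnosed
        )

    @settings(deadline=None, derandomize=True)
    @given(cohort=small_cohorts())
    def test_conservation_and_set_inclusions(self, cohort):
        """diagnosed + undiagnosed = carriers; S5 = S1 u S2; S3 >= S1; S4 >= S2."""
        outs = {s.name: apply_strategy(cohort, s) for s in builtin_strategies()}
        carriers = sum(1 for r in cohort if r.panel_positive or r.sanger_positive)
        for out in outs.values():
            assert out.diagnosed + out.undiagnosed == carriers
        d = {k: set(v.diagnosed_ids) for k, v in outs.items()}
        assert d["S5"] == d["S1"] | d["S2"]
        assert d["S3"] >= d["S1"]
        assert d["S4"] >= d["S2"]

    def test_double_administration_rejected(self, ref_cohort):
        bad = Strategy(
            "twice", (Stage("activity"), Stage("activity"))
        )
        with pytest.raises(StrategyConfigError, match="twice"):
            apply_strategy(ref_cohort, bad)


class TestEvaluateAll:
    def test_reference_report(self, ref_cohort):
        df = evaluate_all(ref_cohort).set_index("strategy")
        assert list(df["sensitivity_pct"]) == [92.8, 98.3, 99.8, 100.0, 100.0]
        assert list(df["allele_frequency_info"]) == [False, True, False, True, True]
        assert list(df["genotype_phenotype_info"]) == [False] * 4 + [True]
        assert df.loc["S5", "diagnosed"] == 517

    def test_custom_strategy_yaml_round_trip(self, tmp_path, ref_cohort):
        cfg = tmp_path / "strategies.yaml"
        cfg.write_text(
            "- name: reflex-females\n"
            "  stages:\n"
            "    - {test: activity}\n"
            "    - {test: panel, filter: {sex: female, prior: {activity: normal}}}\n"
        )
        (loaded,) = load_strategies(cfg)
        out = apply_strategy(ref_cohort, loaded)
        s3 = apply_strategy(ref_cohort, builtin_strategies()[2])
        assert (out.diagnosed, out.n_genotyping_tests) == (
            s3.diagnosed,
            s3.n_genotyping_tests,
        )
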