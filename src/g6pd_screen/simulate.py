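"""Synthetic NBS-positive cohort generator and its analytic oracles.

The generator emulates the statistical structure of a confirmatory
G6PD-deficiency cohort: X-linked genotypes (hemizygous males,
heterozygous/homozygous females), per-class log-normal activity-ratio
distributions, X-inactivation mosaicism in heterozygotes (a symmetric
Beta mixing fraction over deficient and normal red-cell populations), a
small set of mild variants clustering near the diagnostic cutoff,
carriers whose variant lies outside the 12-variant panel, and screening
false positives (non-carriers recalled by the first-tier spot test).

Two structural assumptions mirror how such cohorts are ascertained:
non-carriers have confirmatory ratios at or above the cutoff (there is
no false-positive mechanism in the confirmatory assays), and
out-of-panel carriers are activity-deficient (variants invisible to the
panel are only ever discovered through a deficient ratio followed by
sequencing).  Consequently every carrier is detectable by at least one
assay, and both assays have exact 100% specificity and PPV on generated
cohorts.

``het_deficiency_prob`` computes the probability that a heterozygote's
mixed activity falls below the cutoff by numeric integration; it is the
independent oracle for the generator and the basis for the default
Beta shape, chosen so the heterozygote detection fraction of enzymatic
testing is about 0.62.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import beta as beta_dist

from .assays import resolve_truth
from .cohort import (
    CarrierStatus,
    CohortTable,
    DEFAULT_PANEL,
    InfantRecord,
    PanelDefinition,
    Sex,
    VariantCall,
    Zygosity,
)
from .strategies import Strategy

__all__ = [
    "GeneratorConfig",
    "ExpectedStrategyOutcome",
    "ParameterEstimates",
    "generate",
    "het_deficiency_prob",
    "class_probabilities",
    "expected_strategy_outcome",
    "recover_parameters",
    "OUT_OF_PANEL_VARIANTS",
]

#: Pathogenic variants outside the 12-variant panel, reachable only by
#: sequencing (names as reported in confirmatory sequencing of Chinese
#: NBS-positive infants).
OUT_OF_PANEL_VARIANTS = (
    "c.98T>C",
    "c.202G>A",
    "c.305T>C",
    "c.563C>T",
    "c.739G>A",
    "c.835A>T",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """All parameters of the synthetic NBS-positive cohort model.

    Defaults reproduce the composition of the 555-infant reference
    cohort where a published value exists (female fraction 118/555,
    non-carrier contamination 38/555, out-of-panel fraction 9/517,
    allele frequency 0.0139 from the reported city-level prevalence).
    The activity-distribution parameters are invented defaults chosen to
    give a realistic separation of classes around the 1.0 cutoff:
    deficient-class median 0.35 (broad, sigma 0.55), normal-class median
    1.35 (sigma 0.25), and a mild class (c.1024C>T) with median 0.90
    just below the cutoff.  ``xi_beta_a`` is the symmetric Beta shape of
    the heterozygote X-inactivation fraction, set so that the analytic
    heterozygote deficiency probability is about 0.62.
    """

    n: int = 555
    female_fraction: float = 118 / 555
    q: float = 0.0139
    panel_variant_weights: tuple[float, ...] = (1.0,) * 12
    out_of_panel_fraction: float = 9 / 517
    noncarrier_contamination: float = 38 / 555
    deficient_median: float = 0.35
    deficient_sigma: float = 0.55
    normal_median: float = 1.35
    normal_sigma: float = 0.25
    mild_variants: tuple[str, ...] = ("c.1024C>T",)
    mild_median: float = 0.90
    mild_sigma: float = 0.15
    xi_beta_a: float = 1.938
    cutoff: float = 1.0
    seed: int = 0
    panel: PanelDefinition = field(default=DEFAULT_PANEL, repr=False)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        for name in (
            "female_fraction",
            "q",
            "out_of_panel_fraction",
            "noncarrier_contamination",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        w = np.asarray(self.panel_variant_weights, dtype=float)
        if len(w) != len(self.panel.variants):
            raise ValueError(
                f"need {len(self.panel.variants)} panel variant weights, got {len(w)}"
            )
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("panel weights must be nonnegative, not all zero")
        for name in (
            "deficient_median",
            "deficient_sigma",
            "normal_median",
            "normal_sigma",
            "mild_median",
            "mild_sigma",
            "cutoff",
            "xi_beta_a",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.mild_variants) - self.panel.cdna_names
        if unknown:
            raise ValueError(f"mild variants not on panel: {sorted(unknown)}")

    # -- derived quantities -------------------------------------------------

    @property
    def homozygous_fraction(self) -> float:
        """Homozygote share among female carriers: q : 2(1-q) odds."""
        return self.q / (self.q + 2 * (1 - self.q))

    def severity_params(self, cdna: str) -> tuple[float, float]:
        """(log-median, sigma) of the deficient-class distribution for a variant."""
        if cdna in self.mild_variants:
            return math.log(self.mild_median), self.mild_sigma
        return math.log(self.deficient_median), self.deficient_sigma

    @property
    def mild_panel_weight(self) -> float:
        """Probability a panel-carrier's variant is in the mild class."""
        w = np.asarray(self.panel_variant_weights, dtype=float)
        names = [cdna for cdna, _ in self.panel.variants]
        mild = sum(wi for wi, nm in zip(w, names) if nm in self.mild_variants)
        return float(mild / w.sum())


# ---------------------------------------------------------------------------
# Numeric oracle for heterozygote deficiency


def _lognorm_cdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = ndtr((np.log(x[pos]) - mu) / sigma)
    return out


def _gauss01(n: int) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.legendre.leggauss(n)
    return 0.5 * (nodes + 1.0), 0.5 * weights


def _mixture_deficient_prob(
    mu_def: float,
    sigma_def: float,
    mu_norm: float,
    sigma_norm: float,
    beta_a: float,
    cutoff: float,
    n_nodes: int = 240,
) -> float:
    """P(m*A_def + (1-m)*A_norm < cutoff), m ~ Beta(a, a), A log-normal.

    Probability-integral transforms on both the Beta and the deficient
    activity put the double integral on the unit square, where
    Gauss-Legendre quadrature converges fast for any cutoff.
    """
    if cutoff <= 0:
        return 0.0
    u, wu = _gauss01(n_nodes)
    v, wv = _gauss01(n_nodes)
    m = np.clip(beta_dist.ppf(u, beta_a, beta_a), 1e-13, 1 - 1e-13)
    x = np.exp(mu_def + sigma_def * ndtri(v))  # deficient component quantiles
    arg = (cutoff - m[:, None] * x[None, :]) / (1.0 - m[:, None])
    inner = _lognorm_cdf(arg, mu_norm, sigma_norm) @ wv
    return float(wu @ inner)


def het_deficiency_prob(
    config: GeneratorConfig,
    cutoff: float | None = None,
    variant_class: str = "marginal",
) -> float:
    """Probability a panel-variant heterozygote is enzymatically deficient.

    Numeric integration over the Beta X-inactivation fraction and the
    two log-normal activity classes; ``variant_class`` selects the
    severity class ('regular', 'mild') or the panel-weight marginal.
    """
    c = config.cutoff if cutoff is None else cutoff
    if c <= 0:
        return 0.0
    mu_n, s_n = math.log(config.normal_median), config.normal_sigma
    p_reg = _mixture_deficient_prob(
        math.log(config.deficient_median),
        config.deficient_sigma,
        mu_n,
        s_n,
        config.xi_beta_a,
        c,
    )
    if variant_class == "regular":
        return p_reg
    p_mild = _mixture_deficient_prob(
        math.log(config.mild_median),
        config.mild_sigma,
        mu_n,
        s_n,
        config.xi_beta_a,
        c,
    )
    if variant_class == "mild":
        return p_mild
    if variant_class != "marginal":
        raise ValueError(f"unknown variant_class {variant_class!r}")
    wm = config.mild_panel_weight
    return (1 - wm) * p_reg + wm * p_mild


# ---------------------------------------------------------------------------
# Generation


def _trunc_lognorm(u, mu, sigma, cutoff: float, side: str) -> np.ndarray:
    """Inverse-CDF draw of a log-normal truncated below/above the cutoff.

    ``mu``/``sigma`` may be scalars or per-draw arrays.
    """
    f_c = ndtr((np.log(cutoff) - np.asarray(mu)) / np.asarray(sigma))
    if side == "left":  # values >= cutoff
        u = f_c + u * (1.0 - f_c)
    else:  # values < cutoff
        u = u * f_c
    return np.exp(mu + sigma * ndtri(np.clip(u, 1e-15, 1 - 1e-15)))


def generate(config: GeneratorConfig) -> CohortTable:
    """Draw a synthetic NBS-positive cohort; byte-identical under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    c = config.cutoff
    mu_n, s_n = math.log(config.normal_median), config.normal_sigma

    female = rng.random(n) < config.female_fraction
    carrier = rng.random(n) >= config.noncarrier_contamination
    u_zyg = rng.random(n)
    oop = carrier & (rng.random(n) < config.out_of_panel_fraction)
    w = np.asarray(config.panel_variant_weights, dtype=float)
    panel_idx = rng.choice(len(w), size=n, p=w / w.sum())
    oop_idx = rng.integers(0, len(OUT_OF_PANEL_VARIANTS), size=n)
    u_act = rng.random(n)

    homozygous = female & carrier & (u_zyg < config.homozygous_fraction)
    heterozygous = female & carrier & ~homozygous
    single_dose = carrier & ~heterozygous  # hemizygous males + homozygous females

    panel_names = [cdna for cdna, _ in config.panel.variants]
    variant = np.array(
        [
            OUT_OF_PANEL_VARIANTS[oop_idx[i]] if oop[i] else panel_names[panel_idx[i]]
            for i in range(n)
        ],
        dtype=object,
    )
    sev = np.array(
        [config.severity_params(variant[i]) for i in range(n)], dtype=float
    )
    mu_d, s_d = sev[:, 0], sev[:, 1]

    activity = np.empty(n, dtype=float)

    nc = ~carrier  # screening false positives: confirmatory ratio >= cutoff
    activity[nc] = _trunc_lognorm(u_act[nc], mu_n, s_n, c, "left")

    sp = single_dose & ~oop
    activity[sp] = np.exp(mu_d[sp] + s_d[sp] * ndtri(u_act[sp]))
    so = single_dose & oop  # out-of-panel: ascertained through deficiency
    activity[so] = _trunc_lognorm(u_act[so], mu_d[so], s_d[so], c, "right")

    # heterozygotes: mosaic mixture m*A_def + (1-m)*A_norm
    m_all = rng.beta(config.xi_beta_a, config.xi_beta_a, n)
    z_def = rng.standard_normal(n)
    z_norm = rng.standard_normal(n)
    het_mix = m_all * np.exp(mu_d + s_d * z_def) + (1 - m_all) * np.exp(
        mu_n + s_n * z_norm
    )
    hp = heterozygous & ~oop
    activity[hp] = het_mix[hp]
    ho = np.nonzero(heterozygous & oop)[0]
    for i in ho:  # rejection-sample the mixture below the cutoff
        a = het_mix[i]
        while a >= c:
            m = rng.beta(config.xi_beta_a, config.xi_beta_a)
            a = m * np.exp(mu_d[i] + s_d[i] * rng.standard_normal()) + (
                1 - m
            ) * np.exp(mu_n + s_n * rng.standard_normal())
        activity[i] = a

    records = []
    width = len(str(n))
    for i in range(n):
        sex = Sex.FEMALE if female[i] else Sex.MALE
        if not carrier[i]:
            panel_result: tuple[VariantCall, ...] = ()
            sanger: tuple[VariantCall, ...] | None = ()
        else:
            if not female[i]:
                zyg = Zygosity.HEMIZYGOUS
            elif homozygous[i]:
                zyg = Zygosity.HOMOZYGOUS
            else:
                zyg = Zygosity.HETEROZYGOUS
            call = (VariantCall(str(variant[i]), zyg),)
            panel_result = () if oop[i] else call
            sanger = call  # gold standard available for every carrier
        records.append(
            InfantRecord(
                id=f"SIM-{i:0{width}d}",
                sex=sex,
                activity_ratio=float(activity[i]),
                panel_result=panel_result,
                sanger_result=sanger,
                panel=config.panel,
            )
        )
    return CohortTable(
        records=tuple(records), provenance=f"synthetic(seed={config.seed})"
    )


# ---------------------------------------------------------------------------
# Analytic class probabilities and expected strategy outcomes


def class_probabilities(config: GeneratorConfig) -> pd.DataFrame:
    """Joint probabilities of (sex, carrier, panel+, deficient) cells.

    The analytic counterpart of :func:`generate`: deficiency
    probabilities come from the class log-normal CDFs and the
    heterozygote mixture integral, not from sampling.
    """
    c = config.cutoff
    fd_reg = float(
        ndtr((math.log(c) - math.log(config.deficient_median)) / config.deficient_sigma)
    )
    fd_mild = float(
        ndtr((math.log(c) - math.log(config.mild_median)) / config.mild_sigma)
    )
    p_het_reg = het_deficiency_prob(config, variant_class="regular")
    p_het_mild = het_deficiency_prob(config, variant_class="mild")
    wm = config.mild_panel_weight
    contam = config.noncarrier_contamination
    oopf = config.out_of_panel_fraction

    cells: dict[tuple, float] = {}

    def add(sex: Sex, carrier: bool, panel_pos: bool, deficient: bool, p: float):
        if p <= 0:
            return
        key = (sex, carrier, panel_pos, deficient)
        cells[key] = cells.get(key, 0.0) + p

    def single_dose_branch(sex: Sex, p_branch: float) -> None:
        # hemizygous male or homozygous female carrier
        add(sex, True, False, True, p_branch * oopf)  # out-of-panel, deficient
        for w_cls, fd in ((1 - wm, fd_reg), (wm, fd_mild)):
            add(sex, True, True, True, p_branch * (1 - oopf) * w_cls * fd)
            add(sex, True, True, False, p_branch * (1 - oopf) * w_cls * (1 - fd))

    for sex, p_sex in (
        (Sex.MALE, 1 - config.female_fraction),
        (Sex.FEMALE, config.female_fraction),
    ):
        add(sex, False, False, False, p_sex * contam)
        p_car = p_sex * (1 - contam)
        if sex is Sex.MALE:
            single_dose_branch(sex, p_car)
        else:
            hf = config.homozygous_fraction
            single_dose_branch(sex, p_car * hf)
            p_het = p_car * (1 - hf)
            add(sex, True, False, True, p_het * oopf)
            for w_cls, ph in ((1 - wm, p_het_reg), (wm, p_het_mild)):
                add(sex, True, True, True, p_het * (1 - oopf) * w_cls * ph)
                add(sex, True, True, False, p_het * (1 - oopf) * w_cls * (1 - ph))

    rows = [
        {
            "sex": sex,
            "carrier": carrier,
            "panel_positive": panel_pos,
            "deficient": deficient,
            "prob": p,
        }
        for (sex, carrier, panel_pos, deficient), p in sorted(
            cells.items(), key=lambda kv: (kv[0][0].value,) + kv[0][1:]
        )
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExpectedStrategyOutcome:
    """Analytic expectation of a strategy outcome on the cohort model."""

    strategy: str
    diagnosed: float
    undiagnosed: float
    sensitivity: float
    n_activity_tests: float
    n_genotyping_tests: float


def expected_strategy_outcome(
    strategy: Strategy, config: GeneratorConfig, n: int | None = None
) -> ExpectedStrategyOutcome:
    """Push the analytic cell probabilities through a strategy's stages.

    Each cell's test results are deterministic, so expected test counts
    and diagnoses are exact sums over cells — no Monte Carlo noise.
    """
    n = config.n if n is None else n
    exp_activity = exp_panel = exp_dx = carriers = 0.0
    for cell in class_probabilities(config).itertuples():
        weight = n * cell.prob
        if cell.carrier:
            carriers += weight
        results: dict[str, bool] = {}
        for stage in strategy.stages:
            if not stage.filter.matches(cell.sex, results):
                continue
            if stage.test == "activity":
                results["activity"] = bool(cell.deficient)
                exp_activity += weight
            else:
                results["panel"] = bool(cell.panel_positive)
                exp_panel += weight
        if cell.carrier and any(results.values()):
            exp_dx += weight
    return ExpectedStrategyOutcome(
        strategy=strategy.name,
        diagnosed=exp_dx,
        undiagnosed=carriers - exp_dx,
        sensitivity=exp_dx / carriers if carriers else float("nan"),
        n_activity_tests=exp_activity,
        n_genotyping_tests=exp_panel,
    )


# ---------------------------------------------------------------------------
# Parameter recovery


@dataclass(frozen=True)
class ParameterEstimates:
    """Method-of-moments estimates from a generated cohort.

    The allele frequency q is not identifiable from an NBS-positive
    cohort alone (screening conditions away the unaffected majority), so
    it is reported as None.
    """

    noncarrier_contamination: float
    out_of_panel_fraction: float
    q: float | None
    n: int
    n_carriers: int


def recover_parameters(cohort: CohortTable) -> ParameterEstimates:
    """Estimate contamination and out-of-panel fraction from a cohort."""
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    carriers = [r for r in cohort if resolve_truth(r) is CarrierStatus.CARRIER]
    if not carriers:
        raise ValueError("degenerate cohort: no carriers")
    oop = sum(1 for r in carriers if not r.panel_positive)
    return ParameterEstimates(
        noncarrier_contamination=(n - len(carriers)) / n,
        out_of_panel_fraction=oop / len(carriers),
        q=None,
        n=n,
        n_carriers=len(carriers),
    )
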