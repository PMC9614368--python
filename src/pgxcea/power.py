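"""Genetic-association power, minimum case counts, and "undetected risk
variant" scenarios.

The risk panel explains less than half of CIAG cases, so further risk
variants plausibly exist below the detection limit of the discovery sample.
This module answers two questions about such "undetected" variants
(relative risk RR, minor allele frequency MAF):

1. How many cases would a genome-wide association study need to detect the
   variant at genome-wide significance (power calculation /
   :func:`min_cases_for_power`)?
2. If the variant were found and genotyped, what would the screening panel
   gain (:func:`variant_sens_spec` + :func:`scenario_cea`)?

Power model
-----------
Power is computed for the 1-df Cochran-Armitage trend test on genotype
counts.  Genotype frequencies under Hardy-Weinberg equilibrium are combined
with per-genotype relative risks, anchored to the disease prevalence, and
conditioned on case/control status; the normal approximation with separate
null (pooled) and alternative variances gives the power — the construction
behind the standard association-study power calculators.

The per-genotype risks follow the chosen genetic ``model``; the default is
``dominant`` (heterozygote and homozygote carriers share the same RR) with
two controls recruited per case (``control_ratio = 2``), the planning
convention that reproduces the published minimum-case grid (anchor: 230
cases at RR=3, MAF=10%, with 80% power at genome-wide alpha).  A fixed
control count (e.g. the 13,553 consortium controls) is available by setting
``control_ratio=None``; note a sample that size has essentially full power
for such variants.  See ``docs/methods.md`` for the calibration evidence.

Variant screening performance uses a dominant carrier model: carriers
(frequency ``q = 1 - (1 - MAF)^2``) have RR-fold risk, and Bayes' rule
yields the sensitivity (carrier fraction among cases) and specificity
(non-carrier fraction among non-cases).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CEResult, compare_strategies
from .parameters import ModelParameters, ParameterRegistry
from .performance import (
    PanelPerformance,
    VariantPerformance,
    combine_panels,
)
from .psa import probability_cost_effective, run_psa

__all__ = [
    "PowerQuery",
    "ScenarioVariant",
    "ScenarioResult",
    "association_power",
    "min_cases_for_power",
    "variant_sens_spec",
    "scenario_cea",
    "rr_maf_grid",
    "GENETIC_MODELS",
]

GENETIC_MODELS = ("dominant", "multiplicative", "additive", "recessive")


@dataclass(frozen=True)
class PowerQuery:
    """Inputs of a power calculation for one hypothetical variant.

    ``control_ratio`` selects planning mode (controls = ratio x cases);
    set it to ``None`` to hold ``n_controls`` fixed while cases vary.
    """

    rr: float
    maf: float
    alpha: float = 5e-8
    target_power: float = 0.80
    n_controls: int = 13_553
    control_ratio: Optional[float] = 2.0
    disease_prevalence: float = 0.0343
    model: str = "dominant"

    def __post_init__(self) -> None:
        if self.rr < 1.0:
            raise ValueError("relative risk must be >= 1")
        if not 0.0 < self.maf < 0.5:
            raise ValueError("MAF must lie in (0, 0.5)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.disease_prevalence < 1.0:
            raise ValueError("disease prevalence must lie in (0, 1)")
        if self.model not in GENETIC_MODELS:
            raise ValueError(f"unknown genetic model {self.model!r}")

    def controls_for(self, n_cases: int) -> int:
        if self.control_ratio is None:
            return self.n_controls
        return max(1, int(round(self.control_ratio * n_cases)))


@dataclass(frozen=True)
class ScenarioVariant:
    """A hypothetical risk variant and its implied screening performance."""

    rr: float
    maf: float
    sensitivity: float
    specificity: float

    def as_variant(self) -> VariantPerformance:
        return VariantPerformance(
            name=f"undetected_rr{self.rr:g}_maf{self.maf:g}",
            sensitivity=self.sensitivity,
            specificity=self.specificity,
        )


def _genotype_relative_risks(rr: float, model: str) -> np.ndarray:
    """Per-genotype risk multipliers (aa, Aa, AA) for risk allele A."""
    if model == "multiplicative":
        return np.array([1.0, rr, rr * rr])
    if model == "additive":
        return np.array([1.0, rr, 2.0 * rr - 1.0])
    if model == "dominant":
        return np.array([1.0, rr, rr])
    return np.array([1.0, 1.0, rr])  # recessive


def _case_control_genotype_freqs(q: PowerQuery):
    p = q.maf
    f = np.array([(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p * p])
    m = _genotype_relative_risks(q.rr, q.model)
    k = q.disease_prevalence / float(f @ m)  # baseline (aa) risk
    risks = m * k
    if np.any(risks > 1.0):
        raise ValueError("inconsistent parameters: genotype risk exceeds 1")
    f_case = f * risks / q.disease_prevalence
    f_ctrl = f * (1.0 - risks) / (1.0 - q.disease_prevalence)
    return f_case, f_ctrl


def association_power(q: PowerQuery, n_cases: int) -> float:
    """Power of the 1-df trend test at genome-wide significance.

    Degenerate at the null: for ``rr = 1`` every genotype carries the same
    risk and the power equals ``alpha``.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be at least 1")
    n_ctrl = q.controls_for(n_cases)
    f_case, f_ctrl = _case_control_genotype_freqs(q)
    x = np.array([0.0, 1.0, 2.0])

    mu_case, mu_ctrl = f_case @ x, f_ctrl @ x
    var_case = f_case @ x**2 - mu_case**2
    var_ctrl = f_ctrl @ x**2 - mu_ctrl**2
    f_pool = (n_cases * f_case + n_ctrl * f_ctrl) / (n_cases + n_ctrl)
    var_pool = f_pool @ x**2 - (f_pool @ x) ** 2

    delta = mu_case - mu_ctrl
    sd_null = np.sqrt(var_pool * (1.0 / n_cases + 1.0 / n_ctrl))
    sd_alt = np.sqrt(var_case / n_cases + var_ctrl / n_ctrl)
    if sd_alt == 0.0:
        return q.alpha
    z = stats.norm.isf(q.alpha / 2.0)
    power = stats.norm.sf((z * sd_null - delta) / sd_alt) + stats.norm.sf(
        (z * sd_null + delta) / sd_alt
    )
    return float(power)


def min_cases_for_power(q: PowerQuery, n_max: int = 10_000_000) -> int:
    """Smallest case count reaching ``target_power`` (bisection; power is
    monotone in the sample size)."""
    if q.target_power <= q.alpha:
        return 1
    if association_power(q, n_max) < q.target_power:
        raise ValueError(f"target power not reachable within {n_max} cases")
    lo, hi = 1, n_max
    while lo < hi:
        mid = (lo + hi) // 2
        if association_power(q, mid) >= q.target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def variant_sens_spec(
    rr: float, maf: float, prevalence: float = 0.0343
) -> ScenarioVariant:
    """Screening sensitivity/specificity implied by (RR, MAF) under a
    dominant carrier model.

    Carrier frequency ``q = 1 - (1 - maf)^2``; baseline risk
    ``k = prevalence / (q*rr + 1 - q)``; then by Bayes' rule
    ``sensitivity = q*rr*k / prevalence`` and
    ``specificity = 1 - q*(1 - rr*k) / (1 - prevalence)``.
    """
    if rr < 1.0:
        raise ValueError("relative risk must be >= 1")
    if not 0.0 < maf < 1.0:
        raise ValueError("MAF must lie in (0, 1)")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    q = 1.0 - (1.0 - maf) ** 2
    k = prevalence / (q * rr + 1.0 - q)
    if rr * k > 1.0:
        raise ValueError("inconsistent parameters: carrier risk exceeds 1")
    sensitivity = q * rr * k / prevalence
    specificity = 1.0 - q * (1.0 - rr * k) / (1.0 - prevalence)
    return ScenarioVariant(
        rr=rr, maf=maf, sensitivity=sensitivity, specificity=specificity
    )


@dataclass
class ScenarioResult:
    """Deterministic CEA plus PSA summary for an augmented panel."""

    variant: ScenarioVariant
    panel: PanelPerformance
    ce: CEResult
    psa_summary: dict[str, float]


def scenario_cea(
    params: ModelParameters,
    registry: ParameterRegistry,
    base_panel: PanelPerformance,
    variant: ScenarioVariant,
    test_cost: float = 120.0,
    n_iter: int = 100_000,
    seed: int = 0,
    wtp: float = 30_000.0,
) -> ScenarioResult:
    """CEA after adding *variant* to *base_panel*.

    The genetic-test cost defaults to GBP 120, the midpoint of the
    110-130 band quoted for an extended panel.  The PSA holds the augmented
    sensitivity/specificity fixed (their uncertainty is unreported) while
    all other distributions sample.
    """
    panel = combine_panels(base_panel, variant.as_variant())
    scenario_params = replace(params, cost_genetic_test=test_cost)
    scenario_registry = registry.with_mean("cost_genetic_test", test_cost)
    ce = compare_strategies(scenario_params, panel)
    draws = run_psa(scenario_params, scenario_registry, n_iter, seed, panel=panel)
    summary = draws.summary()
    summary["p_cost_effective"] = probability_cost_effective(draws, wtp)
    return ScenarioResult(variant=variant, panel=panel, ce=ce, psa_summary=summary)


def rr_maf_grid(
    rr_list: Sequence[float],
    maf_list: Sequence[float],
    params: ModelParameters,
    base_panel: PanelPerformance,
    test_cost: float = 120.0,
    query: Optional[PowerQuery] = None,
) -> pd.DataFrame:
    """Minimum case counts and scenario ICERs over an RR x MAF grid.

    For each cell: the cases needed for 80% power, the calibrated variant
    performance, the augmented-panel performance, and the deterministic
    ICER of the augmented PGx strategy (test cost ``test_cost``).
    """
    rows = []
    for rr in rr_list:
        for maf in maf_list:
            q = (
                PowerQuery(rr=rr, maf=maf)
                if query is None
                else replace(query, rr=rr, maf=maf)
            )
            variant = variant_sens_spec(rr, maf, params.ciag_prevalence)
            panel = combine_panels(base_panel, variant.as_variant())
            ce = compare_strategies(
                replace(params, cost_genetic_test=test_cost), panel
            )
            rows.append(
                {
                    "rr": rr,
                    "maf": maf,
                    "min_cases": min_cases_for_power(q),
                    "variant_sensitivity": variant.sensitivity,
                    "variant_specificity": variant.specificity,
                    "panel_sensitivity": panel.sensitivity,
                    "panel_specificity": panel.specificity,
                    "icer": ce.icer,
                }
            )
    return pd.DataFrame(rows)
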