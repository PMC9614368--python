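"""Markov cohort engine: per-strategy discounted costs/QALYs and the ICER.

Three health states are tracked over monthly cycles:

``ON_CLZ_AT_RISK``
    On clozapine during the CIAG risk window; exposed to the per-cycle
    CIAG hazard.
``ON_CLZ_SAFE``
    On clozapine after the risk window; no further CIAG risk.
``ON_SUBSTITUTE``
    Switched to a substitute antipsychotic after a CIAG event (absorbing;
    rechallenge is not modelled).

The cumulative CIAG incidence is spread over the first
``ciag_risk_window_cycles`` cycles as a constant hazard *h* solving
``1 - (1 - h)**window = incidence``.  Rewards: clozapine states accrue drug
plus monitoring costs and the clozapine utility; the substitute state
accrues substitute drug cost and the lower substitute utility.  A CIAG
transition incurs the one-off event cost, and the transition cycle takes
the destination state's reward (no half-cycle correction).  All rewards at
cycle *t* are discounted by ``(1 + r) ** (-t / 12)``.

The PGx-guided strategy pays the genetic-test cost at cycle 0 and replaces
the raw prevalence by the effective incidence
``p * (1 - sensitivity * prevention_rate)``; specificity does not enter the
cohort dynamics because test-positive patients stay on clozapine with
unchanged care, which is why the ICER is structurally invariant to it.

The private :func:`_cohort_outcomes` core broadcasts over parameter arrays
so the 100,000-draw PSA evaluates both arms in a single pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .parameters import ModelParameters
from .performance import PanelPerformance, effective_ciag_incidence

__all__ = [
    "STANDARD_OF_CARE",
    "PGX_GUIDED",
    "Strategy",
    "CohortTrace",
    "StrategyResult",
    "CEResult",
    "ciag_monthly_hazard",
    "run_cohort",
    "compare_strategies",
]

STANDARD_OF_CARE = "standard_of_care"
PGX_GUIDED = "pgx_guided"


@dataclass(frozen=True)
class Strategy:
    """One arm of the comparison."""

    name: str
    panel: Optional[PanelPerformance] = None
    test_cost_applied: bool = False

    def __post_init__(self) -> None:
        if self.name not in (STANDARD_OF_CARE, PGX_GUIDED):
            raise ValueError(f"unknown strategy {self.name!r}")
        if self.name == STANDARD_OF_CARE and self.test_cost_applied:
            raise ValueError("standard of care never pays the genetic test")
        if self.name == PGX_GUIDED and self.panel is None:
            raise ValueError("pgx_guided requires a panel")

    @classmethod
    def standard_of_care(cls) -> "Strategy":
        return cls(STANDARD_OF_CARE)

    @classmethod
    def pgx_guided(cls, panel: PanelPerformance) -> "Strategy":
        return cls(PGX_GUIDED, panel=panel, test_cost_applied=True)


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and incident CIAG fraction.

    Row 0 is the starting distribution (everyone ``ON_CLZ_AT_RISK``);
    rows 1..n are post-transition occupancies.
    """

    on_clz_at_risk: np.ndarray
    on_clz_safe: np.ndarray
    on_substitute: np.ndarray
    incident_ciag: np.ndarray

    @property
    def cycles(self) -> np.ndarray:
        return np.arange(len(self.on_clz_at_risk))

    def occupancy(self) -> np.ndarray:
        return np.column_stack(
            [self.on_clz_at_risk, self.on_clz_safe, self.on_substitute]
        )


@dataclass
class StrategyResult:
    """Discounted expectations per patient for one strategy."""

    strategy: Strategy
    discounted_cost: float
    discounted_qaly: float
    trace: CohortTrace


@dataclass
class CEResult:
    """Incremental comparison of PGx-guided vs standard of care."""

    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    flag: str  # "icer", "dominant", "dominated" or "undefined"
    pgx: Optional[StrategyResult] = None
    soc: Optional[StrategyResult] = None


def ciag_monthly_hazard(cumulative_incidence: float, window_cycles: int) -> float:
    """Constant per-cycle hazard spreading *cumulative_incidence* over
    *window_cycles* cycles: solves ``1 - (1 - h)**window = incidence``."""
    if not 0.0 <= cumulative_incidence < 1.0:
        raise ValueError(
            f"cumulative incidence must lie in [0, 1), got {cumulative_incidence}"
        )
    if window_cycles < 1:
        raise ValueError("window must be at least one cycle")
    return 1.0 - (1.0 - cumulative_incidence) ** (1.0 / window_cycles)


def _cohort_outcomes(
    incidence,
    *,
    window: int,
    n_cycles: int,
    test_cost,
    cost_ciag,
    cost_clz_day,
    cost_sub_day,
    cost_blood,
    utility_clz,
    utility_sub,
    annual_rate: float,
    days_per_cycle: float,
    keep_trace: bool = False,
):
    """Vectorised cohort evaluation.

    All reward parameters broadcast against ``incidence``.  Returns
    ``(cost, qaly)`` arrays, plus the trace arrays when ``keep_trace``
    (scalar use only).
    """
    incidence = np.asarray(incidence, dtype=float)
    h = 1.0 - (1.0 - incidence) ** (1.0 / window)
    beta = (1.0 + annual_rate) ** (-1.0 / 12.0)

    at_risk = np.ones_like(h)
    safe = np.zeros_like(h)
    substitute = np.zeros_like(h)
    cost = np.zeros_like(h) + test_cost
    qaly = np.zeros_like(h)

    clz_cycle_cost = np.asarray(cost_clz_day) * days_per_cycle + cost_blood
    sub_cycle_cost = np.asarray(cost_sub_day) * days_per_cycle
    u_clz_cycle = np.asarray(utility_clz) / 12.0
    u_sub_cycle = np.asarray(utility_sub) / 12.0

    if keep_trace:
        tr_risk = [at_risk.copy()]
        tr_safe = [safe.copy()]
        tr_sub = [substitute.copy()]
        tr_inc = [np.zeros_like(h)]

    for t in range(1, n_cycles + 1):
        if t <= window:
            incident = at_risk * h
            at_risk = at_risk - incident
            substitute = substitute + incident
            if t == window:  # risk window over: remaining mass is safe
                safe = safe + at_risk
                at_risk = np.zeros_like(at_risk)
        else:
            incident = np.zeros_like(h)
        disc = beta**t
        on_clz = at_risk + safe
        cost = cost + disc * (
            on_clz * clz_cycle_cost
            + substitute * sub_cycle_cost
            + incident * cost_ciag
        )
        qaly = qaly + disc * (on_clz * u_clz_cycle + substitute * u_sub_cycle)
        if keep_trace:
            tr_risk.append(at_risk.copy())
            tr_safe.append(safe.copy())
            tr_sub.append(substitute.copy())
            tr_inc.append(incident.copy())

    if keep_trace:
        trace = CohortTrace(
            on_clz_at_risk=np.array(tr_risk, dtype=float).reshape(-1),
            on_clz_safe=np.array(tr_safe, dtype=float).reshape(-1),
            on_substitute=np.array(tr_sub, dtype=float).reshape(-1),
            incident_ciag=np.array(tr_inc, dtype=float).reshape(-1),
        )
        return cost, qaly, trace
    return cost, qaly


def strategy_incidence(params: ModelParameters, strategy: Strategy) -> float:
    """Cumulative CIAG incidence applying in *strategy*'s arm."""
    if strategy.name == STANDARD_OF_CARE:
        return params.ciag_prevalence
    return effective_ciag_incidence(
        params.ciag_prevalence, strategy.panel.sensitivity, params.prevention_rate
    )


def run_cohort(params: ModelParameters, strategy: Strategy) -> StrategyResult:
    """Evaluate one strategy deterministically at the given parameters."""
    incidence = strategy_incidence(params, strategy)
    test_cost = params.cost_genetic_test if strategy.test_cost_applied else 0.0
    cost, qaly, trace = _cohort_outcomes(
        np.array(incidence),
        window=params.ciag_risk_window_cycles,
        n_cycles=params.n_cycles,
        test_cost=test_cost,
        cost_ciag=params.cost_ciag_treatment,
        cost_clz_day=params.cost_clz_per_day,
        cost_sub_day=params.cost_substitute_per_day,
        cost_blood=params.cost_blood_test_per_month,
        utility_clz=params.utility_clz,
        utility_sub=params.utility_substitute,
        annual_rate=params.discount_rate_annual,
        days_per_cycle=params.days_per_cycle,
        keep_trace=True,
    )
    return StrategyResult(
        strategy=strategy,
        discounted_cost=float(cost),
        discounted_qaly=float(qaly),
        trace=trace,
    )


def _classify(delta_cost: float, delta_qaly: float, atol: float = 1e-12):
    if abs(delta_qaly) <= atol and abs(delta_cost) <= atol:
        return None, "undefined"
    if abs(delta_qaly) <= atol:
        return None, "undefined"
    if delta_qaly > 0 and delta_cost <= 0:
        return None, "dominant"
    if delta_qaly < 0 and delta_cost >= 0:
        return None, "dominated"
    return delta_cost / delta_qaly, "icer"


def compare_strategies(
    params: ModelParameters, panel: PanelPerformance
) -> CEResult:
    """Deterministic CEA: PGx-guided (with *panel*) vs standard of care."""
    soc = run_cohort(params, Strategy.standard_of_care())
    pgx = run_cohort(params, Strategy.pgx_guided(panel))
    delta_cost = pgx.discounted_cost - soc.discounted_cost
    delta_qaly = pgx.discounted_qaly - soc.discounted_qaly
    icer, flag = _classify(delta_cost, delta_qaly)
    return CEResult(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=icer,
        flag=flag,
        pgx=pgx,
        soc=soc,
    )
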