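"""Individual-level microsimulation: synthetic patients and cohort oracle.

Simulates patient trajectories whose statistical structure matches the
cohort model exactly — destined-CIAG status at the prevalence, test result
via panel sensitivity/specificity, prevention of destined true positives in
the PGx arm, event timing from the same per-cycle hazard, and identical
per-state rewards and discounting.  Sample means therefore converge to the
cohort model's expectations (law of large numbers), which makes the module
both a brute-force validation oracle for the Markov engine and a generator
of realistic patient-level fixtures.

Randomness uses the counter-based Philox bit generator keyed on the seed;
all per-patient variates are drawn as index-aligned vectors, so patient
``i``'s trajectory depends only on ``(seed, i)`` and results are
independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    PGX_GUIDED,
    Strategy,
    ciag_monthly_hazard,
    strategy_incidence,
)
from .parameters import ModelParameters

__all__ = ["SyntheticPatient", "simulate_patient", "simulate_cohort", "MicrosimResult"]


@dataclass
class SyntheticPatient:
    """One simulated trajectory (see :func:`simulate_cohort` for fields)."""

    patient_id: int
    destined: bool
    test_positive: bool
    averted: bool
    ciag_cycle: int  # -1 when no event
    cost: float
    qaly: float


@dataclass
class MicrosimResult:
    """Monte Carlo means and standard errors for one strategy arm."""

    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    n: int
    patients: pd.DataFrame


def _discount_cumsum(params: ModelParameters) -> np.ndarray:
    """``D[t] = sum_{tau=1..t} (1+r)^(-tau/12)`` for t = 0..n_cycles."""
    beta = (1.0 + params.discount_rate_annual) ** (-1.0 / 12.0)
    t = np.arange(params.n_cycles + 1, dtype=float)
    d = beta**t
    d[0] = 0.0
    return np.cumsum(d)


def simulate_cohort(
    params: ModelParameters, strategy: Strategy, n: int, seed: int
) -> MicrosimResult:
    """Simulate *n* patients under *strategy* and summarise outcomes.

    Event timing: conditional on a (non-averted) CIAG event, the event cycle
    follows the truncated-geometric distribution implied by the arm's
    per-cycle hazard within the risk window — the same dynamics the cohort
    engine integrates deterministically.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.Generator(np.random.Philox(seed))
    pgx = strategy.name == PGX_GUIDED

    u_destined, u_test, u_avert, u_time = rng.random((4, n))

    destined = u_destined < params.ciag_prevalence
    if strategy.panel is not None:
        sens, spec = strategy.panel.sensitivity, strategy.panel.specificity
        test_positive = np.where(destined, u_test < sens, u_test < 1.0 - spec)
    else:
        test_positive = np.zeros(n, dtype=bool)
    averted = pgx & destined & test_positive & (u_avert < params.prevention_rate)
    has_event = destined & ~averted

    # Conditional event-cycle distribution within the risk window.  The
    # cohort engine applies hazard h (from the arm's cumulative incidence)
    # to everyone at risk; conditional on an event, P(cycle=e) is
    # proportional to h*(1-h)^(e-1), e = 1..window.
    window = params.ciag_risk_window_cycles
    incidence = strategy_incidence(params, strategy)
    ciag_cycle = np.full(n, -1, dtype=int)
    if incidence > 0:
        h = ciag_monthly_hazard(incidence, window)
        e = np.arange(1, window + 1)
        pmf = h * (1.0 - h) ** (e - 1)
        cdf = np.cumsum(pmf / pmf.sum())
        ciag_cycle[has_event] = 1 + np.searchsorted(cdf, u_time[has_event])

    # Rewards: clozapine cycles 1..e-1, substitute cycles e..n (destination
    # state's reward at the transition cycle), CIAG cost at cycle e.
    D = _discount_cumsum(params)
    beta = (1.0 + params.discount_rate_annual) ** (-1.0 / 12.0)
    last_clz = np.where(has_event, ciag_cycle - 1, params.n_cycles)
    d_clz = D[last_clz]
    d_sub = D[params.n_cycles] - d_clz

    clz_cycle_cost = (
        params.cost_clz_per_day * params.days_per_cycle
        + params.cost_blood_test_per_month
    )
    sub_cycle_cost = params.cost_substitute_per_day * params.days_per_cycle
    test_cost = params.cost_genetic_test if strategy.test_cost_applied else 0.0

    cost = (
        test_cost
        + clz_cycle_cost * d_clz
        + sub_cycle_cost * d_sub
        + np.where(has_event, params.cost_ciag_treatment * beta**ciag_cycle, 0.0)
    )
    qaly = (params.utility_clz / 12.0) * d_clz + (
        params.utility_substitute / 12.0
    ) * d_sub

    patients = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "destined": destined.astype(int),
            "test_positive": test_positive.astype(int),
            "averted": averted.astype(int),
            "ciag_cycle": ciag_cycle,
            "cost": cost,
            "qaly": qaly,
        }
    )
    return MicrosimResult(
        mean_cost=float(cost.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        mean_qaly=float(qaly.mean()),
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        n=n,
        patients=patients,
    )


def simulate_patient(
    params: ModelParameters, strategy: Strategy, seed: int
) -> SyntheticPatient:
    """Simulate a single trajectory (index 0 of the seeded stream)."""
    row = simulate_cohort(params, strategy, 1, seed).patients.iloc[0]
    return SyntheticPatient(
        patient_id=int(row.patient_id),
        destined=bool(row.destined),
        test_positive=bool(row.test_positive),
        averted=bool(row.averted),
        ciag_cycle=int(row.ciag_cycle),
        cost=float(row.cost),
        qaly=float(row.qaly),
    )
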