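"""Probabilistic and deterministic sensitivity analyses.

The PSA propagates the published gamma/beta parameter distributions through
the cohort model by Monte Carlo: each draw is a full parameter vector, both
strategy arms are evaluated, and the incremental cost and QALY pairs feed
the cost-effectiveness acceptability curve (CEAC) and the incremental
scatter.  Cost-effectiveness at willingness-to-pay ``lambda`` is defined
through the incremental net monetary benefit ``lambda * dQALY - dCost > 0``,
which is robust to the sign of the QALY increment.

Sampling is fully vectorised on one :class:`numpy.random.Generator` seeded
from the master seed, with a fixed parameter order, so a given seed yields
bitwise-identical draws regardless of how results are later consumed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import _cohort_outcomes, compare_strategies
from .parameters import ModelParameters, ParameterRegistry
from .performance import PanelPerformance, effective_ciag_incidence

__all__ = [
    "PSADraws",
    "CEACCurve",
    "DSAResult",
    "sample_parameters",
    "run_psa",
    "ceac",
    "probability_cost_effective",
    "one_way_dsa",
    "default_wtp_grid",
]

#: Registry names sampled for the PSA, in fixed draw order.
_SAMPLED_ORDER = (
    "ciag_prevalence",
    "cost_ciag_treatment",
    "cost_clz_per_day",
    "cost_substitute_per_day",
    "cost_genetic_test",
    "cost_blood_test_per_month",
    "utility_clz",
    "utility_substitute",
    "prevention_rate",
    "sensitivity",
    "specificity",
)


@dataclass
class PSADraws:
    """Sampled parameter vectors and per-strategy outcomes of one PSA."""

    parameters: pd.DataFrame
    cost_soc: np.ndarray
    qaly_soc: np.ndarray
    cost_pgx: np.ndarray
    qaly_pgx: np.ndarray
    seed: int
    n_iter: int

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_pgx - self.cost_soc

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qaly_pgx - self.qaly_soc

    def summary(self) -> dict[str, float]:
        dc, dq = self.delta_cost, self.delta_qaly
        return {
            "mean_cost_soc": float(self.cost_soc.mean()),
            "mean_qaly_soc": float(self.qaly_soc.mean()),
            "mean_cost_pgx": float(self.cost_pgx.mean()),
            "mean_qaly_pgx": float(self.qaly_pgx.mean()),
            "mean_delta_cost": float(dc.mean()),
            "mean_delta_qaly": float(dq.mean()),
            "icer_of_means": float(dc.mean() / dq.mean()),
        }

    def to_frame(self) -> pd.DataFrame:
        out = self.parameters.copy()
        out.insert(0, "iter", np.arange(self.n_iter))
        out["cost_soc"] = self.cost_soc
        out["qaly_soc"] = self.qaly_soc
        out["cost_pgx"] = self.cost_pgx
        out["qaly_pgx"] = self.qaly_pgx
        return out


@dataclass
class CEACCurve:
    """Probability of cost-effectiveness over a willingness-to-pay grid."""

    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})

    def at(self, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp - wtp)))
        return float(self.probability[idx])


@dataclass
class DSAResult:
    """One-way deterministic sensitivity analysis over a parameter grid."""

    parameter: str
    grid: np.ndarray
    icer: np.ndarray
    delta_cost: np.ndarray
    delta_qaly: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": self.grid,
                "icer": self.icer,
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )


def sample_parameters(
    registry: ParameterRegistry, n_iter: int, seed: int
) -> pd.DataFrame:
    """Draw *n_iter* parameter vectors from the registry distributions.

    Gamma entries sample ``Gamma(shape, scale=1/rate)``, beta entries
    ``Beta(alpha, beta)``, fixed entries repeat the mean.  Draw order is the
    fixed registry order, so results are reproducible for a given seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    for name in _SAMPLED_ORDER:
        entry = registry[name]
        spec = entry.spec
        if not entry.psa or spec.kind == "fixed":
            columns[name] = np.full(n_iter, entry.mean)
        elif spec.kind == "gamma":
            columns[name] = rng.gamma(spec.param_a, 1.0 / spec.param_b, n_iter)
        else:  # beta
            columns[name] = rng.beta(spec.param_a, spec.param_b, n_iter)
    return pd.DataFrame(columns)


def run_psa(
    params: ModelParameters,
    registry: ParameterRegistry,
    n_iter: int,
    seed: int,
    panel: Optional[PanelPerformance] = None,
) -> PSADraws:
    """Monte Carlo PSA of PGx-guided vs standard of care.

    When *panel* is ``None`` the panel sensitivity/specificity are sampled
    from their registry distributions (the base-case design); otherwise they
    are held fixed at the panel's values while every other distribution
    still samples — the published convention for the HLA-only comparison and
    the augmented-panel scenario, whose uncertainty distributions are not
    reported.
    """
    draws = sample_parameters(registry, n_iter, seed)
    if panel is not None:
        draws["sensitivity"] = panel.sensitivity
        draws["specificity"] = panel.specificity

    common = dict(
        window=params.ciag_risk_window_cycles,
        n_cycles=params.n_cycles,
        cost_ciag=draws["cost_ciag_treatment"].to_numpy(),
        cost_clz_day=draws["cost_clz_per_day"].to_numpy(),
        cost_sub_day=draws["cost_substitute_per_day"].to_numpy(),
        cost_blood=draws["cost_blood_test_per_month"].to_numpy(),
        utility_clz=draws["utility_clz"].to_numpy(),
        utility_sub=draws["utility_substitute"].to_numpy(),
        annual_rate=params.discount_rate_annual,
        days_per_cycle=params.days_per_cycle,
    )
    prevalence = draws["ciag_prevalence"].to_numpy()
    cost_soc, qaly_soc = _cohort_outcomes(prevalence, test_cost=0.0, **common)
    incidence_pgx = effective_ciag_incidence_vec(
        prevalence,
        draws["sensitivity"].to_numpy(),
        draws["prevention_rate"].to_numpy(),
    )
    cost_pgx, qaly_pgx = _cohort_outcomes(
        incidence_pgx, test_cost=draws["cost_genetic_test"].to_numpy(), **common
    )
    return PSADraws(
        parameters=draws,
        cost_soc=cost_soc,
        qaly_soc=qaly_soc,
        cost_pgx=cost_pgx,
        qaly_pgx=qaly_pgx,
        seed=seed,
        n_iter=n_iter,
    )


def effective_ciag_incidence_vec(prevalence, sensitivity, prevention_rate):
    """Vectorised counterpart of
    :func:`pgxcea.performance.effective_ciag_incidence`."""
    return np.asarray(prevalence) * (
        1.0 - np.asarray(sensitivity) * np.asarray(prevention_rate)
    )


def default_wtp_grid() -> np.ndarray:
    """GBP 0 to 50,000 per QALY in steps of 500."""
    return np.arange(0.0, 50_000.0 + 1, 500.0)


def probability_cost_effective(draws: PSADraws, wtp: float) -> float:
    """Fraction of draws with positive incremental net monetary benefit."""
    nmb = wtp * draws.delta_qaly - draws.delta_cost
    return float(np.mean(nmb > 0))


def ceac(draws: PSADraws, wtp_grid: Optional[Sequence[float]] = None) -> CEACCurve:
    """Cost-effectiveness acceptability curve over *wtp_grid*."""
    grid = np.asarray(
        default_wtp_grid() if wtp_grid is None else wtp_grid, dtype=float
    )
    if grid.size == 0:
        raise ValueError("WTP grid must be non-empty")
    nmb = grid[:, None] * draws.delta_qaly[None, :] - draws.delta_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACCurve(wtp=grid, probability=prob)


def one_way_dsa(
    params: ModelParameters,
    panel: PanelPerformance,
    parameter: str,
    grid: Sequence[float],
) -> DSAResult:
    """Deterministic one-way sweep of *parameter* over *grid*.

    ``sensitivity``/``specificity`` vary the panel; any
    :class:`ModelParameters` field name varies the parameters, all else held
    at point estimates.  The grid must be strictly increasing.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and strictly increasing")

    icers, dcosts, dqalys = [], [], []
    for value in grid:
        if parameter == "sensitivity":
            p = params
            pan = PanelPerformance(float(value), panel.specificity)
        elif parameter == "specificity":
            p = params
            pan = PanelPerformance(panel.sensitivity, float(value))
        elif parameter in {f.name for f in dataclasses.fields(ModelParameters)}:
            p = dataclasses.replace(params, **{parameter: float(value)})
            pan = panel
        else:
            raise ValueError(f"unknown parameter {parameter!r}")
        res = compare_strategies(p, pan)
        icers.append(np.nan if res.icer is None else res.icer)
        dcosts.append(res.delta_cost)
        dqalys.append(res.delta_qaly)
    return DSAResult(
        parameter=parameter,
        grid=grid,
        icer=np.asarray(icers),
        delta_cost=np.asarray(dcosts),
        delta_qaly=np.asarray(dqalys),
    )
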