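"""Model parameters, probabilistic-sensitivity distributions and configuration loading.

The cost-effectiveness model compares pre-emptive pharmacogenomic (PGx)
screening before clozapine initiation against standard blood-count
monitoring, over a 10-year horizon with monthly Markov cycles.  Every
clinical and economic input lives in :class:`ModelParameters`; the published
point estimates together with their probabilistic-sensitivity-analysis (PSA)
sampling distributions form the :class:`ParameterRegistry` returned by
:func:`default_registry`.

Gamma distributions are parameterised as (shape ``alpha``, rate ``lambda``),
so the analytic mean is ``alpha / lambda``; beta distributions as
(``alpha``, ``beta``) with mean ``alpha / (alpha + beta)``.  The registry is
self-checked at construction: each distribution's analytic mean must agree
with its published point estimate to 1% relative.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "DistributionSpec",
    "ModelParameters",
    "ParameterEntry",
    "ParameterRegistry",
    "default_registry",
    "distribution_mean",
    "load_config",
    "write_config",
]


@dataclass(frozen=True)
class DistributionSpec:
    """A PSA sampling distribution: ``gamma``, ``beta`` or ``fixed``.

    ``param_a``/``param_b`` are (shape, rate) for gamma and (alpha, beta)
    for beta; both are ignored for ``fixed``.
    """

    kind: str
    param_a: float = 0.0
    param_b: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("gamma", "beta", "fixed"):
            raise ValueError(f"unknown distribution kind: {self.kind!r}")
        if self.kind != "fixed" and (self.param_a <= 0 or self.param_b <= 0):
            raise ValueError(
                f"{self.kind} distribution requires positive parameters, "
                f"got ({self.param_a}, {self.param_b})"
            )


def distribution_mean(spec: DistributionSpec, fixed_value: float = 0.0) -> float:
    """Analytic mean of *spec*: ``a/b`` (gamma), ``a/(a+b)`` (beta), or the
    fixed value."""
    if spec.kind == "gamma":
        return spec.param_a / spec.param_b
    if spec.kind == "beta":
        return spec.param_a / (spec.param_a + spec.param_b)
    return fixed_value


@dataclass
class ModelParameters:
    """All point-estimate inputs and structural settings of the cohort model.

    Attributes
    ----------
    ciag_prevalence
        10-year cumulative risk of clozapine-induced agranulocytosis/
        granulocytopenia (CIAG) among clozapine starters.
    cost_ciag_treatment
        One-off cost (GBP) of managing a CIAG episode.
    cost_clz_per_day, cost_substitute_per_day
        Daily drug cost (GBP) on clozapine and on the substitute
        antipsychotic (usage-weighted mix of UK first-line drugs).
    cost_genetic_test
        One-off cost (GBP) of the pre-emptive genotyping panel, paid at
        cycle 0 in the PGx arm only.
    cost_blood_test_per_month
        Monitoring cost (GBP) per monthly cycle, accrued while on clozapine.
    utility_clz, utility_substitute
        Annual health-state utilities on clozapine and on substitute.
    prevention_rate
        Probability that fore-knowledge of risk-allele carriage averts CIAG
        in a patient who would otherwise develop it (only true positives of
        the panel benefit).
    discount_rate_annual
        Annual discount rate applied to both costs and QALYs.
    horizon_years, cycle_length_months
        Time horizon and Markov cycle length.
    ciag_risk_window_cycles
        Number of initial cycles over which the cumulative CIAG incidence is
        spread as a constant per-cycle hazard; zero hazard afterwards.  The
        default (36 cycles) calibrates the unreported event-timing structure
        so that the model reproduces the published ICERs; see
        ``docs/methods.md``.
    days_per_cycle
        Days per monthly cycle used to convert daily drug costs
        (365.25 / 12).
    """

    ciag_prevalence: float = 0.0343
    cost_ciag_treatment: float = 469.48
    cost_clz_per_day: float = 1.23
    cost_substitute_per_day: float = 5.11
    cost_genetic_test: float = 110.0
    cost_blood_test_per_month: float = 10.6
    utility_clz: float = 0.693
    utility_substitute: float = 0.560
    prevention_rate: float = 0.30
    discount_rate_annual: float = 0.035
    horizon_years: float = 10.0
    cycle_length_months: float = 1.0
    ciag_risk_window_cycles: int = 36
    days_per_cycle: float = 365.25 / 12

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    _PROBABILITIES = ("ciag_prevalence", "prevention_rate")
    _UTILITIES = ("utility_clz", "utility_substitute")
    _COSTS = (
        "cost_ciag_treatment",
        "cost_clz_per_day",
        "cost_substitute_per_day",
        "cost_genetic_test",
        "cost_blood_test_per_month",
    )

    def validate(self) -> None:
        for name in self._PROBABILITIES + self._UTILITIES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in self._COSTS:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.discount_rate_annual < 0:
            raise ValueError("discount_rate_annual must be non-negative")
        n_cycles = self.horizon_years * 12.0 / self.cycle_length_months
        if n_cycles <= 0 or abs(n_cycles - round(n_cycles)) > 1e-9:
            raise ValueError(
                "horizon_years * 12 / cycle_length_months must be a positive "
                f"integer, got {n_cycles}"
            )
        if not 1 <= self.ciag_risk_window_cycles <= round(n_cycles):
            raise ValueError(
                "ciag_risk_window_cycles must lie in [1, total cycles], got "
                f"{self.ciag_risk_window_cycles}"
            )
        if self.days_per_cycle <= 0:
            raise ValueError("days_per_cycle must be positive")

    @property
    def n_cycles(self) -> int:
        return round(self.horizon_years * 12.0 / self.cycle_length_months)


@dataclass(frozen=True)
class ParameterEntry:
    """One registry row: published mean, PSA distribution and PSA flag."""

    mean: float
    spec: DistributionSpec
    psa: bool


@dataclass
class ParameterRegistry:
    """Mapping of parameter name to its mean and PSA distribution.

    Parameters not varied probabilistically (CIAG prevalence, genetic-test
    cost, blood-test cost) carry ``fixed`` distributions.  Panel
    ``sensitivity`` and ``specificity`` are registry entries as well so the
    PSA can vary them alongside the economic inputs.
    """

    entries: dict[str, ParameterEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.check_means()

    def __getitem__(self, name: str) -> ParameterEntry:
        return self.entries[name]

    def __iter__(self):
        return iter(self.entries)

    def items(self):
        return self.entries.items()

    def check_means(self, rtol: float = 0.01) -> None:
        """Verify every non-fixed distribution's analytic mean against the
        published point estimate (1% relative by default)."""
        for name, entry in self.entries.items():
            if entry.spec.kind == "fixed":
                continue
            mean = distribution_mean(entry.spec)
            if abs(mean - entry.mean) > rtol * abs(entry.mean):
                raise ValueError(
                    f"distribution mean for {name!r} ({mean:.6g}) deviates "
                    f"from the point estimate ({entry.mean:.6g}) by more "
                    f"than {rtol:.0%}"
                )

    def with_mean(self, name: str, mean: float) -> "ParameterRegistry":
        """Return a copy with *name* re-centred on *mean*.

        Gamma entries keep their shape (coefficient of variation) and
        adjust the rate; beta entries keep their concentration
        ``alpha + beta`` and adjust the mean.  Fixed entries just move.
        """
        entry = self.entries[name]
        spec = entry.spec
        if spec.kind == "gamma" and mean > 0:
            new_spec = DistributionSpec("gamma", spec.param_a, spec.param_a / mean)
        elif spec.kind == "beta" and 0.0 < mean < 1.0:
            nu = spec.param_a + spec.param_b
            new_spec = DistributionSpec("beta", mean * nu, (1.0 - mean) * nu)
        elif spec.kind == "fixed":
            new_spec = spec
        else:  # boundary mean: the distribution degenerates to a point mass
            new_spec = DistributionSpec("fixed")
        entries = dict(self.entries)
        entries[name] = ParameterEntry(mean, new_spec, entry.psa)
        return ParameterRegistry(entries)


#: Registry rows: name -> (mean, distribution, PSA flag).  Distribution
#: parameters are the published PSA inputs; `fixed` rows were not varied.
_DEFAULT_ROWS: dict[str, ParameterEntry] = {
    "ciag_prevalence": ParameterEntry(0.0343, DistributionSpec("fixed"), False),
    "cost_ciag_treatment": ParameterEntry(
        469.48, DistributionSpec("gamma", 4.0, 8.5e-3), True
    ),
    "cost_clz_per_day": ParameterEntry(
        1.23, DistributionSpec("gamma", 37.8, 30.75), True
    ),
    "cost_substitute_per_day": ParameterEntry(
        5.11, DistributionSpec("gamma", 104.4, 20.44), True
    ),
    "cost_genetic_test": ParameterEntry(110.0, DistributionSpec("fixed"), False),
    "cost_blood_test_per_month": ParameterEntry(
        10.6, DistributionSpec("fixed"), False
    ),
    "utility_clz": ParameterEntry(0.693, DistributionSpec("beta", 575.0, 255.0), True),
    "utility_substitute": ParameterEntry(
        0.560, DistributionSpec("beta", 86.0, 67.0), True
    ),
    "prevention_rate": ParameterEntry(
        0.30, DistributionSpec("beta", 24.9, 58.1), True
    ),
    "sensitivity": ParameterEntry(
        0.430, DistributionSpec("beta", 169.13, 223.87), True
    ),
    "specificity": ParameterEntry(
        0.869, DistributionSpec("beta", 15531.77, 2342.23), True
    ),
}


def default_registry() -> ParameterRegistry:
    """The published parameter table as a validated registry."""
    return ParameterRegistry(dict(_DEFAULT_ROWS))


def _coerce(name: str, value) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ValueError(f"config value for {name!r} must be numeric, got {value!r}")
    return float(value)


def load_config(path: str | Path) -> tuple[ModelParameters, ParameterRegistry]:
    """Load a flat key/value YAML configuration.

    Recognised keys are exactly the :class:`ModelParameters` field names;
    anything else is an error (fail loud).  Unspecified keys fall back to the
    published defaults.  Every override is logged, and overrides of
    PSA-varied parameters re-centre the corresponding registry distribution
    on the new mean (shape-preserving, see
    :meth:`ParameterRegistry.with_mean`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"config {path} must be a flat key/value mapping")

    valid = {f.name for f in dataclasses.fields(ModelParameters)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    overrides = {}
    for name, value in raw.items():
        if name == "ciag_risk_window_cycles":
            overrides[name] = int(value)
        else:
            overrides[name] = _coerce(name, value)
        logger.info("config override: %s = %s", name, overrides[name])

    params = ModelParameters(**overrides)

    registry = default_registry()
    for name, value in overrides.items():
        if name in registry.entries and value != registry[name].mean:
            registry = registry.with_mean(name, value)
    return params, registry


def write_config(params: ModelParameters, path: str | Path) -> None:
    """Serialise *params* as a flat YAML mapping (round-trips with
    :func:`load_config`)."""
    data = dataclasses.asdict(params)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
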