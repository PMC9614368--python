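"""Screening-panel performance: aggregation, confusion fractions and NNG.

A PGx panel flags a patient as high-risk if *any* component variant set is
carried.  Under independence of carriage between components, panel
sensitivity is the complement-product ``1 - prod(1 - s_i)`` and panel
specificity the plain product ``prod(spec_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "VariantPerformance",
    "PanelPerformance",
    "ConfusionFractions",
    "combine_sensitivity",
    "combine_specificity",
    "combine_panels",
    "confusion_fractions",
    "effective_ciag_incidence",
    "number_needed_to_genotype",
]


def _check_prob(value: float, what: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{what} must lie in [0, 1], got {value}")
    return float(value)


@dataclass(frozen=True)
class VariantPerformance:
    """Sensitivity/specificity of one variant (or variant set) for CIAG."""

    name: str
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        _check_prob(self.sensitivity, f"{self.name} sensitivity")
        _check_prob(self.specificity, f"{self.name} specificity")


@dataclass(frozen=True)
class PanelPerformance:
    """Aggregated performance of a multi-variant panel.

    A panel is at least as sensitive as its most sensitive component and at
    most as specific as its least specific one; both facts follow from the
    union rule and are enforced as invariants.
    """

    sensitivity: float
    specificity: float
    components: tuple[VariantPerformance, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        _check_prob(self.sensitivity, "panel sensitivity")
        _check_prob(self.specificity, "panel specificity")
        if self.components:
            if self.sensitivity < max(c.sensitivity for c in self.components) - 1e-12:
                raise ValueError("panel sensitivity below a component's")
            if self.specificity > min(c.specificity for c in self.components) + 1e-12:
                raise ValueError("panel specificity above a component's")

    @classmethod
    def from_components(
        cls, components: Iterable[VariantPerformance]
    ) -> "PanelPerformance":
        comps = tuple(components)
        return cls(
            sensitivity=combine_sensitivity([c.sensitivity for c in comps]),
            specificity=combine_specificity([c.specificity for c in comps]),
            components=comps,
        )


def combine_sensitivity(sens_list: Sequence[float]) -> float:
    """Union sensitivity ``1 - prod(1 - s_i)`` of independent components."""
    if len(sens_list) == 0:
        raise ValueError("sensitivity list must be non-empty")
    out = 1.0
    for s in sens_list:
        out *= 1.0 - _check_prob(s, "component sensitivity")
    return 1.0 - out


def combine_specificity(spec_list: Sequence[float]) -> float:
    """Intersection specificity ``prod(spec_i)`` of independent components."""
    if len(spec_list) == 0:
        raise ValueError("specificity list must be non-empty")
    out = 1.0
    for s in spec_list:
        out *= _check_prob(s, "component specificity")
    return out


def combine_panels(
    panel: PanelPerformance, extra: VariantPerformance
) -> PanelPerformance:
    """Add one more variant to an existing panel (union rule)."""
    return PanelPerformance(
        sensitivity=combine_sensitivity([panel.sensitivity, extra.sensitivity]),
        specificity=combine_specificity([panel.specificity, extra.specificity]),
        components=panel.components + (extra,),
    )


@dataclass(frozen=True)
class ConfusionFractions:
    """Cohort fractions by destined-CIAG status x test result."""

    tp: float
    fn: float
    fp: float
    tn: float

    def __post_init__(self) -> None:
        total = self.tp + self.fn + self.fp + self.tn
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"confusion fractions must sum to 1, got {total}")


def confusion_fractions(
    prevalence: float, panel: PanelPerformance
) -> ConfusionFractions:
    """Decision-tree branch probabilities for a screened cohort."""
    p = _check_prob(prevalence, "prevalence")
    sens, spec = panel.sensitivity, panel.specificity
    return ConfusionFractions(
        tp=p * sens,
        fn=p * (1.0 - sens),
        fp=(1.0 - p) * (1.0 - spec),
        tn=(1.0 - p) * spec,
    )


def effective_ciag_incidence(
    prevalence: float, sensitivity: float, prevention_rate: float
) -> float:
    """Cumulative CIAG incidence under screening.

    Only destined patients flagged by the panel (true positives) benefit
    from the prevention rate, so the incidence falls from ``p`` to
    ``p * (1 - sensitivity * prevention_rate)``.
    """
    p = _check_prob(prevalence, "prevalence")
    s = _check_prob(sensitivity, "sensitivity")
    r = _check_prob(prevention_rate, "prevention_rate")
    return p * (1.0 - s * r)


def number_needed_to_genotype(
    prevalence_percent: float, sensitivity: float
) -> int:
    """Patients to genotype to prevent one CIAG case:
    ``100 / (prevalence% x sensitivity)``, rounded to nearest."""
    if prevalence_percent <= 0 or sensitivity <= 0:
        raise ValueError("prevalence_percent and sensitivity must be positive")
    return round(100.0 / (prevalence_percent * sensitivity))
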