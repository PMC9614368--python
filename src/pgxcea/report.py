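"""End-to-end reproduction of the published analysis as CSV tables + plots.

:func:`reproduce_paper` runs the whole pipeline — base-case CEAs for the
HLA-only and combined panels, 100,000-draw PSAs with CEACs and incremental
scatters, one-way deterministic sweeps of panel sensitivity and
specificity, the augmented-panel scenario, and the RR x MAF grid — and
writes every result under an output directory together with a run manifest.
CSV files are the contract; the figures are conveniences.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import compare_strategies
from .parameters import ModelParameters, ParameterRegistry, default_registry
from .performance import (
    PanelPerformance,
    VariantPerformance,
    number_needed_to_genotype,
)
from .power import scenario_cea, rr_maf_grid, variant_sens_spec
from .psa import ceac, one_way_dsa, probability_cost_effective, run_psa

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "reproduce_paper", "base_panel", "hla_only_panel"]

#: Published per-component performance: the HLA amino-acid pair and the
#: SLCO1B3-SLCO1B7 intronic SNP rs149104283.
HLA_VARIANT = VariantPerformance("HLA-DQB1(126Q)+HLA-B(158T)", 0.360, 0.890)
SLCO_VARIANT = VariantPerformance("rs149104283", 0.109, 0.976)


def hla_only_panel() -> PanelPerformance:
    return PanelPerformance.from_components([HLA_VARIANT])


def base_panel() -> PanelPerformance:
    """The combined HLA + SLCO panel (sensitivity 0.430, specificity 0.869)."""
    return PanelPerformance.from_components([HLA_VARIANT, SLCO_VARIANT])


@dataclass
class RunManifest:
    """Record of one reproduction run: inputs, outputs and numeric hash."""

    seed: int
    n_iter: int
    config_hash: str
    package_version: str
    timestamp: str
    files: list[str] = field(default_factory=list)
    numeric_hash: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _hash_params(params: ModelParameters) -> str:
    payload = json.dumps(
        {k: v for k, v in sorted(vars(params).items())}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _numeric_hash(summary: pd.DataFrame, tol_decimals: int = 9) -> str:
    rounded = summary.copy()
    rounded["value"] = rounded["value"].round(tol_decimals)
    return hashlib.sha256(
        rounded.to_csv(index=False).encode()
    ).hexdigest()[:16]


def _save_figures(out: Path, ceac_combined, ceac_hla, draws, dsa_sens, dsa_spec):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac_combined.wtp, ceac_combined.probability, label="HLA + SLCO panel")
    ax.plot(ceac_hla.wtp, ceac_hla.probability, label="HLA-only panel")
    ax.axvline(30_000, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("Willingness to pay (GBP/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "ceac.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    within = 30_000 * draws.delta_qaly - draws.delta_cost > 0
    sub = slice(0, min(draws.n_iter, 20_000))  # keep the figure light
    ax.scatter(
        draws.delta_qaly[sub][within[sub]],
        draws.delta_cost[sub][within[sub]],
        s=2,
        c="tab:green",
        label="within WTP",
    )
    ax.scatter(
        draws.delta_qaly[sub][~within[sub]],
        draws.delta_cost[sub][~within[sub]],
        s=2,
        c="tab:red",
        label="outside WTP",
    )
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (GBP)")
    ax.legend(markerscale=4)
    fig.tight_layout()
    fig.savefig(out / "incremental_scatter.png", dpi=150)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    axes[0].plot(dsa_sens.grid, dsa_sens.icer)
    axes[0].set_xlabel("Panel sensitivity")
    axes[0].set_ylabel("ICER (GBP/QALY)")
    axes[1].plot(dsa_spec.grid, dsa_spec.icer)
    axes[1].set_xlabel("Panel specificity")
    fig.tight_layout()
    fig.savefig(out / "one_way_dsa.png", dpi=150)
    plt.close(fig)


def reproduce_paper(
    params: Optional[ModelParameters] = None,
    registry: Optional[ParameterRegistry] = None,
    out_dir: str | Path = "results",
    n_iter: int = 100_000,
    seed: int = 42,
    make_plots: bool = True,
) -> RunManifest:
    """Run the full analysis and write all result tables under *out_dir*."""
    params = params or ModelParameters()
    registry = registry or default_registry()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.6f")
        files.append(name)
        logger.info("wrote %s", path)

    combined = base_panel()
    hla = hla_only_panel()

    # Deterministic base cases -------------------------------------------
    ce_combined = compare_strategies(params, combined)
    ce_hla = compare_strategies(params, hla)
    emit(
        pd.DataFrame(
            [
                {
                    "panel": name,
                    "cost_soc": ce.soc.discounted_cost,
                    "qaly_soc": ce.soc.discounted_qaly,
                    "cost_pgx": ce.pgx.discounted_cost,
                    "qaly_pgx": ce.pgx.discounted_qaly,
                    "delta_cost": ce.delta_cost,
                    "delta_qaly": ce.delta_qaly,
                    "icer": ce.icer,
                }
                for name, ce in [("combined", ce_combined), ("hla_only", ce_hla)]
            ]
        ),
        "strategy_results.csv",
    )
    trace = ce_combined.soc.trace
    emit(
        pd.DataFrame(
            {
                "cycle": trace.cycles,
                "on_clz_at_risk": trace.on_clz_at_risk,
                "on_clz_safe": trace.on_clz_safe,
                "on_substitute": trace.on_substitute,
                "incident_ciag": trace.incident_ciag,
            }
        ),
        "trace_soc.csv",
    )

    # PSA + CEAC ----------------------------------------------------------
    seeds = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    draws_combined = run_psa(params, registry, n_iter, int(seeds[0]))
    draws_hla = run_psa(params, registry, n_iter, int(seeds[1]), panel=hla)
    ceac_combined = ceac(draws_combined)
    ceac_hla = ceac(draws_hla)
    emit(ceac_combined.to_frame(), "ceac_combined.csv")
    emit(ceac_hla.to_frame(), "ceac_hla_only.csv")
    p_ce_combined = probability_cost_effective(draws_combined, 30_000.0)
    p_ce_hla = probability_cost_effective(draws_hla, 30_000.0)

    # One-way DSA ---------------------------------------------------------
    dsa_sens = one_way_dsa(
        params, combined, "sensitivity", np.linspace(0.2, 0.8, 25)
    )
    dsa_spec = one_way_dsa(
        params, combined, "specificity", np.linspace(0.70, 0.99, 25)
    )
    dsa_window = one_way_dsa(
        params, combined, "ciag_risk_window_cycles", np.arange(1.0, 61.0, 1.0)
    )
    emit(dsa_sens.to_frame(), "dsa_sensitivity.csv")
    emit(dsa_spec.to_frame(), "dsa_specificity.csv")
    emit(dsa_window.to_frame(), "dsa_risk_window.csv")

    # Undetected-variant scenario (RR=3, MAF=5%) --------------------------
    variant = variant_sens_spec(3.0, 0.05, params.ciag_prevalence)
    scenario = scenario_cea(
        params,
        registry,
        combined,
        variant,
        n_iter=n_iter,
        seed=int(seeds[2]),
    )

    # RR x MAF grid -------------------------------------------------------
    grid = rr_maf_grid(
        [3.0, 2.5, 2.0], [0.10, 0.075, 0.05, 0.025, 0.01], params, combined
    )
    emit(grid, "rr_maf_grid.csv")

    # Headline summary ----------------------------------------------------
    summary = pd.DataFrame(
        [
            ("combined_sensitivity", combined.sensitivity),
            ("combined_specificity", combined.specificity),
            ("nng", number_needed_to_genotype(
                100.0 * params.ciag_prevalence, combined.sensitivity
            )),
            ("icer_base", ce_combined.icer),
            ("icer_psa_means", draws_combined.summary()["icer_of_means"]),
            ("icer_hla_only", ce_hla.icer),
            ("p_ce_combined", p_ce_combined),
            ("p_ce_hla_only", p_ce_hla),
            ("scenario_sens", scenario.panel.sensitivity),
            ("scenario_spec", scenario.panel.specificity),
            ("scenario_icer", scenario.ce.icer),
            ("scenario_qaly", scenario.psa_summary["mean_qaly_pgx"]),
            ("scenario_cost", scenario.psa_summary["mean_cost_pgx"]),
            ("scenario_p_ce", scenario.psa_summary["p_cost_effective"]),
        ],
        columns=["name", "value"],
    )
    # monetary to 2 decimals, probabilities to 3 (serialisation only)
    money = {
        "icer_base", "icer_psa_means", "icer_hla_only", "scenario_icer",
        "scenario_cost",
    }
    summary["value"] = [
        round(v, 2) if n in money else (round(v, 5) if n == "scenario_qaly" else round(v, 3))
        for n, v in zip(summary["name"], summary["value"])
    ]
    emit(summary, "summary.csv")

    if make_plots:
        _save_figures(out, ceac_combined, ceac_hla, draws_combined, dsa_sens, dsa_spec)
        files += ["ceac.png", "incremental_scatter.png", "one_way_dsa.png"]

    manifest = RunManifest(
        seed=seed,
        n_iter=n_iter,
        config_hash=_hash_params(params),
        package_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        files=files,
        numeric_hash=_numeric_hash(summary),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
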