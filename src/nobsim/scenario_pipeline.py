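"""Global-change treatment scenarios and model-data comparison.

For each treatment the measured drivers are mapped to the two-compartment
soil environment, the community is run to steady state in each
compartment, and per-type abundances are aggregated across compartments
weighted by soil-mass fraction.  Soil-level nitrite oxidation is the
mass-fraction-weighted sum of the compartment solution fluxes converted
to ng-N per g dry soil per hour.

The module also provides the factorial percent-effect statistic,
ordinary-least-squares predicted-vs-observed comparison, and the
model-complexity ablation (1, 2, 3 or 4 functional types).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community_simulator import (
    DEFAULT_CONFIG,
    SimulationConfig,
    SteadyStateResult,
    run_to_steady_state,
)
from .soil_environment import (
    DEFAULT_MAPPING,
    DriverRecord,
    MappingConfig,
    TREATMENTS,
    build_environment,
)
from .trait_catalog import FunctionalTypeSet, build_type_set

__all__ = [
    "ScenarioResult",
    "ComparisonResult",
    "DEFAULT_WATER_CONTENT",
    "nitrite_oxidation_to_soil_units",
    "percent_effect",
    "run_scenario",
    "run_scenarios",
    "compare_predicted_observed",
    "composition_distance",
    "complexity_ablation",
    "genus_shares",
]

#: Soil water content, L per g dry soil (0.21 g H2O per g dry soil).
DEFAULT_WATER_CONTENT = 2.1e-4

#: Molar mass of N used for flux conversion, g mol^-1.
M_N = 14.0


def nitrite_oxidation_to_soil_units(
    flux: float,
    water_content: float = DEFAULT_WATER_CONTENT,
    mass_fraction: float = 1.0,
) -> float:
    """Convert a solution-phase flux (µM s^-1) to ng-N g^-1 dry soil h^-1.

    flux · 1e-6 mol L^-1 s^-1 · water_content L g^-1 · 14e9 ng mol^-1 ·
    3600 s h^-1, weighted by the compartment's soil-mass fraction.
    """
    if flux < 0 or water_content < 0 or mass_fraction < 0:
        raise ValueError("flux, water_content and mass_fraction must be >= 0")
    return flux * 1e-6 * water_content * M_N * 1e9 * 3600.0 * mass_fraction


def percent_effect(elevated: float, ambient: float) -> float:
    """Main-effect size, %: 100 · (elevated − ambient) / ambient."""
    if ambient == 0:
        raise ZeroDivisionError(
            "percent effect undefined for ambient mean of zero"
        )
    return 100.0 * (elevated - ambient) / ambient


@dataclass
class ScenarioResult:
    """Community composition and soil nitrite oxidation for one treatment."""

    treatment: str
    names: tuple[str, ...]
    abundance: np.ndarray  # mass-fraction-weighted biomass per type, M
    relative_abundance: np.ndarray
    nitrite_oxidation: float  # ng-N g^-1 dry soil h^-1
    n_types: int
    converged: bool
    compartment_results: Mapping[str, SteadyStateResult] = field(
        default_factory=dict
    )

    def as_dict(self) -> dict:
        d = {
            "treatment": self.treatment,
            "n_types": self.n_types,
            "nitrite_oxidation_ng_N_g_h": self.nitrite_oxidation,
            "converged": self.converged,
        }
        for name, rel in zip(self.names, self.relative_abundance):
            d[f"rel_{name}"] = float(rel)
        return d


def run_scenario(
    driver: DriverRecord,
    typeset: FunctionalTypeSet,
    config: SimulationConfig = DEFAULT_CONFIG,
    mapping: MappingConfig = DEFAULT_MAPPING,
    water_content: float = DEFAULT_WATER_CONTENT,
) -> ScenarioResult:
    """Steady-state prediction for a single treatment's drivers."""
    env = build_environment(driver, mapping)
    compartments = {
        "hotspot": (env.hotspot, env.hotspot_mass_fraction),
        "bulk": (env.bulk, env.bulk_mass_fraction),
    }
    abundance = np.zeros(typeset.n_types)
    oxidation = 0.0
    converged = True
    results = {}
    for label, (comp_env, mass_fraction) in compartments.items():
        res = run_to_steady_state(typeset, comp_env, config=config)
        results[label] = res
        abundance += mass_fraction * res.biomass
        oxidation += nitrite_oxidation_to_soil_units(
            res.fluxes.total_no2_oxidation, water_content, mass_fraction
        )
        converged &= res.converged
    total = abundance.sum()
    rel = abundance / total if total > 0 else np.zeros_like(abundance)
    return ScenarioResult(
        treatment=driver.treatment,
        names=typeset.names,
        abundance=abundance,
        relative_abundance=rel,
        nitrite_oxidation=oxidation,
        n_types=typeset.n_types,
        converged=converged,
        compartment_results=results,
    )


def _mean_drivers(
    drivers: Iterable[DriverRecord],
) -> dict[str, DriverRecord]:
    """Collapse replicate rows to one mean driver record per treatment."""
    by_treatment: dict[str, list[DriverRecord]] = {}
    for d in drivers:
        by_treatment.setdefault(d.treatment, []).append(d)
    return {
        t: DriverRecord(
            treatment=t,
            ammonification=float(np.mean([d.ammonification for d in ds])),
            respiration=float(np.mean([d.respiration for d in ds])),
        )
        for t, ds in by_treatment.items()
    }


def run_scenarios(
    drivers: Iterable[DriverRecord],
    typeset: FunctionalTypeSet,
    config: SimulationConfig = DEFAULT_CONFIG,
    mapping: MappingConfig = DEFAULT_MAPPING,
    water_content: float = DEFAULT_WATER_CONTENT,
    treatments: Sequence[str] = TREATMENTS,
) -> list[ScenarioResult]:
    """Run every treatment present in the driver table.

    Replicate rows are averaged per treatment.  Treatments listed in
    ``treatments`` but absent from the table are skipped with a warning
    (field campaigns do not always yield drivers for every treatment).
    Deterministic: identical drivers give identical results.
    """
    table = _mean_drivers(drivers)
    missing = [t for t in treatments if t not in table]
    if missing:
        warnings.warn(
            f"no driver values for treatment(s) {missing}; skipped",
            stacklevel=2,
        )
    return [
        run_scenario(table[t], typeset, config, mapping, water_content)
        for t in treatments
        if t in table
    ]


@dataclass
class ComparisonResult:
    """OLS comparison of predicted against observed per-treatment values."""

    treatments: tuple[str, ...]
    predicted: np.ndarray
    observed: np.ndarray
    slope: float
    intercept: float
    correlation: float
    p_value: float
    scope: str = ""

    @property
    def n(self) -> int:
        return len(self.treatments)


def compare_predicted_observed(
    predicted: Mapping[str, float],
    observed: Mapping[str, float],
    scope: str = "",
) -> ComparisonResult:
    """Least-squares fit of observed on predicted over matched treatments."""
    common = [t for t in predicted if t in observed]
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 matched treatments for a regression, got {len(common)}"
        )
    x = np.array([predicted[t] for t in common], dtype=float)
    y = np.array([observed[t] for t in common], dtype=float)
    fit = stats.linregress(x, y)
    return ComparisonResult(
        treatments=tuple(common),
        predicted=x,
        observed=y,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        correlation=float(fit.rvalue),
        p_value=float(fit.pvalue),
        scope=scope,
    )


def genus_shares(result: ScenarioResult) -> dict[str, float]:
    """Relative abundance aggregated to genus (Nitrospira- vs
    Nitrobacter-like types), the level at which configurations with
    different numbers of types are comparable."""
    shares = {"Nitrospira": 0.0, "Nitrobacter": 0.0}
    for name, rel in zip(result.names, result.relative_abundance):
        genus = "Nitrospira" if name.startswith("Nitrospira") else "Nitrobacter"
        # the 1-type 'average NOB' is counted as unclassified and split evenly
        if name == "NOB_avg":
            shares["Nitrospira"] += 0.5 * rel
            shares["Nitrobacter"] += 0.5 * rel
        else:
            shares[genus] += rel
    return shares


def composition_distance(
    a: Sequence[ScenarioResult], b: Sequence[ScenarioResult]
) -> float:
    """Mean absolute difference of genus-level shares across the common
    treatments of two scenario tables."""
    by_a = {r.treatment: r for r in a}
    by_b = {r.treatment: r for r in b}
    common = [t for t in by_a if t in by_b]
    if not common:
        raise ValueError("no common treatments")
    diffs = []
    for t in common:
        sa, sb = genus_shares(by_a[t]), genus_shares(by_b[t])
        diffs.extend(abs(sa[g] - sb[g]) for g in ("Nitrospira", "Nitrobacter"))
    return float(np.mean(diffs))


def complexity_ablation(
    drivers: Iterable[DriverRecord],
    n_types_list: Sequence[int] = (1, 2, 3, 4),
    config: SimulationConfig = DEFAULT_CONFIG,
    mapping: MappingConfig = DEFAULT_MAPPING,
    water_content: float = DEFAULT_WATER_CONTENT,
) -> dict:
    """Scenario tables for each model complexity plus summary metrics.

    Returns a dict with per-complexity results, a tidy oxidation table
    and the genus-level composition distance of each configuration from
    the 3-type reference (when the reference is part of the list).
    """
    drivers = list(drivers)
    results = {
        n: run_scenarios(drivers, build_type_set(n), config, mapping, water_content)
        for n in n_types_list
    }
    oxidation = pd.DataFrame(
        {
            n: {r.treatment: r.nitrite_oxidation for r in res}
            for n, res in results.items()
        }
    )
    distances = {}
    if 3 in results:
        for n, res in results.items():
            if n != 3:
                distances[n] = composition_distance(res, results[3])
    return {
        "results": results,
        "oxidation": oxidation,
        "distance_to_reference": distances,
    }


def scenario_table(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Tidy one-row-per-treatment summary of scenario results."""
    return pd.DataFrame([r.as_dict() for r in results])
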