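"""Mapping of measured soil drivers to compartment substrate concentrations.

Two measured drivers — gross ammonification (a proxy of N availability to
nitrifiers) and basal soil respiration (a proxy of native organic-carbon
availability) — determine the substrate environment of the resource-rich
soil compartment ("hotspot").  Empirical relations convert the drivers to
NO2-, OC and O2 concentrations in soil solution; because those relations
are steep power/linear laws, the OC and O2 outputs are clamped to the
simulated gradient ranges over which the niche model is defined.

The soil is represented by two homogeneous compartments: the hotspot
(default 5.5 % of soil mass) whose environment tracks the drivers, and the
bulk of microhabitats with prescribed low O2 and NO2- (5e-4 M and 1e-5 M)
and no OC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

__all__ = [
    "DriverRecord",
    "EnvironmentState",
    "TwoCompartmentEnvironment",
    "MappingConfig",
    "TREATMENTS",
    "ammonification_to_no2",
    "respiration_to_oc",
    "respiration_to_o2",
    "ppm_to_molar",
    "build_environment",
    "read_driver_csv",
]

#: The eight factorial global-change treatments.
TREATMENTS = ("CTRL", "N", "W", "NW", "CO2", "CO2N", "CO2W", "CO2NW")

#: Physical clamp on mapped O2 concentration (M); the simulated aeration
#: gradient of the niche model.
O2_MIN, O2_MAX = 1e-4, 1e-2
#: Upper clamp on mapped OC concentration (M).
OC_MAX = 5e-3


@dataclass(frozen=True)
class DriverRecord:
    """Measured drivers for one treatment (optionally one replicate).

    ``ammonification`` in ng-N g^-1 h^-1, ``respiration`` in
    mg-C g^-1 h^-1.
    """

    treatment: str
    ammonification: float
    respiration: float
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ammonification < 0:
            raise ValueError(
                f"ammonification must be >= 0, got {self.ammonification}"
            )
        if not self.respiration > 0:
            raise ValueError(
                f"respiration must be > 0 (its log is taken), "
                f"got {self.respiration}"
            )


@dataclass(frozen=True)
class EnvironmentState:
    """Substrate concentrations (M) in the soil solution of one compartment."""

    no2: float
    oc: float
    o2: float
    co2: float = 1e-5

    def __post_init__(self) -> None:
        for fname in ("no2", "oc", "o2", "co2"):
            v = getattr(self, fname)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{fname} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class TwoCompartmentEnvironment:
    """Hotspot plus bulk-soil compartment environments."""

    hotspot: EnvironmentState
    bulk: EnvironmentState
    hotspot_mass_fraction: float = 0.055

    def __post_init__(self) -> None:
        if not 0 < self.hotspot_mass_fraction < 1:
            raise ValueError(
                "hotspot_mass_fraction must lie in (0, 1), "
                f"got {self.hotspot_mass_fraction}"
            )

    @property
    def bulk_mass_fraction(self) -> float:
        return 1.0 - self.hotspot_mass_fraction


@dataclass(frozen=True)
class MappingConfig:
    """Configuration of the driver-to-environment mapping.

    ``oc_mode`` selects the interpretation of the OC relation:
    ``"linear"`` (default) uses 10·respiration − 15.5 clamped to
    [0, oc_max]; ``"log10"`` interprets the relation as
    10^(respiration − 15.5) (effectively zero at realistic respiration,
    retained as an explicit alternative reading).
    """

    oc_mode: str = "linear"
    oc_max: float = OC_MAX
    o2_min: float = O2_MIN
    o2_max: float = O2_MAX
    co2: float = 1e-5
    hotspot_mass_fraction: float = 0.055
    bulk_no2: float = 1e-5
    bulk_o2: float = 5e-4
    bulk_oc: float = 0.0

    def __post_init__(self) -> None:
        if self.oc_mode not in ("linear", "log10"):
            raise ValueError(f"unknown oc_mode {self.oc_mode!r}")


DEFAULT_MAPPING = MappingConfig()


def ammonification_to_no2(a: float) -> float:
    """Hotspot NO2- concentration (M) from gross ammonification.

    Empirical power law 2e-16 · a^5.35 with a in ng-N g^-1 h^-1.
    """
    if a < 0:
        raise ValueError(f"ammonification must be >= 0, got {a}")
    if a == 0:
        return 0.0
    return 2e-16 * a**5.35


def respiration_to_oc(
    r: float, config: MappingConfig = DEFAULT_MAPPING
) -> float:
    """Hotspot OC concentration (M) from basal respiration.

    Linear relation 10·r − 15.5 (r in mg-C g^-1 h^-1), clamped into
    [0, ``config.oc_max``]; the clamp keeps the output inside the OC
    gradient over which the niche model is defined.
    """
    if not r > 0:
        raise ValueError(f"respiration must be > 0, got {r}")
    if config.oc_mode == "log10":
        oc = 10.0 ** (r - 15.5)
    else:
        oc = 10.0 * r - 15.5
    return min(max(oc, 0.0), config.oc_max)


def respiration_to_o2(
    r: float, config: MappingConfig = DEFAULT_MAPPING
) -> float:
    """Hotspot O2 concentration (M) from basal respiration.

    −0.019·ln(r) + 0.0137, clamped into [``config.o2_min``,
    ``config.o2_max``]; strictly decreasing in r before clamping.
    """
    if not r > 0:
        raise ValueError(f"respiration must be > 0, got {r}")
    o2 = -0.019 * math.log(r) + 0.0137
    return min(max(o2, config.o2_min), config.o2_max)


def ppm_to_molar(ppm: float, molar_mass: float) -> float:
    """Convert ppm (mg per liter of soil solution) to mol L^-1.

    150 ppm CH2O (30 g mol^-1) ↦ 5e-3 M; 3.2 ppm O2 (32 g mol^-1)
    ↦ 1e-4 M.
    """
    if ppm < 0:
        raise ValueError(f"ppm must be >= 0, got {ppm}")
    if not molar_mass > 0:
        raise ValueError(f"molar_mass must be > 0, got {molar_mass}")
    return ppm / (1000.0 * molar_mass)


def build_environment(
    driver: DriverRecord, config: MappingConfig = DEFAULT_MAPPING
) -> TwoCompartmentEnvironment:
    """Assemble the two-compartment environment for one driver record.

    The hotspot receives the mapped NO2-/OC/O2; the bulk compartment
    receives prescribed low constants with zero OC.  Deterministic.
    """
    hotspot = EnvironmentState(
        no2=ammonification_to_no2(driver.ammonification),
        oc=respiration_to_oc(driver.respiration, config),
        o2=respiration_to_o2(driver.respiration, config),
        co2=config.co2,
    )
    bulk = EnvironmentState(
        no2=config.bulk_no2,
        oc=config.bulk_oc,
        o2=config.bulk_o2,
        co2=config.co2,
    )
    return TwoCompartmentEnvironment(
        hotspot=hotspot,
        bulk=bulk,
        hotspot_mass_fraction=config.hotspot_mass_fraction,
    )


_CSV_COLUMNS = {
    "treatment": "treatment",
    "ammonification_ng_N_g_h": "ammonification",
    "respiration_mg_C_g_h": "respiration",
}


def read_driver_csv(path) -> list[DriverRecord]:
    """Read a driver table (one row per treatment or per replicate unit).

    Required columns: ``treatment``, ``ammonification_ng_N_g_h``,
    ``respiration_mg_C_g_h``; optional ``replicate``.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"driver CSV missing column(s) {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            DriverRecord(
                treatment=str(row["treatment"]),
                ammonification=float(row["ammonification_ng_N_g_h"]),
                respiration=float(row["respiration_mg_C_g_h"]),
                replicate=(
                    int(row["replicate"])
                    if "replicate" in df.columns and pd.notna(row["replicate"])
                    else None
                ),
            )
        )
    return records
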