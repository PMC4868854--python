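"""Steady-state niche reconstruction over NO2- × OC × O2 gradients.

Sweeps :func:`nobsim.community_simulator.run_to_steady_state` over a 3-D
concentration grid spanning the ranges a soil community plausibly
experiences (NO2- 7.4e-6–3.7e-2 M, OC 0–5e-3 M, O2 1e-4–1e-2 M) and
records per-cell, per-type steady-state biomass, the dominant type and
the total nitrite-oxidation flux.  Cells are independent, so the map is
deterministic and evaluation-order invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .community_simulator import (
    DEFAULT_CONFIG,
    SimulationConfig,
    run_to_steady_state,
)
from .soil_environment import EnvironmentState
from .trait_catalog import FunctionalTypeSet

__all__ = [
    "GradientSpec",
    "NicheMap",
    "sweep",
    "classify_dominance",
    "save_heatmaps",
]

#: Sentinel written for log10 of zero biomass.
LOG10_ZERO = -99.0


@dataclass(frozen=True)
class GradientSpec:
    """Axes of the niche sweep (concentrations in M).

    Default spacing is logarithmic for NO2- and O2 (four decades and two
    decades respectively) and linear for OC, whose range includes zero.
    """

    no2_range: tuple[float, float] = (7.4e-6, 3.7e-2)
    oc_range: tuple[float, float] = (0.0, 5e-3)
    o2_range: tuple[float, float] = (1e-4, 1e-2)
    points_per_axis: int = 12
    no2_spacing: str = "log"
    oc_spacing: str = "linear"
    o2_spacing: str = "log"

    def __post_init__(self) -> None:
        if self.points_per_axis < 2:
            raise ValueError("points_per_axis must be >= 2")
        for name in ("no2_range", "oc_range", "o2_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise ValueError(f"{name} must be positive-ordered: {(lo, hi)}")
        for name in ("no2_spacing", "oc_spacing", "o2_spacing"):
            if getattr(self, name) not in ("log", "linear"):
                raise ValueError(f"{name} must be 'log' or 'linear'")
            if getattr(self, name) == "log" and getattr(
                self, name.replace("_spacing", "_range")
            )[0] <= 0:
                raise ValueError(f"log spacing needs a positive lower {name}")

    def axis(self, name: str) -> np.ndarray:
        lo, hi = getattr(self, f"{name}_range")
        if getattr(self, f"{name}_spacing") == "log":
            return np.geomspace(lo, hi, self.points_per_axis)
        return np.linspace(lo, hi, self.points_per_axis)


@dataclass
class NicheMap:
    """Gridded steady-state community composition.

    ``biomass`` has shape (n_no2, n_oc, n_o2, n_types); ``converged``
    flags any cell whose steady-state run did not meet the residual
    tolerance.
    """

    no2: np.ndarray
    oc: np.ndarray
    o2: np.ndarray
    names: tuple[str, ...]
    biomass: np.ndarray
    total_no2_flux: np.ndarray  # µM s^-1 per cell
    converged: np.ndarray

    @property
    def log10_biomass(self) -> np.ndarray:
        out = np.full_like(self.biomass, LOG10_ZERO)
        pos = self.biomass > 0
        out[pos] = np.log10(self.biomass[pos])
        return out

    @property
    def dominant(self) -> np.ndarray:
        """Index of the dominant (max biomass) type per cell; -1 if all
        extinct.  Ties resolve to the first type in listed order."""
        dom = np.argmax(self.biomass, axis=-1)
        empty = np.all(self.biomass == 0, axis=-1)
        dom = dom.astype(int)
        dom[empty] = -1
        return dom

    @property
    def n_unconverged(self) -> int:
        return int(np.size(self.converged) - np.count_nonzero(self.converged))

    def relative_biomass(self) -> np.ndarray:
        total = self.biomass.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(total > 0, self.biomass / total, 0.0)
        return rel

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (cell, type)."""
        dom = self.dominant
        rows = []
        for i, no2 in enumerate(self.no2):
            for j, oc in enumerate(self.oc):
                for k, o2 in enumerate(self.o2):
                    for m, name in enumerate(self.names):
                        b = self.biomass[i, j, k, m]
                        rows.append(
                            {
                                "no2_M": no2,
                                "oc_M": oc,
                                "o2_M": o2,
                                "type": name,
                                "biomass_M": b,
                                "log10_biomass": (
                                    np.log10(b) if b > 0 else LOG10_ZERO
                                ),
                                "dominant": dom[i, j, k] == m,
                                "converged": bool(self.converged[i, j, k]),
                            }
                        )
        return pd.DataFrame(rows)


def sweep(
    typeset: FunctionalTypeSet,
    spec: GradientSpec = GradientSpec(),
    config: SimulationConfig = DEFAULT_CONFIG,
    co2: float = 1e-5,
) -> NicheMap:
    """Run one steady-state simulation per grid cell.

    Every cell receives the full type set with equal seeding; the map is
    complete (no missing cells) and cells are mutually independent.
    """
    no2_axis = spec.axis("no2")
    oc_axis = spec.axis("oc")
    o2_axis = spec.axis("o2")
    n = spec.points_per_axis
    n_types = typeset.n_types
    biomass = np.zeros((n, n, n, n_types))
    flux = np.zeros((n, n, n))
    converged = np.zeros((n, n, n), dtype=bool)
    for i, no2 in enumerate(no2_axis):
        for j, oc in enumerate(oc_axis):
            for k, o2 in enumerate(o2_axis):
                env = EnvironmentState(no2=no2, oc=oc, o2=o2, co2=co2)
                result = run_to_steady_state(typeset, env, config=config)
                biomass[i, j, k] = result.biomass
                flux[i, j, k] = result.fluxes.total_no2_oxidation
                converged[i, j, k] = result.converged
    return NicheMap(
        no2=no2_axis,
        oc=oc_axis,
        o2=o2_axis,
        names=typeset.names,
        biomass=biomass,
        total_no2_flux=flux,
        converged=converged,
    )


def save_heatmaps(niche_map: NicheMap, outdir, o2_index: int = 0) -> list:
    """Write one log10-biomass heatmap PNG per type (NO2- x OC plane at
    one O2 level).  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    log_b = niche_map.log10_biomass
    for m, name in enumerate(niche_map.names):
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        plane = log_b[:, :, o2_index, m].T  # (oc, no2)
        img = ax.pcolormesh(
            niche_map.no2, niche_map.oc, plane, shading="nearest"
        )
        ax.set_xscale("log")
        ax.set_xlabel("NO2- (M)")
        ax.set_ylabel("OC (M)")
        ax.set_title(f"{name} (log10 biomass, O2={niche_map.o2[o2_index]:.1e} M)")
        fig.colorbar(img, ax=ax)
        path = outdir / f"niche_{name}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written


def classify_dominance(niche_map: NicheMap) -> np.ndarray:
    """Per-cell dominant-type labels (``"none"`` where all types are
    extinct)."""
    dom = niche_map.dominant
    labels = np.empty(dom.shape, dtype=object)
    for idx in np.ndindex(dom.shape):
        labels[idx] = (
            "none" if dom[idx] < 0 else niche_map.names[dom[idx]]
        )
    return labels
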