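"""Packaged observational tables from the Jasper Ridge field study.

Two small CSV fixtures ship with the package: factorial main-effect
sizes with split-plot ANOVA p-values for potential nitrite oxidation
(PNO) and NOB abundances, and the per-treatment percentages of
*Nitrobacter*-like clone-library sequences in the three main *nxrA*
clusters.  These are observations, not model outputs; they serve as the
comparison targets of the scenario pipeline and are protected by a
checksum manifest so silent edits raise rather than propagate.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "EffectSizeRecord",
    "ClusterCompositionRecord",
    "FixtureIntegrityError",
    "load_table1",
    "load_table2",
    "effect_size",
    "cluster_percent",
]

FIXTURE_DIR = Path(__file__).parent / "data" / "fixtures"
MANIFEST_PATH = FIXTURE_DIR / "MANIFEST.json"


class FixtureIntegrityError(RuntimeError):
    """A fixture file does not match its manifest checksum."""


@dataclass(frozen=True)
class EffectSizeRecord:
    """One main effect or interaction from the factorial ANOVA."""

    year: int
    response: str
    factor: str
    percent_effect: Optional[float]
    p_value: float

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")
        main_effect = ":" not in self.factor
        if main_effect and (
            self.percent_effect is None or not math.isfinite(self.percent_effect)
        ):
            raise ValueError(
                f"main effect {self.factor} ({self.year}, {self.response}) "
                "requires a finite percent_effect"
            )


@dataclass(frozen=True)
class ClusterCompositionRecord:
    """Percentage of *Nitrobacter*-like sequences in one cluster."""

    treatment: str
    cluster: str
    percent: float
    se: float
    group: str

    def __post_init__(self) -> None:
        if not 0 <= self.percent <= 100:
            raise ValueError(f"percent must lie in [0, 100], got {self.percent}")
        if self.se < 0:
            raise ValueError(f"se must be >= 0, got {self.se}")


def _verify_checksum(path: Path) -> None:
    manifest = json.loads(MANIFEST_PATH.read_text())
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    expected = manifest.get(path.name)
    if expected is None:
        raise FixtureIntegrityError(f"{path.name} not listed in MANIFEST.json")
    if digest != expected:
        raise FixtureIntegrityError(
            f"checksum mismatch for {path.name}: fixture was modified"
        )


def _read_fixture(name: str) -> pd.DataFrame:
    path = FIXTURE_DIR / name
    if not path.exists():
        raise FileNotFoundError(path)
    _verify_checksum(path)
    return pd.read_csv(path, comment="#")


def load_table1() -> list[EffectSizeRecord]:
    """Main-effect sizes and ANOVA p-values (both sampling years)."""
    df = _read_fixture("effect_sizes.csv")
    return [
        EffectSizeRecord(
            year=int(row.year),
            response=row.response,
            factor=row.factor,
            percent_effect=(
                None if pd.isna(row.percent_effect) else float(row.percent_effect)
            ),
            p_value=float(row.p_value),
        )
        for row in df.itertuples()
    ]


def load_table2() -> list[ClusterCompositionRecord]:
    """Per-treatment *nxrA* cluster percentages (8 treatments × 3 clusters)."""
    df = _read_fixture("cluster_composition.csv")
    return [
        ClusterCompositionRecord(
            treatment=row.treatment,
            cluster=row.cluster,
            percent=float(row.percent),
            se=float(row.se),
            group=str(row.group),
        )
        for row in df.itertuples()
    ]


def effect_size(year: int, response: str, factor: str) -> EffectSizeRecord:
    """Look up one record of the effect-size table."""
    for rec in load_table1():
        if (rec.year, rec.response, rec.factor) == (year, response, factor):
            return rec
    raise KeyError((year, response, factor))


def cluster_percent(treatment: str, cluster: str) -> ClusterCompositionRecord:
    """Look up one record of the cluster-composition table."""
    for rec in load_table2():
        if (rec.treatment, rec.cluster) == (treatment, cluster):
            return rec
    raise KeyError((treatment, cluster))
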