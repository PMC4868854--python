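"""Functional-trait profiles of soil nitrite-oxidizing bacteria (NOB).

The simulator distinguishes a small number of NOB functional types, each
described by a :class:`TraitProfile`: kinetic constants of nitrite (and,
for mixotrophs, organic-carbon) oxidation, carbon-assimilation kinetics,
growth and mortality rates, and growth yield.  Two traits of the
mixotrophic *Nitrobacter* type are *flexible*, i.e. functions of the
ambient environment rather than constants: the maximum specific growth
rate rises with organic-carbon (OC) concentration, and the oxygen
half-saturation constant rises with O2 supply.  Flexible traits are
represented as anchor points and evaluated by piecewise-linear
interpolation with constant extrapolation beyond the outermost anchors.

Units convention (used consistently across the package):

* concentrations passed to evaluators are molar (M);
* half-saturation constants are stored in µM;
* maximal oxidation/assimilation rates in µM (M biomass)^-1 s^-1;
* specific growth and mortality rates in s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "STRATEGIES",
    "TraitProfile",
    "FunctionalTypeSet",
    "TraitValidationError",
    "TraitConfigError",
    "load_trait_config",
    "save_trait_config",
    "default_type_set",
    "evaluate_mu_max",
    "evaluate_k_m_o2",
    "average_traits",
    "build_type_set",
]

STRATEGIES = (
    "K_chemolithotroph",
    "r_chemolithotroph",
    "r_mixotroph",
    "K_mixotroph",
    "average",
)

#: Names of the three reference functional types.
REFERENCE_NAMES = ("Nitrospira", "Nitrobacter_chemolitho", "Nitrobacter_mixo")


class TraitValidationError(ValueError):
    """A trait profile violates one of its invariants."""


class TraitConfigError(ValueError):
    """A trait configuration file is malformed."""


@dataclass(frozen=True)
class TraitProfile:
    """Kinetic and growth traits of one NOB functional type.

    Parameters
    ----------
    name
        Unique identifier of the type.
    strategy
        One of :data:`STRATEGIES`.
    v_max_no2
        Maximal NO2- oxidation rate, µM (M biomass)^-1 s^-1.
    k_m_no2
        Half-saturation constant for NO2-, µM.
    k_m_o2
        Half-saturation constant for O2, µM (base value; superseded by
        ``flexible_k_m_o2`` when anchors are present).
    v_max_oc
        Maximal OC oxidation rate, µM (M biomass)^-1 s^-1; 0 for
        non-mixotrophs.
    k_m_oc
        Half-saturation constant for OC oxidation, µM.
    v_max_c
        Cap on the C-assimilation rate, µM (M biomass)^-1 s^-1.  The
        realized maximal assimilation rate is energy-limited
        (growth_yield × oxidation rate) and this cap rarely binds.
    k_m_c
        Half-saturation constant for C assimilation, µM.
    mu_max
        Maximum specific growth rate, s^-1 (base value; superseded by
        ``flexible_mu_max`` when anchors are present).
    growth_yield
        mol biomass-C fixed per mol substrate oxidized, in (0, 1].
    mortality
        First-order mortality rate, s^-1; > 0.
    flexible_mu_max, flexible_k_m_o2
        Optional anchor pairs ``(concentration_M, value)`` with strictly
        increasing abscissae.
    """

    name: str
    strategy: str
    v_max_no2: float
    k_m_no2: float
    k_m_o2: float
    v_max_oc: float
    k_m_oc: float
    v_max_c: float
    k_m_c: float
    mu_max: float
    growth_yield: float
    mortality: float
    flexible_mu_max: tuple[tuple[float, float], ...] = ()
    flexible_k_m_o2: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "flexible_mu_max", _as_anchor_tuple(self.flexible_mu_max)
        )
        object.__setattr__(
            self, "flexible_k_m_o2", _as_anchor_tuple(self.flexible_k_m_o2)
        )
        self._validate()

    def _validate(self) -> None:
        if self.strategy not in STRATEGIES:
            raise TraitValidationError(
                f"{self.name}: unknown strategy {self.strategy!r}"
            )
        for fname in (
            "v_max_no2",
            "k_m_no2",
            "k_m_o2",
            "v_max_oc",
            "k_m_oc",
            "v_max_c",
            "k_m_c",
            "mu_max",
        ):
            value = getattr(self, fname)
            if not math.isfinite(value) or value < 0:
                raise TraitValidationError(
                    f"{self.name}: field {fname} must be finite and >= 0, "
                    f"got {value!r}"
                )
        if not 0 < self.growth_yield <= 1:
            raise TraitValidationError(
                f"{self.name}: field growth_yield must lie in (0, 1], "
                f"got {self.growth_yield!r}"
            )
        if not self.mortality > 0:
            raise TraitValidationError(
                f"{self.name}: field mortality must be > 0, "
                f"got {self.mortality!r}"
            )
        for fname in ("flexible_mu_max", "flexible_k_m_o2"):
            anchors = getattr(self, fname)
            xs = [a for a, _ in anchors]
            ys = [b for _, b in anchors]
            if any(x < 0 for x in xs) or any(y < 0 for y in ys):
                raise TraitValidationError(
                    f"{self.name}: field {fname} anchors must be >= 0"
                )
            if any(b <= a for a, b in zip(xs, xs[1:])):
                raise TraitValidationError(
                    f"{self.name}: field {fname} anchor abscissae must be "
                    "strictly increasing"
                )
        if not self.is_mixotroph and (
            self.v_max_oc != 0 or self.flexible_mu_max or self.flexible_k_m_o2
        ):
            raise TraitValidationError(
                f"{self.name}: non-mixotroph profiles require v_max_oc = 0 "
                "and no flexible traits"
            )

    @property
    def is_mixotroph(self) -> bool:
        return self.strategy in ("r_mixotroph", "K_mixotroph", "average")

    def mu_max_at(self, oc: float) -> float:
        """Maximum specific growth rate (s^-1) at OC concentration ``oc`` (M)."""
        return evaluate_mu_max(self, oc)

    def k_m_o2_at(self, o2: float) -> float:
        """O2 half-saturation (µM) at O2 concentration ``o2`` (M)."""
        return evaluate_k_m_o2(self, o2)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "strategy": self.strategy,
            "v_max_no2": self.v_max_no2,
            "k_m_no2": self.k_m_no2,
            "k_m_o2": self.k_m_o2,
            "v_max_oc": self.v_max_oc,
            "k_m_oc": self.k_m_oc,
            "v_max_c": self.v_max_c,
            "k_m_c": self.k_m_c,
            "mu_max": self.mu_max,
            "growth_yield": self.growth_yield,
            "mortality": self.mortality,
        }
        if self.flexible_mu_max:
            d["flexible_mu_max"] = [list(a) for a in self.flexible_mu_max]
        if self.flexible_k_m_o2:
            d["flexible_k_m_o2"] = [list(a) for a in self.flexible_k_m_o2]
        return d


def _as_anchor_tuple(anchors) -> tuple[tuple[float, float], ...]:
    return tuple((float(x), float(y)) for x, y in anchors)


@dataclass(frozen=True)
class FunctionalTypeSet:
    """Ordered collection of trait profiles used in one model run."""

    profiles: tuple[TraitProfile, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", tuple(self.profiles))
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise TraitValidationError(f"duplicate profile names: {names}")
        if not 1 <= len(names) <= 4:
            raise TraitValidationError(
                f"a type set holds 1-4 profiles, got {len(names)}"
            )

    @property
    def n_types(self) -> int:
        return len(self.profiles)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def __getitem__(self, key) -> TraitProfile:
        if isinstance(key, str):
            for p in self.profiles:
                if p.name == key:
                    return p
            raise KeyError(key)
        return self.profiles[key]


_REQUIRED_KEYS = {
    "name",
    "strategy",
    "v_max_no2",
    "k_m_no2",
    "k_m_o2",
    "mu_max",
    "growth_yield",
}

#: Defaults for optional config keys.
_OPTIONAL_DEFAULTS = {
    "v_max_oc": 0.0,
    "k_m_oc": 500.0,
    "v_max_c": None,  # filled from yield * (v_max_no2 + v_max_oc)
    "k_m_c": 5.0,
    "mortality": 3e-7,
    "flexible_mu_max": (),
    "flexible_k_m_o2": (),
}


def _profile_from_mapping(raw: dict) -> TraitProfile:
    if not isinstance(raw, dict):
        raise TraitConfigError(f"profile entry is not a mapping: {raw!r}")
    unknown = set(raw) - _REQUIRED_KEYS - set(_OPTIONAL_DEFAULTS)
    if unknown:
        raise TraitConfigError(
            f"unknown key(s) {sorted(unknown)} in profile "
            f"{raw.get('name', '<unnamed>')!r}"
        )
    missing = _REQUIRED_KEYS - set(raw)
    if missing:
        raise TraitConfigError(
            f"missing key(s) {sorted(missing)} in profile "
            f"{raw.get('name', '<unnamed>')!r}"
        )
    data = dict(raw)
    for key, default in _OPTIONAL_DEFAULTS.items():
        data.setdefault(key, default)
    if data["v_max_c"] is None:
        data["v_max_c"] = data["growth_yield"] * (
            data["v_max_no2"] + data["v_max_oc"]
        )
    try:
        return TraitProfile(**data)
    except TypeError as exc:  # pragma: no cover - defensive
        raise TraitConfigError(str(exc)) from exc


def load_trait_config(path: str | Path) -> FunctionalTypeSet:
    """Load a validated :class:`FunctionalTypeSet` from a YAML/JSON file.

    The document holds a ``profiles`` list (keys exactly the
    :class:`TraitProfile` field names; concentrations in M, rates in s^-1,
    half-saturations in µM) and an optional ``provenance`` string.
    Missing optional fields are filled with documented defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise TraitConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict) or "profiles" not in doc:
        raise TraitConfigError(f"{path}: expected a mapping with key 'profiles'")
    profiles = tuple(_profile_from_mapping(p) for p in doc["profiles"])
    return FunctionalTypeSet(
        profiles=profiles, provenance=str(doc.get("provenance", path.name))
    )


def save_trait_config(typeset: FunctionalTypeSet, path: str | Path) -> None:
    """Write a type set back to YAML; round-trips through
    :func:`load_trait_config`."""
    doc = {
        "units": {
            "concentrations": "M",
            "rates": "s^-1",
            "half_saturations": "uM",
            "v_max": "uM (M biomass)^-1 s^-1",
        },
        "provenance": typeset.provenance,
        "profiles": [p.to_dict() for p in typeset.profiles],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_type_set() -> FunctionalTypeSet:
    """The packaged three-type reference configuration."""
    here = Path(__file__).parent / "data" / "default_traits.yaml"
    return load_trait_config(here)


def _interp_anchors(
    anchors: Sequence[tuple[float, float]], x: float
) -> float:
    xs = np.array([a for a, _ in anchors])
    ys = np.array([b for _, b in anchors])
    # np.interp clamps outside the anchor range (constant extrapolation).
    return float(np.interp(x, xs, ys))


def evaluate_mu_max(profile: TraitProfile, oc: float) -> float:
    """Maximum specific growth rate (s^-1) at OC concentration ``oc`` (M).

    Profiles without flexible anchors return their constant ``mu_max``;
    flexible profiles interpolate piecewise-linearly between anchors with
    constant extrapolation.  Nondecreasing in ``oc``.
    """
    if oc < 0:
        raise ValueError(f"oc must be >= 0, got {oc}")
    if not profile.flexible_mu_max:
        return profile.mu_max
    return _interp_anchors(profile.flexible_mu_max, oc)


def evaluate_k_m_o2(profile: TraitProfile, o2: float) -> float:
    """O2 half-saturation constant (µM) at O2 concentration ``o2`` (M)."""
    if o2 < 0:
        raise ValueError(f"o2 must be >= 0, got {o2}")
    if not profile.flexible_k_m_o2:
        return profile.k_m_o2
    return _interp_anchors(profile.flexible_k_m_o2, o2)


def average_traits(
    profiles: Iterable[TraitProfile], name: str, strategy: str = "average"
) -> TraitProfile:
    """Arithmetic trait mean of two or more profiles.

    Scalar traits are averaged directly.  Flexible traits are averaged
    anchor-wise after evaluating every input profile on the union of
    anchor abscissae, so constant profiles contribute their constant at
    each abscissa.  Averaging n copies of one profile reproduces it.
    """
    profiles = tuple(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to average")

    def _mean(values) -> float:
        # exact idempotence: n copies of one profile average to itself
        if all(v == values[0] for v in values):
            return float(values[0])
        return float(np.mean(values))

    def mean(attr: str) -> float:
        return _mean([getattr(p, attr) for p in profiles])

    def merged_anchors(attr: str, evaluate) -> tuple[tuple[float, float], ...]:
        xs = sorted({x for p in profiles for x, _ in getattr(p, attr)})
        if not xs:
            return ()
        return tuple((x, _mean([evaluate(p, x) for p in profiles])) for x in xs)

    return TraitProfile(
        name=name,
        strategy=strategy,
        v_max_no2=mean("v_max_no2"),
        k_m_no2=mean("k_m_no2"),
        k_m_o2=mean("k_m_o2"),
        v_max_oc=mean("v_max_oc"),
        k_m_oc=mean("k_m_oc"),
        v_max_c=mean("v_max_c"),
        k_m_c=mean("k_m_c"),
        mu_max=mean("mu_max"),
        growth_yield=mean("growth_yield"),
        mortality=mean("mortality"),
        flexible_mu_max=merged_anchors("flexible_mu_max", evaluate_mu_max),
        flexible_k_m_o2=merged_anchors("flexible_k_m_o2", evaluate_k_m_o2),
    )


def build_type_set(n_types: int) -> FunctionalTypeSet:
    """Build the reference set or one of its ablations.

    * 3 — the reference set (Nitrospira, chemolithotrophic *Nitrobacter*,
      mixotrophic *Nitrobacter*);
    * 2 — Nitrospira plus an 'average' *Nitrobacter* (trait means of the
      two *Nitrobacter* types, retaining a weakly flexible OC response);
    * 1 — a single 'average' NOB (trait means of all three types);
    * 4 — the reference set plus a near-neutral mixotrophic *Nitrospira*.
    """
    ref = default_type_set()
    if n_types == 3:
        return ref
    if n_types == 2:
        nitrobacter = average_traits(
            [ref["Nitrobacter_chemolitho"], ref["Nitrobacter_mixo"]],
            name="Nitrobacter_avg",
        )
        return FunctionalTypeSet(
            profiles=(ref["Nitrospira"], nitrobacter),
            provenance="ablation: 2 types (genus level)",
        )
    if n_types == 1:
        avg = average_traits(ref.profiles, name="NOB_avg")
        return FunctionalTypeSet(
            profiles=(avg,), provenance="ablation: 1 'average' NOB type"
        )
    if n_types == 4:
        spira = ref["Nitrospira"]
        # Near-neutral mixotrophic Nitrospira: base Nitrospira kinetics with
        # a weak flexible mu_max (<= 1.5x base at high OC) and a modest OC
        # oxidation capacity.
        spira_mixo = replace(
            spira,
            name="Nitrospira_mixo",
            strategy="K_mixotroph",
            v_max_oc=1000.0,
            flexible_mu_max=(
                (0.0, spira.mu_max),
                (5e-3, 1.2 * spira.mu_max),
            ),
        )
        return FunctionalTypeSet(
            profiles=ref.profiles + (spira_mixo,),
            provenance="ablation: 4 types (split Nitrospira)",
        )
    raise ValueError(f"n_types must be in {{1, 2, 3, 4}}, got {n_types}")
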