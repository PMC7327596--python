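"""Packaged parameter presets, scenario construction and perturbation.

The catalog of default values ships with the package as a versioned YAML
file (``data/table1.yaml``): per pathway, a base estimate with plausible
lower/upper bounds for access rate, completion rate, consultation duration,
supply-related demand and (e-consultation only) the telephone follow-up
split, plus the fixed conventional mix and shared phone-cascade parameters.

For the telephone-first pathway the pathway's completion rate and call
duration *are* the shared telephone parameters — there is only one kind of
telephone consultation in the model — so :func:`with_param` moves the
phone-cascade values in lockstep when either is changed on a telephone
scenario.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

from .model import (
    ConventionalMix,
    PathwayKind,
    PathwayParams,
    PhoneCascadeParams,
    Scenario,
    ValidationError,
)

__all__ = [
    "ParameterBound",
    "PresetCatalog",
    "load_catalog",
    "variables_for",
    "base_case",
    "bound_case",
    "with_param",
    "random_scenario",
    "preset_names",
    "preset",
]

#: Scenario parameters that can be varied, in catalog order.
ALL_VARIABLES = (
    "access_rate",
    "completion_rate",
    "phone_followup_fraction",
    "digital_duration",
    "demand_fraction",
)

_PERCENT_VARIABLES = frozenset(
    {"access_rate", "completion_rate", "phone_followup_fraction", "demand_fraction"}
)


@dataclass(frozen=True)
class ParameterBound:
    """Base estimate and plausible bounds for one pathway variable."""

    variable: str
    base: float
    lower: float
    upper: float
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.lower <= self.base <= self.upper:
            raise ValidationError(
                f"{self.variable}: bounds must satisfy lower <= base <= upper, "
                f"got {self.lower} <= {self.base} <= {self.upper}"
            )


@dataclass(frozen=True)
class PresetCatalog:
    """The full default-value catalog: bounds per pathway plus fixed baseline."""

    version: int
    mix: ConventionalMix
    phone_cascade: PhoneCascadeParams
    bounds: dict[PathwayKind, dict[str, ParameterBound]]


def _from_units(value: float, units: str) -> float:
    return float(value) / 100.0 if units == "percent" else float(value)


@functools.cache
def load_catalog() -> PresetCatalog:
    """Load the packaged default-value catalog (cached)."""
    text = (resources.files("gpworkload") / "data" / "table1.yaml").read_text()
    raw = yaml.safe_load(text)
    mix = ConventionalMix(
        f2f_fraction=raw["conventional"]["f2f_pct"] / 100.0,
        phone_fraction=raw["conventional"]["phone_pct"] / 100.0,
        f2f_duration=raw["conventional"]["f2f_minutes"],
        phone_duration=raw["conventional"]["phone_minutes"],
    )
    cascade = PhoneCascadeParams(
        phone_completion=raw["phone_cascade"]["completion_pct"] / 100.0,
        phone_duration=raw["phone_cascade"]["minutes"],
    )
    bounds: dict[PathwayKind, dict[str, ParameterBound]] = {}
    for kind_name, entries in raw["pathways"].items():
        kind = PathwayKind(kind_name)
        bounds[kind] = {}
        for var, cell in entries.items():
            units = cell["units"]
            bounds[kind][var] = ParameterBound(
                variable=var,
                base=_from_units(cell["base"], units),
                lower=_from_units(cell["lower"], units),
                upper=_from_units(cell["upper"], units),
                source_note=cell.get("source_note", ""),
            )
    return PresetCatalog(
        version=int(raw["version"]), mix=mix, phone_cascade=cascade, bounds=bounds
    )


def variables_for(kind: PathwayKind | str) -> tuple[str, ...]:
    """Variable names defined for a pathway (no phone follow-up split
    outside the e-consultation pathway)."""
    kind = PathwayKind(kind)
    return tuple(v for v in ALL_VARIABLES if v in load_catalog().bounds[kind])


def base_case(kind: PathwayKind | str) -> Scenario:
    """The base-case scenario for a pathway, from the packaged catalog."""
    kind = PathwayKind(kind)
    cat = load_catalog()
    b = cat.bounds[kind]
    pathway = PathwayParams(
        kind=kind,
        access_rate=b["access_rate"].base,
        completion_rate=b["completion_rate"].base,
        digital_duration=b["digital_duration"].base,
        demand_fraction=b["demand_fraction"].base,
        phone_followup_fraction=(
            b["phone_followup_fraction"].base if kind is PathwayKind.ECONSULT else 0.0
        ),
    )
    cascade = cat.phone_cascade
    if kind is PathwayKind.TELEPHONE:
        cascade = PhoneCascadeParams(
            phone_completion=pathway.completion_rate,
            phone_duration=pathway.digital_duration,
        )
    return Scenario(
        mix=cat.mix, pathway=pathway, phone_cascade=cascade, label=f"{kind.value}-base"
    )


def with_param(scenario: Scenario, variable: str, value: float) -> Scenario:
    """A copy of ``scenario`` with one pathway variable replaced.

    On a telephone-first scenario, ``completion_rate`` and
    ``digital_duration`` also update the shared phone cascade, since the
    model has a single set of telephone parameters.
    """
    if variable not in ALL_VARIABLES:
        raise ValidationError(
            f"unknown variable {variable!r}; expected one of {ALL_VARIABLES}"
        )
    kind = scenario.pathway.kind
    if variable == "phone_followup_fraction" and kind is not PathwayKind.ECONSULT:
        raise ValidationError(
            f"phone_followup_fraction is not defined for the {kind.value} pathway"
        )
    pathway = replace(scenario.pathway, **{variable: value})
    cascade = scenario.phone_cascade
    if kind is PathwayKind.TELEPHONE:
        if variable == "completion_rate":
            cascade = replace(cascade, phone_completion=value)
        elif variable == "digital_duration":
            cascade = replace(cascade, phone_duration=value)
    return replace(scenario, pathway=pathway, phone_cascade=cascade)


def bound_case(
    kind: PathwayKind | str, variable: str, side: str
) -> Scenario:
    """Base case with one variable set to its catalog ``lower`` or ``upper`` bound."""
    kind = PathwayKind(kind)
    if side not in ("lower", "upper"):
        raise ValidationError(f"side must be 'lower' or 'upper', got {side!r}")
    bounds = load_catalog().bounds[kind]
    if variable not in bounds:
        raise ValidationError(
            f"variable {variable!r} is not defined for the {kind.value} pathway; "
            f"expected one of {tuple(bounds)}"
        )
    value = getattr(bounds[variable], side)
    scenario = with_param(base_case(kind), variable, value)
    return replace(scenario, label=f"{kind.value}-{_short_name(variable)}-{side}")


def random_scenario(
    seed: int | np.random.Generator, kind: PathwayKind | str | None = None
) -> Scenario:
    """A scenario drawn uniformly within the catalog lower-upper ranges.

    The conventional mix stays fixed; the pathway kind is drawn uniformly
    unless given.  Every draw satisfies ``demand_fraction * access_rate < 1``
    by construction (demand tops out at 0.30), so the workload model is
    always evaluable.  Deterministic for a fixed integer seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kind is None:
        kind = PathwayKind(rng.choice([k.value for k in PathwayKind]))
    else:
        kind = PathwayKind(kind)
    scenario = base_case(kind)
    bounds = load_catalog().bounds[kind]
    for var in variables_for(kind):
        b = bounds[var]
        scenario = with_param(scenario, var, rng.uniform(b.lower, b.upper))
    return replace(scenario, label=f"{kind.value}-random")


_SHORT_NAMES = {
    "access_rate": "access",
    "completion_rate": "completion",
    "phone_followup_fraction": "phone-followup",
    "digital_duration": "duration",
    "demand_fraction": "demand",
}


def _short_name(variable: str) -> str:
    return _SHORT_NAMES[variable]


@functools.cache
def _preset_map() -> dict[str, tuple]:
    out: dict[str, tuple] = {}
    for kind in PathwayKind:
        out[f"{kind.value}-base"] = (kind, None, None)
        for var in variables_for(kind):
            for side in ("lower", "upper"):
                out[f"{kind.value}-{_short_name(var)}-{side}"] = (kind, var, side)
    return out


def preset_names() -> tuple[str, ...]:
    """Names of all packaged presets: ``<kind>-base`` and
    ``<kind>-<variable>-lower/upper`` for every catalog cell."""
    return tuple(_preset_map())


def preset(name: str) -> Scenario:
    """Look up a packaged preset scenario by name."""
    try:
        kind, var, side = _preset_map()[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
    return base_case(kind) if var is None else bound_case(kind, var, side)
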