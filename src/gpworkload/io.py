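"""Declarative scenario configs and result serialization.

Configs are YAML (JSON, being a YAML subset, also parses) with three
sections.  Rate fields end in ``_pct`` and are percentages, mirroring how
the default-value catalog prints them; durations are minutes.

.. code-block:: yaml

    label: my-scenario          # optional
    conventional:               # optional, defaults to the catalog baseline
      f2f_pct: 86
      phone_pct: 14
      f2f_minutes: 9
      phone_minutes: 5
    phone_cascade:              # optional; for a telephone-first pathway it
      completion_pct: 52        # defaults to the pathway's own values
      minutes: 5
    pathway:
      kind: telephone           # econsult | telephone | video (required)
      access_pct: 93
      completion_pct: 52
      phone_followup_pct: 0     # econsult only
      minutes: 5
      new_demand_pct: 0

Missing optional fields default to the base case for the declared kind.
Validation reports *every* invalid field, not just the first.
"""

from __future__ import annotations

import io as _io
import json
import math

import yaml

from .model import (
    ConventionalMix,
    PathwayKind,
    PathwayParams,
    PhoneCascadeParams,
    Scenario,
    ValidationError,
    WorkloadResult,
)
from .scenarios import base_case

__all__ = [
    "load_scenario",
    "load_scenario_file",
    "serialize_scenario",
    "scenario_to_config",
    "result_record",
    "result_json",
]


def _pct(fraction: float) -> float:
    # round-trip safe: 10 decimals of a percentage is far below float noise
    return round(100.0 * fraction, 10)


def scenario_to_config(scenario: Scenario) -> dict:
    """The config-dict form of a scenario (percent units, deterministic order)."""
    cfg: dict = {}
    if scenario.label:
        cfg["label"] = scenario.label
    cfg["conventional"] = {
        "f2f_pct": _pct(scenario.mix.f2f_fraction),
        "phone_pct": _pct(scenario.mix.phone_fraction),
        "f2f_minutes": scenario.mix.f2f_duration,
        "phone_minutes": scenario.mix.phone_duration,
    }
    cfg["phone_cascade"] = {
        "completion_pct": _pct(scenario.phone_cascade.phone_completion),
        "minutes": scenario.phone_cascade.phone_duration,
    }
    pathway = {
        "kind": scenario.pathway.kind.value,
        "access_pct": _pct(scenario.pathway.access_rate),
        "completion_pct": _pct(scenario.pathway.completion_rate),
        "minutes": scenario.pathway.digital_duration,
        "new_demand_pct": _pct(scenario.pathway.demand_fraction),
    }
    if scenario.pathway.kind is PathwayKind.ECONSULT:
        pathway["phone_followup_pct"] = _pct(scenario.pathway.phone_followup_fraction)
    cfg["pathway"] = pathway
    return cfg


def serialize_scenario(scenario: Scenario) -> str:
    """Serialize a scenario to YAML config text (round-trips through
    :func:`load_scenario`)."""
    return yaml.safe_dump(scenario_to_config(scenario), sort_keys=False)


class _Collector:
    """Accumulates field-level validation messages."""

    def __init__(self) -> None:
        self.errors: list[str] = []

    def number(self, section: dict, section_name: str, key: str, default, *,
               lo=None, hi=None, lo_open=False, hi_open=False):
        value = section.get(key, default)
        if value is None:
            self.errors.append(f"{section_name}.{key}: required field is missing")
            return None
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            self.errors.append(f"{section_name}.{key}: expected a number, got {value!r}")
            return None
        value = float(value)
        if not math.isfinite(value):
            self.errors.append(f"{section_name}.{key}: must be finite, got {value!r}")
            return None
        ok_lo = lo is None or (value > lo if lo_open else value >= lo)
        ok_hi = hi is None or (value < hi if hi_open else value <= hi)
        if not (ok_lo and ok_hi):
            lo_b = "(" if lo_open else "["
            hi_b = ")" if hi_open else "]"
            self.errors.append(
                f"{section_name}.{key}: {value} outside allowed range "
                f"{lo_b}{lo}, {hi}{hi_b}"
            )
            return None
        return value


def load_scenario(text: str) -> Scenario:
    """Parse and validate a scenario config from YAML/JSON text."""
    try:
        raw = yaml.safe_load(_io.StringIO(text))
    except yaml.YAMLError as exc:
        raise ValidationError(f"config does not parse as YAML/JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValidationError("config must be a mapping with a 'pathway' section")

    pathway_cfg = raw.get("pathway")
    if not isinstance(pathway_cfg, dict) or "kind" not in pathway_cfg:
        raise ValidationError("pathway.kind: required field is missing")
    try:
        kind = PathwayKind(pathway_cfg["kind"])
    except ValueError:
        raise ValidationError(
            f"pathway.kind: unknown kind {pathway_cfg['kind']!r}; expected one of "
            f"{[k.value for k in PathwayKind]}"
        ) from None

    defaults = base_case(kind)
    c = _Collector()

    conv = raw.get("conventional") or {}
    f2f_pct = c.number(conv, "conventional", "f2f_pct",
                       _pct(defaults.mix.f2f_fraction), lo=0, hi=100)
    phone_pct = c.number(conv, "conventional", "phone_pct",
                         _pct(defaults.mix.phone_fraction), lo=0, hi=100)
    f2f_min = c.number(conv, "conventional", "f2f_minutes",
                       defaults.mix.f2f_duration, lo=0, lo_open=True)
    phone_min = c.number(conv, "conventional", "phone_minutes",
                         defaults.mix.phone_duration, lo=0, lo_open=True)

    access = c.number(pathway_cfg, "pathway", "access_pct",
                      _pct(defaults.pathway.access_rate), lo=0, hi=100)
    completion = c.number(pathway_cfg, "pathway", "completion_pct",
                          _pct(defaults.pathway.completion_rate), lo=0, hi=100)
    minutes = c.number(pathway_cfg, "pathway", "minutes",
                       defaults.pathway.digital_duration, lo=0, lo_open=True)
    demand = c.number(pathway_cfg, "pathway", "new_demand_pct",
                      _pct(defaults.pathway.demand_fraction),
                      lo=-100, hi=100, lo_open=True, hi_open=True)
    if kind is PathwayKind.ECONSULT:
        followup = c.number(pathway_cfg, "pathway", "phone_followup_pct",
                            _pct(defaults.pathway.phone_followup_fraction), lo=0, hi=100)
    else:
        followup = pathway_cfg.get("phone_followup_pct", 0)
        if followup not in (0, 0.0):
            c.errors.append(
                "pathway.phone_followup_pct: only defined for the econsult "
                f"pathway, not {kind.value!r}"
            )
        followup = 0.0

    cascade_cfg = raw.get("phone_cascade")
    if cascade_cfg is None and kind is PathwayKind.TELEPHONE:
        # single set of telephone parameters: cascade follows the pathway
        cascade_completion, cascade_minutes = completion, minutes
    else:
        cascade_cfg = cascade_cfg or {}
        cascade_completion = c.number(
            cascade_cfg, "phone_cascade", "completion_pct",
            _pct(defaults.phone_cascade.phone_completion), lo=0, hi=100)
        cascade_minutes = c.number(
            cascade_cfg, "phone_cascade", "minutes",
            defaults.phone_cascade.phone_duration, lo=0, lo_open=True)

    if c.errors:
        raise ValidationError("invalid scenario config:\n  " + "\n  ".join(c.errors))

    if access is not None and demand is not None:
        if (demand / 100.0) * (access / 100.0) >= 1.0:
            raise ValidationError(
                "pathway: demand_fraction * access_rate >= 1 (unbounded induced demand)"
            )

    return Scenario(
        mix=ConventionalMix(
            f2f_fraction=f2f_pct / 100.0,
            phone_fraction=phone_pct / 100.0,
            f2f_duration=f2f_min,
            phone_duration=phone_min,
        ),
        pathway=PathwayParams(
            kind=kind,
            access_rate=access / 100.0,
            completion_rate=completion / 100.0,
            digital_duration=minutes,
            demand_fraction=demand / 100.0,
            phone_followup_fraction=followup / 100.0 if kind is PathwayKind.ECONSULT else 0.0,
        ),
        phone_cascade=PhoneCascadeParams(
            phone_completion=cascade_completion / 100.0,
            phone_duration=cascade_minutes,
        ),
        label=str(raw.get("label", "")),
    )


def load_scenario_file(path) -> Scenario:
    with open(path, encoding="utf-8") as fh:
        return load_scenario(fh.read())


def result_record(scenario: Scenario, result: WorkloadResult) -> dict:
    """Flat, self-describing record: resolved parameters plus all result
    fields, in deterministic key order."""
    record: dict = {"label": scenario.label or scenario.pathway.kind.value}
    for section, fields in scenario_to_config(scenario).items():
        if section == "label":
            continue
        for key, value in fields.items():
            record[f"{section}.{key}"] = value
    record.update(result.to_dict())
    return record


def result_json(scenario: Scenario, result: WorkloadResult) -> str:
    """JSON text of :func:`result_record` (stable across runs)."""
    return json.dumps(result_record(scenario, result), indent=2)
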