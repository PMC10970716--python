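"""Domain data model and configuration I/O for exclusion-impact scenarios.

A :class:`Scenario` bundles everything the cascade needs: the national
population and the insured segments counted as covered lives, the formularies
whose exclusions are modelled, the indication (prevalence range plus any
eligibility multipliers), medication share groups, and the outcome models
(discontinuation range and an adverse-event rule) each medication points to.

Configurations are YAML (canonical) or JSON.  Fractions may be written either
as plain numbers (``0.485``) or as percent strings (``48.5%``); they are
stored internally as fractions.  Validation aggregates every problem it finds
into a single error carrying dotted field paths rather than stopping at the
first.
"""

from __future__ import annotations

import json

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .ranges import BoundedRange

__all__ = [
    "CoverageSegment",
    "PopulationModel",
    "Formulary",
    "Indication",
    "Medication",
    "ShareGroup",
    "FlatRate",
    "CoupledCompound",
    "OutcomeModel",
    "Scenario",
    "ScenarioValidationError",
    "SCENARIO_SCHEMA",
    "validate_scenario",
    "scenario_from_dict",
    "scenario_to_dict",
    "load_scenario",
    "save_scenario",
    "case_study_fixtures",
    "fixture_names",
    "load_fixture",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class CoverageSegment:
    """One insured slice of the population counted as covered lives."""

    name: str
    percent: float  # fraction of total population, in [0, 1]


@dataclass
class PopulationModel:
    total_population: float  # persons
    segments: list[CoverageSegment] = field(default_factory=list)


@dataclass
class Formulary:
    name: str
    market_share: float  # fraction of covered lives, in (0, 1]


@dataclass
class Indication:
    """Disease context: prevalence range among covered lives plus optional
    multiplicative eligibility factors (e.g. the fraction of migraine
    patients with enough attacks to qualify for preventive treatment).

    ``calibration_factor`` is an explicit, overridable multiplier applied to
    the pool; it defaults to 1 and carries a provenance note when it was
    fitted to published output rather than taken from an input source.
    """

    name: str
    prevalence: BoundedRange
    eligibility_factors: list[tuple[str, float]] = field(default_factory=list)
    calibration_factor: float = 1.0
    calibration_provenance: Optional[str] = None


@dataclass
class Medication:
    brand_name: str
    generic_name: str
    group_id: str
    outcome_model_id: str
    prescriptions: Optional[float] = None  # raw count, if given
    share: Optional[float] = None  # fraction of group, populated after normalization


@dataclass
class ShareGroup:
    """Medications competing within one class or subclass; their market
    shares are defined relative to this group and sum to one after
    normalization."""

    group_id: str
    medications: list[Medication] = field(default_factory=list)
    normalization: str = "within_group"


@dataclass
class FlatRate:
    """Adverse events as a flat fraction of everyone affected."""

    rate: BoundedRange


@dataclass
class CoupledCompound:
    """Adverse events compounded over the discontinue/switch split:
    ``e*d + s*(1-d)`` with the complement taken at the same scenario bound."""

    event_given_discontinuation: BoundedRange
    event_given_switch: BoundedRange


@dataclass
class OutcomeModel:
    id: str
    discontinuation: BoundedRange
    adverse_event_rule: Union[FlatRate, CoupledCompound]


@dataclass
class Scenario:
    name: str
    population: PopulationModel
    formularies: list[Formulary]
    indication: Indication
    share_groups: list[ShareGroup]
    outcome_models: list[OutcomeModel]
    output_unit: str = "thousands"
    notes: list[str] = field(default_factory=list)

    def outcome_model(self, model_id: str) -> OutcomeModel:
        for om in self.outcome_models:
            if om.id == model_id:
                return om
        raise KeyError(f"no outcome model with id {model_id!r}")

    def share_group(self, group_id: str) -> ShareGroup:
        for g in self.share_groups:
            if g.group_id == group_id:
                return g
        raise KeyError(f"no share group with id {group_id!r}")

    def formulary(self, name: str) -> Formulary:
        for f in self.formularies:
            if f.name == name:
                return f
        raise KeyError(f"no formulary named {name!r}")

    def medication(self, brand_name: str) -> Medication:
        for g in self.share_groups:
            for m in g.medications:
                if m.brand_name == brand_name:
                    return m
        raise KeyError(f"no medication named {brand_name!r}")


class ScenarioValidationError(ValueError):
    """Raised with the full list of validation problems (field paths)."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "invalid scenario:\n" + "\n".join(f"  - {e}" for e in self.errors)
        )


# ---------------------------------------------------------------------------
# Published schema (documentation of the accepted config shape)
# ---------------------------------------------------------------------------

_FRACTION = {
    "oneOf": [
        {"type": "number", "minimum": 0, "maximum": 1},
        {"type": "string", "pattern": r"^\s*\d+(\.\d+)?\s*%\s*$"},
    ]
}
_RANGE = {
    "type": "object",
    "required": ["low", "high"],
    "properties": {"low": _FRACTION, "high": _FRACTION},
}

SCENARIO_SCHEMA: dict[str, Any] = {
    "$schema": "https://json-schema.org/draft/2020-12/schema",
    "title": "Formulary exclusion impact scenario",
    "type": "object",
    "required": [
        "name",
        "population",
        "formularies",
        "indication",
        "share_groups",
        "outcome_models",
    ],
    "properties": {
        "name": {"type": "string"},
        "output_unit": {"const": "thousands"},
        "notes": {"type": "array", "items": {"type": "string"}},
        "population": {
            "type": "object",
            "required": ["total", "segments"],
            "properties": {
                "total": {"type": "number", "exclusiveMinimum": 0},
                "segments": {
                    "type": "array",
                    "items": {
                        "type": "object",
                        "required": ["name", "percent"],
                        "properties": {
                            "name": {"type": "string"},
                            "percent": _FRACTION,
                        },
                    },
                },
            },
        },
        "formularies": {
            "type": "array",
            "minItems": 1,
            "items": {
                "type": "object",
                "required": ["name", "market_share"],
                "properties": {
                    "name": {"type": "string"},
                    "market_share": _FRACTION,
                },
            },
        },
        "indication": {
            "type": "object",
            "required": ["name", "prevalence"],
            "properties": {
                "name": {"type": "string"},
                "prevalence": _RANGE,
                "eligibility_factors": {
                    "type": "array",
                    "items": {
                        "type": "object",
                        "required": ["label", "fraction"],
                        "properties": {
                            "label": {"type": "string"},
                            "fraction": _FRACTION,
                        },
                    },
                },
                "calibration_factor": _FRACTION,
                "calibration_provenance": {"type": "string"},
            },
        },
        "share_groups": {
            "type": "array",
            "minItems": 1,
            "items": {
                "type": "object",
                "required": ["group_id", "medications"],
                "properties": {
                    "group_id": {"type": "string"},
                    "normalization": {"const": "within_group"},
                    "medications": {
                        "type": "array",
                        "minItems": 1,
                        "items": {
                            "type": "object",
                            "required": ["brand_name", "outcome_model_id"],
                            "properties": {
                                "brand_name": {"type": "string"},
                                "generic_name": {"type": "string"},
                                "share": _FRACTION,
                                "prescriptions": {"type": "number", "minimum": 0},
                                "outcome_model_id": {"type": "string"},
                            },
                        },
                    },
                },
            },
        },
        "outcome_models": {
            "type": "array",
            "minItems": 1,
            "items": {
                "type": "object",
                "required": ["id", "discontinuation", "adverse_event_rule"],
                "properties": {
                    "id": {"type": "string"},
                    "discontinuation": _RANGE,
                    "adverse_event_rule": {
                        "type": "object",
                        "required": ["type"],
                        "properties": {
                            "type": {"enum": ["flat_rate", "coupled_compound"]},
                            "rate": _RANGE,
                            "event_given_discontinuation": _RANGE,
                            "event_given_switch": _RANGE,
                        },
                    },
                },
            },
        },
    },
}


# ---------------------------------------------------------------------------
# Parsing helpers (fractions, ranges) — errors are accumulated, not raised
# ---------------------------------------------------------------------------


class _Errors:
    def __init__(self) -> None:
        self.items: list[str] = []

    def add(self, path: str, message: str) -> None:
        self.items.append(f"{path}: {message}")

    def raise_if_any(self) -> None:
        if self.items:
            raise ScenarioValidationError(self.items)


def _as_number(value: Any, path: str, errors: _Errors, default: float = 0.0) -> float:
    """Parse a plain number or a percent string like '48.5%' into a float
    (percent strings are divided by 100)."""
    if isinstance(value, str):
        text = value.strip()
        if text.endswith("%"):
            try:
                return float(text[:-1].strip()) / 100.0
            except ValueError:
                errors.add(path, f"cannot parse percent string {value!r}")
                return default
        try:
            return float(text)
        except ValueError:
            errors.add(path, f"cannot parse number {value!r}")
            return default
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        errors.add(path, f"expected a number or percent string, got {value!r}")
        return default
    return float(value)


def _as_range(value: Any, path: str, errors: _Errors) -> BoundedRange:
    if isinstance(value, dict):
        low = _as_number(value.get("low"), f"{path}.low", errors)
        high = _as_number(value.get("high"), f"{path}.high", errors)
    elif isinstance(value, (list, tuple)) and len(value) == 2:
        low = _as_number(value[0], f"{path}[0]", errors)
        high = _as_number(value[1], f"{path}[1]", errors)
    else:
        low = high = _as_number(value, path, errors)
    try:
        return BoundedRange(low, high)
    except ValueError as exc:
        errors.add(path, str(exc))
        return BoundedRange(0.0, 0.0)


def _range_to_obj(r: BoundedRange) -> dict[str, float]:
    return {"low": r.low, "high": r.high}


# ---------------------------------------------------------------------------
# Dict <-> Scenario
# ---------------------------------------------------------------------------


def scenario_from_dict(data: Any) -> Scenario:
    """Build a Scenario from parsed YAML/JSON, aggregating every problem into
    one :class:`ScenarioValidationError` instead of failing on the first."""
    errors = _Errors()
    if not isinstance(data, dict):
        raise ScenarioValidationError(["document: expected a mapping at top level"])

    name = data.get("name")
    if not isinstance(name, str) or not name:
        errors.add("name", "required non-empty string")
        name = "<unnamed>"

    pop_data = data.get("population")
    segments: list[CoverageSegment] = []
    total = 0.0
    if not isinstance(pop_data, dict):
        errors.add("population", "required mapping")
    else:
        total = _as_number(pop_data.get("total"), "population.total", errors)
        for i, seg in enumerate(pop_data.get("segments") or []):
            path = f"population.segments[{i}]"
            if not isinstance(seg, dict):
                errors.add(path, "expected a mapping")
                continue
            segments.append(
                CoverageSegment(
                    name=str(seg.get("name", f"segment {i}")),
                    percent=_as_number(seg.get("percent"), f"{path}.percent", errors),
                )
            )
    population = PopulationModel(total_population=total, segments=segments)

    formularies: list[Formulary] = []
    for i, f in enumerate(data.get("formularies") or []):
        path = f"formularies[{i}]"
        if not isinstance(f, dict):
            errors.add(path, "expected a mapping")
            continue
        formularies.append(
            Formulary(
                name=str(f.get("name", f"formulary {i}")),
                market_share=_as_number(
                    f.get("market_share"), f"{path}.market_share", errors
                ),
            )
        )

    ind_data = data.get("indication")
    if not isinstance(ind_data, dict):
        errors.add("indication", "required mapping")
        indication = Indication("<missing>", BoundedRange(0, 0))
    else:
        elig: list[tuple[str, float]] = []
        for i, ef in enumerate(ind_data.get("eligibility_factors") or []):
            path = f"indication.eligibility_factors[{i}]"
            if not isinstance(ef, dict):
                errors.add(path, "expected a mapping")
                continue
            elig.append(
                (
                    str(ef.get("label", f"factor {i}")),
                    _as_number(ef.get("fraction"), f"{path}.fraction", errors),
                )
            )
        cal = ind_data.get("calibration_factor", 1.0)
        indication = Indication(
            name=str(ind_data.get("name", "<unnamed>")),
            prevalence=_as_range(
                ind_data.get("prevalence"), "indication.prevalence", errors
            ),
            eligibility_factors=elig,
            calibration_factor=_as_number(
                cal, "indication.calibration_factor", errors, default=1.0
            ),
            calibration_provenance=ind_data.get("calibration_provenance"),
        )

    outcome_models: list[OutcomeModel] = []
    for i, om in enumerate(data.get("outcome_models") or []):
        path = f"outcome_models[{i}]"
        if not isinstance(om, dict):
            errors.add(path, "expected a mapping")
            continue
        rule_data = om.get("adverse_event_rule")
        rule: Union[FlatRate, CoupledCompound]
        if not isinstance(rule_data, dict):
            errors.add(f"{path}.adverse_event_rule", "required mapping")
            rule = FlatRate(BoundedRange(0, 0))
        else:
            rtype = rule_data.get("type")
            if rtype == "flat_rate":
                rule = FlatRate(
                    rate=_as_range(
                        rule_data.get("rate"),
                        f"{path}.adverse_event_rule.rate",
                        errors,
                    )
                )
            elif rtype == "coupled_compound":
                rule = CoupledCompound(
                    event_given_discontinuation=_as_range(
                        rule_data.get("event_given_discontinuation"),
                        f"{path}.adverse_event_rule.event_given_discontinuation",
                        errors,
                    ),
                    event_given_switch=_as_range(
                        rule_data.get("event_given_switch"),
                        f"{path}.adverse_event_rule.event_given_switch",
                        errors,
                    ),
                )
            else:
                errors.add(
                    f"{path}.adverse_event_rule.type",
                    f"expected 'flat_rate' or 'coupled_compound', got {rtype!r}",
                )
                rule = FlatRate(BoundedRange(0, 0))
        outcome_models.append(
            OutcomeModel(
                id=str(om.get("id", f"model {i}")),
                discontinuation=_as_range(
                    om.get("discontinuation"), f"{path}.discontinuation", errors
                ),
                adverse_event_rule=rule,
            )
        )

    share_groups: list[ShareGroup] = []
    for gi, g in enumerate(data.get("share_groups") or []):
        gpath = f"share_groups[{gi}]"
        if not isinstance(g, dict):
            errors.add(gpath, "expected a mapping")
            continue
        group_id = str(g.get("group_id", f"group {gi}"))
        meds: list[Medication] = []
        for mi, m in enumerate(g.get("medications") or []):
            mpath = f"{gpath}.medications[{mi}]"
            if not isinstance(m, dict):
                errors.add(mpath, "expected a mapping")
                continue
            share = m.get("share")
            prescriptions = m.get("prescriptions")
            if share is None and prescriptions is None:
                errors.add(mpath, "one of 'share' or 'prescriptions' is required")
            share_val = (
                _as_number(share, f"{mpath}.share", errors)
                if share is not None
                else None
            )
            if share_val is not None and not (0.0 <= share_val <= 1.0):
                errors.add(f"{mpath}.share", f"must lie in [0, 1], got {share_val}")
            rx_val = (
                _as_number(prescriptions, f"{mpath}.prescriptions", errors)
                if prescriptions is not None
                else None
            )
            if rx_val is not None and rx_val < 0:
                errors.add(f"{mpath}.prescriptions", f"must be >= 0, got {rx_val}")
            meds.append(
                Medication(
                    brand_name=str(m.get("brand_name", f"medication {mi}")),
                    generic_name=str(m.get("generic_name", "")),
                    group_id=group_id,
                    outcome_model_id=str(m.get("outcome_model_id", "")),
                    prescriptions=rx_val,
                    share=share_val,
                )
            )
        share_groups.append(
            ShareGroup(
                group_id=group_id,
                medications=meds,
                normalization=str(g.get("normalization", "within_group")),
            )
        )

    notes = [str(n) for n in (data.get("notes") or [])]
    scenario = Scenario(
        name=name,
        population=population,
        formularies=formularies,
        indication=indication,
        share_groups=share_groups,
        outcome_models=outcome_models,
        output_unit=str(data.get("output_unit", "thousands")),
        notes=notes,
    )
    errors.items.extend(validate_scenario(scenario))
    errors.raise_if_any()
    return scenario


def validate_scenario(s: Scenario) -> list[str]:
    """Return every invariant violation as a dotted field path message."""
    errors: list[str] = []
    if s.population.total_population <= 0:
        errors.append(
            f"population.total: must be > 0, got {s.population.total_population}"
        )
    pct_sum = 0.0
    for i, seg in enumerate(s.population.segments):
        if not (0.0 <= seg.percent <= 1.0):
            errors.append(
                f"population.segments[{i}].percent: must lie in [0, 1], "
                f"got {seg.percent}"
            )
        else:
            pct_sum += seg.percent
    if pct_sum > 1.0 + 1e-9:
        errors.append(
            f"population.segments: percents sum to {pct_sum:.4f}, must be <= 1"
        )
    if not s.formularies:
        errors.append("formularies: at least one formulary is required")
    for i, f in enumerate(s.formularies):
        if not (0.0 < f.market_share <= 1.0):
            errors.append(
                f"formularies[{i}].market_share: must lie in (0, 1], "
                f"got {f.market_share}"
            )
    if not s.indication.prevalence.is_fraction():
        errors.append("indication.prevalence: must lie within [0, 1]")
    for i, (label, frac) in enumerate(s.indication.eligibility_factors):
        if not (0.0 < frac <= 1.0):
            errors.append(
                f"indication.eligibility_factors[{i}].fraction: must lie in "
                f"(0, 1], got {frac} ({label!r})"
            )
    if not (0.0 < s.indication.calibration_factor <= 1.0):
        errors.append(
            "indication.calibration_factor: must lie in (0, 1], "
            f"got {s.indication.calibration_factor}"
        )
    model_ids = [om.id for om in s.outcome_models]
    if len(set(model_ids)) != len(model_ids):
        errors.append("outcome_models: ids must be unique")
    for i, om in enumerate(s.outcome_models):
        if not om.discontinuation.is_fraction():
            errors.append(
                f"outcome_models[{i}].discontinuation: must lie within [0, 1]"
            )
        rule = om.adverse_event_rule
        if isinstance(rule, FlatRate):
            if not rule.rate.is_fraction():
                errors.append(
                    f"outcome_models[{i}].adverse_event_rule.rate: must lie "
                    "within [0, 1]"
                )
        else:
            if not rule.event_given_discontinuation.is_fraction():
                errors.append(
                    f"outcome_models[{i}].adverse_event_rule."
                    "event_given_discontinuation: must lie within [0, 1]"
                )
            if not rule.event_given_switch.is_fraction():
                errors.append(
                    f"outcome_models[{i}].adverse_event_rule."
                    "event_given_switch: must lie within [0, 1]"
                )
    group_ids = [g.group_id for g in s.share_groups]
    if len(set(group_ids)) != len(group_ids):
        errors.append("share_groups: group_ids must be unique")
    if not s.share_groups:
        errors.append("share_groups: at least one group is required")
    for gi, g in enumerate(s.share_groups):
        if not g.medications:
            errors.append(f"share_groups[{gi}].medications: must be non-empty")
        for mi, m in enumerate(g.medications):
            path = f"share_groups[{gi}].medications[{mi}]"
            if m.outcome_model_id not in model_ids:
                errors.append(
                    f"{path}.outcome_model_id: {m.outcome_model_id!r} does not "
                    "resolve to an outcome model"
                )
            if m.share is not None and not (0.0 <= m.share <= 1.0):
                errors.append(f"{path}.share: must lie in [0, 1], got {m.share}")
            if m.share is None and m.prescriptions is None:
                errors.append(f"{path}: one of share/prescriptions must be set")
    if s.output_unit != "thousands":
        errors.append(f"output_unit: only 'thousands' is supported, got {s.output_unit!r}")
    return errors


def scenario_to_dict(s: Scenario) -> dict[str, Any]:
    """Serializable form; fractions are written as plain numbers."""
    doc: dict[str, Any] = {
        "name": s.name,
        "output_unit": s.output_unit,
        "population": {
            "total": s.population.total_population,
            "segments": [
                {"name": seg.name, "percent": seg.percent}
                for seg in s.population.segments
            ],
        },
        "formularies": [
            {"name": f.name, "market_share": f.market_share} for f in s.formularies
        ],
        "indication": {
            "name": s.indication.name,
            "prevalence": _range_to_obj(s.indication.prevalence),
            "eligibility_factors": [
                {"label": label, "fraction": frac}
                for label, frac in s.indication.eligibility_factors
            ],
            "calibration_factor": s.indication.calibration_factor,
        },
        "outcome_models": [],
        "share_groups": [],
    }
    if s.indication.calibration_provenance:
        doc["indication"]["calibration_provenance"] = s.indication.calibration_provenance
    for om in s.outcome_models:
        rule = om.adverse_event_rule
        if isinstance(rule, FlatRate):
            rule_doc: dict[str, Any] = {
                "type": "flat_rate",
                "rate": _range_to_obj(rule.rate),
            }
        else:
            rule_doc = {
                "type": "coupled_compound",
                "event_given_discontinuation": _range_to_obj(
                    rule.event_given_discontinuation
                ),
                "event_given_switch": _range_to_obj(rule.event_given_switch),
            }
        doc["outcome_models"].append(
            {
                "id": om.id,
                "discontinuation": _range_to_obj(om.discontinuation),
                "adverse_event_rule": rule_doc,
            }
        )
    for g in s.share_groups:
        meds = []
        for m in g.medications:
            med_doc: dict[str, Any] = {
                "brand_name": m.brand_name,
                "generic_name": m.generic_name,
                "outcome_model_id": m.outcome_model_id,
            }
            if m.prescriptions is not None:
                med_doc["prescriptions"] = m.prescriptions
            if m.share is not None:
                med_doc["share"] = m.share
            meds.append(med_doc)
        doc["share_groups"].append(
            {
                "group_id": g.group_id,
                "normalization": g.normalization,
                "medications": meds,
            }
        )
    if s.notes:
        doc["notes"] = list(s.notes)
    return doc


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def load_scenario(path: Union[str, Path]) -> Scenario:
    """Load and validate a scenario config (YAML or JSON).

    Shares are normalized on load: prescription counts are converted to
    within-group fractions, and share fractions are renormalized by their own
    sum so each group sums to exactly one.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    scenario = scenario_from_dict(data)
    from .cascade import normalize_shares  # deferred: cascade imports this module

    scenario.share_groups = [normalize_shares(g) for g in scenario.share_groups]
    return scenario


def save_scenario(s: Scenario, path: Union[str, Path]) -> None:
    """Serialize a scenario to YAML (or JSON by extension).

    The scenario is validated first; the written form reloads to an equal
    Scenario and a second save is byte-identical to the first.
    """
    errors = validate_scenario(s)
    if errors:
        raise ScenarioValidationError(errors)
    path = Path(path)
    doc = scenario_to_dict(s)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))


# ---------------------------------------------------------------------------
# Packaged study fixtures
# ---------------------------------------------------------------------------

_FIXTURE_NAMES = ("anticoagulants", "migraine", "psoriasis")


def _data_path(filename: str) -> Path:
    from importlib.resources import files

    return Path(str(files("formulary_impact").joinpath("data", filename)))


def fixture_names() -> tuple[str, ...]:
    """Names of the packaged case-study scenarios."""
    return _FIXTURE_NAMES


def load_fixture(name: str):
    """Load one packaged case study: ``(Scenario, ReferenceTable)``."""
    if name not in _FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(_FIXTURE_NAMES)}"
        )
    from .reporting import load_reference_table

    scenario = load_scenario(_data_path(f"{name}.yaml"))
    reference = load_reference_table(_data_path(f"{name}_reference.yaml"))
    return scenario, reference


def case_study_fixtures():
    """All three packaged case studies (anticoagulants for AFib/VTE, migraine
    prevention, psoriasis), each paired with its printed reference table."""
    return [load_fixture(name) for name in _FIXTURE_NAMES]
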