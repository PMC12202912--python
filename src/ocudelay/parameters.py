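"""Model parameters: domain types, shipped Dutch 2023 defaults, config I/O.

The default parameter set encodes the published Dutch 2023 values for the
five key ophthalmic diagnoses handled by remote triage (cataract, dry eye
syndrome, age-related macular disease, diabetic retinopathy, stable
glaucoma) together with the economy-wide costing constants (wages, labour
force, informal-care shadow price, unit costs of care items).

Users override any subset of these through a YAML document; absent fields
fall back to the shipped defaults and every validation failure is reported
at once.
"""

from __future__ import annotations

import enum
import io
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator
from pydantic import ValidationError as PydanticValidationError

from .errors import ConfigurationError
from .intervals import Interval

__all__ = [
    "InclusionPolicy",
    "SymptomClass",
    "CostingConstants",
    "DiagnosisProfile",
    "DelayImpact",
    "default_parameters",
    "load_parameters",
    "dump_parameters",
    "UNIT_COST_ITEMS",
]

# Canonical care-item names used in the shipped unit-cost table.
CONSULTATION = "outpatient_consultation"
OCT_SCAN = "oct_scan"
IVI = "intravitreal_injection"
PI_LASER = "laser_peripheral_iridotomy"
GLAUCOMA_MEDICATION = "glaucoma_medication"
UNIT_COST_ITEMS = (CONSULTATION, OCT_SCAN, IVI, PI_LASER, GLAUCOMA_MEDICATION)


class InclusionPolicy(str, enum.Enum):
    """How productivity and informal-care costs accrue for a diagnosis.

    * ``full`` — both accrue unconditionally over the whole delay.
    * ``event_conditional`` — both accrue only with the probability that a
      clinical event is missed during the delay.
    * ``productivity_only`` — productivity accrues unconditionally,
      informal care is zero.
    * ``none`` — neither accrues.
    """

    FULL = "full"
    EVENT_CONDITIONAL = "event_conditional"
    PRODUCTIVITY_ONLY = "productivity_only"
    NONE = "none"


class SymptomClass(str, enum.Enum):
    """Whether delay prolongs curable symptoms or defers care of stable
    disease.  Symptomatic diagnoses lose quality of life for the whole
    delay; stable ones only through missed events."""

    SYMPTOMATIC = "symptomatic"
    STABLE = "stable"


class CostingConstants(BaseModel):
    """Economy-wide unit costs and labour parameters (EUR, Dutch 2023).

    ``productivity_working_weeks_per_half_year`` counts *working* weeks
    (47 working weeks per year / 2), while informal care runs over the 26
    calendar weeks of a half year — the two week counts are deliberately
    distinct.
    """

    model_config = ConfigDict(frozen=True)

    wage_per_hour: float = Field(default=39.88, ge=0)
    workweek_hours: float = Field(default=32.2, gt=0)
    productivity_working_weeks_per_half_year: float = Field(default=23.5, gt=0)
    informal_care_weeks_per_half_year: float = Field(default=26.0, gt=0)
    productivity_loss_fraction: float = Field(default=0.2058, ge=0, le=1)
    employed_labour_force_fraction: float = Field(default=0.7039, ge=0, le=1)
    informal_care_hours_per_week: float = Field(default=5.8, gt=0)
    informal_care_rate_per_hour: float = Field(default=18.80, ge=0)
    unit_costs: Mapping[str, float] = Field(
        default_factory=lambda: {
            CONSULTATION: 120.00,
            OCT_SCAN: 62.31,
            IVI: 286.62,
            PI_LASER: 379.04,
            GLAUCOMA_MEDICATION: 31.36,
        }
    )

    @field_validator("unit_costs")
    @classmethod
    def _non_negative_unit_costs(cls, v: Mapping[str, float]) -> Mapping[str, float]:
        bad = {k: c for k, c in v.items() if c < 0}
        if bad:
            raise ValueError(f"unit costs must be >= 0, got {bad}")
        return dict(v)


class DiagnosisProfile(BaseModel):
    """All per-diagnosis model inputs for one key diagnosis.

    ``medical_cost_delta_semester`` is the change in direct medical cost per
    patient per 6 months of delay (negative = saving from avoided care);
    ``missed_event_probability`` is the chance, per 6 months of delay, of an
    adverse event composed of the priced ``missed_event_items``.

    ``reported_qaly_event_probability`` optionally overrides the event
    probability *only* for the quality-of-life pathway in ``as_printed``
    mode; it exists because one published source table uses a different
    (hundred-fold) probability for the QALY figure than for the costs.
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    name: str
    medical_cost_delta_semester: Interval = Interval.point(0.0)
    utility_decrement: Interval = Interval.point(0.0)
    working_population_fraction: float = Field(default=0.0, ge=0, le=1)
    missed_event_probability: float = Field(default=0.0, ge=0, le=1)
    missed_event_items: tuple[str, ...] = ()
    inclusion_policy: InclusionPolicy = InclusionPolicy.FULL
    symptom_class: SymptomClass = SymptomClass.SYMPTOMATIC
    reported_qaly_event_probability: Optional[float] = Field(
        default=None, ge=0, le=1
    )

    @field_validator("medical_cost_delta_semester", "utility_decrement", mode="before")
    @classmethod
    def _coerce_intervals(cls, v):
        return Interval.coerce(v)

    @field_validator("utility_decrement")
    @classmethod
    def _utility_in_unit_interval(cls, v: Interval) -> Interval:
        if v.lower < 0 or v.upper > 1:
            raise ValueError(f"utility decrement must lie in [0, 1], got {v}")
        return v


class DelayImpact(BaseModel):
    """Per-patient impact of a care delay of ``months`` months.

    Cost components are EUR; QALY loss is dimensionless.  Totals are the
    exact full-precision sums of the components:
    ``direct_cost_total = medical_cost + missed_event_cost`` and
    ``societal_cost_total = medical_cost + productivity_cost +
    informal_care_cost + missed_event_cost`` (bound-wise for intervals).
    Negative values are savings; negative months denote expedited care.
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    diagnosis: str
    months: float
    qaly_loss: Interval
    medical_cost: Interval
    productivity_cost: float
    informal_care_cost: float
    missed_event_cost: float
    direct_cost_total: Interval
    societal_cost_total: Interval


# ----------------------------------------------------------------------
# Shipped defaults
# ----------------------------------------------------------------------

def _default_profiles() -> tuple[DiagnosisProfile, ...]:
    return (
        DiagnosisProfile(
            name="cataract",
            # surgery is delayed, not avoided, so no medical saving
            medical_cost_delta_semester=0.0,
            utility_decrement=Interval(0.07, 0.09),
            working_population_fraction=0.106,
            missed_event_probability=0.0,
            missed_event_items=(),
            inclusion_policy=InclusionPolicy.FULL,
            symptom_class=SymptomClass.SYMPTOMATIC,
        ),
        DiagnosisProfile(
            name="des",
            medical_cost_delta_semester=-423.91,
            utility_decrement=0.05,
            working_population_fraction=0.5901,
            missed_event_probability=0.0,
            missed_event_items=(),
            inclusion_policy=InclusionPolicy.PRODUCTIVITY_ONLY,
            symptom_class=SymptomClass.SYMPTOMATIC,
        ),
        DiagnosisProfile(
            name="amd",
            medical_cost_delta_semester=Interval(-663.09, -581.32),
            utility_decrement=0.095,
            working_population_fraction=0.0337,
            missed_event_probability=0.59,
            missed_event_items=(CONSULTATION, OCT_SCAN, IVI),
            inclusion_policy=InclusionPolicy.EVENT_CONDITIONAL,
            symptom_class=SymptomClass.STABLE,
        ),
        DiagnosisProfile(
            name="drp",
            medical_cost_delta_semester=-85.84,
            utility_decrement=0.075,
            working_population_fraction=0.50,
            missed_event_probability=0.037,
            missed_event_items=(CONSULTATION, OCT_SCAN, IVI),
            inclusion_policy=InclusionPolicy.EVENT_CONDITIONAL,
            symptom_class=SymptomClass.STABLE,
        ),
        DiagnosisProfile(
            name="glaucoma",
            medical_cost_delta_semester=-408.78,
            utility_decrement=0.10,
            working_population_fraction=0.207,
            missed_event_probability=3.1e-5,
            missed_event_items=(CONSULTATION, OCT_SCAN, PI_LASER, GLAUCOMA_MEDICATION),
            inclusion_policy=InclusionPolicy.EVENT_CONDITIONAL,
            symptom_class=SymptomClass.STABLE,
            # the published QALY figure uses the per-cent number read as a
            # proportion (0.0031) instead of 3.1e-5
            reported_qaly_event_probability=0.0031,
        ),
    )


def default_parameters() -> tuple[CostingConstants, tuple[DiagnosisProfile, ...]]:
    """The shipped Dutch 2023 parameter set; stable across calls."""
    return CostingConstants(), _default_profiles()


# ----------------------------------------------------------------------
# Configuration I/O
# ----------------------------------------------------------------------

def _interval_to_doc(iv: Interval) -> Union[float, dict]:
    if iv.is_point:
        return iv.lower
    return {"lower": iv.lower, "upper": iv.upper}


def _profile_to_doc(p: DiagnosisProfile) -> dict:
    doc: dict[str, Any] = {
        "name": p.name,
        "medical_cost_delta_semester": _interval_to_doc(p.medical_cost_delta_semester),
        "utility_decrement": _interval_to_doc(p.utility_decrement),
        "working_population_fraction": p.working_population_fraction,
        "missed_event_probability": p.missed_event_probability,
        "missed_event_items": list(p.missed_event_items),
        "inclusion_policy": p.inclusion_policy.value,
        "symptom_class": p.symptom_class.value,
    }
    if p.reported_qaly_event_probability is not None:
        doc["reported_qaly_event_probability"] = p.reported_qaly_event_probability
    return doc


def dump_parameters(
    constants: Optional[CostingConstants] = None,
    profiles: Optional[Sequence[DiagnosisProfile]] = None,
    path: Optional[Union[str, Path]] = None,
) -> str:
    """Serialize a parameter set to YAML (defaults if not given).

    Returns the YAML text; also writes it to ``path`` when provided.
    The output round-trips through :func:`load_parameters`.
    """
    if constants is None or profiles is None:
        d_const, d_prof = default_parameters()
        constants = constants or d_const
        profiles = profiles or d_prof
    doc = {
        "constants": {
            "wage_per_hour": constants.wage_per_hour,
            "workweek_hours": constants.workweek_hours,
            "productivity_working_weeks_per_half_year": constants.productivity_working_weeks_per_half_year,
            "informal_care_weeks_per_half_year": constants.informal_care_weeks_per_half_year,
            "productivity_loss_fraction": constants.productivity_loss_fraction,
            "employed_labour_force_fraction": constants.employed_labour_force_fraction,
            "informal_care_hours_per_week": constants.informal_care_hours_per_week,
            "informal_care_rate_per_hour": constants.informal_care_rate_per_hour,
            "unit_costs": dict(constants.unit_costs),
        },
        "profiles": [_profile_to_doc(p) for p in profiles],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def _format_pydantic_errors(name: str, exc: PydanticValidationError) -> list[str]:
    msgs = []
    for err in exc.errors():
        loc = ".".join(str(part) for part in err["loc"]) or "<root>"
        msgs.append(f"{name}: field '{loc}': {err['msg']}")
    return msgs


def load_parameters(
    source: Union[str, Path, Mapping[str, Any], io.IOBase, None] = None,
) -> tuple[CostingConstants, tuple[DiagnosisProfile, ...]]:
    """Load a parameter set from a YAML document, filling gaps from defaults.

    ``source`` may be a path, YAML text, an open file, an already-parsed
    mapping, or ``None``/empty (pure defaults).  Profiles are merged by
    ``name``: known names override the shipped profile field-wise, new
    names define new diagnoses.  All validation problems are collected and
    raised together as :class:`~ocudelay.errors.ConfigurationError`.
    """
    doc = _read_document(source)
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ConfigurationError(
            f"parameter document must be a mapping, got {type(doc).__name__}"
        )
    unknown = set(doc) - {"constants", "profiles"}
    if unknown:
        raise ConfigurationError(
            f"unknown top-level keys in parameter document: {sorted(unknown)} "
            "(expected 'constants' and/or 'profiles')"
        )

    problems: list[str] = []
    defaults_const, defaults_prof = default_parameters()

    const_doc = dict(doc.get("constants") or {})
    base_const = defaults_const.model_dump()
    if "unit_costs" in const_doc:
        merged_costs = dict(base_const["unit_costs"])
        merged_costs.update(const_doc.pop("unit_costs"))
        base_const["unit_costs"] = merged_costs
    extra = set(const_doc) - set(base_const)
    if extra:
        problems.append(f"constants: unknown fields {sorted(extra)}")
        for k in extra:
            const_doc.pop(k)
    base_const.update(const_doc)
    constants = defaults_const
    try:
        constants = CostingConstants(**base_const)
    except PydanticValidationError as exc:
        problems.extend(_format_pydantic_errors("constants", exc))

    by_name = {p.name: p for p in defaults_prof}
    order = [p.name for p in defaults_prof]
    for entry in doc.get("profiles") or []:
        if not isinstance(entry, Mapping) or "name" not in entry:
            problems.append(
                f"profiles: each entry needs a 'name' field, got {entry!r}"
            )
            continue
        name = entry["name"]
        base = by_name.get(name)
        fields = dict(entry)
        try:
            if base is None:
                prof = DiagnosisProfile(**fields)
            else:
                merged = _profile_to_doc(base)
                merged.update(fields)
                prof = DiagnosisProfile(**merged)
        except PydanticValidationError as exc:
            problems.extend(_format_pydantic_errors(f"profile '{name}'", exc))
            continue
        except (TypeError, ValueError) as exc:
            problems.append(f"profile '{name}': {exc}")
            continue
        if name not in by_name:
            order.append(name)
        by_name[name] = prof

    profiles = tuple(by_name[n] for n in order)
    problems.extend(_check_items_priced(constants, profiles))
    if problems:
        raise ConfigurationError(
            "invalid parameter document:\n  - " + "\n  - ".join(problems)
        )
    return constants, profiles


def _check_items_priced(
    constants: CostingConstants, profiles: Iterable[DiagnosisProfile]
) -> list[str]:
    problems = []
    for p in profiles:
        missing = [i for i in p.missed_event_items if i not in constants.unit_costs]
        if missing:
            problems.append(
                f"profile '{p.name}': missed-event items {missing} have no "
                f"unit cost (known items: {sorted(constants.unit_costs)})"
            )
    return problems


def _read_document(source):
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return source
    if isinstance(source, Path):
        return yaml.safe_load(source.read_text())
    if hasattr(source, "read"):
        return yaml.safe_load(source.read())
    if isinstance(source, str):
        # a path if it points at an existing file, else YAML text
        p = Path(source)
        try:
            if p.is_file():
                return yaml.safe_load(p.read_text())
        except OSError:
            pass
        try:
            return yaml.safe_load(source)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse parameter document: {exc}") from exc
    raise ConfigurationError(
        f"unsupported parameter source type: {type(source).__name__}"
    )
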