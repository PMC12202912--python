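"""Societal cost of a care delay, per patient per diagnosis.

The model prices a 6-month postponement of elective ophthalmic follow-up
from a societal perspective, as four components:

* **medical cost delta** — change in direct medical spending (consults,
  scans, injections avoided during the delay); negative = saving,
* **productivity cost** — lost paid-work value of vision impairment over
  the delay (human capital approach: wage x hours x working weeks x
  condition-specific productivity reduction x employment rate x the share
  of patients of working age),
* **informal care cost** — unpaid caregiver hours over the calendar weeks
  of the delay, valued at a shadow hourly rate,
* **expected missed-event cost** — probability of an adverse event during
  the delay (e.g. choroidal neovascularisation, acute angle closure) times
  the price of the care bundle it triggers.

Whether productivity and informal care accrue unconditionally or only when
an event is missed is governed by the profile's inclusion policy; see
:class:`~ocudelay.parameters.InclusionPolicy`.

All arithmetic is carried at full floating-point precision; rounding to
cents happens only on display (see :mod:`ocudelay.tables`).  Durations
other than 6 months scale linearly; negative durations model expedited
care as the exact mirror image of delay.
"""

from __future__ import annotations

from .errors import ConfigurationError
from .intervals import Interval
from .parameters import (
    CostingConstants,
    DelayImpact,
    DiagnosisProfile,
    InclusionPolicy,
)

__all__ = [
    "base_semester_productivity_value",
    "productivity_cost",
    "informal_care_cost",
    "expected_missed_event_cost",
    "societal_delay_cost",
    "scale_by_duration",
]

SEMESTER_MONTHS = 6.0

# Conditioning factor applied per policy: 1.0 = unconditional, "p" = the
# missed-event probability, 0.0 = excluded.
_PRODUCTIVITY_FACTOR = {
    InclusionPolicy.FULL: 1.0,
    InclusionPolicy.PRODUCTIVITY_ONLY: 1.0,
    InclusionPolicy.EVENT_CONDITIONAL: "p",
    InclusionPolicy.NONE: 0.0,
}
_INFORMAL_FACTOR = {
    InclusionPolicy.FULL: 1.0,
    InclusionPolicy.PRODUCTIVITY_ONLY: 0.0,
    InclusionPolicy.EVENT_CONDITIONAL: "p",
    InclusionPolicy.NONE: 0.0,
}


def _factor(table, profile: DiagnosisProfile) -> float:
    f = table[profile.inclusion_policy]
    return profile.missed_event_probability if f == "p" else f


def base_semester_productivity_value(constants: CostingConstants) -> float:
    """Productivity value lost over 6 months by a working, employed patient.

    wage/h x h/week x working weeks per half year x productivity-loss
    fraction x employed labour-force fraction.  Defaults give ~4371.55 EUR.
    """
    return (
        constants.wage_per_hour
        * constants.workweek_hours
        * constants.productivity_working_weeks_per_half_year
        * constants.productivity_loss_fraction
        * constants.employed_labour_force_fraction
    )


def productivity_cost(
    profile: DiagnosisProfile, constants: CostingConstants
) -> float:
    """Average 6-month productivity cost per patient for one diagnosis."""
    return (
        base_semester_productivity_value(constants)
        * profile.working_population_fraction
        * _factor(_PRODUCTIVITY_FACTOR, profile)
    )


def informal_care_cost(
    profile: DiagnosisProfile, constants: CostingConstants
) -> float:
    """Average 6-month informal (unpaid) care cost per patient."""
    return (
        constants.informal_care_hours_per_week
        * constants.informal_care_rate_per_hour
        * constants.informal_care_weeks_per_half_year
        * _factor(_INFORMAL_FACTOR, profile)
    )


def missed_event_bundle_cost(
    profile: DiagnosisProfile, constants: CostingConstants
) -> float:
    """Price of the care bundle triggered by one missed event."""
    total = 0.0
    for item in profile.missed_event_items:
        try:
            total += constants.unit_costs[item]
        except KeyError:
            raise ConfigurationError(
                f"profile '{profile.name}': missed-event item '{item}' has no "
                f"unit cost (known items: {sorted(constants.unit_costs)})"
            ) from None
    return total


def expected_missed_event_cost(
    profile: DiagnosisProfile, constants: CostingConstants
) -> float:
    """Expected 6-month cost of adverse events missed during the delay."""
    return profile.missed_event_probability * missed_event_bundle_cost(
        profile, constants
    )


def societal_delay_cost(
    profile: DiagnosisProfile,
    constants: CostingConstants,
    qaly_mode: "QalyMode | str | None" = None,
) -> DelayImpact:
    """Assemble the full per-patient impact of a 6-month delay.

    Components are computed at full precision and summed bound-wise; the
    medical delta (and hence the totals) may be an interval when the
    literature gives upper/lower bounds.  The QALY loss is filled in from
    :func:`ocudelay.qaly_model.qaly_loss` (``as_printed`` mode unless
    overridden).
    """
    from .qaly_model import QalyMode, qaly_loss  # local import: avoid cycle

    mode = QalyMode(qaly_mode) if qaly_mode is not None else QalyMode.AS_PRINTED
    medical = profile.medical_cost_delta_semester
    prod = productivity_cost(profile, constants)
    informal = informal_care_cost(profile, constants)
    event = expected_missed_event_cost(profile, constants)
    return DelayImpact(
        diagnosis=profile.name,
        months=SEMESTER_MONTHS,
        qaly_loss=qaly_loss(profile, mode),
        medical_cost=medical,
        productivity_cost=prod,
        informal_care_cost=informal,
        missed_event_cost=event,
        direct_cost_total=medical + Interval.point(event),
        societal_cost_total=medical + Interval.point(prod + informal + event),
    )


def scale_by_duration(impact: DelayImpact, months: float) -> DelayImpact:
    """Rescale an impact linearly to a delay of ``months`` months.

    Linearity in duration is a modelling assumption: costs and QALY losses
    accrue at a constant rate over the delay.  Negative months denote
    expedited care and negate every component (the symmetric mirror of a
    delay of the same length).
    """
    f = months / impact.months if impact.months != 0 else 0.0
    if impact.months == 0:
        if months == 0:
            return impact
        raise ValueError("cannot rescale an impact with zero duration")
    return DelayImpact(
        diagnosis=impact.diagnosis,
        months=months,
        qaly_loss=impact.qaly_loss.scale(f),
        medical_cost=impact.medical_cost.scale(f),
        productivity_cost=impact.productivity_cost * f,
        informal_care_cost=impact.informal_care_cost * f,
        missed_event_cost=impact.missed_event_cost * f,
        direct_cost_total=impact.direct_cost_total.scale(f),
        societal_cost_total=impact.societal_cost_total.scale(f),
    )
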