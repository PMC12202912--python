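"""Publication-style summary tables of the per-diagnosis delay model.

Two views are provided:

* :func:`cost_breakdown` — the full costing worksheet: one row per
  diagnosis (two for a diagnosis whose medical delta carries bounds),
  with every component and both totals, rounded to cents for display.
* :func:`delay_summary` — the headline per-patient-per-6-months view:
  QALY loss, medical, productivity, informal-care and total societal
  costs.

All rounding is half-up (away from zero on ties) to the cent and happens
only here; model arithmetic is full precision.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Union

import pandas as pd

from .cost_model import societal_delay_cost
from .intervals import Interval
from .parameters import CostingConstants, DiagnosisProfile, default_parameters
from .qaly_model import QalyMode

__all__ = ["round_half_up", "cost_breakdown", "delay_summary"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (so 0.005 -> 0.01, -0.005 -> -0.01)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _bound_variants(profile: DiagnosisProfile) -> list[tuple[str, DiagnosisProfile]]:
    """Split a profile with a non-degenerate medical delta into its two
    bound rows; the larger (less negative) delta is the 'upper' row."""
    delta = profile.medical_cost_delta_semester
    if delta.is_point:
        return [(profile.name, profile)]
    return [
        (
            f"{profile.name} (upper)",
            profile.model_copy(
                update={"medical_cost_delta_semester": Interval.point(delta.upper)}
            ),
        ),
        (
            f"{profile.name} (lower)",
            profile.model_copy(
                update={"medical_cost_delta_semester": Interval.point(delta.lower)}
            ),
        ),
    ]


def cost_breakdown(
    constants: Optional[CostingConstants] = None,
    profiles: Optional[Sequence[DiagnosisProfile]] = None,
    rounded: bool = True,
) -> pd.DataFrame:
    """Per-diagnosis costing worksheet for a 6-month delay (EUR).

    Columns: medical cost delta, working-population share, missed-event
    probability, expected event cost, productivity, informal care, direct
    total and societal total.  ``rounded=False`` returns full precision.
    """
    if constants is None or profiles is None:
        d_const, d_prof = default_parameters()
        constants = constants or d_const
        profiles = profiles or d_prof
    rows = []
    for profile in profiles:
        for label, variant in _bound_variants(profile):
            impact = societal_delay_cost(variant, constants)
            rows.append(
                {
                    "diagnosis": label,
                    "medical_cost": impact.medical_cost.lower,
                    "working_population_fraction": variant.working_population_fraction,
                    "missed_event_probability": variant.missed_event_probability,
                    "missed_event_cost": impact.missed_event_cost,
                    "productivity_cost": impact.productivity_cost,
                    "informal_care_cost": impact.informal_care_cost,
                    "direct_cost_total": impact.direct_cost_total.lower,
                    "societal_cost_total": impact.societal_cost_total.lower,
                }
            )
    df = pd.DataFrame(rows).set_index("diagnosis")
    if rounded:
        money = [
            "medical_cost",
            "missed_event_cost",
            "productivity_cost",
            "informal_care_cost",
            "direct_cost_total",
            "societal_cost_total",
        ]
        df[money] = df[money].map(round_half_up)
    return df


def _fmt_interval(iv: Interval, ndigits: int) -> str:
    if iv.is_point:
        return f"{round_half_up(iv.lower, ndigits):g}"
    return (
        f"{round_half_up(iv.lower, ndigits):g}"
        f"; {round_half_up(iv.upper, ndigits):g}"
    )


def delay_summary(
    constants: Optional[CostingConstants] = None,
    profiles: Optional[Sequence[DiagnosisProfile]] = None,
    mode: Union[QalyMode, str] = QalyMode.AS_PRINTED,
    qaly_digits: int = 5,
) -> pd.DataFrame:
    """Headline per-patient-per-6-months summary (QALY + EUR, rounded).

    Interval quantities are shown as ``lower; upper`` strings, matching
    the convention of the published summary table.
    """
    if constants is None or profiles is None:
        d_const, d_prof = default_parameters()
        constants = constants or d_const
        profiles = profiles or d_prof
    rows = []
    for profile in profiles:
        impact = societal_delay_cost(profile, constants, qaly_mode=mode)
        rows.append(
            {
                "diagnosis": profile.name,
                "qaly_loss": _fmt_interval(impact.qaly_loss, qaly_digits),
                "medical_cost": _fmt_interval(impact.medical_cost, 0),
                "productivity_cost": f"{round_half_up(impact.productivity_cost, 0):g}",
                "informal_care_cost": f"{round_half_up(impact.informal_care_cost, 0):g}",
                "societal_cost_total": _fmt_interval(impact.societal_cost_total, 0),
            }
        )
    return pd.DataFrame(rows).set_index("diagnosis")
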