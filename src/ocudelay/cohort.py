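"""Cohort-level aggregation of delay impacts and the prioritisation trade-off.

A triage cohort is a table of patients, each with a diagnosis, a triage
decision and a delay duration.  Aggregation prices every delayed patient's
harm (their per-6-month delay impact scaled to their actual delay) and
every expedited patient's gain (the mirror image: negative months negate
every component), then sums by decision and by diagnosis.

The net trade-off — harm to the delayed plus the (negative) harm of the
expedited — is the model's accounting of prioritisation: postponing stable
patients frees capacity whose value accrues to the patients treated
earlier.  Modelling the expedited gain as the exact negation of delay harm
is a strong symmetry assumption, surfaced rather than hidden.

Records triaged to referral, cancellation, teleconsultation, "other" or an
unchanged consultation are costed at zero impact by default, because no
delay parameters exist for those pathways; ``decision_delay_overrides``
lets a sensitivity analysis assign them a delay-equivalent duration in
months.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cost_model import SEMESTER_MONTHS, scale_by_duration, societal_delay_cost
from .errors import UnknownDiagnosisError
from .intervals import Interval
from .parameters import CostingConstants, DiagnosisProfile
from .qaly_model import QalyMode

__all__ = ["DECISIONS", "TriageCohort", "CohortResult", "cohort_aggregate"]

DECISIONS = (
    "unchanged",
    "delayed",
    "referred",
    "cancelled",
    "teleconsultation",
    "expedited",
    "other",
)

COLUMNS = ("patient_id", "diagnosis", "decision", "delay_months")

# numeric columns of the aggregation frames; interval quantities carry
# explicit lower/upper bounds
_IMPACT_COLUMNS = (
    "n",
    "qaly_lower",
    "qaly_upper",
    "medical_lower",
    "medical_upper",
    "productivity_cost",
    "informal_care_cost",
    "missed_event_cost",
    "direct_lower",
    "direct_upper",
    "societal_lower",
    "societal_upper",
)


class TriageCohort:
    """A validated table of triage records.

    Wraps a :class:`pandas.DataFrame` with columns ``patient_id``,
    ``diagnosis``, ``decision``, ``delay_months``.  Decisions come from
    the closed set :data:`DECISIONS`; ``delay_months`` must be positive
    for delayed records, negative for expedited ones, and zero otherwise.
    """

    def __init__(self, records: Union[pd.DataFrame, Sequence[Mapping]]):
        if not isinstance(records, pd.DataFrame):
            records = pd.DataFrame(list(records), columns=list(COLUMNS))
        df = records.copy()
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"cohort table lacks columns {sorted(missing)}")
        df = df.loc[:, list(COLUMNS)].reset_index(drop=True)
        if len(df):
            df["delay_months"] = df["delay_months"].astype(float)
            self._validate(df)
        else:
            df = df.astype(
                {"patient_id": object, "diagnosis": object, "decision": object,
                 "delay_months": float}
            )
        self._df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        bad_decision = ~df["decision"].isin(DECISIONS)
        if bad_decision.any():
            bad = sorted(df.loc[bad_decision, "decision"].unique())
            raise ValueError(
                f"unknown triage decisions {bad}; allowed: {list(DECISIONS)}"
            )
        delay = df["delay_months"].to_numpy()
        decision = df["decision"].to_numpy()
        problems = []
        if (delay[decision == "delayed"] <= 0).any():
            problems.append("delayed records must have delay_months > 0")
        if (delay[decision == "expedited"] >= 0).any():
            problems.append("expedited records must have delay_months < 0")
        neutral = ~np.isin(decision, ("delayed", "expedited"))
        if (delay[neutral] != 0).any():
            problems.append(
                "records that are neither delayed nor expedited must have "
                "delay_months == 0"
            )
        if problems:
            raise ValueError("invalid cohort: " + "; ".join(problems))

    # -- container protocol -------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying records as a DataFrame (copy)."""
        return self._df.copy()

    def __eq__(self, other) -> bool:
        return isinstance(other, TriageCohort) and self._df.equals(other._df)

    # -- I/O ------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "TriageCohort":
        return cls(pd.read_csv(path))

    def to_csv(self, path: Union[str, Path]) -> None:
        self._df.to_csv(path, index=False)

    def concat(self, other: "TriageCohort") -> "TriageCohort":
        return TriageCohort(
            pd.concat([self._df, other._df], ignore_index=True)
        )


@dataclass(frozen=True)
class CohortResult:
    """Aggregated delay impacts over a cohort.

    ``per_decision`` and ``per_diagnosis`` hold record counts and summed
    impact components (EUR / QALY) by stratum; ``totals`` are the grand
    sums; ``net_tradeoff_cost`` / ``net_tradeoff_qaly`` balance the harm
    to delayed patients against the mirrored gain of expedited ones.
    """

    per_decision: pd.DataFrame
    per_diagnosis: pd.DataFrame
    totals: pd.Series
    net_tradeoff_cost: Interval
    net_tradeoff_qaly: Interval


def _impact_row(impact) -> dict:
    return {
        "n": 1,
        "qaly_lower": impact.qaly_loss.lower,
        "qaly_upper": impact.qaly_loss.upper,
        "medical_lower": impact.medical_cost.lower,
        "medical_upper": impact.medical_cost.upper,
        "productivity_cost": impact.productivity_cost,
        "informal_care_cost": impact.informal_care_cost,
        "missed_event_cost": impact.missed_event_cost,
        "direct_lower": impact.direct_cost_total.lower,
        "direct_upper": impact.direct_cost_total.upper,
        "societal_lower": impact.societal_cost_total.lower,
        "societal_upper": impact.societal_cost_total.upper,
    }


def _zero_row() -> dict:
    return {c: 0 for c in _IMPACT_COLUMNS} | {"n": 1}


def cohort_aggregate(
    cohort: TriageCohort,
    profiles: Sequence[DiagnosisProfile],
    constants: CostingConstants,
    mode: Union[QalyMode, str] = QalyMode.AS_PRINTED,
    decision_delay_overrides: Optional[Mapping[str, float]] = None,
) -> CohortResult:
    """Sum per-patient delay impacts over a triage cohort.

    Each delayed/expedited record contributes its diagnosis's 6-month
    impact scaled linearly to its own ``delay_months``; other decisions
    contribute zero unless ``decision_delay_overrides`` maps them to a
    delay-equivalent duration (months) for sensitivity exploration.
    """
    overrides = dict(decision_delay_overrides or {})
    unknown = set(overrides) - set(DECISIONS)
    if unknown:
        raise ValueError(f"overrides name unknown decisions: {sorted(unknown)}")
    by_name = {p.name: p for p in profiles}
    base: dict[str, object] = {}

    df = cohort.frame
    rows = []
    for rec in df.itertuples(index=False):
        if rec.decision in ("delayed", "expedited"):
            months = float(rec.delay_months)
        else:
            months = float(overrides.get(rec.decision, 0.0))
        if months == 0.0:
            rows.append(_zero_row())
            continue
        if rec.diagnosis not in by_name:
            raise UnknownDiagnosisError(
                f"record {rec.patient_id!r}: no profile for diagnosis "
                f"{rec.diagnosis!r} (known: {sorted(by_name)})"
            )
        if rec.diagnosis not in base:
            base[rec.diagnosis] = societal_delay_cost(
                by_name[rec.diagnosis], constants, qaly_mode=mode
            )
        rows.append(_impact_row(scale_by_duration(base[rec.diagnosis], months)))

    impacts = pd.DataFrame(rows, columns=list(_IMPACT_COLUMNS), dtype=float)
    if len(impacts) == 0:
        impacts = pd.DataFrame(columns=list(_IMPACT_COLUMNS), dtype=float)
    impacts["n"] = impacts.get("n", pd.Series(dtype=float)).astype(int)

    keyed = pd.concat(
        [df[["diagnosis", "decision"]].reset_index(drop=True), impacts], axis=1
    )
    per_decision = (
        keyed.drop(columns="diagnosis").groupby("decision").sum()
        if len(keyed)
        else pd.DataFrame(columns=list(_IMPACT_COLUMNS))
    )
    per_diagnosis = (
        keyed.drop(columns="decision").groupby("diagnosis").sum()
        if len(keyed)
        else pd.DataFrame(columns=list(_IMPACT_COLUMNS))
    )
    totals = (
        impacts.sum()
        if len(impacts)
        else pd.Series({c: 0.0 for c in _IMPACT_COLUMNS})
    )

    tradeoff_mask = df["decision"].isin(["delayed", "expedited"]).to_numpy()
    trade = (
        impacts.loc[tradeoff_mask].sum()
        if len(impacts)
        else pd.Series({c: 0.0 for c in _IMPACT_COLUMNS})
    )
    # summed bounds of scaled intervals can arrive in either order once
    # negative-duration records are mixed in, so normalise
    net_cost = Interval(
        min(trade["societal_lower"], trade["societal_upper"]),
        max(trade["societal_lower"], trade["societal_upper"]),
    )
    net_qaly = Interval(
        min(trade["qaly_lower"], trade["qaly_upper"]),
        max(trade["qaly_lower"], trade["qaly_upper"]),
    )
    return CohortResult(
        per_decision=per_decision,
        per_diagnosis=per_diagnosis,
        totals=totals,
        net_tradeoff_cost=net_cost,
        net_tradeoff_qaly=net_qaly,
    )
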