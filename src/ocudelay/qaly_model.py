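"""Quality-of-life loss (QALYs) attributable to a care delay.

Two mechanisms, by symptom class:

* **symptomatic** diagnoses (cataract, dry eye): the patient lives the
  whole delay with curable symptoms, so the 6-month QALY difference is the
  utility decrement itself (the published convention, adopted here as-is;
  the alternative ``decrement x 0.5 year`` reading is documented in the
  methods note but not used).
* **stable** diagnoses (AMD, diabetic retinopathy, glaucoma): delay harms
  quality of life only if an adverse event is missed, so the decrement is
  weighted by the missed-event probability.

For glaucoma the published source is internally inconsistent: the cost
cells use an event probability of 3.1e-5 (printed "0.0031%") while the
published QALY figure of 0.00031 requires 0.0031.  Both readings are
implemented: ``as_printed`` reproduces the published figure via the
profile's ``reported_qaly_event_probability`` override, while
``internally_consistent`` uses the same probability as the cost model.
"""

from __future__ import annotations

import enum

from .intervals import Interval
from .parameters import DiagnosisProfile, SymptomClass

__all__ = ["QalyMode", "qaly_loss"]


class QalyMode(str, enum.Enum):
    """Which reading of the published QALY figures to reproduce."""

    AS_PRINTED = "as_printed"
    INTERNALLY_CONSISTENT = "internally_consistent"


def qaly_loss(
    profile: DiagnosisProfile, mode: QalyMode | str = QalyMode.AS_PRINTED
) -> Interval:
    """QALY loss per patient per 6 months of delay, as an interval.

    Always in [0, 1]; zero when the utility decrement is zero or (for
    stable disease) the event probability is zero.
    """
    mode = QalyMode(mode)
    if profile.symptom_class is SymptomClass.SYMPTOMATIC:
        return profile.utility_decrement
    factor = profile.missed_event_probability
    if (
        mode is QalyMode.AS_PRINTED
        and profile.reported_qaly_event_probability is not None
    ):
        factor = profile.reported_qaly_event_probability
    return profile.utility_decrement.scale(factor)
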