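"""Seeded synthetic triage cohorts with the structure of a remote-triage
service.

The generator emulates the published cohort of a tele-triage service that
re-triaged 3658 scheduled ophthalmic appointments: 51% left unchanged, 20%
delayed (by 6 +/- 4 months on average), 13% referred, 6% cancelled, 4%
handled by teleconsultation, 1% expedited and 5% other.  It produces only
the fields the delay model consumes (diagnosis, decision, delay months) —
no demographics, visual acuities or test results — and is fully
deterministic given a seed.

Delay durations are drawn from a normal distribution truncated below at a
minimum delay (default 1 month; a realised delay cannot be zero or
negative) and rounded to whole months.  The truncated distribution is
moment-matched: its location and scale are solved so that the *truncated*
mean and standard deviation equal the requested ones, because the
published 6 +/- 4 figure describes the realised, necessarily positive,
delays.  Expedited records receive the negated draw.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, stats

from .cohort import DECISIONS, TriageCohort

__all__ = ["CohortSpec", "generate_cohort", "truncated_delay_distribution"]

DEFAULT_DECISION_MIX: Mapping[str, float] = {
    "unchanged": 0.51,
    "delayed": 0.20,
    "referred": 0.13,
    "cancelled": 0.06,
    "teleconsultation": 0.04,
    "expedited": 0.01,
    "other": 0.05,
}

# Per-diagnosis counts of the source cohort are not published; a uniform
# mix over the five key diagnoses is the documented placeholder.
DEFAULT_DIAGNOSIS_MIX: Mapping[str, float] = {
    "cataract": 0.2,
    "des": 0.2,
    "amd": 0.2,
    "drp": 0.2,
    "glaucoma": 0.2,
}

_MIX_TOL = 1e-9


class CohortSpec(BaseModel):
    """Sampling specification for a synthetic triage cohort.

    ``delay_mean_months`` / ``delay_sd_months`` are the target moments of
    the generated (truncated-at-``delay_min_months``) delay durations.
    Proportions in each mix must sum to 1 within 1e-9.
    """

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=3658, ge=0)
    decision_mix: Mapping[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_DECISION_MIX)
    )
    diagnosis_mix: Mapping[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_DIAGNOSIS_MIX)
    )
    delay_mean_months: float = Field(default=6.0, gt=0)
    delay_sd_months: float = Field(default=4.0, ge=0)
    delay_min_months: float = Field(default=1.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        for label, mix in (
            ("decision_mix", self.decision_mix),
            ("diagnosis_mix", self.diagnosis_mix),
        ):
            bad = {k: p for k, p in mix.items() if not 0 <= p <= 1}
            if bad:
                raise ValueError(f"{label}: proportions outside [0, 1]: {bad}")
            total = sum(mix.values())
            if abs(total - 1.0) > _MIX_TOL:
                raise ValueError(f"{label}: proportions sum to {total}, not 1")
        unknown = set(self.decision_mix) - set(DECISIONS)
        if unknown:
            raise ValueError(
                f"decision_mix names unknown decisions: {sorted(unknown)}"
            )
        if self.delay_sd_months > 0 and self.delay_mean_months <= self.delay_min_months:
            raise ValueError(
                "delay_mean_months must exceed delay_min_months when the "
                "standard deviation is positive"
            )
        return self


def truncated_delay_distribution(
    mean: float, sd: float, minimum: float
) -> stats._distn_infrastructure.rv_frozen:
    """Normal distribution truncated below at ``minimum``, moment-matched so
    its truncated mean and sd equal ``mean`` and ``sd``.

    Solves for the underlying location and (log-)scale with a root finder;
    the solution exists whenever ``mean > minimum``.
    """
    if sd == 0:
        raise ValueError("degenerate distribution: sd must be > 0")

    def frozen(loc: float, scale: float):
        a = (minimum - loc) / scale
        return stats.truncnorm(a, np.inf, loc=loc, scale=scale)

    def residual(x):
        loc, log_scale = x
        d = frozen(loc, math.exp(log_scale))
        m, v = d.stats(moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(residual, x0=[mean, math.log(sd)], tol=1e-12)
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(
            f"could not moment-match truncated normal (mean={mean}, sd={sd}, "
            f"min={minimum}): {sol.message}"
        )
    loc, log_scale = sol.x
    return frozen(loc, math.exp(log_scale))


def _sample_delays(spec: CohortSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    min_months = math.ceil(spec.delay_min_months)
    if size == 0:
        return np.empty(0)
    if spec.delay_sd_months == 0:
        months = np.full(size, max(round(spec.delay_mean_months), min_months))
        return months.astype(float)
    dist = truncated_delay_distribution(
        spec.delay_mean_months, spec.delay_sd_months, spec.delay_min_months
    )
    draws = dist.rvs(size=size, random_state=rng)
    return np.maximum(np.rint(draws), min_months)


def generate_cohort(spec: CohortSpec) -> TriageCohort:
    """Generate a synthetic triage cohort; identical specs (incl. seed)
    yield identical cohorts."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    decisions = list(spec.decision_mix)
    decision_draw = rng.choice(
        len(decisions), size=n, p=[spec.decision_mix[d] for d in decisions]
    )
    decision = np.array(decisions, dtype=object)[decision_draw]

    diagnoses = list(spec.diagnosis_mix)
    diagnosis_draw = rng.choice(
        len(diagnoses), size=n, p=[spec.diagnosis_mix[d] for d in diagnoses]
    )
    diagnosis = np.array(diagnoses, dtype=object)[diagnosis_draw]

    delay = np.zeros(n)
    delayed = decision == "delayed"
    expedited = decision == "expedited"
    delay[delayed] = _sample_delays(spec, int(delayed.sum()), rng)
    delay[expedited] = -_sample_delays(spec, int(expedited.sum()), rng)

    return TriageCohort(
        pd.DataFrame(
            {
                "patient_id": [f"P{i:06d}" for i in range(n)],
                "diagnosis": diagnosis,
                "decision": decision,
                "delay_months": delay,
            }
        )
    )
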