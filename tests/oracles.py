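"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: each is a single
closed-form expression over raw numbers, so agreement with the
implementation is a genuine cross-check rather than a tautology.
"""


def societal_cost_oracle(
    medical_delta: float,
    working_population_fraction: float,
    event_probability: float,
    event_bundle_cost: float,
    policy: str,
    wage: float,
    workweek_hours: float,
    working_weeks: float,
    productivity_loss: float,
    employed_fraction: float,
    informal_hours: float,
    informal_rate: float,
    informal_weeks: float,
) -> float:
    """Six-month societal cost of delay as one flat expression."""
    prod_factor = {
        "full": 1.0,
        "productivity_only": 1.0,
        "event_conditional": event_probability,
        "none": 0.0,
    }[policy]
    informal_factor = {
        "full": 1.0,
        "productivity_only": 0.0,
        "event_conditional": event_probability,
        "none": 0.0,
    }[policy]
    return (
        medical_delta
        + wage
        * workweek_hours
        * working_weeks
        * productivity_loss
        * employed_fraction
        * working_population_fraction
        * prod_factor
        + informal_hours * informal_rate * informal_weeks * informal_factor
        + event_probability * event_bundle_cost
    )
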