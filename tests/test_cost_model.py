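"""Cost components, totals, duration scaling, and the published worksheet."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ocudelay import (
    CostingConstants,
    DiagnosisProfile,
    InclusionPolicy,
    Interval,
    base_semester_productivity_value,
    cost_breakdown,
    expected_missed_event_cost,
    informal_care_cost,
    productivity_cost,
    scale_by_duration,
    societal_delay_cost,
)
from ocudelay.errors import ConfigurationError

from .oracles import societal_cost_oracle

CENT = 0.01  # tolerance matching values printed to the cent


class TestBaseProductivity:
    def test_default_value(self, constants):
        # 39.88 x 32.2 x 23.5 x 0.2058 x 0.7039, hand-checked
        assert base_semester_productivity_value(constants) == pytest.approx(
            4371.55, abs=CENT
        )

    def test_zero_loss_fraction_gives_zero(self, constants):
        c = constants.model_copy(update={"productivity_loss_fraction": 0.0})
        assert base_semester_productivity_value(c) == 0.0

    def test_unit_factors_give_one(self):
        c = CostingConstants(
            wage_per_hour=1, workweek_hours=1,
            productivity_working_weeks_per_half_year=1,
            productivity_loss_fraction=1, employed_labour_force_fraction=1,
        )
        assert base_semester_productivity_value(c) == 1.0


# Every numeric cell of the published costing worksheet, reproduced from
# the default parameter set to within one cent.
WORKSHEET = {
    # diagnosis/bound: (medical, event, productivity, informal, direct, societal)
    "cataract": (0.0, 0.0, 463.38, 2835.04, 0.0, 3298.42),
    "amd (upper)": (-581.32, 276.66, 86.92, 1672.67, -304.65, 1454.94),
    "amd (lower)": (-663.09, 276.66, 86.92, 1672.67, -386.42, 1373.17),
    "drp": (-85.84, 17.35, 80.87, 104.90, -68.49, 117.28),
    "glaucoma": (-408.78, 0.02, 0.03, 0.09, -408.77, -408.65),
    "des": (-423.91, 0.0, 2579.65, 0.0, -423.91, 2155.74),
}


class TestWorksheetReconstruction:
    @pytest.mark.parametrize("row", sorted(WORKSHEET))
    def test_every_cell_within_one_cent(self, defaults, row):
        constants, profs = defaults
        name = row.split(" ")[0]
        profile = {p.name: p for p in profs}[name]
        delta = profile.medical_cost_delta_semester
        bound = delta.upper if "upper" in row or delta.is_point else delta.lower
        variant = profile.model_copy(
            update={"medical_cost_delta_semester": Interval.point(bound)}
        )
        impact = societal_delay_cost(variant, constants)
        medical, event, prod, informal, direct, societal = WORKSHEET[row]
        assert impact.medical_cost.lower == pytest.approx(medical, abs=CENT)
        assert impact.missed_event_cost == pytest.approx(event, abs=CENT)
        assert impact.productivity_cost == pytest.approx(prod, abs=CENT)
        assert impact.informal_care_cost == pytest.approx(informal, abs=CENT)
        assert impact.direct_cost_total.lower == pytest.approx(direct, abs=CENT)
        assert impact.societal_cost_total.lower == pytest.approx(societal, abs=CENT)

    def test_breakdown_table_matches_worksheet(self, defaults):
        df = cost_breakdown(*defaults)
        for row, cells in WORKSHEET.items():
            assert df.loc[row, "societal_cost_total"] == pytest.approx(
                cells[-1], abs=CENT
            )

    def test_unrounded_summation_reproduces_glaucoma_total(self, defaults):
        # summing components already rounded to cents would give -408.64;
        # only full-precision accumulation yields the published -408.65
        constants, profs = defaults
        g = {p.name: p for p in profs}["glaucoma"]
        impact = societal_delay_cost(g, constants)
        rounded_components = sum(
            round(v, 2)
            for v in (
                impact.medical_cost.lower,
                impact.productivity_cost,
                impact.informal_care_cost,
                impact.missed_event_cost,
            )
        )
        assert round(rounded_components, 2) == -408.64
        assert round(impact.societal_cost_total.lower, 2) == -408.65


class TestAmdBounds:
    def test_interval_totals_propagate_bound_wise(self, constants, profiles):
        impact = societal_delay_cost(profiles["amd"], constants)
        assert impact.societal_cost_total.lower == pytest.approx(1373.17, abs=CENT)
        assert impact.societal_cost_total.upper == pytest.approx(1454.94, abs=CENT)
        assert impact.direct_cost_total.lower == pytest.approx(-386.42, abs=CENT)
        assert impact.direct_cost_total.upper == pytest.approx(-304.65, abs=CENT)


class TestMissedEvents:
    def test_unknown_item_raises_configuration_error(self, constants):
        p = DiagnosisProfile(
            name="x", missed_event_probability=0.1,
            missed_event_items=("imaginary_item",),
        )
        with pytest.raises(ConfigurationError, match="imaginary_item"):
            expected_missed_event_cost(p, constants)

    def test_zero_probability_gives_zero(self, constants, profiles):
        p = profiles["amd"].model_copy(update={"missed_event_probability": 0.0})
        assert expected_missed_event_cost(p, constants) == 0.0


# ---------------------------------------------------------------------------
# property-based checks against the independent oracle
# ---------------------------------------------------------------------------

policies = st.sampled_from(list(InclusionPolicy))
fractions = st.floats(0, 1, allow_nan=False)
money = st.floats(0, 500, allow_nan=False)


@st.composite
def random_case(draw):
    constants = CostingConstants(
        wage_per_hour=draw(st.floats(0, 100)),
        workweek_hours=draw(st.floats(1, 60)),
        productivity_working_weeks_per_half_year=draw(st.floats(1, 26)),
        informal_care_weeks_per_half_year=draw(st.floats(1, 26)),
        productivity_loss_fraction=draw(fractions),
        employed_labour_force_fraction=draw(fractions),
        informal_care_hours_per_week=draw(st.floats(0.1, 40)),
        informal_care_rate_per_hour=draw(st.floats(0, 60)),
        unit_costs={"a": draw(money), "b": draw(money)},
    )
    profile = DiagnosisProfile(
        name="random",
        medical_cost_delta_semester=draw(st.floats(-1000, 1000)),
        utility_decrement=draw(fractions),
        working_population_fraction=draw(fractions),
        missed_event_probability=draw(fractions),
        missed_event_items=("a", "b"),
        inclusion_policy=draw(policies),
    )
    return constants, profile


@given(case=random_case())
def test_oracle_equivalence(case):
    """The assembled model equals a flat single-expression computation."""
    constants, profile = case
    impact = societal_delay_cost(profile, constants)
    expected = societal_cost_oracle(
        profile.medical_cost_delta_semester.lower,
        profile.working_population_fraction,
        profile.missed_event_probability,
        sum(constants.unit_costs[i] for i in profile.missed_event_items),
        profile.inclusion_policy.value,
        constants.wage_per_hour,
        constants.workweek_hours,
        constants.productivity_working_weeks_per_half_year,
        constants.productivity_loss_fraction,
        constants.employed_labour_force_fraction,
        constants.informal_care_hours_per_week,
        constants.informal_care_rate_per_hour,
        constants.informal_care_weeks_per_half_year,
    )
    assert math.isclose(
        impact.societal_cost_total.lower, expected, rel_tol=1e-9, abs_tol=1e-9
    )


@given(case=random_case())
def test_additivity_of_components(case):
    constants, profile = case
    impact = societal_delay_cost(profile, constants)
    for bound in ("lower", "upper"):
        assert getattr(impact.societal_cost_total, bound) == pytest.approx(
            getattr(impact.medical_cost, bound)
            + impact.productivity_cost
            + impact.informal_care_cost
            + impact.missed_event_cost,
            rel=1e-12, abs=1e-9,
        )
        assert getattr(impact.direct_cost_total, bound) == pytest.approx(
            getattr(impact.medical_cost, bound) + impact.missed_event_cost,
            rel=1e-12, abs=1e-9,
        )


@given(case=random_case())
def test_policy_ordering(case):
    """Non-medical societal costs: full >= event_conditional >= none."""
    constants, profile = case
    by_policy = {}
    for policy in (InclusionPolicy.FULL, InclusionPolicy.EVENT_CONDITIONAL,
                   InclusionPolicy.NONE):
        p = profile.model_copy(update={"inclusion_policy": policy})
        by_policy[policy] = productivity_cost(p, constants) + informal_care_cost(
            p, constants
        )
    eps = 1e-9
    assert by_policy[InclusionPolicy.FULL] >= by_policy[
        InclusionPolicy.EVENT_CONDITIONAL
    ] - eps
    assert by_policy[InclusionPolicy.EVENT_CONDITIONAL] >= by_policy[
        InclusionPolicy.NONE
    ] - eps


@given(case=random_case(), bump=st.floats(0.001, 0.5))
def test_monotonicity(case, bump):
    """Societal total is non-decreasing in event probability, wage and
    informal-care hours."""
    constants, profile = case
    base = societal_delay_cost(profile, constants).societal_cost_total.lower
    eps = 1e-9

    p2 = profile.model_copy(update={
        "missed_event_probability": min(1.0, profile.missed_event_probability + bump)
    })
    assert societal_delay_cost(p2, constants).societal_cost_total.lower >= base - eps

    c2 = constants.model_copy(update={"wage_per_hour": constants.wage_per_hour + bump})
    assert societal_delay_cost(profile, c2).societal_cost_total.lower >= base - eps

    c3 = constants.model_copy(update={
        "informal_care_hours_per_week": constants.informal_care_hours_per_week + bump
    })
    assert societal_delay_cost(profile, c3).societal_cost_total.lower >= base - eps


class TestDurationScaling:
    def test_six_months_is_identity(self, constants, profiles):
        impact = societal_delay_cost(profiles["cataract"], constants)
        assert scale_by_duration(impact, 6) == impact

    def test_zero_months_zeroes_everything(self, constants, profiles):
        z = scale_by_duration(societal_delay_cost(profiles["amd"], constants), 0)
        assert z.societal_cost_total == Interval.point(0.0)
        assert z.qaly_loss == Interval.point(0.0)
        assert z.productivity_cost == 0.0

    def test_negative_months_negate(self, constants, profiles):
        impact = societal_delay_cost(profiles["cataract"], constants)
        mirrored = scale_by_duration(impact, -6)
        assert mirrored.societal_cost_total.lower == pytest.approx(
            -3298.42, abs=CENT
        )
        assert mirrored.productivity_cost == -impact.productivity_cost
        assert mirrored.qaly_loss == -impact.qaly_loss

    @pytest.mark.parametrize("months", [1, 3, 12, -3])
    def test_linearity(self, constants, profiles, months):
        impact = societal_delay_cost(profiles["drp"], constants)
        scaled = scale_by_duration(impact, months)
        f = months / 6
        assert scaled.societal_cost_total.midpoint == pytest.approx(
            impact.societal_cost_total.midpoint * f
        )
        assert scaled.missed_event_cost == pytest.approx(impact.missed_event_cost * f)
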