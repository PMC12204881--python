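"""Engine equations: duration cascade, discounting helpers, and the three
pathway simulators checked against independently hand-computed examples."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from meicost.engine import (
    annual_checkup_cost,
    compute_top,
    event_year,
    present_value,
    run_cohort,
    simulate_group1,
    simulate_group2,
    simulate_group3,
    to_frame,
    upgrade_schedule,
)

from conftest import make_draws


@pytest.mark.parametrize(
    "ages, expected_top",
    [
        ((54.0, 10.0, 10.0), 27),  # clean candidate passes every check
        ((90.0, 100.0, 50.0), 31),  # first two fall below 1, third accepted
        ((90.0, 100.0, 95.0), 1),  # all below 1, floor at 1
        ((3.0, 54.0, 10.0), 27),  # above upper check, falls back to AFIb
        ((3.0, 2.0, 1.0), 76),  # all above, AFIc used then clamped at LEX-MIA
    ],
)
def test_top_cascade(ages, expected_top):
    top, afi = compute_top(*ages, lex=81, mia=5)
    assert top == expected_top
    assert afi == 81 - top


@given(st.tuples(*[st.floats(min_value=-50, max_value=130)] * 3))
def test_top_cascade_is_total_and_bounded(ages):
    top, afi = compute_top(*ages, lex=81, mia=5)
    assert 1 <= top <= 76
    assert afi == 81 - top


@pytest.mark.parametrize("t, expected", [(2.4, 2), (0.0, 0), (10.5, 10), (0.49, 0), (1.5, 1)])
def test_event_year(t, expected):
    assert event_year(t) == expected


def test_event_year_rejects_negative_times():
    with pytest.raises(ValueError):
        event_year(-0.1)


def test_present_value():
    assert present_value(1000, 0, 0.05) == 1000
    assert present_value(1000, 1, 0.05) == pytest.approx(952.381, abs=1e-3)
    assert present_value(5719.9, 7, 0.05) == pytest.approx(4065.03, abs=0.01)
    with pytest.raises(ValueError):
        present_value(100, -1, 0.05)


def test_annual_checkup_cost():
    assert annual_checkup_cost(145, 1, 0.05) == 0
    assert annual_checkup_cost(145, 2, 0.05) == pytest.approx(138.0952, abs=1e-4)
    assert annual_checkup_cost(145, 10, 0.05) == pytest.approx(1030.634, abs=1e-3)
    assert annual_checkup_cost(145, 10, 0.0) == 145 * 9  # analytic zero-rate limit
    with pytest.raises(ValueError):
        annual_checkup_cost(145, 0, 0.05)


def test_upgrade_schedule():
    assert upgrade_schedule(7, 10) == [7]
    assert upgrade_schedule(7, 26) == [7, 14, 21]
    assert upgrade_schedule(6, 76) == [6 * k for k in range(1, 13)]  # cap binds
    assert upgrade_schedule(7, 17, offset=3) == [10, 17]
    with pytest.raises(ValueError):
        upgrade_schedule(0, 10)


def test_group1_no_event_run(params):
    """TOP 10, no failures/revisions, one upgrade at year 7."""
    o = simulate_group1(make_draws(afia=71.0, isb=14409.0), params)
    assert (o.top, o.noi, o.nor, o.nop) == (10, 1, 0, 1)
    assert o.cfi == pytest.approx(14844.0)
    assert o.apu == pytest.approx(4065.03, abs=0.01)
    assert o.tsc == pytest.approx(1030.63, abs=0.01)
    assert o.ltc == pytest.approx(19939.66, abs=0.01)


def test_group1_zero_discount_totals(params):
    p0 = params.model_copy(update={"discount_rate": 0.0})
    o = simulate_group1(make_draws(afia=71.0, isb=14409.0), p0)
    assert o.ltc == pytest.approx(14844.0 + 5719.9 + 145 * 9, abs=1e-9)


def test_group1_with_reimplantation(params):
    """TOP 20, one failure at 9.4 years, upgrades at 7 and 14."""
    o = simulate_group1(
        make_draws(afia=61.0, isb=14000.0, lts=[9.4, 400.0, 400.0]), params
    )
    assert (o.top, o.noi, o.first_failure_year) == (20, 2, 9)
    assert o.cfi == pytest.approx(14435.0)
    assert o.cri == pytest.approx(9211.46, abs=0.01)
    assert o.apu == pytest.approx(6953.96, abs=0.01)
    assert o.tsc == pytest.approx(1752.37, abs=0.01)
    assert o.ltc == pytest.approx(32352.80, abs=0.01)


def test_group2_worked_example(params):
    """TOP 20, 2 surgeries over THI 3 years, implant at year 3."""
    o = simulate_group2(
        make_draws(afia=61.0, isb=14000.0, thit=3.2, dsh=[2.4, 10.0] + [400.0] * 13),
        params,
    )
    assert (o.top, o.thi, o.tsb, o.nhi) == (20, 3, 17, 2)
    assert o.cfi == pytest.approx(4290.0)
    assert o.cfs == pytest.approx(3759.64, abs=0.01)
    assert o.vsb == pytest.approx(12344.24, abs=0.01)
    assert o.apu == pytest.approx(6007.10, abs=0.01)
    assert o.tsc == pytest.approx(1752.37, abs=0.01)
    assert o.ltc == pytest.approx(28153.34, abs=0.01)


def test_group2_surgical_phase_caps(params):
    # the surgical phase never exceeds TOP: the implant is still charged,
    # at the end of life, even though no implant years remain
    o = simulate_group2(make_draws(afia=61.0, isb=14000.0, thit=30.0), params)
    assert (o.thi, o.tsb, o.noi, o.nor, o.nop) == (20, 0, 1, 0, 0)
    assert o.vsb == pytest.approx(14290.0 / 1.05**20, abs=1e-9)
    # ... and never exceeds the 25-year cap
    o = simulate_group2(make_draws(afia=30.0, thit=40.0), params)
    assert o.thi == 25


def test_group2_undermodelled_run_is_flagged(params):
    o = simulate_group2(make_draws(afia=30.0, thit=40.0, dsh=[2.0] * 15), params)
    assert o.thi == 25
    assert o.nhi == 6
    assert o.ep_nhi == pytest.approx(13.0)
    assert o.care_gap == pytest.approx(13.0)


def test_group3_worked_example(params):
    """TOP 5, three surgeries (initial, year 2 and year 4)."""
    o = simulate_group3(
        make_draws(afia=76.0, dsh=[2.4, 1.8, 10.0] + [400.0] * 12), params
    )
    assert (o.top, o.nhi) == (5, 3)
    assert o.cfi == pytest.approx(4290.0)
    assert o.cfs == pytest.approx(7169.74, abs=0.01)
    assert o.tsc == pytest.approx(514.16, abs=0.01)
    assert o.ltc == pytest.approx(11973.90, abs=0.01)


def test_group3_care_gap(params):
    o = simulate_group3(make_draws(afia=41.0, dsh=[2.0] * 15), params)
    assert (o.top, o.nhi) == (40, 15)
    assert o.ep_nhi == pytest.approx(10.0)
    assert o.care_gap == pytest.approx(10.0)
    assert o.successful_years == pytest.approx(30.0)


def test_group3_single_year_run(params):
    o = simulate_group3(make_draws(afia=80.0, dsh=[5.0] + [400.0] * 14), params)
    assert (o.top, o.nhi) == (1, 1)
    assert o.cfs == 0.0
    assert o.tsc == 0.0
    assert o.ltc == pytest.approx(o.cfi)


def test_lifetime_cost_monotone_in_duration_for_g1_and_g3(params):
    """Longer horizons only add (discounted) events for the implant-only and
    surgery-only pathways."""
    draws = dict(isb=14000.0, lts=[9.4, 30.0, 400.0], ttr=[4.2, 50.0, 200.0, 200.0],
                 dsh=[2.4, 1.8] + [3.0] * 13)
    for sim in (simulate_group1, simulate_group3):
        prev = -1.0
        for top in range(1, 77):
            o = sim(make_draws(afia=float(81 - top), **draws), params)
            assert o.top == top
            assert o.ltc >= prev - 1e-9
            prev = o.ltc


def test_group2_cost_can_decrease_with_duration(params):
    """Characterization: a longer horizon can delay the implant (THI grows
    with TOP up to round(THIt)) and shrink its present value by more than
    the added check-up costs, so group 2 is not monotone in TOP."""
    lo = simulate_group2(make_draws(afia=76.0, thit=10.0, dsh=[20.0] * 15), params)
    hi = simulate_group2(make_draws(afia=75.0, thit=10.0, dsh=[20.0] * 15), params)
    assert hi.top == lo.top + 1
    assert hi.ltc < lo.ltc


def test_component_sums(params):
    rng = np.random.default_rng(3)
    from meicost.sampling import draw_run

    for _ in range(50):
        d = draw_run(params, rng)
        o1 = simulate_group1(d, params)
        assert o1.ltc == pytest.approx(o1.cfi + o1.cri + o1.cre + o1.apu + o1.tsc, rel=1e-12)
        o2 = simulate_group2(d, params)
        assert o2.ltc == pytest.approx(
            o2.cfi + o2.cfs + o2.vsb + o2.cri + o2.cre + o2.apu + o2.tsc, rel=1e-12
        )
        o3 = simulate_group3(d, params)
        assert o3.ltc == pytest.approx(o3.cfi + o3.cfs + o3.tsc, rel=1e-12)


def test_run_cohort_validation(params):
    with pytest.raises(ValueError):
        run_cohort(params, "g9", 5, 1)
    with pytest.raises(ValueError):
        run_cohort(params, "g1", 0, 1)


def test_run_cohort_determinism_and_prefix_property(params):
    a = run_cohort(params, "g1", 30, 123)
    b = run_cohort(params, "g1", 30, 123)
    assert a == b
    # runs are indexed substreams: a longer cohort extends a shorter one
    c = run_cohort(params, "g1", 50, 123)
    assert c[:30] == a
    # a different seed changes the draws
    assert run_cohort(params, "g1", 30, 124) != a


def test_to_frame(params):
    frame = to_frame(run_cohort(params, "g3", 20, 1))
    assert len(frame) == 20
    assert {"top", "nhi", "ltc", "care_gap"} <= set(frame.columns)
    with pytest.raises(ValueError):
        to_frame([])
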