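"""Unit and property tests for the NEWS2 rubric and the NEWS2-L composite."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from news2l.scoring import (
    AVPU,
    ScoringError,
    SpO2Scale,
    VitalSigns,
    compute_news2,
    compute_news2_l,
    score_consciousness,
    score_pulse,
    score_respiratory_rate,
    score_spo2,
    score_supplemental_oxygen,
    score_systolic_bp,
    score_temperature,
)

# ---------------------------------------------------------------------------
# every chart cell, including both edges of every band
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rr,expected", [
    (0, 3), (5, 3), (8, 3), (9, 1), (11, 1), (12, 0), (16, 0), (20, 0),
    (21, 2), (22, 2), (24, 2), (25, 3), (40, 3),
])
def test_respiratory_rate_bands(rr, expected):
    assert score_respiratory_rate(rr) == expected


@pytest.mark.parametrize("spo2,expected", [
    (70, 3), (91, 3), (92, 2), (93, 2), (94, 1), (95, 1), (96, 0), (100, 0),
])
@pytest.mark.parametrize("on_oxygen", [False, True])
def test_spo2_scale1_bands_ignore_oxygen(spo2, expected, on_oxygen):
    assert score_spo2(spo2, SpO2Scale.SCALE1, on_oxygen) == expected


@pytest.mark.parametrize("spo2,on_oxygen,expected", [
    (80, False, 3), (83, False, 3), (84, False, 2), (85, False, 2),
    (86, False, 1), (87, False, 1), (88, False, 0), (92, False, 0),
    (93, False, 0), (97, False, 0), (100, False, 0),
    (83, True, 3), (88, True, 0), (92, True, 0),
    (93, True, 1), (94, True, 1), (95, True, 2), (96, True, 2),
    (97, True, 3), (100, True, 3),
])
def test_spo2_scale2_bands(spo2, on_oxygen, expected):
    assert score_spo2(spo2, SpO2Scale.SCALE2, on_oxygen) == expected


@pytest.mark.parametrize("on_oxygen,expected", [(True, 2), (False, 0)])
def test_supplemental_oxygen(on_oxygen, expected):
    assert score_supplemental_oxygen(on_oxygen) == expected


@pytest.mark.parametrize("t,expected", [
    (33.0, 3), (34.9, 3), (35.0, 3), (35.1, 1), (36.0, 1), (36.1, 0),
    (37.0, 0), (38.0, 0), (38.1, 1), (39.0, 1), (39.1, 2), (41.0, 2),
])
def test_temperature_bands(t, expected):
    assert score_temperature(t) == expected


def test_temperature_is_banded_at_one_decimal():
    # 38.05 rounds half-up to 38.1, so the apparent 38.0->38.1 gap is closed
    assert score_temperature(38.05) == 1
    assert score_temperature(38.04) == 0
    assert score_temperature(35.04) == 3


@pytest.mark.parametrize("sbp,expected", [
    (60, 3), (90, 3), (91, 2), (100, 2), (101, 1), (105, 1), (110, 1),
    (111, 0), (127, 0), (219, 0), (220, 3), (260, 3),
])
def test_systolic_bp_bands(sbp, expected):
    assert score_systolic_bp(sbp) == expected


@pytest.mark.parametrize("hr,expected", [
    (30, 3), (40, 3), (41, 1), (50, 1), (51, 0), (71, 0), (90, 0),
    (91, 1), (110, 1), (111, 2), (120, 2), (130, 2), (131, 3), (180, 3),
])
def test_pulse_bands(hr, expected):
    assert score_pulse(hr) == expected


@pytest.mark.parametrize("gcs,expected", [(15, 0), (14, 3), (8, 3), (3, 3)])
def test_consciousness_gcs(gcs, expected):
    assert score_consciousness(gcs=gcs) == expected


@pytest.mark.parametrize("avpu,expected", [
    (AVPU.ALERT, 0), (AVPU.VERBAL, 3), (AVPU.PAIN, 3), (AVPU.UNRESPONSIVE, 3),
    ("A", 0), ("U", 3),
])
def test_consciousness_avpu(avpu, expected):
    assert score_consciousness(avpu=avpu) == expected


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def test_domain_errors():
    with pytest.raises(ScoringError):
        score_respiratory_rate(-1)
    with pytest.raises(ScoringError):
        score_spo2(101)
    with pytest.raises(ScoringError):
        score_consciousness(gcs=15, avpu=AVPU.ALERT)
    with pytest.raises(ScoringError):
        score_consciousness()
    with pytest.raises(ScoringError):
        score_consciousness(gcs=2)
    with pytest.raises(ScoringError):
        VitalSigns(16, 96, False, 36.5, 120, 70)  # no consciousness input


# ---------------------------------------------------------------------------
# aggregate score
# ---------------------------------------------------------------------------

def _vitals(**kw):
    base = dict(respiratory_rate=16, spo2=96, on_supplemental_oxygen=False,
                temperature=36.5, systolic_bp=127, heart_rate=71, gcs=15)
    base.update(kw)
    return VitalSigns(**base)


def test_all_normal_scores_zero_with_no_flags():
    b = compute_news2(_vitals())
    assert b.total == 0
    assert not b.any_single_three and not b.urgent_review and not b.critical_review


def test_mixed_observation_set_sums_cell_weights():
    b = compute_news2(_vitals(respiratory_rate=22, spo2=93, temperature=35.7,
                              systolic_bp=105, heart_rate=82, gcs=14))
    assert b.sub_scores == {
        "respiratory_rate": 2, "spo2": 2, "supplemental_oxygen": 0,
        "temperature": 1, "systolic_bp": 1, "heart_rate": 0, "consciousness": 3,
    }
    assert b.total == 9
    assert b.urgent_review and b.critical_review


def test_structural_maximum_is_twenty():
    b = compute_news2(VitalSigns(
        respiratory_rate=8, spo2=83, on_supplemental_oxygen=True,
        temperature=34.9, systolic_bp=90, heart_rate=40, gcs=3,
        spo2_scale=SpO2Scale.SCALE2))
    assert b.total == 20
    assert all(v == 3 for k, v in b.sub_scores.items() if k != "supplemental_oxygen")


def test_single_red_parameter_triggers_urgent_but_not_critical():
    b = compute_news2(_vitals(respiratory_rate=8))
    assert b.total == 3
    assert b.any_single_three and b.urgent_review and not b.critical_review


def test_missing_vital_is_named():
    with pytest.raises(ScoringError, match="temperature"):
        compute_news2(_vitals(temperature=float("nan")))


def test_bands_partition_every_input_domain():
    """Each rubric function returns exactly one valid weight everywhere."""
    for rr in range(0, 81):
        assert score_respiratory_rate(rr) in {0, 1, 2, 3}
    for spo2 in range(0, 101):
        for scale in SpO2Scale:
            for o2 in (False, True):
                assert score_spo2(spo2, scale, o2) in {0, 1, 2, 3}
    for sbp in range(0, 301):
        assert score_systolic_bp(sbp) in {0, 1, 2, 3}
    for hr in range(0, 251):
        assert score_pulse(hr) in {0, 1, 2, 3}
    for t10 in range(250, 451):
        assert score_temperature(t10 / 10.0) in {0, 1, 2, 3}


_WORSENING = {
    # representative values ordered by non-decreasing sub-score weight
    "respiratory_rate": [16, 10, 22, 8],
    "spo2": [96, 94, 92, 91],
    "temperature": [37.0, 36.0, 39.5, 34.0],
    "systolic_bp": [150, 105, 95, 85],
    "heart_rate": [70, 100, 120, 135],
    "gcs": [15, 14],
}


@pytest.mark.parametrize("param,values", _WORSENING.items())
def test_total_monotone_when_one_parameter_worsens(param, values):
    totals = [compute_news2(_vitals(**{param: v})).total for v in values]
    assert totals == sorted(totals)


vitals_strategy = st.builds(
    _vitals,
    respiratory_rate=st.integers(0, 60),
    spo2=st.integers(50, 100),
    on_supplemental_oxygen=st.booleans(),
    temperature=st.integers(250, 450).map(lambda t: t / 10.0),
    systolic_bp=st.integers(40, 280),
    heart_rate=st.integers(20, 220),
    gcs=st.integers(3, 15),
)


@settings(max_examples=200, derandomize=True)
@given(v=vitals_strategy)
def test_total_bounds_and_flag_consistency(v):
    b = compute_news2(v)
    assert 0 <= b.total <= 20
    assert b.total == sum(b.sub_scores.values())
    if b.critical_review:
        assert b.urgent_review
    if b.any_single_three:
        assert b.urgent_review


@settings(max_examples=200, derandomize=True)
@given(spo2=st.integers(0, 100), on_oxygen=st.booleans())
def test_scale1_spo2_independent_of_oxygen(spo2, on_oxygen):
    assert score_spo2(spo2, SpO2Scale.SCALE1, on_oxygen) == score_spo2(
        spo2, SpO2Scale.SCALE1, False)


# ---------------------------------------------------------------------------
# NEWS2-L composite
# ---------------------------------------------------------------------------

def test_composite_examples():
    assert compute_news2_l(0, 0.8).news2_l == pytest.approx(0.8)
    assert compute_news2_l(11, 5.2).news2_l == pytest.approx(16.2)
    assert compute_news2_l(3, 2.6).news2_l == pytest.approx(5.6)


@settings(max_examples=200, derandomize=True)
@given(total=st.integers(0, 20),
       lactate=st.floats(0.01, 30.0, allow_nan=False, allow_infinity=False))
def test_composite_is_exact_addition(total, lactate):
    c = compute_news2_l(total, lactate)
    assert c.news2_l == total + lactate  # float addition, stored unmodified
    assert c.news2_l - c.lactate == pytest.approx(total, abs=1e-9)


def test_composite_lactate_validation():
    assert not compute_news2_l(5, 1.0).lactate_out_of_range
    assert compute_news2_l(5, 0.5).lactate_out_of_range
    assert compute_news2_l(5, 22.0).lactate_out_of_range
    with pytest.raises(ScoringError):
        compute_news2_l(5, 0.0)
    with pytest.raises(ScoringError):
        compute_news2_l(5, -1.0)
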