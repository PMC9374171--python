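"""Instrument scoring: hand-worked fixtures and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sleeppi as sp
from sleeppi.errors import ConfigurationError, ScoringError
from sleeppi.scoring import (
    DEFAULT_NQ_WEIGHTS,
    SampleSizeParams,
    score_berlin,
    score_gsrs,
    score_nq,
    score_psqi,
)
from sleeppi.synthetic import BERLIN_CAT1_ITEMS, BERLIN_CAT2_ITEMS, GSRS_ITEMS

from conftest import best_psqi_items


# ---------------------------------------------------------------------------
# PSQI
# ---------------------------------------------------------------------------


def test_psqi_floor_case():
    comps, total, flag = score_psqi(best_psqi_items())
    assert comps == (0,) * 7
    assert total == 0 and flag is False


def test_psqi_hand_scored_components():
    """45-min latency + weekly trouble, 5.5 h sleep in 8 h bed time."""
    items = best_psqi_items()
    items.update(
        psqi_latency_min=45.0,  # band 2; +1 frequency -> raw 3 -> component 2
        psqi_q5a=1,
        psqi_sleep_hours=5.5,   # 5-6 h band -> 2
        psqi_bed_hours=8.0,     # efficiency 68.75% -> 2
    )
    comps, total, flag = score_psqi(items)
    assert comps[1] == 2 and comps[2] == 2 and comps[3] == 2
    assert total == 6 and flag is True


def test_psqi_disturbance_flag_threshold():
    items = best_psqi_items()
    items.update(psqi_quality=3, psqi_medication=3)  # global 6
    assert score_psqi(items)[1:] == (6, True)
    items.update(psqi_medication=2)  # global 5
    assert score_psqi(items)[1:] == (5, False)


def test_psqi_missing_item_is_an_error():
    items = best_psqi_items()
    del items["psqi_q5c"]
    with pytest.raises(ScoringError, match="psqi_q5c"):
        score_psqi(items)
    items = best_psqi_items()
    items["psqi_quality"] = float("nan")
    with pytest.raises(ScoringError, match="psqi_quality"):
        score_psqi(items)


_ORDINAL_PSQI = [
    "psqi_q5a", "psqi_quality", "psqi_medication", "psqi_daysleepy",
    "psqi_enthusiasm", *sp.synthetic.PSQI_DISTURBANCE_ITEMS,
]


@settings(max_examples=60, deadline=None)
@given(
    data=st.data(),
    levels=st.lists(st.integers(0, 3), min_size=len(_ORDINAL_PSQI),
                    max_size=len(_ORDINAL_PSQI)),
    latency=st.floats(0, 180), sleep=st.floats(1, 10), extra_bed=st.floats(0.1, 6),
)
def test_psqi_global_bounded_and_monotone(data, levels, latency, sleep, extra_bed):
    """Global score stays in [0, 21]; worsening one item never lowers it."""
    items = dict(zip(_ORDINAL_PSQI, levels))
    items.update(
        psqi_latency_min=latency, psqi_sleep_hours=sleep,
        psqi_bed_hours=sleep + extra_bed,
    )
    _, total, _ = score_psqi(items)
    assert 0 <= total <= 21
    worsened = dict(items)
    which = data.draw(st.sampled_from(_ORDINAL_PSQI + ["psqi_latency_min", "psqi_sleep_hours"]))
    if which == "psqi_latency_min":
        worsened[which] = latency + 30
    elif which == "psqi_sleep_hours":
        worsened[which] = max(sleep - 1.0, 0.5)
    else:
        worsened[which] = min(int(items[which]) + 1, 3)
    _, worse_total, _ = score_psqi(worsened)
    assert worse_total >= total


# ---------------------------------------------------------------------------
# Berlin
# ---------------------------------------------------------------------------


def _berlin_items(cat1_pos=0, cat2_pos=0):
    items = {n: False for n in BERLIN_CAT1_ITEMS + BERLIN_CAT2_ITEMS}
    items["berlin_c2_drive"] = False
    for n in BERLIN_CAT1_ITEMS[:cat1_pos]:
        items[n] = True
    for n in BERLIN_CAT2_ITEMS[:cat2_pos]:
        items[n] = True
    return items


def test_berlin_all_negative_is_low_risk():
    assert score_berlin(_berlin_items(), bmi=24.0, bp_history=False) == (
        False, False, False, "low",
    )


def test_berlin_two_positive_categories_is_high_risk():
    cat1, cat2, cat3, risk = score_berlin(_berlin_items(2, 2), bmi=24.0, bp_history=False)
    assert (cat1, cat2, cat3, risk) == (True, True, False, "high")


def test_berlin_bmi_alone_gives_category3_but_low_risk():
    cat1, cat2, cat3, risk = score_berlin(_berlin_items(), bmi=31.0, bp_history=False)
    assert (cat1, cat2, cat3, risk) == (False, False, True, "low")


def test_berlin_category_order_invariance():
    """Which two items in a category are positive does not matter."""
    base = score_berlin(_berlin_items(2, 0), bmi=24.0, bp_history=True)
    items = _berlin_items()
    items[BERLIN_CAT1_ITEMS[3]] = True
    items[BERLIN_CAT1_ITEMS[4]] = True
    assert score_berlin(items, bmi=24.0, bp_history=True) == base


def test_berlin_missing_item_is_an_error():
    items = _berlin_items()
    del items[BERLIN_CAT2_ITEMS[0]]
    with pytest.raises(ScoringError):
        score_berlin(items, bmi=24.0, bp_history=False)


# ---------------------------------------------------------------------------
# GSRS
# ---------------------------------------------------------------------------


def test_gsrs_floor_and_ceiling():
    assert score_gsrs({n: 1 for n in GSRS_ITEMS}) == 0.0
    assert score_gsrs({n: 7 for n in GSRS_ITEMS}) == 90.0


def test_gsrs_conventions():
    items = {n: 1 for n in GSRS_ITEMS}
    items[GSRS_ITEMS[0]] = 3
    items[GSRS_ITEMS[5]] = 5
    assert score_gsrs(items) == 6.0  # (3-1) + (5-1)
    assert score_gsrs(items, "sum1") == 6.0 + 15
    assert score_gsrs(items, "mean") == pytest.approx((13 + 3 + 5) / 15)
    with pytest.raises(ConfigurationError):
        score_gsrs(items, "median")


@settings(max_examples=50, deadline=None)
@given(levels=st.lists(st.integers(1, 7), min_size=15, max_size=15))
def test_gsrs_matches_bruteforce_summation(levels):
    items = dict(zip(GSRS_ITEMS, levels))
    assert score_gsrs(items) == sum(lv - 1 for lv in levels)


def test_gsrs_out_of_range_level_is_an_error():
    items = {n: 1 for n in GSRS_ITEMS}
    items[GSRS_ITEMS[2]] = 8
    with pytest.raises(ScoringError, match=GSRS_ITEMS[2]):
        score_gsrs(items)


# ---------------------------------------------------------------------------
# NQ
# ---------------------------------------------------------------------------


def test_nq_toy_weight_table():
    weights = {
        "item_factor": {"q1": "f", "q2": "f"},
        "item_points": {"q1": [0, 10, 20], "q2": [0, 5, 10, 15]},
        "factor_weights": {"f": 1.0},
    }
    # levels are 1-based: level 2 -> second entry (10), level 3 -> third (10)
    global_score, factors, grade = score_nq({"q1": 2, "q2": 3}, weights)
    assert factors["f"] == 10 + 10
    assert global_score == 20.0


def test_nq_zero_weights_score_zero_and_grade_monitoring():
    weights = {
        "item_factor": {"q1": "f"},
        "item_points": {"q1": [0.0] * 5},
        "factor_weights": {"f": 1.0},
    }
    global_score, factors, grade = score_nq({"q1": 4}, weights)
    assert global_score == 0.0 and grade == "monitoring"


def test_nq_grade_threshold_at_58():
    weights = {
        "item_factor": {"q1": "f"},
        "item_points": {"q1": [0.0, 57.99, 58.0]},
        "factor_weights": {"f": 1.0},
    }
    assert score_nq({"q1": 3}, weights)[2] == "good"
    assert score_nq({"q1": 2}, weights)[2] == "monitoring"


def test_nq_default_table_scores_all_items():
    items = {n: 5 for n in sp.synthetic.NQ_ITEMS}
    global_score, factors, grade = score_nq(items, DEFAULT_NQ_WEIGHTS)
    assert global_score == pytest.approx(100.0)
    assert grade == "good"
    assert factors["balance"] == pytest.approx(70.0)


def test_nq_missing_point_table_is_a_configuration_error():
    weights = {
        "item_factor": {"q1": "f"},
        "item_points": {},
        "factor_weights": {"f": 1.0},
    }
    with pytest.raises(ConfigurationError, match="q1"):
        score_nq({"q1": 1}, weights)


# ---------------------------------------------------------------------------
# Sample-size design
# ---------------------------------------------------------------------------


def test_sample_size_reproduces_study_design():
    params = SampleSizeParams(N=300_000, e=0.03, confidence=0.95, p=0.5)
    assert sp.sample_size(params) == 1064
    assert sp.required_invitations(1064, 0.03) == 35_467


def test_sample_size_closed_forms():
    # infinite-population limit: ceil(1.96^2 * 0.25 / 0.03^2) = 1068
    assert sp.sample_size(SampleSizeParams(N=1e12, e=0.03)) == 1068
    assert sp.sample_size(SampleSizeParams(N=300_000, e=0.05)) == 384
    assert sp.required_invitations(100, 0.5) == 200
    assert sp.required_invitations(77, 1.0) == 77


def test_sample_size_monotonicity():
    base = sp.sample_size(SampleSizeParams(N=300_000, e=0.03))
    assert sp.sample_size(SampleSizeParams(N=300_000, e=0.02)) >= base
    assert sp.sample_size(SampleSizeParams(N=500_000, e=0.03)) >= base
    assert sp.sample_size(SampleSizeParams(N=300_000, e=0.03, confidence=0.99)) >= base


@pytest.mark.parametrize(
    "params",
    [
        SampleSizeParams(N=300_000, e=0.0),
        SampleSizeParams(N=300_000, e=0.03, p=1.0),
        SampleSizeParams(N=0, e=0.03),
    ],
)
def test_sample_size_invalid_params(params):
    with pytest.raises(ConfigurationError):
        sp.sample_size(params)


def test_required_invitations_zero_rate_is_an_error():
    with pytest.raises(ConfigurationError):
        sp.required_invitations(100, 0.0)


# ---------------------------------------------------------------------------
# Whole-table scoring
# ---------------------------------------------------------------------------


def test_score_table_columns_and_identities(small_scored):
    comps = small_scored[[f"psqi_c{i}" for i in range(1, 8)]].sum(axis=1)
    assert np.allclose(comps, small_scored["psqi_global"])
    assert ((small_scored["psqi_global"] > 5) == small_scored["psqi_disturbed"]).all()
    n_cats = (
        small_scored[["berlin_cat1", "berlin_cat2", "berlin_cat3"]]
        .astype(bool).sum(axis=1)
    )
    assert ((n_cats >= 2) == (small_scored["berlin_risk"] == "high")).all()
    assert small_scored["gsrs_total"].between(0, 90).all()
    good = small_scored["nq_grade"] == "good"
    assert (good == (small_scored["nq_global"] >= 58)).all()
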