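"""Oxygenation indices, distress criteria, OEWS engine, sample size."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from luscohort.cohort_model import Avpu
from luscohort.physiology import (
    OewsChart,
    derive_fio2,
    oews,
    respiratory_distress,
    sample_size_for_proportion,
    sf_ratio,
)

from .conftest import make_obs


@pytest.mark.parametrize("flow, fio2", [(0.0, 0.21), (5.0, 0.36), (30.0, 1.0)])
def test_fio2_from_flow(flow, fio2):
    assert derive_fio2(flow) == pytest.approx(fio2)


def test_negative_flow_rejected():
    with pytest.raises(ValueError):
        derive_fio2(-1.0)


@pytest.mark.parametrize(
    "spo2, flow, expected",
    [(99.0, 0.0, 471.43), (98.0, 0.0, 466.67), (92.0, 5.0, 255.56)],
)
def test_sf_ratio_examples(spo2, flow, expected):
    assert sf_ratio(spo2, flow) == pytest.approx(expected, abs=0.01)


@settings(max_examples=100, deadline=None)
@given(spo2=st.floats(50, 100), flows=st.tuples(st.floats(0, 26), st.floats(0, 26)))
def test_sf_ratio_strictly_decreasing_in_flow_below_cap(spo2, flows):
    lo, hi = sorted(flows)
    if hi > lo + 1e-6:  # distinguishable at float precision
        assert sf_ratio(spo2, hi) < sf_ratio(spo2, lo)


@pytest.mark.parametrize(
    "kw, expected",
    [
        (dict(rr=31.0, spo2=99.0), True),           # tachypnea alone
        (dict(rr=24.0, spo2=99.0), False),
        (dict(rr=20.0, spo2=92.0, flow=5.0), True), # S/F 255.6 <= 315
        (dict(rr=20.0, spo2=99.0, accessory=True), True),
        (dict(rr=20.0, spo2=99.0, nasal=True), True),
    ],
)
def test_respiratory_distress_criteria(kw, expected):
    assert respiratory_distress(make_obs(**kw)) is expected


def test_distress_monotone_under_worsening():
    """Worsening any single criterion never flips a positive call negative."""
    base = make_obs(rr=31.0, spo2=99.0)
    assert respiratory_distress(base)
    worse_rr = make_obs(rr=40.0, spo2=99.0)
    worse_spo2 = make_obs(rr=31.0, spo2=85.0)
    worse_signs = make_obs(rr=31.0, spo2=99.0, accessory=True, nasal=True)
    for obs in (worse_rr, worse_spo2, worse_signs):
        assert respiratory_distress(obs)


# ---------------------------------------------------------------------------
# OEWS engine
# ---------------------------------------------------------------------------

def _flat_chart(weight=0):
    bands = {
        p: [(float("-inf"), float("inf"), weight)]
        for p in ("respiratory_rate", "spo2", "temperature", "systolic_bp",
                  "diastolic_bp", "heart_rate")
    }
    return OewsChart(bands=bands, avpu_weights={a: weight for a in Avpu})


def test_all_zero_chart_scores_zero():
    assert oews(make_obs(rr=45.0, spo2=70.0), _flat_chart(0)) == 0


def test_default_chart_zero_band(default_chart):
    obs = make_obs(rr=18.0, spo2=99.0, temp=37.0,
                   heart_rate=80.0, systolic_bp=120.0, diastolic_bp=70.0)
    assert oews(obs, default_chart) == 0


def test_unresponsive_contributes_max_avpu_weight(default_chart):
    obs_alert = make_obs(rr=18.0, spo2=99.0, temp=37.0, heart_rate=80.0,
                         systolic_bp=120.0, diastolic_bp=70.0)
    obs_unresp = obs_alert.model_copy(update={"avpu": Avpu.UNRESPONSIVE})
    delta = oews(obs_unresp, default_chart) - oews(obs_alert, default_chart)
    assert delta == max(default_chart.avpu_weights.values())


def test_single_out_of_band_value_adds_exactly_that_weight(default_chart):
    baseline = make_obs(rr=18.0, spo2=99.0, temp=37.0, heart_rate=80.0,
                        systolic_bp=120.0, diastolic_bp=70.0)
    tachypneic = baseline.model_copy(update={"respiratory_rate": 32.0})
    band_weight = default_chart.weight("respiratory_rate", 32.0)
    assert oews(tachypneic, default_chart) - oews(baseline, default_chart) == band_weight


def test_missing_temperature_warns_and_contributes_zero(default_chart):
    full = make_obs(rr=18.0, spo2=99.0, temp=37.0, heart_rate=80.0,
                    systolic_bp=120.0, diastolic_bp=70.0)
    missing = full.model_copy(update={"temperature_c": None})
    with pytest.warns(UserWarning, match="temperature"):
        assert oews(missing, default_chart) == oews(full, default_chart)


@pytest.mark.parametrize(
    "doc",
    [
        {"bands": {"respiratory_rate": [{"low": 0, "high": 10, "weight": 1},
                                        {"low": 12, "high": 99, "weight": 0}]},
         "avpu_weights": {a.value: 0 for a in Avpu}},          # gap between bands
        {"bands": {"respiratory_rate": [{"low": 0, "high": 99, "weight": -1}]},
         "avpu_weights": {a.value: 0 for a in Avpu}},          # negative weight
        {"bands": {}, "avpu_weights": {"alert": 0}},            # incomplete AVPU map
    ],
)
def test_malformed_charts_rejected_at_load(doc):
    with pytest.raises(ValueError):
        OewsChart.from_dict(doc)


# ---------------------------------------------------------------------------
# Sample size for a proportion
# ---------------------------------------------------------------------------

def test_sample_size_20pct_5pct_precision():
    assert sample_size_for_proportion(0.20, 0.05, 0.95) == 246


def test_sample_size_maximal_at_half():
    at_half = sample_size_for_proportion(0.5, 0.05)
    for p in (0.1, 0.25, 0.4, 0.6, 0.9):
        assert sample_size_for_proportion(p, 0.05) <= at_half


def test_finite_population_correction_shrinks_n():
    n0 = sample_size_for_proportion(0.2, 0.05)
    n_fpc = sample_size_for_proportion(0.2, 0.05, population=n0)
    assert n_fpc < n0
    # FPC algebra: with N = n0, n = n0 / (2 - 1/n0), slightly above n0/2
    assert n_fpc == math.ceil(n0 / (2.0 - 1.0 / n0) - 1e-12)
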