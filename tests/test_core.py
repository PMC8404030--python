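"""Unit and property tests for normalization, polarity and AMPI aggregation."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ampindex as ai
from ampindex.core import ValidationError

from conftest import random_panel


def ampi_literal(row, ddof=1):
    """Independent literal transcription of the aggregation formula:
    score = M - S * (S / M), with S the standard deviation of the row."""
    row = np.asarray(row, float)
    m = row.sum() / len(row)
    s = np.sqrt(((row - m) ** 2).sum() / (len(row) - ddof))
    return m - s * (s / m)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x, lo, hi, expected",
    [(50.0, 50.0, 150.0, 70.0), (150.0, 50.0, 150.0, 130.0), (100.0, 50.0, 150.0, 100.0)],
)
def test_normalize_goalpost_anchors(x, lo, hi, expected):
    """Values at the lower goalpost, upper goalpost and midpoint map to 70,
    130 and 100 respectively."""
    panel = ai.IndicatorPanel(
        pd.DataFrame({"a": [x, lo]}, index=["target", "other"])
    )
    gp = ai.Goalposts.from_mapping({"a": (lo, hi)})
    r = ai.normalize(panel, gp)
    assert r.loc["target", "a"] == pytest.approx(expected, abs=1e-12)


def test_normalize_observed_goalposts_range(small_panel):
    """With observed min/max goalposts every normalized value is in [70, 130]
    and the column extremes hit the anchors exactly."""
    r = ai.normalize(small_panel, ai.observed_goalposts(small_panel))
    assert (r.to_numpy() >= 70 - 1e-9).all() and (r.to_numpy() <= 130 + 1e-9).all()
    assert r.min().min() == pytest.approx(70.0)
    assert r.max().max() == pytest.approx(130.0)


def test_normalize_outside_goalposts_warns_not_clips(small_panel, caplog):
    gp = ai.Goalposts.from_mapping(
        {"life_exp": (79.0, 83.0), "mortality": (0.0, 10.0), "spending": (0.0, 3000.0)}
    )
    with caplog.at_level(logging.WARNING, logger="ampindex"):
        r = ai.normalize(small_panel, gp)
    assert r.loc["south", "life_exp"] < 70  # 78 below the 79 goalpost
    assert r.loc["islands", "life_exp"] > 130
    assert any("outside" in rec.message for rec in caplog.records)


def test_degenerate_and_missing_goalposts_error(small_panel):
    with pytest.raises(ValidationError, match="life_exp"):
        ai.Goalposts.from_mapping(
            {"life_exp": (80.0, 80.0), "mortality": (0, 10), "spending": (0, 3000)}
        )
    gp = ai.Goalposts.from_mapping({"life_exp": (70.0, 90.0)})
    with pytest.raises(ValidationError, match="mortality"):
        ai.normalize(small_panel, gp)


@given(
    a=st.floats(0.01, 100),
    b=st.floats(-1000, 1000),
    seed=st.integers(0, 2**16),
)
def test_normalize_affine_invariance(a, b, seed):
    """Rescaling a raw column by x -> a*x + b (a > 0) and transforming its
    goalposts identically leaves the normalized panel unchanged."""
    rng = np.random.default_rng(seed)
    panel = random_panel(rng, 5, 3)
    gp = ai.observed_goalposts(panel)
    r1 = ai.normalize(panel, gp)
    df2 = panel.data.copy()
    df2["x0"] = a * df2["x0"] + b
    bounds = gp.bounds.copy()
    bounds.loc["x0"] = [a * bounds.loc["x0", "min"] + b, a * bounds.loc["x0", "max"] + b]
    r2 = ai.normalize(ai.IndicatorPanel(df2), ai.Goalposts(bounds))
    assert np.allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-9)


# ---------------------------------------------------------------------------
# polarity
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "r, polarity, expected",
    [(130.0, "negative", 70.0), (100.0, "negative", 100.0), (85.0, "positive", 85.0)],
)
def test_polarity_complement(r, polarity, expected):
    df = pd.DataFrame({"a": [r]}, index=["u"])
    out = ai.apply_polarity(df, {"a": polarity})
    assert out.loc["u", "a"] == pytest.approx(expected)


def test_polarity_unknown_or_missing_errors():
    df = pd.DataFrame({"a": [100.0]}, index=["u"])
    with pytest.raises(ValidationError, match="polarity"):
        ai.apply_polarity(df, {"a": "sideways"})
    with pytest.raises(ValidationError, match="polarity"):
        ai.apply_polarity(df, {})


@given(
    st.lists(st.floats(70, 130), min_size=2, max_size=8),
)
def test_polarity_involution_and_range(values):
    """The 200-complement applied twice is the identity, and it maps
    [70, 130] onto itself."""
    df = pd.DataFrame({"a": values}, index=[f"u{i}" for i in range(len(values))])
    once = ai.apply_polarity(df, {"a": "negative"})
    assert ((once["a"] >= 70 - 1e-9) & (once["a"] <= 130 + 1e-9)).all()
    twice = ai.apply_polarity(once, {"a": "negative"})
    assert np.allclose(twice["a"], df["a"], atol=1e-12)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def test_aggregate_hand_computed_example():
    """(80, 100, 120): M=100, S=20 (sample), cv=0.2, penalty=4, score=96."""
    res = ai.aggregate_ampi([80.0, 100.0, 120.0])
    assert res.mean_level == pytest.approx(100.0)
    assert res.penalty == pytest.approx(4.0)
    assert res.score == pytest.approx(96.0)


def test_aggregate_published_subindex_row():
    """The published Quality row for Trento: sub-index scores
    (94.13, 108.13, 135.07) aggregate to 108.59 with the sample sd."""
    res = ai.aggregate_ampi([94.13, 108.13, 135.07], sd_convention="sample")
    assert res.score == pytest.approx(108.59, abs=0.02)


@given(st.floats(1.0, 200.0), st.integers(2, 8))
def test_aggregate_constant_row_has_zero_penalty(q, n):
    res = ai.aggregate_ampi([q] * n)
    assert res.penalty == pytest.approx(0.0, abs=1e-9)
    assert res.score == pytest.approx(q)


def test_aggregate_errors():
    with pytest.raises(ValidationError, match="2 components"):
        ai.aggregate_ampi([100.0])
    with pytest.raises(ValidationError, match="positive"):
        ai.aggregate_ampi([-5.0, 5.0])
    with pytest.raises(ValidationError, match="convention"):
        ai.aggregate_ampi([80.0, 120.0], sd_convention="bayesian")


@given(
    st.lists(st.floats(70, 130), min_size=2, max_size=10),
    st.sampled_from(["sample", "population"]),
)
def test_aggregate_matches_independent_oracle(values, convention):
    """Aggregation agrees with an independently coded literal transcription
    of the mean-minus-penalty formula to 1e-9, for both sd conventions."""
    res = ai.aggregate_ampi(values, sd_convention=convention)
    ddof = 1 if convention == "sample" else 0
    assert res.score == pytest.approx(ampi_literal(values, ddof=ddof), abs=1e-9)
    assert res.score == pytest.approx(res.mean_level - res.penalty, abs=1e-9)
    assert res.penalty >= -1e-12
    assert res.score <= res.mean_level + 1e-12


# ---------------------------------------------------------------------------
# full index pipeline
# ---------------------------------------------------------------------------


def test_compute_index_dominating_unit_saturates(small_panel):
    """'islands' has the best value of every indicator (mortality is
    negative-polarity), so under observed goalposts it normalizes to 130
    everywhere and scores exactly 130 with zero penalty."""
    pol = {"life_exp": "positive", "mortality": "negative", "spending": "positive"}
    out = ai.compute_index(small_panel, polarities=pol)
    assert out.loc["islands", "score"] == pytest.approx(130.0, abs=1e-9)
    assert out.loc["islands", "penalty"] == pytest.approx(0.0, abs=1e-9)


def test_compute_index_single_unit_panel_rejected():
    with pytest.raises(ValidationError, match="one unit"):
        ai.IndicatorPanel(pd.DataFrame({"a": [1.0]}, index=["only"]))


def test_compute_index_single_indicator_gate():
    panel = ai.IndicatorPanel(pd.DataFrame({"a": [1.0, 2.0, 3.0]}, index=list("uvw")))
    with pytest.raises(ValidationError, match="single indicator"):
        ai.compute_index(panel, polarities={"a": "positive"})
    out = ai.compute_index(
        panel, polarities={"a": "positive"}, allow_single_indicator=True
    )
    assert (out["penalty"] == 0).all()
    assert out.loc["w", "score"] == pytest.approx(130.0)


@given(st.integers(0, 2**16))
def test_compute_index_permutation_invariance(seed):
    """Shuffling indicator column order leaves every score unchanged."""
    rng = np.random.default_rng(seed)
    panel = random_panel(rng, 6, 4)
    pol = {f"x{j}": ("negative" if j % 2 else "positive") for j in range(4)}
    out1 = ai.compute_index(panel, polarities=pol)
    shuffled = panel.data[["x2", "x0", "x3", "x1"]]
    out2 = ai.compute_index(ai.IndicatorPanel(shuffled), polarities=pol)
    assert np.allclose(out1["score"], out2["score"], atol=1e-12)
    assert np.allclose(out1["penalty"], out2["penalty"], atol=1e-12)


def test_panel_rejects_missing_values():
    with pytest.raises(ValidationError, match="missing"):
        ai.IndicatorPanel(
            pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]}, index=["u", "v"])
        )


def test_reference_goalposts_center_on_mean(small_panel):
    gp = ai.reference_goalposts(small_panel)
    mid = (gp.bounds["min"] + gp.bounds["max"]) / 2
    assert np.allclose(mid, small_panel.data.mean(axis=0), atol=1e-12)
    # width equals the observed range
    width = gp.bounds["max"] - gp.bounds["min"]
    rng_ = small_panel.data.max(axis=0) - small_panel.data.min(axis=0)
    assert np.allclose(width, rng_, atol=1e-12)
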