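"""Rival models: CWA prediction/fit, signed sum, misreadings, Venn coding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from etdfallacy.rivals import (
    CwaParams,
    cwa_predict,
    code_venn,
    fit_cwa,
    neg_base_misread,
    signed_sum_check,
    venn_consistency,
)
from etdfallacy.taxonomy import classify_compound
from tests.conftest import make_cohort

probs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


@pytest.mark.parametrize(
    "lo, hi, beta, conn, expected",
    [
        (0.2, 0.8, 0.7, "and", 0.38),
        (0.2, 0.8, 0.3, "or", 0.62),
    ],
)
def test_cwa_predict_values(lo, hi, beta, conn, expected):
    assert cwa_predict(lo, hi, CwaParams(beta, conn)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "beta, conn",
    [(0.5, "and"), (1.0, "and"), (0.5, "or"), (0.0, "or"), (0.7, "or"), (0.3, "and")],
)
def test_cwa_params_open_interval(beta, conn):
    with pytest.raises(ValueError):
        CwaParams(beta, conn)


@settings(max_examples=200, derandomize=True)
@given(pa=probs, pb=probs,
       beta_and=st.floats(min_value=0.51, max_value=0.99),
       beta_or=st.floats(min_value=0.01, max_value=0.49))
def test_cwa_output_is_single_fallacy(pa, pb, beta_and, beta_or):
    """A CWA compound lies strictly between distinct constituents → single class."""
    if pa == pb:
        return
    lo, hi = min(pa, pb), max(pa, pb)
    for beta, conn in ((beta_and, "and"), (beta_or, "or")):
        v = cwa_predict(lo, hi, CwaParams(beta, conn))
        if lo < v < hi:  # excludes float underflow at tiny gaps
            assert classify_compound(v, pa, pb, conn).value == "single"


def test_fit_cwa_noiseless_recovery(conjunction_design):
    """σ = 0 cohorts reproduce the generating weights to 1e-10 with R² = 1."""
    table, _ = make_cohort(conjunction_design, "conjunction", n=60, seed=31,
                           response_model="cwa", beta=0.75, sigma=0.0)
    fits, verdicts = fit_cwa(table, "and")
    total = fits["total"]
    assert total.r_squared == pytest.approx(1.0, abs=1e-10)
    # raw weights: back out from standardized coefficients
    assert verdicts["total"] == "consistent"
    rows = []
    for rec in table.records:
        group = table.design.group(rec.group_id)
        for comp in group.compounds:
            a, b = (rec.estimates[c] for c in comp.constituents)
            rows.append((rec.estimates[comp.id], max(a, b), min(a, b)))
    y, hi, lo = (np.array(c) for c in zip(*rows))
    X = np.column_stack([np.ones_like(y), hi, lo])
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    assert coef[1] == pytest.approx(0.25, abs=1e-10)
    assert coef[2] == pytest.approx(0.75, abs=1e-10)


def test_fit_cwa_noisy_direction(disjunction_design):
    """β = 0.3 disjunction cohorts: the larger constituent dominates."""
    table, _ = make_cohort(disjunction_design, "disjunction", n=500, seed=32,
                           response_model="cwa", beta=0.3, sigma=0.05)
    fits, verdicts = fit_cwa(table, "or")
    assert fits["total"].beta_large > fits["total"].beta_small
    assert verdicts["total"] == "consistent"


def test_fit_cwa_requires_compounds(disjunction_design):
    table, _ = make_cohort(disjunction_design, "disjunction", n=10, seed=33)
    with pytest.raises(ValueError):
        fit_cwa(table, "and")  # disjunction design has no conjunctions


def _counts(zero, single, double):
    return pd.DataFrame(
        {"zero": zero, "single": single, "double": double},
        index=["UU", "LU", "LL"],
    )


def test_signed_sum_all_true_pattern():
    report = signed_sum_check(_counts([30, 10, 9], [15, 70, 15], [5, 20, 26]))
    assert all(report[cls]["verdict"] for cls in ("zero", "single", "double"))
    assert report["single"]["expected_peak"] == "LU"


def test_signed_sum_tie_fails():
    # zero share equal in UU and LL → strict-peak rule fails for zero
    report = signed_sum_check(_counts([20, 10, 20], [20, 60, 20], [10, 30, 10]))
    assert not report["zero"]["verdict"]
    assert report["single"]["verdict"]


def test_signed_sum_missing_stratum():
    df = _counts([1, 2, 3], [4, 5, 6], [7, 8, 9]).drop(index="LL")
    with pytest.raises(ValueError, match="missing"):
        signed_sum_check(df)


@pytest.mark.parametrize(
    "t, f, prob, met",
    [
        (0.1, 0.8, 0.72, True),
        (0.5, 1.0, 0.5, False),  # boundary: strict inequality
        (0.2, 0.2, 0.16, False),
    ],
)
def test_neg_base_misread(t, f, prob, met):
    res = neg_base_misread(t, f)
    assert res.prob_neg_base_and_added == pytest.approx(prob)
    assert res.condition_met is met


@settings(max_examples=200, derandomize=True)
@given(t=probs, f=probs, d=st.floats(min_value=0.0, max_value=1.0))
def test_neg_base_misread_monotone(t, f, d):
    """Condition is non-decreasing in f and non-increasing in t."""
    base = neg_base_misread(t, f).condition_met
    f_up = min(1.0, f + d)
    t_up = min(1.0, t + d)
    if base:
        assert neg_base_misread(t, f_up).condition_met
    if not base:
        assert not neg_base_misread(t_up, f).condition_met


@pytest.mark.parametrize(
    "option, coding, d_flag",
    [("C", "intersection", False), ("B", "disjunction", False),
     ("D", "other", True), ("A", "other", False), ("F", "other", False)],
)
def test_code_venn(option, coding, d_flag):
    interp = code_venn(option)
    assert interp.coding == coding
    assert interp.complement_conjunction_candidate is d_flag


def test_code_venn_unknown():
    with pytest.raises(ValueError):
        code_venn("G")


def test_venn_consistency_linked_cohort(conjunction_design):
    """When interpretation drives behavior, the crosstab is diagonal-dominant."""
    table, _ = make_cohort(conjunction_design, "conjunction", n=200, seed=34,
                           response_model="cwa", beta=0.7, sigma=0.0,
                           venn_linkage=True)
    out = venn_consistency(table)
    ct = out["crosstab"]
    # intersection-choosers respond by the probability rule: never fallacious
    assert ct["intersection"]["both_rule"] == ct["intersection"]["n"]
    # disjunction-choosers place compounds above both constituents
    assert out["disjunction_full_accord"] == ct["disjunction"]["n"]
    assert ct["disjunction"]["both_fallacy"] == ct["disjunction"]["n"]
    assert out["option_d"]["n"] > 0
    assert 0.0 <= out["option_d"]["fraction"] <= 1.0
    total = sum(ct[c]["n"] for c in ct)
    assert total == out["n_with_venn"] == 200


def test_venn_consistency_requires_data(conjunction_design):
    table, _ = make_cohort(conjunction_design, "conjunction", n=10, seed=35,
                           venn_mixture=None)
    with pytest.raises(ValueError, match="no Venn data"):
        venn_consistency(table)


def test_venn_against_interpretation_counted(conjunction_design):
    """A B-chooser whose compounds fall below both constituents obeys the
    conjunction rule — behavior contrary to the disjunctive interpretation."""
    from etdfallacy.io import ResponseRecord, ResponseTable
    est = {"T": 0.3, "F": 0.8, "Y": 0.4, "P": 0.35, "TaF": 0.1, "YaP": 0.1}
    rec = ResponseRecord("p0", "g1", est, venn_option="B", complete=True)
    out = venn_consistency(ResponseTable(conjunction_design, [rec]))
    assert out["crosstab"]["disjunction"]["both_rule"] == 1
    assert out["disjunction_full_accord"] == 0
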