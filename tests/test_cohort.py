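"""Synthetic cohort generator: determinism, model signatures, oracles."""

import numpy as np
import pytest

from etdfallacy.cohort import (
    CohortConfig,
    analytic_rates,
    draw_components,
    generate_cohort,
    respond_compound,
)
from etdfallacy.io import write_responses
from etdfallacy.taxonomy import tally
from tests.conftest import make_cohort


@pytest.mark.parametrize(
    "model, pa, pb, conn, expected",
    [
        ("probability_rule", 0.2, 0.8, "and", 0.16),
        ("probability_rule", 0.2, 0.8, "or", 0.84),
        ("cwa", 0.2, 0.8, "and", 0.38),
        ("averaging", 0.2, 0.8, "and", 0.5),
    ],
)
def test_respond_compound_deterministic_models(model, pa, pb, conn, expected):
    rng = np.random.default_rng(0)
    params = {"beta": 0.7, "sigma": 0.0}
    assert respond_compound(model, params, pa, pb, conn, rng) == pytest.approx(expected)


def test_respond_compound_rejects_unknown_model():
    with pytest.raises(ValueError):
        respond_compound("psychic", {}, 0.2, 0.8, "and", np.random.default_rng(0))


def test_respond_compound_always_in_unit_interval():
    rng = np.random.default_rng(6)
    for model in ("random_error", "signed_sum", "etd_ordinal", "reversed"):
        for _ in range(100):
            a, b = rng.uniform(0, 1, 2)
            v = respond_compound(model, {"error_half_width": 0.5}, a, b, "and", rng)
            assert 0.0 <= v <= 1.0


def test_draw_components_respect_intervals(conjunction_design):
    config = CohortConfig(
        design=conjunction_design, n_participants=1, seed=1,
        component_classes={"g1": {"T": "unlikely", "F": "likely",
                                  "Y": "unlikely", "P": "unlikely"}},
    )
    rng = np.random.default_rng(0)
    for _ in range(200):
        est = draw_components(config, "g1", rng)
        assert est["T"] < 0.5 and est["Y"] < 0.5 and est["P"] < 0.5
        assert est["F"] > 0.5


def test_draw_components_seed_determinism(conjunction_design):
    config = CohortConfig(design=conjunction_design, n_participants=1, seed=1)
    a = draw_components(config, "g1", np.random.default_rng(9))
    b = draw_components(config, "g1", np.random.default_rng(9))
    assert a == b


def test_draw_components_mean_matches_interval_midpoint(conjunction_design):
    config = CohortConfig(
        design=conjunction_design, n_participants=1, seed=1,
        component_classes={"g1": {"F": "likely"}},
    )
    rng = np.random.default_rng(10)
    draws = [draw_components(config, "g1", rng)["F"] for _ in range(10_000)]
    assert np.mean(draws) == pytest.approx(0.75, abs=0.02)


def test_generate_cohort_byte_identical(tmp_path, conjunction_design):
    files = []
    for run in range(2):
        table, _ = make_cohort(conjunction_design, "conjunction", n=40, seed=17)
        path = tmp_path / f"run{run}.csv"
        write_responses(table, path)
        files.append(path.read_bytes())
    assert files[0] == files[1]


def test_adding_participants_preserves_earlier_records(conjunction_design):
    small, _ = make_cohort(conjunction_design, "conjunction", n=30, seed=18)
    large, _ = make_cohort(conjunction_design, "conjunction", n=60, seed=18)
    for a, b in zip(small.records, large.records[:30]):
        assert a.estimates == b.estimates
        assert a.venn_option == b.venn_option


def test_probability_rule_cohort_all_zero_class(conjunction_design):
    table, truth = make_cohort(conjunction_design, "conjunction", n=100, seed=19,
                               response_model="probability_rule")
    counts = tally(table)
    byc = counts.by_connective()
    assert byc.loc["and", "zero"] == counts.total == 200
    assert (truth["realized_class"] == "zero").all()


def test_cwa_sigma_zero_cohort_all_single(conjunction_design):
    table, truth = make_cohort(conjunction_design, "conjunction", n=100, seed=20,
                               response_model="cwa", beta=0.7, sigma=0.0)
    assert (truth["realized_class"] == "single").all()


def test_etd_ordinal_cohort_all_single(disjunction_design):
    table, truth = make_cohort(disjunction_design, "disjunction", n=100, seed=21,
                               response_model="etd_ordinal")
    assert (truth["realized_class"] == "single").all()


def test_config_validation(conjunction_design):
    with pytest.raises(ValueError):
        CohortConfig(design=conjunction_design, n_participants=0, seed=1)
    with pytest.raises(ValueError):
        CohortConfig(design=conjunction_design, n_participants=10, seed=1,
                     response_model="nope")
    with pytest.raises(ValueError):
        CohortConfig(design=conjunction_design, n_participants=10, seed=1,
                     group_sizes={"g1": 10})
    with pytest.raises(ValueError):
        CohortConfig(design=conjunction_design, n_participants=10, seed=1,
                     venn_mixture={"A": 0.5, "B": 0.6})


def test_group_sizes_block_assignment(conjunction_design):
    sizes = {"g1": 10, "g2": 5, "g3": 3, "g4": 2}
    table, _ = make_cohort(conjunction_design, "conjunction", n=20, seed=22,
                           group_sizes=sizes)
    observed = {}
    for rec in table.records:
        observed[rec.group_id] = observed.get(rec.group_id, 0) + 1
    assert observed == sizes


def test_analytic_rates_closed_forms():
    assert analytic_rates("probability_rule")["zero"] == 1.0
    assert analytic_rates("etd_ordinal")["single"] == 1.0
    assert analytic_rates("cwa", {"sigma": 0.0})["single"] == 1.0


def test_analytic_rates_twin_oracle_random_error():
    """Monte-Carlo class distribution agrees with an independent sampler within 3 SE."""
    params = {"error_half_width": 0.3}
    intervals = ((0.2, 0.2), (0.8, 0.8))  # degenerate: fixed components
    est = analytic_rates("random_error", params, intervals, "and",
                         n_mc=20_000, seed=100)
    # independent second sampler: vectorized direct draw
    rng = np.random.default_rng(200)
    n = 20_000
    vals = np.clip(0.16 + rng.uniform(-0.3, 0.3, n), 0, 1)
    twin = {
        "zero": float(np.mean(vals <= 0.2)),
        "single": float(np.mean((vals > 0.2) & (vals <= 0.8))),
        "double": float(np.mean(vals > 0.8)),
    }
    for cls in ("zero", "single", "double"):
        se = np.sqrt(max(est[cls] * (1 - est[cls]), twin[cls] * (1 - twin[cls])) / n)
        assert abs(est[cls] - twin[cls]) <= max(3 * se * np.sqrt(2), 1e-3)


def test_pipeline_recovery_of_cwa_beta(disjunction_design):
    """fit_cwa on a σ = 0.05, n = 500 disjunction cohort recovers β within 0.05."""
    from etdfallacy.rivals import fit_cwa
    table, _ = make_cohort(disjunction_design, "disjunction", n=500, seed=23,
                           response_model="cwa", beta=0.3, sigma=0.05)
    rows = []
    for rec in table.records:
        group = table.design.group(rec.group_id)
        for comp in group.compounds:
            a, b = (rec.estimates[c] for c in comp.constituents)
            rows.append((rec.estimates[comp.id], max(a, b), min(a, b)))
    y, hi, lo = (np.array(c) for c in zip(*rows))
    X = np.column_stack([np.ones_like(y), hi, lo])
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    assert coef[2] == pytest.approx(0.3, abs=0.05)   # weight on the smaller
    assert coef[1] == pytest.approx(0.7, abs=0.05)


def test_mixed_design_lu_stratum_has_higher_fallacy_rate(conjunction_design):
    """With σ > 0, CWA cohorts show strictly more fallacies in LU than LL/UU."""
    table, _ = make_cohort(conjunction_design, "conjunction", n=400, seed=24,
                           response_model="cwa", beta=0.7, sigma=0.1)
    counts = tally(table)
    fbt = counts.fallacious_by_type("and")
    lu_rate = fbt.loc["LU", True] / fbt.loc["LU"].sum()
    rest = fbt.loc[fbt.index.intersection(["LL", "UU"])].sum()
    rest_rate = rest[True] / rest.sum()
    assert lu_rate > rest_rate
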