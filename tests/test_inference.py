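"""Attribution, unit conversion, HR rescaling, composites, deciles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spcacox.inference import (
    NonIdentifiableComponentError,
    assign_deciles,
    decile_exposure_response,
    make_composite,
    pc_unit_in_raw_units,
    rescale_hr,
    trace_attribution,
)
from spcacox.sparse_pca import SparsePCA
from spcacox.survival import CoxPH


def test_pc_unit_single_variable_identity():
    raw, mean = pc_unit_in_raw_units([1.0], [3.7])
    assert raw[0] == pytest.approx(3.7)
    assert mean == pytest.approx(3.7)


def test_pc_unit_equal_weights_closed_form():
    w = np.full(3, 1 / np.sqrt(3))
    raw, mean = pc_unit_in_raw_units(w, np.full(3, 4.243))
    assert np.allclose(raw, 4.243 / np.sqrt(3), atol=1e-9)
    assert mean == pytest.approx(2.450, abs=1e-3)


def test_pc_unit_study_noise_value_from_table_sds():
    # equal weights over the three noise variables with their common 4.24 dB SD
    w = np.full(3, 1 / np.sqrt(3))
    _, mean = pc_unit_in_raw_units(w, np.full(3, 4.24))
    assert abs(mean - 2.47) < 0.05


def test_pc_unit_scale_invariance_of_hazard_statement():
    """Rescaling the weight vector rescales scores by c and raw changes by
    1/c, so an HR per raw unit is unchanged end to end."""
    rng = np.random.default_rng(0)
    b = rng.standard_normal(4)
    s = np.abs(rng.standard_normal(4)) + 0.5
    raw1, _ = pc_unit_in_raw_units(b, s)
    raw2, _ = pc_unit_in_raw_units(3.0 * b, s)
    assert np.allclose(raw2, raw1 / 3.0, atol=1e-12)


def test_pc_unit_mixed_units_suppresses_aggregate():
    raw, mean = pc_unit_in_raw_units([0.5, 0.5], [1.0, 2.0], units=["dB", "%"])
    assert mean is None
    assert raw.shape == (2,)


def test_pc_unit_empty_support_rejected():
    with pytest.raises(ValueError, match="empty"):
        pc_unit_in_raw_units([0.0, 0.0], [1.0, 1.0])


def test_rescale_hr_worked_example():
    hr, (lo, hi) = rescale_hr(1.017, (1.004, 1.030), per=2.47, target=10.0)
    assert round(hr, 2) == 1.07
    assert round(lo, 2) == 1.02
    assert round(hi, 2) == 1.13


def test_rescale_hr_identity_and_validation():
    assert rescale_hr(1.5, (1.2, 1.9), 3.0, 3.0) == (1.5, (1.2, 1.9))
    with pytest.raises(ValueError):
        rescale_hr(-1.0, (0.9, 1.1), 1.0, 2.0)


@settings(derandomize=True, max_examples=60)
@given(
    st.floats(0.5, 2.0), st.floats(0.4, 0.99), st.floats(1.0, 3.0),
    st.floats(0.1, 20.0), st.floats(0.1, 20.0),
)
def test_rescale_hr_round_trip(hr, lo_frac, hi_mult, per, target):
    ci = (hr * lo_frac, hr * hi_mult)
    h2, ci2 = rescale_hr(*rescale_hr(hr, ci, per, target), per=target, target=per)
    assert h2 == pytest.approx(hr, rel=1e-12)
    assert ci2[0] == pytest.approx(ci[0], rel=1e-12)
    assert ci2[1] == pytest.approx(ci[1], rel=1e-12)


def test_make_composite_arithmetic():
    df = pd.DataFrame({"a": [55.0], "b": [51.0], "c": [46.0]})
    assert make_composite(df).iloc[0] == pytest.approx(50.6667, abs=1e-4)
    single = pd.DataFrame({"a": [1.0, 2.0]})
    pd.testing.assert_series_equal(make_composite(single), single["a"], check_names=False)
    with pytest.raises(ValueError, match="lengths differ"):
        make_composite([np.ones(3), np.ones(4)])


def test_composite_mean_matches_table_means(cohort_50k):
    comp = make_composite(cohort_50k[["noise_day_db", "noise_evening_db", "noise_night_db"]])
    target = (55.37 + 51.62 + 46.55) / 3
    se = 4.24 / np.sqrt(len(comp))  # conservative: ignores the 0.98 correlation
    assert abs(comp.mean() - target) < 3 * 3 * se


# -- attribution -----------------------------------------------------------

def _fitted_cox_with_scores(weights, n=4000, beta=None, seed=0):
    """Cox fit on scores of a fixed weight matrix over synthetic exposures."""
    rng = np.random.default_rng(seed)
    p, k = weights.shape
    X = rng.standard_normal((n, p))
    Z = X @ weights
    lp = Z @ (beta if beta is not None else np.zeros(k))
    t = -np.log(rng.random(n)) / (0.02 * np.exp(lp))
    e = (t <= 8).astype(int)
    t = np.minimum(t, 8)
    cox = CoxPH().fit(pd.DataFrame(Z, columns=[f"PC{j+1}" for j in range(k)]), (t, e))
    fit = SparsePCA(n_components=k)
    fit.weights_ = weights
    return fit, cox


def test_attribution_lists_exactly_the_support():
    W = np.zeros((6, 2))
    W[[0, 1, 2], 0] = 1 / np.sqrt(3)  # "noise" component
    W[[4, 5], 1] = 0.7
    fit, cox = _fitted_cox_with_scores(W, beta=np.array([0.6, 0.0]), seed=3)
    assert cox.p_[0] < 0.05
    names = [f"v{i}" for i in range(6)]
    rep = trace_attribution(fit, cox, variable_names=names, sds=np.full(6, 2.0))
    assert len(rep.entries) == 1
    assert rep.entries[0].variables == ["v0", "v1", "v2"]
    assert all(abs(w) > 1e-8 for w in rep.entries[0].weights)


def test_attribution_empty_when_nothing_significant():
    W = np.zeros((6, 2))
    W[[0, 1], 0] = 0.7
    W[[2, 3], 1] = 0.7
    fit, cox = _fitted_cox_with_scores(W, beta=np.zeros(2), seed=4)
    rep = trace_attribution(fit, cox)
    assert rep.entries == [] or all(e.p < 0.05 for e in rep.entries)


def test_dense_component_above_cap_is_refused():
    rng = np.random.default_rng(5)
    W = rng.standard_normal((20, 1))
    fit, cox = _fitted_cox_with_scores(W, beta=np.array([0.5]), seed=5)
    assert cox.p_[0] < 0.05
    with pytest.raises(NonIdentifiableComponentError, match="cannot be disentangled"):
        trace_attribution(fit, cox, max_support=5)


# -- deciles ---------------------------------------------------------------

def test_decile_assignment_boundaries_and_ties():
    idx, bounds = assign_deciles(np.arange(1.0, 21.0))
    assert sorted(np.bincount(idx, minlength=10)) == [2] * 10
    assert set(np.flatnonzero(idx == 0).tolist()) == {0, 1}  # two smallest values
    assert len(bounds) == 10
    assert all(a <= b for a, b in bounds)
    # boundary value goes to the LOWER decile: (a, b] intervals
    q1 = bounds[0][1]
    at_boundary = np.flatnonzero(np.arange(1.0, 21.0) == q1)
    if at_boundary.size:
        assert idx[at_boundary[0]] == 0


def test_decile_assignment_partitions_subjects():
    rng = np.random.default_rng(1)
    x = rng.normal(50, 5, 997)
    idx, _ = assign_deciles(x)
    assert idx.shape == x.shape
    assert np.bincount(idx, minlength=10).sum() == 997


def test_decile_requires_ten_distinct_values():
    with pytest.raises(ValueError, match="distinct"):
        assign_deciles(np.repeat([1.0, 2.0, 3.0], 10))


def test_decile_exposure_response_structure():
    rng = np.random.default_rng(2)
    n = 3000
    comp = rng.normal(51, 2, n)
    others = rng.standard_normal((n, 5))
    cov = pd.DataFrame({"age": rng.standard_normal(n)})
    t = -np.log(rng.random(n)) / 0.03
    e = (t <= 8).astype(int)
    t = np.minimum(t, 8)
    res = decile_exposure_response(comp, others, cov, t, e, pca_threshold=0.92)
    assert len(res.table) == 9
    assert len(res.boundaries) == 10
    assert res.counts.sum() == n
    assert list(res.table.index) == [f"decile_{d}" for d in range(2, 11)]
    assert res.n_adjustment_pcs >= 1


def test_decile_zero_variance_composite_rejected():
    with pytest.raises(ValueError, match="variance|distinct"):
        decile_exposure_response(
            np.ones(100), np.random.default_rng(0).standard_normal((100, 3)),
            pd.DataFrame(index=range(100)), np.ones(100), np.ones(100, dtype=int),
        )


def test_link_diagram_edges_structure():
    W = np.zeros((5, 2))
    W[[0, 1], 0] = 0.7
    W[[3, 4], 1] = 0.6
    fit, cox = _fitted_cox_with_scores(W, beta=np.array([0.3, 0.0]), seed=9)
    from spcacox.inference import link_diagram_edges

    edges = link_diagram_edges(fit, cox, variable_names=[f"v{i}" for i in range(5)])
    var_edges = edges[edges["target"] != "outcome"]
    assert set(var_edges["source"]) == {"v0", "v1", "v3", "v4"}
    out_edges = edges[edges["target"] == "outcome"]
    assert len(out_edges) == 2
    assert (out_edges["weight"] >= 0).all()
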