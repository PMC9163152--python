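"""Cox estimation: oracles, invariances, tie handling, the L1 path."""

import numpy as np
import pandas as pd
import pytest

from spcacox.preprocessing import ZeroVarianceError
from spcacox.survival import CoxL1Path, CoxPH, default_cox_lambda_grid

from conftest import TINY_COX_FIXTURES, brute_force_cox, efron_loglik_naive


def test_three_subject_closed_form_mle():
    """Events at 1<2<3, covariate on the middle event: L(b) has an interior
    maximum at b = ln(2)/2."""
    X = np.array([[0.0], [1.0], [0.0]])
    fit = CoxPH().fit(X, (np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1])))
    assert fit.converged_
    assert fit.coef_[0] == pytest.approx(np.log(2.0) / 2.0, abs=1e-8)


def test_monotone_likelihood_is_flagged():
    """Covariate 1 on the earliest event makes the partial likelihood
    monotone (no finite MLE); the fit must flag non-convergence."""
    X = np.array([[1.0], [0.0], [0.0]])
    fit = CoxPH().fit(X, (np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1])))
    assert fit.converged_ is False
    assert fit.coef_[0] > 10  # runaway estimate is reported, not hidden


@pytest.mark.parametrize("idx", range(len(TINY_COX_FIXTURES)))
def test_matches_bruteforce_partial_likelihood(idx):
    X, time, event = TINY_COX_FIXTURES[idx]
    oracle = brute_force_cox(X, time, event)
    assert np.all(np.abs(oracle) < 7.9), "fixture must have an interior optimum"
    fit = CoxPH().fit(X, (time, event))
    assert fit.converged_
    assert np.allclose(fit.coef_, oracle, atol=1e-6)


def test_efron_score_at_zero_matches_hand_computation():
    """6 subjects with one tied event pair: the score at beta=0 equals the
    naive Efron gradient computed by explicit enumeration."""
    X = np.array([[1.0], [0.0], [1.0], [0.0], [1.0], [0.0]])
    time = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    event = np.array([1, 1, 1, 0, 1, 1])
    fit = CoxPH(max_iter=1).fit(X, (time, event))
    eps = 1e-6
    numeric = (
        efron_loglik_naive([eps], X, time, event) - efron_loglik_naive([-eps], X, time, event)
    ) / (2 * eps)
    assert fit.score_at([0.0])[0] == pytest.approx(numeric, abs=1e-6)
    # and against the fully hand-derived value for this fixture:
    # t=1 (d=2, D={x=1,x=0}, R=all 6, 3 with x=1):
    #   l=0: 3/6 ; l=1: (3 - 1/2*1)/(6 - 1/2*2) = 2.5/5
    # t=2: R has 4 subjects, 2 with x=1 -> 2/4 ; t=4: 1/2 ; t=5: 0/1
    hand = 3.0 - (3 / 6 + 2.5 / 5) - 2 / 4 - 1 / 2 - 0.0
    assert fit.score_at([0.0])[0] == pytest.approx(hand, abs=1e-12)


def test_zero_variance_term_is_named():
    X = pd.DataFrame({"ok": [0.0, 1.0, 2.0], "flat": [1.0, 1.0, 1.0]})
    with pytest.raises(ZeroVarianceError, match="flat"):
        CoxPH().fit(X, (np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0])))


def test_requires_at_least_one_event():
    with pytest.raises(ValueError, match="at least one event"):
        CoxPH().fit(np.ones((3, 1)), (np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0])))


@pytest.fixture(scope="module")
def moderate_design():
    rng = np.random.default_rng(5)
    n, p = 400, 3
    X = rng.standard_normal((n, p))
    lp = X @ np.array([0.4, -0.2, 0.0])
    t = np.round(-np.log(rng.random(n)) / (0.08 * np.exp(lp)), 1) + 0.1
    e = (t <= 9).astype(int)
    return X, np.minimum(t, 9), e


def test_agrees_with_lifelines_on_tied_data(moderate_design):
    lifelines = pytest.importorskip("lifelines")
    X, t, e = moderate_design
    fit = CoxPH().fit(X, (t, e))
    df = pd.DataFrame(X, columns=["x0", "x1", "x2"])
    df["T"], df["E"] = t, e
    ref = lifelines.CoxPHFitter().fit(df, "T", "E")
    assert np.allclose(fit.coef_, ref.params_.to_numpy(), atol=1e-5)
    assert np.allclose(fit.se_, ref.standard_errors_.to_numpy(), atol=1e-5)


def test_time_rescaling_and_covariate_scaling_invariance(moderate_design):
    X, t, e = moderate_design
    base = CoxPH().fit(X, (t, e))
    rescaled_time = CoxPH().fit(X, (t * 365.25, e))
    assert np.allclose(base.coef_, rescaled_time.coef_, atol=1e-8)
    X2 = X.copy()
    X2[:, 0] *= 10.0
    scaled_cov = CoxPH().fit(X2, (t, e))
    assert scaled_cov.coef_[0] == pytest.approx(base.coef_[0] / 10.0, abs=1e-8)
    assert np.allclose(scaled_cov.coef_[1:], base.coef_[1:], atol=1e-8)


def test_ci_invariants(moderate_design):
    X, t, e = moderate_design
    fit = CoxPH().fit(X, (t, e))
    s = fit.summary_
    assert np.allclose(s["ci_low"], np.exp(s["coef"] - 1.959964 * s["se"]), atol=1e-9)
    assert np.allclose(s["ci_high"], np.exp(s["coef"] + 1.959964 * s["se"]), atol=1e-9)
    assert np.all(s["ci_low"] <= s["HR"]) and np.all(s["HR"] <= s["ci_high"])


# -- L1 path ---------------------------------------------------------------

@pytest.fixture(scope="module")
def path_design():
    rng = np.random.default_rng(9)
    n = 800
    z = rng.standard_normal((n, 2))
    X = np.column_stack([z[:, 0], 0.9 * z[:, 0] + np.sqrt(1 - 0.81) * rng.standard_normal(n),
                         z[:, 1], rng.standard_normal(n)])
    lp = 0.03 * X[:, 0] + 0.03 * X[:, 1] + 0.4 * X[:, 3]
    t = -np.log(rng.random(n)) / (0.02 * np.exp(lp))
    e = (t <= 8).astype(int)
    t = np.minimum(t, 8)
    mask = np.array([True, True, True, False])  # last term is an unpenalized covariate
    return pd.DataFrame(X, columns=["e1", "e2", "e3", "cov"]), t, e, mask


def test_path_at_zero_matches_newton(path_design):
    X, t, e, mask = path_design
    path = CoxL1Path(lambdas=np.linspace(0, 0.05, 6), penalized=mask).fit(X, (t, e))
    newton = CoxPH().fit(X, (t, e))
    assert path.converged_[0]
    assert np.allclose(path.coef_path_[0], newton.coef_, atol=1e-6)


def test_large_lambda_zeroes_masked_terms_only(path_design):
    X, t, e, mask = path_design
    path = CoxL1Path(lambdas=np.linspace(0, 0.05, 6), penalized=mask).fit(X, (t, e))
    final = path.coef_path_[-1]
    assert np.all(final[mask] == 0.0)  # exact zeros from soft-thresholding
    assert abs(final[~mask][0]) > 0.1  # the covariate is never shrunk away


def test_masked_coefficients_shrink_along_path(path_design):
    X, t, e, mask = path_design
    path = CoxL1Path(lambdas=np.linspace(0, 0.05, 6), penalized=mask).fit(X, (t, e))
    mags = np.abs(path.coef_path_[:, mask])
    assert np.all(mags[1:] <= mags[:-1] + 1e-4)


def test_default_grid_matches_printed_design():
    g = default_cox_lambda_grid()
    assert g[0] == 0.0
    assert g[-1] == pytest.approx(2e-3)
    assert len(g) == 41
    assert np.allclose(np.diff(g), 5e-5)
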