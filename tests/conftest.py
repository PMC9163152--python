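import numpy as np
import pandas as pd
import pytest

from spcacox.cohort import generate_cohort, paper_like_spec


def exact_correlation_sample(n: int, R: np.ndarray, seed: int = 0) -> np.ndarray:
    """Sample X (n x p) whose sample mean is exactly 0, sample SD (ddof=1)
    exactly 1, and sample correlation exactly R — closed-form fixtures for
    PCA/SPCA tests."""
    p = R.shape[0]
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, p))
    z -= z.mean(axis=0)
    S = z.T @ z / (n - 1)
    z = z @ np.linalg.inv(np.linalg.cholesky(S)).T
    return z @ np.linalg.cholesky(R).T


def block_correlation(sizes, within, cross=0.0) -> np.ndarray:
    blocks = []
    p = sum(sizes)
    R = np.full((p, p), cross, dtype=float)
    start = 0
    for size, r in zip(sizes, within):
        R[start:start + size, start:start + size] = r
        start += size
    np.fill_diagonal(R, 1.0)
    return R


@pytest.fixture(scope="session")
def two_block_X() -> np.ndarray:
    """4 variables: two within-block pairs at r=0.9, zero cross-block."""
    R = block_correlation([2, 2], [0.9, 0.9])
    return exact_correlation_sample(2000, R, seed=11)


@pytest.fixture(scope="session")
def cohort_50k() -> pd.DataFrame:
    spec = paper_like_spec(n_subjects=50_000, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def spec_50k():
    return paper_like_spec(n_subjects=50_000, seed=7)


# ---------------------------------------------------------------------------
# brute-force Cox oracle: naive Efron partial likelihood by enumeration

def efron_loglik_naive(beta, X, time, event) -> float:
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    eta = X @ beta
    ll = 0.0
    for t in sorted(set(np.asarray(time)[np.asarray(event) == 1])):
        D = [i for i in range(len(time)) if time[i] == t and event[i] == 1]
        R = [i for i in range(len(time)) if time[i] >= t]
        sR = sum(np.exp(eta[i]) for i in R)
        sD = sum(np.exp(eta[i]) for i in D)
        d = len(D)
        ll += sum(eta[i] for i in D)
        for l in range(d):
            ll -= np.log(sR - (l / d) * sD)
    return float(ll)


def brute_force_cox(X, time, event, bounds=(-8.0, 8.0)):
    """Maximize the naive Efron partial likelihood by direct numeric search."""
    from scipy import optimize

    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    p = X.shape[1]
    if p == 1:
        res = optimize.minimize_scalar(
            lambda b: -efron_loglik_naive([b], X, time, event),
            bounds=bounds, method="bounded",
            options={"xatol": 1e-12},
        )
        return np.array([res.x])
    best = None
    for start in ([0.0] * p, [0.5] * p, [-0.5] * p):
        res = optimize.minimize(
            lambda b: -efron_loglik_naive(b, X, time, event),
            x0=np.array(start), method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000, "maxfev": 20000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x


#: Tiny survival designs with interior optima (checked against ``bounds``):
#: (X, time, event) with n <= 8, including tied event times.
TINY_COX_FIXTURES = [
    # 3 subjects, all events, covariate on the middle event: MLE = ln(2)/2
    (np.array([[0.0], [1.0], [0.0]]), np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1])),
    # 5 subjects with one censored and a tied event pair
    (np.array([[1.0], [0.0], [1.0], [0.0], [1.0]]),
     np.array([2.0, 2.0, 3.0, 4.0, 5.0]), np.array([1, 1, 0, 1, 1])),
    # 6 subjects, binary + continuous covariates, tie at t=1
    (np.array([[1.0, 0.2], [0.0, -0.5], [1.0, 1.0], [0.0, 0.3], [1.0, -1.2], [0.0, 0.7]]),
     np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0]), np.array([1, 1, 1, 0, 1, 1])),
    # 8 subjects, continuous covariate, two tied pairs
    (np.array([[0.5], [-0.3], [0.8], [0.1], [-0.9], [0.4], [-0.2], [0.6]]),
     np.array([1.0, 1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
     np.array([1, 1, 1, 1, 0, 1, 1, 0])),
]
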