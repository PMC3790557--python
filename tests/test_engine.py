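"""Penalized IRLS engine: oracle equivalence, shrinkage, EDF behaviour."""

import numpy as np
import pytest

from phenogamm.model import PhenologyGamm


def newton_logistic(X, y, weights, maxiter=100):
    """Independent Newton-Raphson logistic regression oracle."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = weights * mu * (1 - mu)
        grad = X.T @ (weights * (y - mu))
        H = (X * W[:, None]).T @ X
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = 1 / (1 + np.exp(-(X @ beta)))
    dev = 2 * np.sum(weights * (
        np.where(y > 0, y * np.log(y / mu), 0)
        + np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0)
    ))
    return beta, dev


@pytest.fixture(scope="module")
def m1_counts():
    rng = np.random.default_rng(77)
    t = np.arange(1, 121, dtype=float)
    cal = ((t - 1) % 12) + 1
    eta = 0.012 * (t - t.mean()) + 1.2 * np.sin(2 * np.pi * cal / 12)
    k = rng.binomial(25, 1 / (1 + np.exp(-eta)))
    model = PhenologyGamm.from_arrays(
        "M1", y=k / 25, t_values=t, calendar_values=cal,
        weights=np.full(120, 25.0),
    )
    return model


def test_intercept_only_logit_half():
    y = np.r_[np.ones(30), np.zeros(30)]
    res = PhenologyGamm.from_arrays("M5", y=y, t_values=np.arange(60.0)).fit()
    assert res.params[0] == pytest.approx(0.0, abs=1e-10)
    assert res.llf == pytest.approx(60 * np.log(0.5), rel=1e-10)


def test_unpenalized_fit_matches_newton_oracle(m1_counts):
    """lambda=0 engine equals an independently coded Newton logistic fit."""
    res = m1_counts.fit(lambdas={"trend": 0.0, "seasonal": 0.0})
    d = m1_counts.design
    beta_o, dev_o = newton_logistic(d.X, d.y, d.weights)
    np.testing.assert_allclose(res.params, beta_o, rtol=1e-6, atol=1e-8)
    assert res.deviance == pytest.approx(dev_o, rel=1e-6)
    # cross-check the oracle itself against statsmodels once
    import statsmodels.api as sm
    glm = sm.GLM(d.y, d.X, family=sm.families.Binomial(),
                 freq_weights=d.weights).fit()
    np.testing.assert_allclose(beta_o, glm.params, rtol=1e-6, atol=1e-8)


def test_huge_lambda_shrinks_smooth_to_null_space(m1_counts):
    res = m1_counts.fit(lambdas={"trend": 1e9, "seasonal": 1e9})
    # cyclic term: centred null space empty -> contribution vanishes
    band = res.credible_band("seasonal", np.linspace(0.5, 12, 48))
    assert np.max(np.abs(band.fit)) < 1e-3
    # cubic trend: only the (centred) linear component survives
    t = np.arange(1, 121, dtype=float)
    fit_t = res.credible_band("trend", t).fit
    lin = np.polyfit(t, fit_t, 1)
    assert np.max(np.abs(fit_t - np.polyval(lin, t))) < 1e-3


def test_edf_monotone_in_lambda(m1_counts):
    lams = [1e-3, 1e-1, 10.0, 1e3, 1e5, 1e8]
    edfs = [
        m1_counts.fit(lambdas={"trend": lam, "seasonal": 1.0}).edf("trend")
        for lam in lams
    ]
    assert all(a >= b - 1e-8 for a, b in zip(edfs, edfs[1:]))
    assert edfs[0] <= 9.0 + 1e-8 and edfs[-1] >= 1.0 - 1e-8


def test_ml_selection_strong_signal_and_determinism(m1_counts):
    res1 = m1_counts.fit()
    res2 = m1_counts.fit()
    assert res1.converged
    np.testing.assert_array_equal(res1.params, res2.params)
    # cyclic term EDF substantially above 1 under a strong annual signal
    assert res1.edf("seasonal") > 2.0
    assert res1.smooth_test("seasonal").p_value < 1e-6


def test_posterior_cov_is_symmetric_psd(m1_counts):
    res = m1_counts.fit()
    V = res.cov_params
    np.testing.assert_allclose(V, V.T, atol=1e-12)
    assert np.linalg.eigvalsh(V).min() > -1e-10


def test_separation_triggers_ridge_fallback():
    y = np.r_[np.zeros(20), np.ones(20)]
    x = np.r_[np.zeros(20), np.ones(20)]
    from phenogamm._engine import fit_pirls
    X = np.column_stack([np.ones(40), x])
    with pytest.warns(RuntimeWarning, match="separation"):
        fit = fit_pirls(X, y, np.ones(40), np.zeros(2), maxiter=50)
    assert fit.ridged
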