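"""Results-object inference: bands, Wald tests, summaries."""

import numpy as np
import pytest

from phenogamm.model import PhenologyGamm


@pytest.fixture(scope="module")
def seasonal_fit():
    rng = np.random.default_rng(8)
    t = np.arange(1, 121, dtype=float)
    cal = ((t - 1) % 12) + 1
    eta = 1.0 * np.sin(2 * np.pi * cal / 12)
    k = rng.binomial(20, 1 / (1 + np.exp(-eta)))
    return PhenologyGamm.from_arrays(
        "M1", y=k / 20, t_values=t, calendar_values=cal,
        weights=np.full(120, 20.0),
    ).fit()


def test_band_level_monotonicity(seasonal_fit):
    pts = np.linspace(0.5, 12.0, 24)
    b95 = seasonal_fit.credible_band("seasonal", pts, level=0.95)
    b80 = seasonal_fit.credible_band("seasonal", pts, level=0.80)
    assert np.all(b95.lower <= b80.lower + 1e-12)
    assert np.all(b95.upper >= b80.upper - 1e-12)
    assert np.all(b95.lower <= b95.fit) and np.all(b95.fit <= b95.upper)
    with pytest.raises(ValueError):
        seasonal_fit.credible_band("seasonal", pts, level=1.2)


def test_zero_posterior_cov_collapses_band(seasonal_fit):
    import copy
    res = copy.copy(seasonal_fit)
    res.cov_params = np.zeros_like(seasonal_fit.cov_params)
    b = res.credible_band("seasonal", np.arange(12) + 0.5)
    np.testing.assert_array_equal(b.lower, b.fit)
    np.testing.assert_array_equal(b.upper, b.fit)


def test_zero_coefficients_give_zero_statistic(seasonal_fit):
    import copy
    res = copy.copy(seasonal_fit)
    res.params = np.zeros_like(seasonal_fit.params)
    st = res.smooth_test("seasonal")
    assert st.statistic == 0.0
    assert st.p_value == 1.0


def test_smooth_test_invariant_to_basis_rotation(seasonal_fit):
    """Function-space statistic is unchanged by rotating the term's columns
    (with the matching coefficient/covariance transforms)."""
    import copy
    res = copy.copy(seasonal_fit)
    ti = res.design.term("seasonal")
    cols = ti.cols
    rng = np.random.default_rng(0)
    q, _ = np.linalg.qr(rng.normal(size=(len(cols), len(cols))))
    # rotate: beta -> Q' beta, V -> Q' V Q, design rows -> rows Q
    params = seasonal_fit.params.copy()
    params[cols] = q.T @ params[cols]
    V = seasonal_fit.cov_params.copy()
    V[np.ix_(cols, cols)] = q.T @ V[np.ix_(cols, cols)] @ q
    import dataclasses
    design = copy.copy(res.design)
    design.terms = [copy.copy(x) for x in res.design.terms]
    tnew = design.term("seasonal")
    tnew.transform = ti.transform @ q
    res.design = design
    res.params = params
    res.cov_params = V
    st0 = seasonal_fit.smooth_test("seasonal")
    st1 = res.smooth_test("seasonal")
    assert st1.statistic == pytest.approx(st0.statistic, rel=1e-8)
    assert st1.rank_r == st0.rank_r


def test_extrapolation_warning(seasonal_fit):
    with pytest.warns(RuntimeWarning, match="outside"):
        seasonal_fit.credible_band("trend", np.array([150.0]))


def test_summary_and_json(seasonal_fit, tmp_path):
    text = seasonal_fit.summary()
    assert "structure: M1" in text and "s(seasonal)" in text
    out = tmp_path / "fit.json"
    seasonal_fit.to_json(out)
    import json
    d = json.loads(out.read_text())
    assert d["structure"] == "M1"
    assert set(d["smooth_tests"]) == {"trend", "seasonal"}
    assert d["edf_per_smooth"]["seasonal"] > 0
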