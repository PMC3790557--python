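"""Mixed-model extensions: lag-1 term and per-plant random intercepts."""

import numpy as np
import pandas as pd
import pytest

from phenogamm.design import build_lag_term
from phenogamm.model import PhenologyGamm
from phenogamm.panel import PhenologyPanel


def _panel_from_matrix(Y, species="A"):
    t = np.arange(1, Y.shape[1] + 1)
    frames = [
        pd.DataFrame({
            "plant_id": f"p{k:03d}", "species": species, "month_index": t,
            "calendar_month": (((t - 1) % 12) + 1).astype(float),
            "status": Y[k].astype(float),
        })
        for k in range(Y.shape[0])
    ]
    return PhenologyPanel(pd.concat(frames, ignore_index=True))


def test_lag_column_alignment_and_first_drop():
    panel = _panel_from_matrix(np.array([[1, 1, 0, 0], [0, 1, 1, 1]]))
    pd_ = build_lag_term(panel)
    assert pd_.dropped_first_obs == 2
    np.testing.assert_array_equal(pd_.lag_column, [1, 1, 0, 0, 1, 1])
    np.testing.assert_array_equal(pd_.y, [1, 0, 0, 1, 1, 1])
    # no cross-plant leakage: each row's lag equals the same plant's previous
    np.testing.assert_array_equal(pd_.plant_index, [0, 0, 0, 1, 1, 1])


def test_lag_requires_complete_panel():
    Y = np.array([[1.0, np.nan, 0, 1]])
    with pytest.raises(ValueError, match="missing"):
        build_lag_term(_panel_from_matrix(Y))


def test_single_plant_refuses_random_effects():
    from phenogamm.design import add_random_intercepts

    panel = _panel_from_matrix(np.array([[1, 0, 1, 0, 1, 0]]))
    with pytest.raises(ValueError, match="at least 2 plants"):
        add_random_intercepts(build_lag_term(panel))


@pytest.fixture(scope="module")
def heterogeneous_panel():
    """20 plants, 120 months, sigma=1 heterogeneity, persistent chains."""
    rng = np.random.default_rng(314)
    b = rng.normal(0, 1.0, 20)
    Y = np.empty((20, 120))
    for k in range(20):
        prev = 0.0
        for i in range(120):
            eta = -0.5 + b[k] + 1.0 * prev
            Y[k, i] = rng.random() < 1 / (1 + np.exp(-eta))
            prev = Y[k, i]
    return _panel_from_matrix(Y)


def test_mixed_fit_recovers_heterogeneity_and_persistence(heterogeneous_panel):
    res = PhenologyGamm.from_panel(heterogeneous_panel, "M5", mixed=True).fit()
    assert res.converged
    assert 0.5 < res.re_sd < 1.6
    lag = res.design.term("lag")
    beta_lag = res.params[lag.cols[0]]
    se = np.sqrt(res.cov_params[lag.cols[0], lag.cols[0]])
    assert beta_lag - 2 * se > 0  # persistence detected as positive
    # predicted random intercepts roughly centred
    assert abs(res.random_effects.mean()) < 0.25


def test_sigma_zero_data_gives_small_sigma_hat():
    rng = np.random.default_rng(99)
    Y = (rng.random((20, 120)) < 0.5).astype(float)
    res = PhenologyGamm.from_panel(_panel_from_matrix(Y), "M5", mixed=True).fit()
    assert res.re_sd < 0.15


def test_plant_relabelling_permutes_random_effects(heterogeneous_panel):
    res = PhenologyGamm.from_panel(heterogeneous_panel, "M5", mixed=True).fit()
    frame = heterogeneous_panel.frame.copy()
    relabel = {f"p{k:03d}": f"q{(k * 7) % 20:03d}" for k in range(20)}
    frame["plant_id"] = frame["plant_id"].map(relabel)
    res2 = PhenologyGamm.from_panel(
        PhenologyPanel(frame), "M5", mixed=True
    ).fit()
    b1 = res.random_effects.rename(index=relabel).sort_index()
    b2 = res2.random_effects.sort_index()
    np.testing.assert_allclose(b1.to_numpy(), b2.to_numpy(), atol=1e-4)
    assert res.llf == pytest.approx(res2.llf, abs=1e-6)


def test_independent_bernoulli_lag_near_zero():
    rng = np.random.default_rng(123)
    hits = 0
    for rep in range(10):
        Y = (rng.random((10, 120)) < 0.5).astype(float)
        res = PhenologyGamm.from_panel(
            _panel_from_matrix(Y), "M5", mixed=True
        ).fit()
        j = res.design.term("lag").cols[0]
        se = np.sqrt(res.cov_params[j, j])
        hits += abs(res.params[j]) < 2 * se
    assert hits >= 9
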