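"""Two-state hidden Markov imputation of missing monthly fruit states.

Each plant's monthly 0/1 series is modelled by a two-state HMM with
Bernoulli emissions, fitted per plant by Baum-Welch EM; missing months
contribute a unit emission likelihood.  Missing entries are then replaced
using the forward-backward (smoothed) posterior probability of showing
fruit, thresholded at 0.5 so the completed series stays binary for the
lag-1 autocorrelation term downstream.

All recursions are scaled, never raw probability products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import PhenologyPanel

__all__ = ["HmmModel", "fit_hmm", "smooth_impute", "impute_panel"]

#: fixed, deterministic EM starting point
INIT_INITIAL = (0.5, 0.5)
INIT_TRANS_DIAG = 0.7
INIT_EMISSION = (0.25, 0.75)

EM_TOL = 1e-6
EM_MAXITER = 500
PROB_FLOOR = 1e-6


@dataclass
class HmmModel:
    """Two-state Bernoulli-emission hidden Markov model.

    ``emission[s]`` is the probability of observing fruit (status 1) in
    latent state ``s``.
    """

    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray
    log_likelihood: float = np.nan
    loglik_trace: list = field(default_factory=list)
    degenerate: bool = False

    def __post_init__(self):
        self.initial = np.asarray(self.initial, float)
        self.transition = np.asarray(self.transition, float)
        self.emission = np.asarray(self.emission, float)
        if self.initial.shape != (2,) or not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial must be a 2-vector summing to 1")
        if self.transition.shape != (2, 2) or not np.allclose(
            self.transition.sum(axis=1), 1.0
        ):
            raise ValueError("transition rows must sum to 1")
        if np.any((self.emission < 0) | (self.emission > 1)):
            raise ValueError("emission probabilities must lie in [0, 1]")


def _emission_matrix(series, emission):
    """(T, 2) observation likelihoods; missing entries contribute 1."""
    T = len(series)
    E = np.ones((T, 2))
    for s in range(2):
        p = emission[s]
        obs1 = series == 1
        obs0 = series == 0
        E[obs1, s] = p
        E[obs0, s] = 1.0 - p
    return E


def _forward_backward(series, model: HmmModel):
    """Scaled forward-backward pass.

    Returns (gamma, xi, loglik): smoothed state marginals (T, 2), pairwise
    marginals (T-1, 2, 2) and the observed-data log-likelihood.
    """
    E = _emission_matrix(series, model.emission)
    T = len(series)
    A = model.transition
    alpha = np.zeros((T, 2))
    beta = np.zeros((T, 2))
    c = np.zeros(T)

    a = model.initial * E[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * E[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]

    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        b = A @ (E[t + 1] * beta[t + 1])
        beta[t] = b / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi = np.zeros((T - 1, 2, 2))
    for t in range(T - 1):
        m = alpha[t][:, None] * A * (E[t + 1] * beta[t + 1])[None, :]
        xi[t] = m / m.sum()

    return gamma, xi, float(np.sum(np.log(c)))


def fit_hmm(series) -> HmmModel:
    """Baum-Welch fit of the two-state model to one plant's series.

    ``series`` holds {0, 1, NaN}; NaN marks a missed survey.  The EM start
    is fixed (not random) so the fit is reproducible.  Degenerate all-0 or
    all-1 observed series shortcut to an emission pinned near the boundary.
    """
    s = np.asarray(series, float)
    obs = s[~np.isnan(s)]
    if len(s) < 4:
        raise ValueError("series must have length >= 4")
    if len(obs) == 0:
        raise ValueError("series is entirely missing")

    if np.all(obs == obs[0]):
        v = obs[0]
        p1 = 1.0 - PROB_FLOOR if v == 1 else PROB_FLOOR
        return HmmModel(
            initial=np.array([0.5, 0.5]),
            transition=np.array([[0.5, 0.5], [0.5, 0.5]]),
            emission=np.array([p1, p1]),
            log_likelihood=len(obs) * np.log(1.0 - PROB_FLOOR),
            degenerate=True,
        )

    model = HmmModel(
        initial=np.array(INIT_INITIAL),
        transition=np.array(
            [[INIT_TRANS_DIAG, 1 - INIT_TRANS_DIAG],
             [1 - INIT_TRANS_DIAG, INIT_TRANS_DIAG]]
        ),
        emission=np.array(INIT_EMISSION),
    )
    observed_mask = ~np.isnan(s)
    prev_ll = -np.inf
    trace = []
    for _ in range(EM_MAXITER):
        gamma, xi, ll = _forward_backward(s, model)
        trace.append(ll)
        if ll - prev_ll < EM_TOL and np.isfinite(prev_ll):
            break
        prev_ll = ll
        # M step
        initial = np.clip(gamma[0], PROB_FLOOR, None)
        initial /= initial.sum()
        num = xi.sum(axis=0)
        trans = num / np.clip(num.sum(axis=1, keepdims=True), 1e-300, None)
        trans = np.clip(trans, PROB_FLOOR, 1 - PROB_FLOOR)
        trans /= trans.sum(axis=1, keepdims=True)
        gobs = gamma[observed_mask]
        yobs = s[observed_mask]
        emission = (gobs * yobs[:, None]).sum(axis=0) / np.clip(
            gobs.sum(axis=0), 1e-300, None
        )
        emission = np.clip(emission, PROB_FLOOR, 1 - PROB_FLOOR)
        model = HmmModel(initial=initial, transition=trans, emission=emission)
    model.log_likelihood = trace[-1]
    model.loglik_trace = trace
    return model


def smooth_impute(series, model: HmmModel) -> tuple[np.ndarray, np.ndarray]:
    """Complete a series using smoothed posterior fruit probabilities.

    Returns ``(completed, posterior)`` where ``posterior[t]`` is the
    smoothed P(fruit=1) at month t.  Observed entries are never altered;
    each missing entry becomes ``1`` if its posterior exceeds 0.5, ``0`` if
    below, with exact ties resolved to the previous month's completed value
    (the study start falls back to 0).
    """
    s = np.asarray(series, float)
    gamma, _, _ = _forward_backward(s, model)
    posterior = gamma @ model.emission
    completed = s.copy()
    for t in np.flatnonzero(np.isnan(s)):
        p = posterior[t]
        if p > 0.5:
            completed[t] = 1.0
        elif p < 0.5:
            completed[t] = 0.0
        else:
            completed[t] = completed[t - 1] if t > 0 else 0.0
    return completed, posterior


def impute_panel(panel: PhenologyPanel):
    """HMM-impute every plant's series; returns (completed panel, mask table).

    The mask table records one row per imputed entry:
    ``plant_id, month_index, imputed_value, posterior``.
    """
    frame = panel.frame.copy()
    mask_rows = []
    for plant, grp in frame.groupby("plant_id", sort=False):
        s = grp["status"].to_numpy(float)
        if not np.isnan(s).any():
            continue
        model = fit_hmm(s)
        completed, posterior = smooth_impute(s, model)
        miss = np.flatnonzero(np.isnan(s))
        frame.loc[grp.index[miss], "status"] = completed[miss]
        for i in miss:
            mask_rows.append(
                {"plant_id": plant,
                 "month_index": int(grp["month_index"].iloc[i]),
                 "imputed_value": int(completed[i]),
                 "posterior": float(posterior[i])}
            )
    mask = pd.DataFrame(
        mask_rows,
        columns=["plant_id", "month_index", "imputed_value", "posterior"],
    )
    return PhenologyPanel(frame, start_month=panel.start_month), mask
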