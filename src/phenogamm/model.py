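"""The model class: a binomial GAMM for fruiting phenology panels.

Typical use::

    model = PhenologyGamm.from_panel(panel, structure="M1", mixed=True)
    res = model.fit()          # ML smoothing-parameter selection
    print(res.summary())
    band = res.credible_band("seasonal")

``fit(lambdas=...)`` fixes the smoothing parameters instead of selecting
them, which is occasionally useful for profiling and for tests.
"""

from __future__ import annotations

import numpy as np

from ._engine import fit_pirls, laplace_ml, select_lambda_ml, MLSelection
from .design import ModelDesign, assemble_from_panel, assemble_model
from .panel import PhenologyPanel
from .results import GammResults

__all__ = ["PhenologyGamm"]


class PhenologyGamm:
    """Binomial logit additive (mixed) model over a phenology design."""

    def __init__(self, design: ModelDesign):
        self.design = design

    # -- constructors ---------------------------------------------------------
    @classmethod
    def from_panel(
        cls,
        panel: PhenologyPanel,
        structure: str = "M1",
        *,
        mixed: bool = True,
        k_trend: int = 10,
        k_seasonal: int = 8,
    ) -> "PhenologyGamm":
        """Build a model from a complete (imputed) panel.

        ``mixed=True`` adds the lag-1 autocorrelation term and per-plant
        random intercepts of the empirical-analysis models.
        """
        return cls(assemble_from_panel(
            structure, panel, mixed=mixed,
            k_trend=k_trend, k_seasonal=k_seasonal,
        ))

    @classmethod
    def from_arrays(
        cls,
        structure: str,
        *,
        y,
        t_values,
        calendar_values=None,
        weights=None,
        k_trend: int = 10,
        k_seasonal: int = 8,
        **kw,
    ) -> "PhenologyGamm":
        """Build a model directly from arrays.

        ``y`` may be a 0/1 vector or, with ``weights`` giving binomial trial
        counts, a vector of success proportions — the natural form when
        exchangeable plants are aggregated by month.
        """
        return cls(assemble_model(
            structure, y=y, t_values=t_values,
            calendar_values=calendar_values, weights=weights,
            k_trend=k_trend, k_seasonal=k_seasonal, **kw,
        ))

    # -- fitting ----------------------------------------------------------------
    def fit(self, lambdas: dict | None = None, method: str = "ML") -> GammResults:
        """Fit the model.

        Parameters
        ----------
        lambdas : dict, optional
            Fixed smoothing parameters keyed by penalized term name
            (e.g. ``{"trend": 1.0, "seasonal": 0.5}``).  When omitted, all
            smoothing parameters (and the random-intercept variance) are
            selected by maximising the Laplace marginal likelihood.
        method : {"ML"}
            Only maximum-likelihood selection is provided.
        """
        if method != "ML":
            raise ValueError("only ML smoothing-parameter selection is supported")
        d = self.design
        pen_terms = d.penalized_terms
        if lambdas is not None:
            missing = [t.name for t in pen_terms if t.name not in lambdas]
            if missing:
                raise ValueError(f"lambdas missing for terms {missing}")
            pen = np.zeros(d.n_coef)
            for t in pen_terms:
                lam = float(lambdas[t.name])
                if lam < 0:
                    raise ValueError("smoothing parameters must be >= 0")
                pen[t.penalized_cols] = lam
            pirls = fit_pirls(d.X, d.y, d.weights, pen)
            blocks = [(t.penalized_cols, max(float(lambdas[t.name]), 1e-300))
                      for t in pen_terms]
            sel = MLSelection(
                fit=pirls,
                log_lambdas=np.log([max(float(lambdas[t.name]), 1e-300)
                                    for t in pen_terms]),
                ml=laplace_ml(pirls, blocks) if pen_terms else pirls.loglik,
                trace=[],
            )
            return GammResults(d, pirls, sel)

        if not pen_terms:
            pirls = fit_pirls(d.X, d.y, d.weights, np.zeros(d.n_coef))
            return GammResults(d, pirls, None)

        sel = select_lambda_ml(
            d.X, d.y, d.weights, [t.penalized_cols for t in pen_terms]
        )
        return GammResults(d, sel.fit, sel)
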