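"""Fitted-model results: EDFs, Wald smooth tests, credible bands, LRTs.

The posterior coefficient covariance ``(X'WX + S_lambda)^{-1}`` comes from
viewing the roughness penalty as a Gaussian prior; pointwise credible bands
for a smooth are ``f_hat +/- z * SE`` on the linear-predictor scale.  The
Wald test for a smooth uses the rank-r pseudoinverse of the term's posterior
covariance block with r tied to the term's effective degrees of freedom, and
refers the quadratic form to a chi-square upper tail.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ._engine import MLSelection, PirlsFit
from .design import ModelDesign


@dataclass
class SmoothTest:
    """Wald chi-square test of a smooth term against the zero function."""

    term_name: str
    statistic: float
    rank_r: int
    edf: float
    p_value: float


@dataclass
class CredibleBand:
    """Pointwise Bayesian credible band of a smooth on the logit scale."""

    term_name: str
    eval_points: np.ndarray
    fit: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def contains(self, target) -> np.ndarray:
        """Elementwise containment of a target function in the band."""
        target = np.asarray(target, float)
        return (self.lower <= target) & (target <= self.upper)

    def zero_excluded(self) -> np.ndarray:
        return ~self.contains(np.zeros_like(self.fit))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"eval_point": self.eval_points, "fit": self.fit,
             "lower": self.lower, "upper": self.upper}
        )


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of two nested structures."""

    full_label: str
    nested_label: str
    statistic: float
    df: int
    p_value: float
    flagged: bool = False


class GammResults:
    """Results of a penalized binomial GAM/GAMM fit.

    Parameters are reported in the natural parameterisation (intercept,
    parametric coefficients, then per-smooth null and range coordinates);
    use :meth:`credible_band` / :meth:`predict_smooth` for function-space
    summaries, which handle the parameterisation internally.
    """

    def __init__(self, design: ModelDesign, pirls: PirlsFit,
                 selection: MLSelection | None = None):
        self.design = design
        self._pirls = pirls
        self._selection = selection
        self.params = pirls.beta
        self.deviance = pirls.deviance
        self.converged = pirls.converged and (
            selection is None or selection.optimizer_converged
        )
        self.n_obs = design.n_obs
        self.scale = 1.0  # binomial

        # Bayesian posterior covariance (X'WX + S_lambda)^-1
        A = pirls.H.copy()
        A[np.diag_indices_from(A)] += pirls.pen_diag + 1e-10
        self.cov_params = np.linalg.inv(A)
        self._edf_diag = np.einsum("ij,ji->i", self.cov_params, pirls.H)

        self.smoothing_params = {}
        if selection is not None:
            for ti, rho in zip(design.penalized_terms, selection.log_lambdas):
                self.smoothing_params[ti.name] = float(np.exp(rho))
        elif pirls.pen_diag is not None:
            for ti in design.penalized_terms:
                lam = np.unique(pirls.pen_diag[ti.penalized_cols])
                self.smoothing_params[ti.name] = float(lam[0])

    # -- likelihoods ---------------------------------------------------------
    @property
    def llf(self) -> float:
        """Laplace-approximate marginal log-likelihood (ML criterion)."""
        if self._selection is not None:
            return self._selection.ml
        from ._engine import laplace_ml
        blocks = [
            (ti.penalized_cols, self.smoothing_params[ti.name])
            for ti in self.design.penalized_terms
        ]
        return laplace_ml(self._pirls, blocks)

    @property
    def loglik_conditional(self) -> float:
        """Conditional (kernel) binomial log-likelihood at the fitted state."""
        return self._pirls.loglik

    @property
    def fittedvalues(self) -> np.ndarray:
        return self._pirls.mu

    @property
    def linear_predictor(self) -> np.ndarray:
        return self._pirls.eta

    # -- effective degrees of freedom ----------------------------------------
    def edf(self, term_name: str | None = None) -> float:
        if term_name is None:
            return float(self._edf_diag.sum())
        ti = self.design.term(term_name)
        return float(self._edf_diag[ti.cols].sum())

    @property
    def edf_per_smooth(self) -> dict:
        return {name: self.edf(name) for name in self.design.smooth_names}

    # -- random effects --------------------------------------------------------
    @property
    def re_sd(self) -> float:
        """Random-intercept SD sigma = lambda_re ** -0.5 (0 if absent)."""
        lam = self.smoothing_params.get("random_intercept")
        if lam is None:
            return 0.0
        return float(lam ** -0.5)

    @property
    def random_effects(self) -> pd.Series | None:
        try:
            ti = self.design.term("random_intercept")
        except KeyError:
            return None
        return pd.Series(self.params[ti.cols], index=ti.levels, name="b_k")

    # -- inference -------------------------------------------------------------
    def smooth_test(self, term_name: str) -> SmoothTest:
        """Wald chi-square test that a smooth term is the zero function.

        The quadratic form is built in *function space*: the fitted term
        values over the observed covariate grid and the rank-r pseudoinverse
        of their posterior covariance, with r the term's effective degrees
        of freedom rounded to the nearest integer (minimum 1).  Function
        space makes the statistic invariant to how the basis is
        parameterised, and the rank truncation keeps exactly the effective
        estimation space of the penalized smooth.
        """
        ti = self.design.term(term_name)
        if ti.kind != "smooth":
            raise ValueError(f"{term_name!r} is not a smooth term")
        if term_name == "seasonal":
            grid = np.unique(self.design.calendar_values)
            rows = self.design.term_rows(term_name, new_calendar=grid)
        else:
            grid = np.unique(self.design.t_values)
            rows = self.design.term_rows(term_name, new_t=grid)
        beta_j = self.params[ti.cols]
        V_j = self.cov_params[np.ix_(ti.cols, ti.cols)]
        f = rows @ beta_j
        # eigenpairs of rows V rows' through an economical SVD
        vals, vecs = np.linalg.eigh(0.5 * (V_j + V_j.T))
        vals = np.clip(vals, 0.0, None)
        B = rows @ (vecs * np.sqrt(vals))
        U, s, _ = np.linalg.svd(B, full_matrices=False)
        lam = s**2
        edf = self.edf(term_name)
        r = max(1, int(round(edf)))
        usable = int(np.sum(lam > 1e-10 * max(lam[0], 1e-300)))
        if usable < r:
            warnings.warn(
                f"covariance of {term_name!r} rank-deficient; "
                f"reducing Wald rank {r} -> {usable}", RuntimeWarning,
            )
            r = max(1, usable)
        proj = U[:, :r].T @ f
        stat = float(np.sum(proj**2 / lam[:r]))
        return SmoothTest(
            term_name=term_name, statistic=stat, rank_r=r, edf=edf,
            p_value=float(stats.chi2.sf(stat, r)),
        )

    def credible_band(self, term_name: str, eval_points=None,
                      level: float = 0.95) -> CredibleBand:
        """Pointwise (1-level omitted) Bayesian band for a smooth term."""
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        ti = self.design.term(term_name)
        if eval_points is None:
            if term_name == "seasonal":
                eval_points = np.arange(12) + 0.5
            else:
                eval_points = np.unique(self.design.t_values)
        eval_points = np.asarray(eval_points, float)
        if ti.kind == "smooth" and ti.expansion.spec.basis_kind == "cubic":
            kn = ti.expansion.knots
            if eval_points.min() < kn[0] - 1e-9 or eval_points.max() > kn[-1] + 1e-9:
                warnings.warn(
                    f"evaluating {term_name!r} outside its training range; "
                    "linear extrapolation", RuntimeWarning,
                )
        rows = self.design.term_rows(
            term_name,
            new_t=eval_points if term_name != "seasonal" else None,
            new_calendar=eval_points if term_name == "seasonal" else None,
        )
        fit = rows @ self.params[ti.cols]
        V = self.cov_params[np.ix_(ti.cols, ti.cols)]
        se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", rows, V, rows), 0, None))
        z = stats.norm.ppf(0.5 + level / 2.0)
        return CredibleBand(
            term_name=term_name, eval_points=eval_points, fit=fit,
            lower=fit - z * se, upper=fit + z * se, level=level,
        )

    def slope_interval(self, level: float = 0.95):
        """Estimate and CI of the parametric linear-trend coefficient (M2)."""
        ti = self.design.term("linear_trend")
        j = ti.cols[0]
        est = float(self.params[j])
        se = float(np.sqrt(self.cov_params[j, j]))
        z = stats.norm.ppf(0.5 + level / 2.0)
        return est, est - z * se, est + z * se

    # -- presentation ----------------------------------------------------------
    def summary(self) -> str:
        d = self.design
        lines = [
            "Binomial GAMM fit (logit link)",
            f"  structure: {d.structure}   mixed: {d.mixed}   "
            f"n_obs: {self.n_obs}   converged: {self.converged}",
            f"  deviance: {self.deviance:.3f}   marginal logLik: {self.llf:.3f}"
            f"   total EDF: {self.edf():.2f}",
        ]
        if d.mixed:
            lines.append(f"  random-intercept SD sigma: {self.re_sd:.4f}")
            try:
                ti = d.term("lag")
                j = ti.cols[0]
                lines.append(
                    f"  lag-1 coefficient: {self.params[j]:.4f} "
                    f"(SE {np.sqrt(self.cov_params[j, j]):.4f})"
                )
            except KeyError:
                pass
        for name in d.smooth_names:
            st = self.smooth_test(name)
            lines.append(
                f"  s({name}): edf={st.edf:.2f} lambda="
                f"{self.smoothing_params.get(name, float('nan')):.4g} "
                f"chi2={st.statistic:.2f} rank={st.rank_r} p={st.p_value:.4g}"
            )
        try:
            est, lo, hi = self.slope_interval()
            lines.append(f"  linear trend slope: {est:.5f} [{lo:.5f}, {hi:.5f}]")
        except KeyError:
            pass
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "structure": self.design.structure,
            "mixed": self.design.mixed,
            "n_obs": self.n_obs,
            "converged": bool(self.converged),
            "deviance": self.deviance,
            "llf": self.llf,
            "edf_total": self.edf(),
            "edf_per_smooth": self.edf_per_smooth,
            "smoothing_params": self.smoothing_params,
            "re_sd": self.re_sd,
            "smooth_tests": {
                name: asdict(self.smooth_test(name))
                for name in self.design.smooth_names
            },
        }
        return out

    def to_json(self, path=None, **kw) -> str:
        s = json.dumps(self.to_dict(), indent=2, default=float, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def likelihood_ratio_test(
    full: GammResults, nested: GammResults, df_rule: str = "structural"
) -> ModelComparison:
    """LRT of two nested structures fitted by ML on the same data.

    With the ``"structural"`` df rule each trend/seasonal component counts
    its fixed null-space coefficients plus its variance components: a cubic
    trend smooth contributes 2, a cyclic seasonal smooth 1, a parametric
    slope 1.  Chi-square reference as in standard practice; the boundary
    caveat for variance components is documented, not corrected for.
    """
    if df_rule != "structural":
        raise ValueError("only the 'structural' df rule is implemented")
    df = full.design.structural_df() - nested.design.structural_df()
    if df < 1:
        raise ValueError(
            f"{nested.design.structure} is not nested below {full.design.structure}"
        )
    stat = 2.0 * (full.llf - nested.llf)
    flagged = False
    if stat < -1e-6:
        flagged = True
    stat = max(stat, 0.0)
    return ModelComparison(
        full_label=full.design.structure,
        nested_label=nested.design.structure,
        statistic=float(stat), df=int(df),
        p_value=float(stats.chi2.sf(stat, df)), flagged=flagged,
    )
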