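"""Model assembly: the M1–M5 structure suite, lag terms and random intercepts.

The five core structures on the logit scale are

====== =========================================================
label  linear predictor
====== =========================================================
M1     beta0 + s1(t) + s2(calendar month)   nonlinear trend + seasonality
M2     beta0 + beta1 t + s2(calendar month) linear trend + seasonality
M3     beta0 + s1(t)                        nonlinear trend only
M4     beta0 + s2(calendar month)           seasonality only
M5     beta0                                constant probability
====== =========================================================

For panel (mixed) fits every structure gains a lag-1 autocorrelation term
``beta_lag * y[t-1]`` and per-plant random intercepts ``b_k ~ N(0, sigma^2)``.
Random intercepts are represented as one more penalized block with identity
penalty and smoothing parameter ``lambda_re = 1 / sigma^2``, so one optimizer
estimates smoothing parameters and the random-effect variance jointly.

Smooth blocks are re-expressed internally in the *natural* parameterisation
(eigenbasis of the centred penalty): null-space directions become ordinary
unpenalised columns and range-space directions carry an identity penalty.
This makes every penalty diagonal, is numerically stable, and mirrors the
mixed-model representation of a penalized smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import PhenologyPanel
from .splines import BasisExpansion, SmoothTermSpec, build_basis

MODEL_LABELS = ("M1", "M2", "M3", "M4", "M5")

#: structural degrees of freedom of each trend/seasonal component, used by
#: the likelihood-ratio df rule: a cubic trend smooth counts its linear
#: fixed part plus one variance component (2), a cyclic smooth one variance
#: component (1), a parametric slope one fixed coefficient (1).
STRUCTURAL_DF = {"M1": 3, "M2": 2, "M3": 2, "M4": 1, "M5": 0}

#: trend/seasonal components present in each structure
COMPONENTS = {
    "M1": ("trend", "seasonal"),
    "M2": ("linear", "seasonal"),
    "M3": ("trend",),
    "M4": ("seasonal",),
    "M5": (),
}


@dataclass
class TermInfo:
    """Placement of one model term inside the assembled design matrix."""

    name: str
    kind: str                      # intercept | linear | lag | smooth | random
    cols: np.ndarray               # all columns of the term
    penalized_cols: np.ndarray     # subset carrying the identity penalty
    rank: int                      # penalty rank (0 for unpenalised terms)
    expansion: BasisExpansion | None = None
    transform: np.ndarray | None = None   # centred-basis -> natural columns
    levels: np.ndarray | None = None      # random-effect level labels

    @property
    def penalized(self) -> bool:
        return self.rank > 0


@dataclass
class ModelDesign:
    """Assembled design matrix plus term bookkeeping for one model structure."""

    structure: str
    X: np.ndarray
    y: np.ndarray                   # successes / trials, in [0, 1]
    weights: np.ndarray             # binomial trials per row
    terms: list[TermInfo]
    t_values: np.ndarray            # month index per row
    calendar_values: np.ndarray
    mixed: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    def term(self, name: str) -> TermInfo:
        for ti in self.terms:
            if ti.name == name:
                return ti
        raise KeyError(f"no term named {name!r}; have {[t.name for t in self.terms]}")

    @property
    def penalized_terms(self) -> list[TermInfo]:
        return [t for t in self.terms if t.penalized]

    @property
    def smooth_names(self) -> list[str]:
        return [t.name for t in self.terms if t.kind == "smooth"]

    def structural_df(self) -> int:
        return STRUCTURAL_DF[self.structure]

    def term_rows(self, name: str, new_t=None, new_calendar=None) -> np.ndarray:
        """Design rows for one smooth term at new covariate values, mapped to
        the term's natural columns (for prediction and credible bands)."""
        ti = self.term(name)
        if ti.kind != "smooth":
            raise ValueError(f"{name!r} is not a smooth term")
        values = new_t if name == "trend" else new_calendar
        if values is None:
            raise ValueError(f"need evaluation points for term {name!r}")
        return ti.expansion.design_rows(np.asarray(values, float)) @ ti.transform


@dataclass
class PanelDesign:
    """Panel rows prepared for a mixed fit: lag column and plant indexing.

    The first month of each plant's series has no within-plant predecessor;
    those rows are dropped (conditional likelihood given each first month),
    counted in ``dropped_first_obs``.
    """

    panel: PhenologyPanel
    y: np.ndarray
    lag_column: np.ndarray
    plant_index: np.ndarray          # integer code per row
    plant_levels: np.ndarray
    t_values: np.ndarray
    calendar_values: np.ndarray
    dropped_first_obs: int


def build_lag_term(panel: PhenologyPanel) -> PanelDesign:
    """Within-plant lag-1 status column; first observation per plant dropped."""
    if not panel.is_complete():
        raise ValueError("panel has missing statuses; impute before building lags")
    f = panel.frame
    lag = f.groupby("plant_id")["status"].shift(1)
    keep = lag.notna().to_numpy()
    levels, codes = np.unique(f["plant_id"].to_numpy(), return_inverse=True)
    return PanelDesign(
        panel=panel,
        y=f["status"].to_numpy(float)[keep],
        lag_column=lag.to_numpy(float)[keep],
        plant_index=codes[keep],
        plant_levels=levels,
        t_values=f["month_index"].to_numpy(float)[keep],
        calendar_values=f["calendar_month"].to_numpy(float)[keep],
        dropped_first_obs=int((~keep).sum()),
    )


def add_random_intercepts(pdesign: PanelDesign) -> tuple[np.ndarray, np.ndarray]:
    """Indicator block for per-plant random intercepts (identity penalty).

    Returns the (n, n_plants) indicator matrix and the level labels.  With
    smoothing parameter ``lambda_re`` the implied random-intercept SD is
    ``sigma = lambda_re ** -0.5``.
    """
    n_plants = len(pdesign.plant_levels)
    if n_plants < 2:
        raise ValueError(
            "random intercepts need at least 2 plants; use a fixed intercept"
        )
    Z = np.zeros((len(pdesign.y), n_plants))
    Z[np.arange(len(pdesign.y)), pdesign.plant_index] = 1.0
    return Z, pdesign.plant_levels


def _natural_smooth_columns(expansion: BasisExpansion):
    """Split a centred smooth into unpenalised null and identity-penalised
    range columns via the penalty eigenbasis."""
    vals, vecs = np.linalg.eigh(expansion.penalty)
    d0 = expansion.null_space_dim
    order = np.argsort(vals)
    vals, vecs = vals[order], vecs[:, order]
    U0 = vecs[:, :d0]
    Up = vecs[:, d0:]
    dp = np.clip(vals[d0:], 1e-12, None)
    T = np.hstack([U0, Up / np.sqrt(dp)])
    return expansion.design_block @ T, T, d0


def assemble_model(
    structure: str,
    *,
    y,
    t_values,
    calendar_values=None,
    weights=None,
    k_trend: int = 10,
    k_seasonal: int = 8,
    period: float = 12.0,
    lag_column=None,
    plant_index=None,
    plant_levels=None,
    mixed: bool = False,
) -> ModelDesign:
    """Assemble the design matrix for one of the M1–M5 structures.

    Array-level entry point; see :func:`assemble_from_panel` for panels.
    ``weights`` are binomial trial counts (default 1), allowing month-level
    aggregation of exchangeable plants.
    """
    if structure not in MODEL_LABELS:
        raise ValueError(f"unknown model label {structure!r}")
    y = np.asarray(y, float)
    t_values = np.asarray(t_values, float)
    n = len(y)
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, float)
    comps = COMPONENTS[structure]
    if "seasonal" in comps:
        if calendar_values is None:
            raise ValueError(f"structure {structure} needs calendar_values")
        calendar_values = np.asarray(calendar_values, float)
    elif calendar_values is None:
        calendar_values = np.full(n, np.nan)

    blocks: list[np.ndarray] = [np.ones((n, 1))]
    terms: list[TermInfo] = [
        TermInfo("intercept", "intercept", np.array([0]), np.array([], int), 0)
    ]
    col = 1

    def push(name, kind, block, *, rank=0, expansion=None, transform=None,
             levels=None, pen_offset=None):
        nonlocal col
        p = block.shape[1]
        cols = np.arange(col, col + p)
        pen = cols[pen_offset:] if rank else np.array([], int)
        blocks.append(block)
        terms.append(TermInfo(name, kind, cols, pen, rank, expansion,
                              transform, levels))
        col += p

    if "linear" in comps:
        tc = t_values - t_values.mean()
        push("linear_trend", "linear", tc[:, None])
    if "trend" in comps:
        exp1 = build_basis(SmoothTermSpec("month_index", "cubic", k_trend),
                           t_values)
        Xs, T, d0 = _natural_smooth_columns(exp1)
        push("trend", "smooth", Xs, rank=Xs.shape[1] - d0,
             expansion=exp1, transform=T, pen_offset=d0)
    if "seasonal" in comps:
        exp2 = build_basis(
            SmoothTermSpec("calendar_month", "cyclic_cubic", k_seasonal,
                           period=period),
            calendar_values,
        )
        Xs, T, d0 = _natural_smooth_columns(exp2)
        push("seasonal", "smooth", Xs, rank=Xs.shape[1] - d0,
             expansion=exp2, transform=T, pen_offset=d0)

    if mixed:
        if plant_index is None:
            raise ValueError("mixed=True requires plant_index")
        if lag_column is not None:
            lag = np.asarray(lag_column, float)
            push("lag", "lag", lag[:, None])
        plant_index = np.asarray(plant_index)
        n_plants = int(plant_index.max()) + 1
        Z = np.zeros((n, n_plants))
        Z[np.arange(n), plant_index] = 1.0
        push("random_intercept", "random", Z, rank=n_plants,
             levels=plant_levels, pen_offset=0)

    X = np.hstack(blocks)
    return ModelDesign(
        structure=structure, X=X, y=y, weights=weights, terms=terms,
        t_values=t_values, calendar_values=calendar_values, mixed=mixed,
    )


def assemble_from_panel(
    structure: str,
    panel: PhenologyPanel,
    *,
    mixed: bool = True,
    k_trend: int = 10,
    k_seasonal: int = 8,
) -> ModelDesign:
    """Assemble a structure from a (complete) phenology panel.

    With ``mixed=True`` the design follows the empirical-analysis form: lag-1
    autocorrelation term plus per-plant random intercepts, first month of
    each plant's series conditioned on.
    """
    if mixed:
        pd_ = build_lag_term(panel)
        md = assemble_model(
            structure, y=pd_.y, t_values=pd_.t_values,
            calendar_values=pd_.calendar_values,
            k_trend=k_trend, k_seasonal=k_seasonal,
            lag_column=pd_.lag_column, plant_index=pd_.plant_index,
            plant_levels=pd_.plant_levels, mixed=True,
        )
        md.meta["dropped_first_obs"] = pd_.dropped_first_obs
        return md
    f = panel.frame
    if f["status"].isna().any():
        raise ValueError("panel has missing statuses; impute first")
    return assemble_model(
        structure, y=f["status"].to_numpy(float),
        t_values=f["month_index"].to_numpy(float),
        calendar_values=f["calendar_month"].to_numpy(float),
        k_trend=k_trend, k_seasonal=k_seasonal,
    )
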