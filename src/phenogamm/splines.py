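"""Cubic and cyclic-cubic regression spline bases with curvature penalties.

A smooth term :math:`s(x)` is represented as a natural (or periodic) cubic
spline parameterised by its values at a set of knots.  The associated
roughness penalty is the integrated squared second derivative
:math:`\\int s''(x)^2\\,dx`, available in closed form from the spline
representation.  Identifiability of multiple smooths alongside an intercept
is enforced by a sum-to-zero constraint over the fitting data, absorbed into
the basis by a Householder reparameterisation, so each returned design
column sums exactly to zero.

The value-at-knot parameterisation follows the classical natural-spline
construction: with knots :math:`x_1 < \\dots < x_k` and
:math:`h_j = x_{j+1} - x_j`, the vector of second derivatives at the knots
is :math:`\\gamma = B^{-1} D \\beta` for banded matrices ``B`` and ``D``
determined by the knot spacing, and the penalty is
:math:`S = D^\\top B^{-1} D`.  The cyclic variant wraps both matrices so the
function and its first two derivatives match across the period boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "SmoothTermSpec",
    "BasisExpansion",
    "build_basis",
    "evaluate_smooth",
    "DegenerateBasisError",
]


class DegenerateBasisError(ValueError):
    """Raised when the covariate carries too few distinct values for the basis."""


@dataclass(frozen=True)
class SmoothTermSpec:
    """Declarative description of one smooth term.

    Parameters
    ----------
    covariate_name : str
        Column / covariate label the smooth applies to.
    basis_kind : {"cubic", "cyclic_cubic"}
        Natural cubic regression spline, or its periodic variant.
    max_dim : int
        Maximum basis dimension (number of knots, counting the duplicated
        period endpoint for the cyclic basis).  The realised column count
        after constraints is ``max_dim - 1`` (cubic) or ``max_dim - 2``
        (cyclic).
    period : float, optional
        Period of the cyclic basis (e.g. 12 for calendar months).
    knots : array-like, optional
        Explicit strictly increasing knot locations.  Cyclic knots must span
        exactly one period.  Default: evenly spaced over the observed range
        (cubic) or over ``[0, period]`` (cyclic).
    """

    covariate_name: str
    basis_kind: str = "cubic"
    max_dim: int = 10
    period: float | None = None
    knots: tuple | None = None

    def __post_init__(self):
        if self.basis_kind not in ("cubic", "cyclic_cubic"):
            raise ValueError(f"unknown basis_kind {self.basis_kind!r}")
        if self.max_dim < 3:
            raise ValueError("max_dim must be at least 3")
        if self.basis_kind == "cyclic_cubic":
            if self.period is None or not self.period > 0:
                raise ValueError("cyclic_cubic basis requires period > 0")
        if self.knots is not None:
            k = np.asarray(self.knots, dtype=float)
            if k.ndim != 1 or len(k) != self.max_dim:
                raise ValueError("knots must be a vector of length max_dim")
            if np.any(np.diff(k) <= 0):
                raise ValueError("knots must be strictly increasing")
            if self.basis_kind == "cyclic_cubic":
                if not np.isclose(k[-1] - k[0], self.period):
                    raise ValueError("cyclic knots must span exactly one period")
            object.__setattr__(self, "knots", tuple(float(v) for v in k))


@dataclass
class BasisExpansion:
    """A realised smooth basis: centred design block plus curvature penalty.

    Attributes
    ----------
    design_block : (n, p) ndarray
        Centred basis evaluations at the fitting covariate values; every
        column sums to zero.
    penalty : (p, p) ndarray
        Symmetric positive semi-definite penalty such that
        ``coef @ penalty @ coef`` equals the integrated squared second
        derivative of the represented function.
    null_space_dim : int
        Dimension of the penalty null space after centring (1 for cubic —
        the centred linear function; 0 for cyclic).
    centering_constants : (p_raw,) ndarray
        Column means of the raw (unconstrained) basis over the fitting data;
        the constraint vector absorbed by the reparameterisation.
    """

    spec: SmoothTermSpec
    knots: np.ndarray
    design_block: np.ndarray
    penalty: np.ndarray
    null_space_dim: int
    centering_constants: np.ndarray
    _Z: np.ndarray = field(repr=False, default=None)
    _F: np.ndarray = field(repr=False, default=None)

    @property
    def n_columns(self) -> int:
        return self.design_block.shape[1]

    def design_rows(self, new_values) -> np.ndarray:
        """Centred basis rows at arbitrary covariate values.

        Uses the centring transform frozen at build time, so predictions are
        consistent with the fitted design.  Non-cyclic evaluation outside the
        knot range extrapolates linearly (natural-spline behaviour).
        """
        raw = _raw_rows(self.spec, self.knots, self._F, np.asarray(new_values, float))
        return raw @ self._Z


def build_basis(spec: SmoothTermSpec, covariate_values) -> BasisExpansion:
    """Construct the centred design block and penalty for one smooth term."""
    x = np.asarray(covariate_values, dtype=float)
    if x.size == 0:
        raise ValueError("covariate_values must be non-empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate_values must be finite")

    cyclic = spec.basis_kind == "cyclic_cubic"
    k = spec.max_dim
    if cyclic:
        xr = np.mod(x - (spec.knots[0] if spec.knots else 0.0), spec.period)
        n_distinct = len(np.unique(xr))
        # k knots include the duplicated endpoint: k-1 free values needed
        required = k - 1
    else:
        n_distinct = len(np.unique(x))
        required = k
    if n_distinct < required:
        raise DegenerateBasisError(
            f"{n_distinct} distinct covariate values for basis dimension {k}"
        )

    if spec.knots is not None:
        knots = np.asarray(spec.knots, dtype=float)
    elif cyclic:
        knots = np.linspace(0.0, spec.period, k)
    else:
        knots = np.linspace(x.min(), x.max(), k)

    F, S_raw = (_cyclic_matrices if cyclic else _natural_matrices)(knots)
    raw = _raw_rows(spec, knots, F, x)

    c = raw.mean(axis=0)
    Z = _householder_null(c)
    design = raw @ Z
    # exact zero column sums, up to accumulated rounding
    penalty = Z.T @ S_raw @ Z
    penalty = 0.5 * (penalty + penalty.T)
    null_dim = 0 if cyclic else 1
    return BasisExpansion(
        spec=spec,
        knots=knots,
        design_block=design,
        penalty=penalty,
        null_space_dim=null_dim,
        centering_constants=c,
        _Z=Z,
        _F=F,
    )


def evaluate_smooth(expansion: BasisExpansion, coefficients, new_values) -> np.ndarray:
    """Evaluate a fitted smooth at new covariate values (linear-predictor scale)."""
    beta = np.asarray(coefficients, dtype=float)
    if beta.shape != (expansion.n_columns,):
        raise ValueError(
            f"coefficient length {beta.shape} does not match basis "
            f"columns {expansion.n_columns}"
        )
    return expansion.design_rows(new_values) @ beta


# ---------------------------------------------------------------------------
# internals

def _natural_matrices(knots):
    """Second-derivative map F (k x k) and penalty S = D' B^-1 D for a
    natural cubic spline parameterised by its values at the knots."""
    k = len(knots)
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    Binv_D = linalg.solve(B, D, assume_a="pos")
    F = np.vstack([np.zeros(k), Binv_D, np.zeros(k)])  # natural end conditions
    S = D.T @ Binv_D
    return F, 0.5 * (S + S.T)

def _cyclic_matrices(knots):
    """Periodic analogue of :func:`_natural_matrices` on k-1 free values."""
    k = len(knots)
    m = k - 1
    h = np.diff(knots)
    B = np.zeros((m, m))
    D = np.zeros((m, m))
    for j in range(m):
        prev = (j - 1) % m
        nxt = (j + 1) % m
        hp, hj = h[prev], h[j]
        B[j, j] += (hp + hj) / 3.0
        B[j, nxt] += hj / 6.0
        B[j, prev] += hp / 6.0
        D[j, j] += -1.0 / hp - 1.0 / hj
        D[j, nxt] += 1.0 / hj
        D[j, prev] += 1.0 / hp
    Binv_D = linalg.solve(B, D)
    S = D.T @ Binv_D
    return Binv_D, 0.5 * (S + S.T)


def _raw_rows(spec, knots, F, x):
    """Unconstrained basis rows: value-at-knot interpolation matrices A + C F."""
    cyclic = spec.basis_kind == "cyclic_cubic"
    k = len(knots)
    p = k - 1 if cyclic else k
    if cyclic:
        xe = knots[0] + np.mod(x - knots[0], spec.period)
    else:
        xe = np.clip(x, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, xe, side="right") - 1, 0, k - 2)
    h = knots[j + 1] - knots[j]
    dl = xe - knots[j]          # distance from left knot
    dr = knots[j + 1] - xe      # distance from right knot
    am = dr / h
    ap = dl / h
    cm = (dr**3 / h - h * dr) / 6.0
    cp = (dl**3 / h - h * dl) / 6.0

    n = len(x)
    rows = np.arange(n)
    A = np.zeros((n, p))
    C = np.zeros((n, k)) if not cyclic else np.zeros((n, p))
    jl = j % p if cyclic else j
    jr = (j + 1) % p if cyclic else j + 1
    np.add.at(A, (rows, jl), am)
    np.add.at(A, (rows, jr), ap)
    np.add.at(C, (rows, jl), cm)
    np.add.at(C, (rows, jr), cp)
    out = A + C @ F

    if not cyclic:
        # natural linear extrapolation beyond the end knots
        lo = x < knots[0]
        hi = x > knots[-1]
        if np.any(lo) or np.any(hi):
            out = out.copy()
            eps = 1e-6 * (knots[-1] - knots[0])
            for mask, x0 in ((lo, knots[0]), (hi, knots[-1])):
                if not np.any(mask):
                    continue
                b0 = _raw_rows(spec, knots, F, np.array([x0]))[0]
                b1 = _raw_rows(
                    spec, knots, F, np.array([x0 + (eps if x0 == knots[0] else -eps)])
                )[0]
                slope = (b1 - b0) / (eps if x0 == knots[0] else -eps)
                out[mask] = b0 + np.outer(x[mask] - x0, slope)
    return out


def _householder_null(c):
    """Orthonormal basis of the null space of a single row vector c."""
    c = np.asarray(c, dtype=float)
    p = len(c)
    nrm = np.linalg.norm(c)
    if nrm < 1e-12:  # nothing to absorb
        return np.eye(p)[:, : p - 1]
    v = c.copy()
    v[0] += np.sign(c[0]) * nrm if c[0] != 0 else nrm
    H = np.eye(p) - 2.0 * np.outer(v, v) / (v @ v)
    return H[:, 1:]
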