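"""Two-step structure selection over the M1-M5 suite.

Step 1 screens by likelihood-ratio tests: the full model M1 is tested
against the null M5; if M5 is rejected, M1 is tested against each of the
reduced structures M2-M4 and the most parsimonious structure that is not
rejected wins (parsimony by structural df, ties broken by the larger LRT
P-value).  Step 2 inspects the winner's smooth terms against the zero
function: a trend smooth is retained only if its 95% credible band excludes
zero for at least ``s1_month_threshold`` study months, a seasonal smooth
only if it excludes zero for at least ``s2_month_threshold`` of the 12
calendar months, and an M2 slope only if its 95% interval excludes zero.
Components that fail are dropped and the final label is the most
parsimonious structure containing the survivors (a bare linear trend maps
to M2).

The thresholds default to the permissive lower ends of the "about 10-12
study months / 2-3 calendar months" guidance and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .design import COMPONENTS, STRUCTURAL_DF
from .model import PhenologyGamm
from .panel import PhenologyPanel
from .results import GammResults, ModelComparison, likelihood_ratio_test

__all__ = ["ModelDecision", "two_step_select", "fit_structure"]

S1_MONTH_THRESHOLD = 10
S2_MONTH_THRESHOLD = 2


@dataclass
class ModelDecision:
    """Outcome of the two-step selection for one panel."""

    chosen: str
    step1_choice: str
    comparisons: list = field(default_factory=list)
    zero_exclusion_fraction_s1: float = np.nan
    zero_exclusion_fraction_s2: float = np.nan
    demoted: bool = False
    flagged_unreliable: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["comparisons"] = [asdict(c) if not isinstance(c, dict) else c
                            for c in self.comparisons]
        return d


def fit_structure(panel: PhenologyPanel, label: str, *, mixed: bool = True,
                  k_trend: int = 10, k_seasonal: int = 8) -> GammResults:
    """Fit one M1-M5 structure to a complete panel by ML."""
    return PhenologyGamm.from_panel(
        panel, label, mixed=mixed, k_trend=k_trend, k_seasonal=k_seasonal
    ).fit()


def _surviving_label(components: set) -> str:
    """Most parsimonious structure containing the surviving components."""
    if components == {"trend", "seasonal"}:
        return "M1"
    if components == {"linear", "seasonal"} or components == {"linear"}:
        return "M2"
    if components == {"trend"}:
        return "M3"
    if components == {"seasonal"}:
        return "M4"
    return "M5"


def two_step_select(
    panel: PhenologyPanel,
    alpha: float = 0.05,
    *,
    mixed: bool = True,
    k_trend: int = 10,
    k_seasonal: int = 8,
    s1_month_threshold: int = S1_MONTH_THRESHOLD,
    s2_month_threshold: int = S2_MONTH_THRESHOLD,
):
    """Run the two-step selection; returns ``(decision, fits)``.

    ``fits`` maps each fitted structure label to its :class:`GammResults`;
    the entry for ``decision.chosen`` is the final model.  The decision is a
    deterministic function of the fitted likelihoods and bands.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    fits: dict[str, GammResults] = {}

    def get(label):
        if label not in fits:
            fits[label] = fit_structure(
                panel, label, mixed=mixed,
                k_trend=k_trend, k_seasonal=k_seasonal,
            )
        return fits[label]

    comparisons: list[ModelComparison] = []
    full = get("M1")
    null = get("M5")
    c0 = likelihood_ratio_test(full, null)
    comparisons.append(c0)

    if c0.p_value >= alpha:
        step1 = "M5"
    else:
        candidates = []
        for label in ("M2", "M3", "M4"):
            c = likelihood_ratio_test(full, get(label))
            comparisons.append(c)
            if c.p_value >= alpha:
                candidates.append((STRUCTURAL_DF[label], -c.p_value, label))
        step1 = min(candidates)[2] if candidates else "M1"

    decision = ModelDecision(chosen=step1, step1_choice=step1,
                             comparisons=comparisons)
    decision.flagged_unreliable = any(
        not f.converged for f in fits.values()
    )

    # ---- step 2: zero-function inspection of the winner's components ------
    res = get(step1)
    surviving = set(COMPONENTS[step1])
    months = np.unique(res.design.t_values)
    cal_grid = np.arange(12) + 0.5

    if "trend" in surviving:
        band = res.credible_band("trend", months, level=0.95)
        excl = int(band.zero_excluded().sum())
        decision.zero_exclusion_fraction_s1 = excl / len(months)
        if excl < s1_month_threshold:
            surviving.discard("trend")
    if "seasonal" in surviving:
        band = res.credible_band("seasonal", cal_grid, level=0.95)
        excl = int(band.zero_excluded().sum())
        decision.zero_exclusion_fraction_s2 = excl / 12.0
        if excl < s2_month_threshold:
            surviving.discard("seasonal")
    if "linear" in surviving:
        _, lo, hi = res.slope_interval(level=0.95)
        if lo <= 0.0 <= hi:
            surviving.discard("linear")

    final = _surviving_label(surviving)
    if final != step1:
        decision.demoted = True
        decision.chosen = final
        get(final)
        decision.flagged_unreliable = decision.flagged_unreliable or (
            not fits[final].converged
        )
    return decision, fits
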