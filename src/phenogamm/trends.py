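"""Per-species, per-month qualitative trend labels from final selected models.

For a species whose final model carries a nonlinear trend smooth (M1/M3),
month *t* is labelled ``positive`` when the smooth's 95% credible band lies
entirely above zero there, ``negative`` when entirely below, ``none``
otherwise.  A linear-trend species (M2) is labelled by the sign of its
slope at every month, provided the slope's 95% interval excludes zero.
Species without a trend component (M4/M5) are ``none`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .results import GammResults
from .selection import ModelDecision

__all__ = ["TrendLabels", "classify_trend", "sort_species_by_trend"]

LABELS = ("positive", "negative", "none")


@dataclass
class TrendLabels:
    """Species-by-month label matrix plus each species' chosen model."""

    frame: pd.DataFrame            # index: species, columns: month_index
    chosen_models: dict

    def counts(self) -> pd.DataFrame:
        pos = (self.frame == "positive").sum(axis=1)
        neg = (self.frame == "negative").sum(axis=1)
        return pd.DataFrame({"positive": pos, "negative": neg,
                             "score": pos - neg})

    def to_long(self) -> pd.DataFrame:
        long = self.frame.stack().rename("label").reset_index()
        long.columns = ["species", "month_index", "label"]
        return long


def classify_trend(decision: ModelDecision, fit: GammResults, months) -> np.ndarray:
    """Label one species' months from its final model fit."""
    months = np.asarray(months, float)
    labels = np.full(len(months), "none", dtype=object)
    chosen = decision.chosen
    if chosen in ("M4", "M5"):
        return labels
    if fit.design.structure != chosen:
        raise ValueError(
            f"fit structure {fit.design.structure} does not match "
            f"decision {chosen}"
        )
    if chosen == "M2":
        est, lo, hi = fit.slope_interval(level=0.95)
        if lo > 0:
            labels[:] = "positive"
        elif hi < 0:
            labels[:] = "negative"
        return labels
    band = fit.credible_band("trend", months, level=0.95)
    labels[band.lower > 0] = "positive"
    labels[band.upper < 0] = "negative"
    return labels


def sort_species_by_trend(labels: TrendLabels) -> TrendLabels:
    """Order species from most positive to most negative net trending.

    Descending by (months positive - months negative); ties by species name.
    """
    counts = labels.counts()
    order = sorted(labels.frame.index,
                   key=lambda sp: (-counts.loc[sp, "score"], sp))
    return TrendLabels(frame=labels.frame.loc[order],
                       chosen_models=labels.chosen_models)


def plot_heatmap(labels: TrendLabels, path=None):
    """Convenience heatmap: white none, black positive, grey negative."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    code = labels.frame.replace({"none": 0, "positive": 1, "negative": 2})
    code = code.infer_objects(copy=False).astype(int)
    fig, ax = plt.subplots(
        figsize=(10, 0.25 * len(code) + 1.5), constrained_layout=True
    )
    ax.pcolormesh(code.to_numpy(),
                  cmap=ListedColormap(["white", "black", "grey"]),
                  vmin=0, vmax=2, edgecolors="none")
    ax.set_yticks(np.arange(len(code)) + 0.5)
    ax.set_yticklabels(code.index, fontsize=6)
    ax.invert_yaxis()
    ax.set_xlabel("study month")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
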