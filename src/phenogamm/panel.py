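"""Long-format presence/absence phenology panels.

The universal input: one row per (plant, month) with a binary fruiting
status, ``NaN`` marking a missed survey.  Calendar months are reals in
(0, 12] with 1 = January; month indices are contiguous integers per plant,
tied to the calendar by a declared start month.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("plant_id", "species", "month_index", "calendar_month", "status")


class PanelValidationError(ValueError):
    """Input panel violates the long-format contract; message itemises rows."""


def calendar_month_of(month_index, start_month: int = 9):
    """Calendar month (1..12) of a study month index under a start-month convention.

    ``month_index`` 1 maps to ``start_month`` (default September, matching a
    study window opening in that month).
    """
    t = np.asarray(month_index)
    return ((start_month - 1 + t - 1) % 12) + 1


@dataclass
class PhenologyPanel:
    """Binary fruiting-status panel for marked individual plants.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``plant_id, species, month_index, calendar_month, status``;
        status in {0, 1} or NaN for a missed survey.
    start_month : int
        Calendar month (1..12) of ``month_index == 1``.
    """

    frame: pd.DataFrame
    start_month: int = 9

    def __post_init__(self):
        self.frame = self.validate(self.frame)

    @staticmethod
    def validate(frame: pd.DataFrame) -> pd.DataFrame:
        problems = []
        missing_cols = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing_cols:
            raise PanelValidationError(f"missing required columns: {missing_cols}")
        if len(frame) == 0:
            raise PanelValidationError("panel is empty")
        frame = frame.copy()
        frame["status"] = pd.to_numeric(frame["status"], errors="coerce")
        observed = frame["status"].dropna()
        bad = observed[~observed.isin([0.0, 1.0])]
        if len(bad):
            problems.append(
                f"non-binary status at rows {bad.index[:10].tolist()}"
            )
        dup = frame.duplicated(subset=["plant_id", "month_index"])
        if dup.any():
            problems.append(
                f"duplicate (plant, month) rows at {frame.index[dup][:10].tolist()}"
            )
        for plant, grp in frame.groupby("plant_id", sort=False):
            t = np.sort(grp["month_index"].to_numpy())
            if len(t) > 1 and not np.array_equal(t, np.arange(t[0], t[0] + len(t))):
                problems.append(f"non-contiguous month_index for plant {plant!r}")
        if problems:
            raise PanelValidationError("; ".join(problems))
        frame = frame.sort_values(["plant_id", "month_index"], kind="stable")
        return frame.reset_index(drop=True)

    # -- basic accessors -----------------------------------------------------
    def __len__(self):
        return len(self.frame)

    @property
    def n_plants(self) -> int:
        return self.frame["plant_id"].nunique()

    @property
    def n_species(self) -> int:
        return self.frame["species"].nunique()

    @property
    def n_months(self) -> int:
        return self.frame["month_index"].nunique()

    @property
    def missing_fraction(self) -> float:
        return float(self.frame["status"].isna().mean())

    def is_complete(self) -> bool:
        return not self.frame["status"].isna().any()

    def species_panel(self, species: str) -> "PhenologyPanel":
        sub = self.frame[self.frame["species"] == species]
        if len(sub) == 0:
            raise KeyError(f"no rows for species {species!r}")
        return PhenologyPanel(sub, start_month=self.start_month)

    def plant_series(self, plant_id) -> np.ndarray:
        sub = self.frame[self.frame["plant_id"] == plant_id]
        return sub["status"].to_numpy()

    def monthly_proportions(self) -> pd.DataFrame:
        """Observed proportion of plants with fruit per study month."""
        g = self.frame.groupby("month_index")["status"]
        return pd.DataFrame(
            {"month_index": g.mean().index, "proportion": g.mean().to_numpy(),
             "n_observed": g.count().to_numpy()}
        )

    # -- I/O ------------------------------------------------------------------
    @classmethod
    def from_csv(cls, path_or_buf, start_month: int = 9) -> "PhenologyPanel":
        try:
            frame = pd.read_csv(path_or_buf, na_values=["NA"])
        except pd.errors.EmptyDataError:
            raise PanelValidationError("empty input file") from None
        return cls(frame, start_month=start_month)

    def to_csv(self, path_or_buf=None):
        out = self.frame.copy()
        out["status"] = out["status"].map(
            lambda v: "NA" if pd.isna(v) else str(int(v))
        )
        return out.to_csv(path_or_buf, index=False)

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()
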