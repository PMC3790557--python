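import numpy as np
import pandas as pd
import pytest

from phenogamm.panel import PhenologyPanel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def small_panel():
    """Four plants, 24 months, deterministic statuses, two species."""
    rows = []
    rng = np.random.default_rng(5)
    t = np.arange(1, 25)
    cal = ((8 + t - 1) % 12) + 1  # September start
    for k, sp in enumerate(["A", "A", "B", "B"]):
        y = rng.integers(0, 2, size=24).astype(float)
        rows.append(pd.DataFrame({
            "plant_id": f"p{k}", "species": sp, "month_index": t,
            "calendar_month": cal.astype(float), "status": y,
        }))
    return PhenologyPanel(pd.concat(rows, ignore_index=True))


def month_grid(n_months=120):
    t = np.arange(1, n_months + 1, dtype=float)
    return t, ((t - 1) % 12) + 1
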