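"""Synthetic multi-species fruiting panels with realistic statistical structure.

Generates presence/absence panels shaped like a long-term Afromontane
monitoring study: 33 species totalling 249 marked plants followed for 95
monthly surveys starting in September, with 25 "focal" species of at least
five individuals (229 plants) and ~6% of entries missing completely at
random.  Species differ in trend type (none / linear / nonlinear bumps),
seasonal amplitude and peak month, per-plant random-intercept SD, and lag-1
persistence, so every structure of the M1-M5 suite is represented and the
full selection pipeline can be exercised without any field data.

Species-level effect sizes are illustrative: chosen to be typical of
strongly seasonal tropical fruiting records (seasonal peaks of one to three
logits, episodic good/bad years of about one logit, persistence odds ratios
of two to four), not estimates from any particular forest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import PhenologyPanel, calendar_month_of

__all__ = ["SpeciesProfile", "generate_panel", "default_bwindi_profiles"]

N_SPECIES = 33
N_PLANTS_TOTAL = 249
N_FOCAL = 25
N_FOCAL_PLANTS = 229
DEFAULT_N_MONTHS = 95
DEFAULT_MISSING_RATE = 0.06
START_MONTH = 9  # September

#: step-1 structure mix over the 25 focal species (counts of generating
#: structures M1..M5), mirroring a balanced community
FOCAL_STRUCTURE_COUNTS = {"M1": 7, "M2": 5, "M3": 9, "M4": 1, "M5": 3}

_TREND_TYPE = {"M1": "nonlinear", "M2": "linear", "M3": "nonlinear",
               "M4": "none", "M5": "none"}
_HAS_SEASON = {"M1": True, "M2": True, "M3": False, "M4": True, "M5": False}


@dataclass
class SpeciesProfile:
    """Generating parameters for one species.

    ``trend_params`` holds ``{"slope": logits/month}`` for a linear trend or
    ``{"bumps": [(start_month, end_month, amplitude), ...]}`` for a
    nonlinear one.  ``seasonal_amplitude`` is the peak-to-trough seasonal
    range on the logit scale; ``lag_coef`` multiplies last month's fruit
    state.
    """

    species_name: str
    n_plants: int
    trend_type: str = "none"          # none | linear | nonlinear
    trend_params: dict = field(default_factory=dict)
    seasonal_amplitude: float = 0.0
    peak_month: float = 1.0
    re_sd: float = 0.5
    lag_coef: float = 1.0
    baseline_logit: float = -0.5
    structure: str = "M5"             # generating M-structure label

    def __post_init__(self):
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        if self.seasonal_amplitude < 0 or self.re_sd < 0:
            raise ValueError("seasonal_amplitude and re_sd must be >= 0")
        if self.trend_type not in ("none", "linear", "nonlinear"):
            raise ValueError(f"unknown trend_type {self.trend_type!r}")

    # -- logit-scale components ------------------------------------------------
    def trend(self, month_index) -> np.ndarray:
        t = np.asarray(month_index, float)
        if self.trend_type == "none":
            return np.zeros_like(t)
        if self.trend_type == "linear":
            return self.trend_params["slope"] * (t - t.mean())
        out = np.zeros_like(t)
        for start, end, amp in self.trend_params["bumps"]:
            up = np.clip(t - (start - 1.0), 0.0, 1.0)
            down = np.clip((end + 1.0) - t, 0.0, 1.0)
            out += amp * np.minimum(up, down)
        return out

    def seasonal(self, calendar_month) -> np.ndarray:
        c = np.asarray(calendar_month, float)
        if self.seasonal_amplitude == 0:
            return np.zeros_like(c)
        d = np.abs((c - self.peak_month + 6.0) % 12.0 - 6.0)
        pulse = np.clip(1.0 - d / 3.0, 0.0, None)  # triangular, half-width 3
        grid = np.arange(1, 13, dtype=float)
        dg = np.abs((grid - self.peak_month + 6.0) % 12.0 - 6.0)
        pulse_mean = np.clip(1.0 - dg / 3.0, 0.0, None).mean()
        return self.seasonal_amplitude * (pulse - pulse_mean)


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, float)))


def generate_panel(
    profiles: list[SpeciesProfile],
    n_months: int = DEFAULT_N_MONTHS,
    missing_rate: float = DEFAULT_MISSING_RATE,
    seed: int = 0,
    start_month: int = START_MONTH,
) -> PhenologyPanel:
    """Simulate a complete panel, then mask entries completely at random.

    Each plant-month draw is Bernoulli with logit
    ``baseline + trend(t) + seasonal(calendar) + b_k + lag_coef * y[t-1]``
    where ``b_k ~ N(0, re_sd^2)`` per plant and the first month has no lag
    contribution.  Reproducible: all randomness flows from ``seed``.
    """
    if not 0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must be in [0, 0.5)")
    if not profiles:
        raise ValueError("need at least one species profile")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(profiles) + 1)
    t = np.arange(1, n_months + 1)
    cal = calendar_month_of(t, start_month).astype(float)

    frames = []
    plant_counter = 0
    for prof, ss in zip(profiles, streams[:-1]):
        rng = np.random.default_rng(ss)
        base = prof.baseline_logit + prof.trend(t) + prof.seasonal(cal)
        b = rng.normal(0.0, prof.re_sd, size=prof.n_plants)
        for k in range(prof.n_plants):
            plant_counter += 1
            y = np.empty(n_months)
            prev = 0.0
            for i in range(n_months):
                eta = base[i] + b[k] + (prof.lag_coef * prev if i > 0 else 0.0)
                y[i] = rng.random() < _expit(eta)
                prev = y[i]
            frames.append(pd.DataFrame({
                "plant_id": f"p{plant_counter:04d}",
                "species": prof.species_name,
                "month_index": t,
                "calendar_month": cal,
                "status": y,
            }))
    frame = pd.concat(frames, ignore_index=True)

    if missing_rate > 0:
        rng = np.random.default_rng(streams[-1])
        mask = rng.random(len(frame)) < missing_rate
        frame.loc[mask, "status"] = np.nan
    return PhenologyPanel(frame, start_month=start_month)


def default_bwindi_profiles(seed: int = 0) -> list[SpeciesProfile]:
    """The default 33-species community: 249 plants, 25 focal species >= 5.

    Deterministic given ``seed`` (which only shuffles which species gets
    which structure/parameter variant, not the count structure).
    """
    rng = np.random.default_rng(seed)

    # focal plant counts: 25 species, all >= 5, summing to 229
    w = 0.88 ** np.arange(N_FOCAL)
    extras = np.floor((N_FOCAL_PLANTS - 5 * N_FOCAL) * w / w.sum()).astype(int)
    counts = 5 + extras
    counts[0] += N_FOCAL_PLANTS - counts.sum()
    assert counts.sum() == N_FOCAL_PLANTS and counts.min() >= 5
    minor_counts = [4, 4, 3, 3, 2, 2, 1, 1]  # 8 species, 20 plants
    assert sum(minor_counts) + N_FOCAL_PLANTS == N_PLANTS_TOTAL

    structures = [s for s, c in FOCAL_STRUCTURE_COUNTS.items() for _ in range(c)]
    # spread structures across the size-ordered focal species so every
    # structure sees a range of sample sizes
    order = rng.permutation(N_FOCAL)
    profiles = []
    good_windows = [(50, 62), (55, 70), (60, 72), (45, 60)]
    for i in range(N_FOCAL):
        label = structures[order[i]]
        profiles.append(_make_profile(
            f"sp{i + 1:02d}", int(counts[i]), label, rng, good_windows,
        ))
    for j, c in enumerate(minor_counts):
        label = ("M1", "M2", "M3", "M4", "M5")[j % 5]
        profiles.append(_make_profile(
            f"sp{N_FOCAL + j + 1:02d}", c, label, rng, good_windows,
        ))
    return profiles


def _make_profile(name, n_plants, label, rng, good_windows) -> SpeciesProfile:
    trend_type = _TREND_TYPE[label]
    params: dict = {}
    if trend_type == "linear":
        slope = rng.choice([-1.0, 1.0]) * rng.uniform(0.012, 0.02)
        params = {"slope": float(slope)}
    elif trend_type == "nonlinear":
        a, b = good_windows[rng.integers(len(good_windows))]
        amp = rng.choice([-1.0, 1.0]) * rng.uniform(1.2, 1.8)
        params = {"bumps": [(float(a), float(b), float(amp))]}
        if rng.random() < 0.5:  # optional second, opposite-signed episode
            params["bumps"].append((10.0, 22.0, float(-0.6 * amp)))
    amp_seas = float(rng.uniform(1.8, 3.0)) if _HAS_SEASON[label] else 0.0
    return SpeciesProfile(
        species_name=name,
        n_plants=n_plants,
        trend_type=trend_type,
        trend_params=params,
        seasonal_amplitude=amp_seas,
        peak_month=float(rng.integers(1, 13)),
        re_sd=float(rng.uniform(0.3, 0.9)),
        lag_coef=float(rng.uniform(0.8, 1.5)),
        baseline_logit=float(rng.uniform(-1.4, -0.4)),
        structure=label,
    )
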