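"""Nuclear FUCCI state classification.

Each nucleus is called positive or negative for mVenus and mCherry against
per-channel thresholds and assigned exactly one of four categories:

====================  =========  =========
state                 mCherry    mVenus
====================  =========  =========
BLUE  (no reporter)   negative   negative
RED   (G0/G1)         positive   negative
YELLOW (G1/S)         positive   positive
GREEN (S/G2/M)        negative   positive
====================  =========  =========

Intensities exactly equal to a threshold classify as negative.  The screen's
main parameter is the percentage of mVenus+ nuclei among all FUCCI+
(RED + YELLOW + GREEN) nuclei.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STATES = ("BLUE", "RED", "YELLOW", "GREEN")
THRESHOLD_METHODS = ("fixed", "otsu-on-log", "quantile-mixture")
MIN_RECORDS_FOR_HISTOGRAM = 50


@dataclass
class FucciThresholds:
    mvenus_thr: float
    mcherry_thr: float
    method: str = "fixed"

    def __post_init__(self) -> None:
        if self.mvenus_thr <= 0 or self.mcherry_thr <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class StateCounts:
    n_blue: int = 0
    n_red: int = 0
    n_yellow: int = 0
    n_green: int = 0

    def __post_init__(self) -> None:
        for f in ("n_blue", "n_red", "n_yellow", "n_green"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @property
    def total(self) -> int:
        return self.n_blue + self.n_red + self.n_yellow + self.n_green

    @property
    def fucci_positive(self) -> int:
        return self.n_red + self.n_yellow + self.n_green

    @classmethod
    def from_states(cls, states) -> "StateCounts":
        s = pd.Series(list(states))
        c = s.value_counts()
        return cls(
            n_blue=int(c.get("BLUE", 0)),
            n_red=int(c.get("RED", 0)),
            n_yellow=int(c.get("YELLOW", 0)),
            n_green=int(c.get("GREEN", 0)),
        )


def derive_channel_threshold(values: np.ndarray, method: str = "otsu-on-log") -> float:
    """One positive/negative threshold for a skewed fluorescence histogram.

    ``otsu-on-log`` applies Otsu's criterion to log(1 + x); the default for
    fluorescence data, whose positive and background modes are log-normal.
    ``quantile-mixture`` fits a 2-component Gaussian mixture on the log scale
    and places the cut at the equal-posterior boundary between the component
    means; if the fit does not separate two modes it falls back to
    otsu-on-log with a warning.
    """
    from skimage.filters import threshold_otsu

    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    x = np.maximum(x, 0.0)
    if not np.any(x > 0):
        raise ValueError("all intensities are zero: no threshold derivable")
    # small offset keeps zeros finite on the log scale and compresses
    # sub-noise values without distorting the positive modes
    delta = 1e-3 * float(np.max(x))
    logx = np.log(x + delta)

    def otsu() -> float:
        return float(np.exp(threshold_otsu(logx)) - delta)

    if method == "otsu-on-log":
        return otsu()
    if method != "quantile-mixture":
        raise ValueError(f"unknown threshold method: {method!r}")

    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(n_components=2, random_state=0)
    gm.fit(logx.reshape(-1, 1))
    mus = np.sort(gm.means_.ravel())
    # a genuine two-mode histogram has a density dip between the component
    # means; without one the fit merely split a single mode
    probe = np.array([mus[0], (mus[0] + mus[1]) / 2, mus[1]]).reshape(-1, 1)
    dens = gm.score_samples(probe)
    if dens[1] >= min(dens[0], dens[2]):
        log.warning(
            "quantile-mixture: channel histogram looks unimodal "
            "(component means %.3f/%.3f); falling back to otsu-on-log",
            mus[0], mus[1],
        )
        return otsu()
    grid = np.linspace(mus[0], mus[1], 512).reshape(-1, 1)
    post = gm.predict_proba(grid)
    lo_comp = int(np.argmin(gm.means_.ravel()))
    cross = np.nonzero(post[:, lo_comp] < 0.5)[0]
    cut = grid[cross[0], 0] if len(cross) else (mus[0] + mus[1]) / 2
    return float(np.exp(cut) - delta)


def derive_thresholds(
    records: pd.DataFrame,
    method: str = "otsu-on-log",
    mvenus_thr: float | None = None,
    mcherry_thr: float | None = None,
) -> FucciThresholds:
    """Per-channel FUCCI thresholds from a population of nucleus records.

    ``fixed`` returns the supplied thresholds unchanged; the histogram
    methods require at least 50 records.
    """
    if method == "fixed":
        if mvenus_thr is None or mcherry_thr is None:
            raise ValueError("fixed method requires mvenus_thr and mcherry_thr")
        return FucciThresholds(mvenus_thr, mcherry_thr, method="fixed")
    if method not in THRESHOLD_METHODS:
        raise ValueError(f"unknown threshold method: {method!r}")
    if len(records) < MIN_RECORDS_FOR_HISTOGRAM:
        raise ValueError(
            f"histogram threshold methods need >= {MIN_RECORDS_FOR_HISTOGRAM} records, "
            f"got {len(records)}"
        )
    return FucciThresholds(
        mvenus_thr=derive_channel_threshold(records["mvenus"].to_numpy(), method),
        mcherry_thr=derive_channel_threshold(records["mcherry"].to_numpy(), method),
        method=method,
    )


def classify_nucleus(mvenus: float, mcherry: float, thr: FucciThresholds) -> str:
    """One state per nucleus; a value equal to the threshold is negative."""
    if mvenus is None or mcherry is None or np.isnan(mvenus) or np.isnan(mcherry):
        raise ValueError("nucleus record is missing a FUCCI intensity")
    v = mvenus > thr.mvenus_thr
    c = mcherry > thr.mcherry_thr
    if v and c:
        return "YELLOW"
    if v:
        return "GREEN"
    if c:
        return "RED"
    return "BLUE"


def classify_records(records: pd.DataFrame, thr: FucciThresholds) -> pd.DataFrame:
    """Vectorized classification; adds a ``fucci_state`` column."""
    if records[["mvenus", "mcherry"]].isna().any().any():
        raise ValueError("nucleus records are missing FUCCI intensities")
    v = records["mvenus"].to_numpy() > thr.mvenus_thr
    c = records["mcherry"].to_numpy() > thr.mcherry_thr
    state = np.where(v & c, "YELLOW", np.where(v, "GREEN", np.where(c, "RED", "BLUE")))
    out = records.copy()
    out["fucci_state"] = state
    return out


def state_fractions(counts: StateCounts) -> dict:
    """Fractions of each state among all nuclei and among FUCCI+ nuclei."""
    if counts.total == 0:
        raise ValueError("no classified nuclei: fractions undefined")
    total = counts.total
    out = {
        "over_total": {
            "BLUE": counts.n_blue / total,
            "RED": counts.n_red / total,
            "YELLOW": counts.n_yellow / total,
            "GREEN": counts.n_green / total,
        },
        "fucci_positive_defined": counts.fucci_positive > 0,
        "over_fucci_positive": None,
    }
    if counts.fucci_positive > 0:
        fp = counts.fucci_positive
        out["over_fucci_positive"] = {
            "RED": counts.n_red / fp,
            "YELLOW": counts.n_yellow / fp,
            "GREEN": counts.n_green / fp,
        }
    return out


def main_parameter(counts: StateCounts, include_yellow: bool = True) -> float:
    """Screen main parameter: % mVenus+ among all FUCCI+ nuclei.

    YELLOW (double-positive) nuclei are mVenus+ by the truth table and count
    in the numerator by default; ``include_yellow=False`` restricts the
    numerator to GREEN.
    """
    fp = counts.fucci_positive
    if fp == 0:
        raise ValueError("no FUCCI-positive nuclei: main parameter undefined")
    num = counts.n_green + (counts.n_yellow if include_yellow else 0)
    return 100.0 * num / fp
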