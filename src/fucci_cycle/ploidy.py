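"""DNA-content ploidy and binucleation analysis.

Nuclear DNA-stain intensity is proportional to DNA content, so a population
of nuclei shows modes at 2N, 4N and 8N in fixed intensity ratio 1:2:4.
After gating to marker-positive (cardiomyocyte) and, optionally, Ki-67-
negative (non-cycling) nuclei, class boundaries are placed at the density
minima between modes of the intensity histogram, with geometric-mean
fallbacks (sqrt(2) x mode, 2 sqrt(2) x mode) when a minimum is absent.
Integrated (sum-equivalent) intensity is assumed; the whole analysis is
scale-equivariant, so units cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .classify import derive_channel_threshold


@dataclass
class PloidyThresholds:
    boundaries: tuple[float, float]   # (2N/4N cut, 4N/8N cut)
    reference_2n_mode: float

    def __post_init__(self) -> None:
        b1, b2 = self.boundaries
        if not b1 < b2:
            raise ValueError("boundaries must be strictly increasing")
        if not b1 > self.reference_2n_mode:
            raise ValueError("first boundary must exceed the 2N mode")


@dataclass
class PloidyResult:
    classes: pd.Series            # per-nucleus class in {2N, 4N, 8N+}
    fractions: dict
    n_gated: int
    thresholds: PloidyThresholds


def gate_nuclei(
    records: pd.DataFrame,
    marker_channel: str | None = "marker_intensity",
    ki67_channel: str | None = "ki67_intensity",
    require_ki67_negative: bool = True,
    threshold_method: str = "otsu-on-log",
    thresholds: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Gate to marker+ (and optionally Ki-67-) nuclei.

    Thresholds are derived from each channel's histogram unless supplied in
    ``thresholds``.  Marker and Ki-67 gates commute (both are independent
    per-row predicates).  Returns (gated subset, gate log with counts at
    each step); an empty final gate raises with those counts.
    """
    thresholds = dict(thresholds or {})
    gated = records
    counts = {"input": len(records)}
    if marker_channel is not None:
        thr = thresholds.get(marker_channel)
        if thr is None:
            thr = derive_channel_threshold(records[marker_channel].to_numpy(), threshold_method)
            thresholds[marker_channel] = thr
        gated = gated[gated[marker_channel] > thr]
        counts["marker_positive"] = len(gated)
    if require_ki67_negative and ki67_channel is not None:
        thr = thresholds.get(ki67_channel)
        if thr is None:
            thr = derive_channel_threshold(records[ki67_channel].to_numpy(), threshold_method)
            thresholds[ki67_channel] = thr
        gated = gated[gated[ki67_channel] <= thr]
        counts["ki67_negative"] = len(gated)
    if len(gated) == 0:
        raise ValueError(f"gating left no nuclei; counts per step: {counts}")
    return gated.copy(), {"counts": counts, "thresholds": thresholds}


def derive_ploidy_thresholds(dna_intensities: np.ndarray) -> PloidyThresholds:
    """Class boundaries from the DNA-content histogram.

    A Gaussian KDE (Silverman bandwidth) on log intensity locates the
    dominant (2N) mode; each boundary is the density minimum between the
    expected positions of successive modes (x2 apart on the raw scale), or
    the geometric mean of those modes when the minimum is absent (e.g. a
    class is empty).  Requires at least 100 nuclei.
    """
    x = np.asarray(dna_intensities, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if len(x) < 100:
        raise ValueError(f"ploidy thresholding needs >= 100 gated nuclei, got {len(x)}")
    logx = np.log(x)
    kde = gaussian_kde(logx, bw_method="silverman")
    grid = np.linspace(logx.min() - 0.1, logx.max() + 0.1, 1024)
    dens = kde(grid)

    # dominant mode = 2N reference
    from scipy.signal import argrelextrema

    maxima = argrelextrema(dens, np.greater)[0]
    if len(maxima) == 0:
        maxima = np.array([int(np.argmax(dens))])
    mode_log = grid[maxima[np.argmax(dens[maxima])]]
    mode = float(np.exp(mode_log))

    ln2 = np.log(2.0)

    def boundary_between(lo_log: float, hi_log: float, fallback: float) -> float:
        margin = 0.1 * (hi_log - lo_log)
        mask = (grid > lo_log + margin) & (grid < hi_log - margin)
        if not np.any(mask):
            return fallback
        seg = dens[mask]
        seg_grid = grid[mask]
        i_min = int(np.argmin(seg))
        interior = 0 < i_min < len(seg) - 1
        # a genuine valley must dip below the density at both segment edges
        if interior and seg[i_min] < seg[0] and seg[i_min] < seg[-1]:
            return float(np.exp(seg_grid[i_min]))
        return fallback

    b1 = boundary_between(mode_log, mode_log + ln2, fallback=np.sqrt(2.0) * mode)
    b2 = boundary_between(mode_log + ln2, mode_log + 2 * ln2, fallback=2.0 * np.sqrt(2.0) * mode)
    if not b1 < b2:
        b2 = 2.0 * np.sqrt(2.0) * mode
    return PloidyThresholds(boundaries=(float(b1), float(b2)), reference_2n_mode=mode)


def call_ploidy(
    records: pd.DataFrame | np.ndarray,
    thresholds: PloidyThresholds,
    dna_column: str = "dna_intensity",
) -> PloidyResult:
    """Assign 2N / 4N / 8N+ by interval membership.

    A value exactly at a boundary falls into the lower class.
    """
    if isinstance(records, pd.DataFrame):
        x = records[dna_column]
    else:
        x = pd.Series(np.asarray(records, dtype=float))
    b1, b2 = thresholds.boundaries
    classes = pd.Series(
        np.where(x <= b1, "2N", np.where(x <= b2, "4N", "8N+")), index=x.index
    )
    n = len(classes)
    fractions = {k: int((classes == k).sum()) / n for k in ("2N", "4N", "8N+")}
    return PloidyResult(classes=classes, fractions=fractions, n_gated=n, thresholds=thresholds)


def binucleation_fraction(records: pd.DataFrame, cell_id_column: str = "cell_id") -> dict:
    """Fractions of cells with 1, 2 and >2 nuclei, over cells."""
    counts = records.groupby(cell_id_column).size()
    n_cells = len(counts)
    if n_cells == 0:
        raise ValueError("no cells present")
    return {
        "mononucleated": float((counts == 1).sum() / n_cells),
        "binucleated": float((counts == 2).sum() / n_cells),
        "multinucleated_gt2": float((counts > 2).sum() / n_cells),
        "n_cells": n_cells,
    }


def marker_positive_fraction(
    records: pd.DataFrame,
    marker_channel: str,
    threshold_method: str = "otsu-on-log",
    threshold: float | None = None,
) -> tuple[float, float]:
    """Percentage of marker-positive nuclei (e.g. Ki-67+ or EdU+).

    Returns (percentage, threshold used); the threshold is derived from the
    channel histogram unless given.
    """
    if len(records) == 0:
        raise ValueError("no nuclei to score")
    x = records[marker_channel].to_numpy()
    if threshold is None:
        threshold = derive_channel_threshold(x, threshold_method)
    return 100.0 * float((x > threshold).sum()) / len(x), float(threshold)
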