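"""Single-cell FUCCI trace analysis.

A cardiomyocyte carrying the FUCCI reporter pair expresses mCherry-hCdt1 in
G0/G1 and mVenus-hGeminin in S/G2/M, with a short double-positive window at
the G1/S transition.  A time-lapse trace of nuclear mCherry/mVenus intensity
therefore encodes the cell-cycle history of the cell, and its shape at cycle
exit discriminates the three possible outcomes of a cardiomyocyte cell cycle:

* division / binucleation — mitotic entry destroys geminin abruptly, so
  mVenus collapses within a fraction of an hour;
* polyploidization (endoreplication) — the cell arrests in G2, the
  anaphase-promoting complex is never activated, mVenus decays slowly and
  mCherry re-accumulates while mVenus is still present.

Division and binucleation are kinetically indistinguishable from intensities
alone; they are resolved by a post-mitosis daughter-object annotation (two
separate objects vs. two nuclei inside one cell outline), mirroring how an
observer resolves them by watching the movie.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import medfilt

NONCYCLING = "noncycling"
DIVISION = "division"
BINUCLEATION = "binucleation"
POLYPLOIDIZATION = "polyploidization"
MITOTIC_UNRESOLVED = "mitotic-unresolved"
FATES = (NONCYCLING, DIVISION, BINUCLEATION, POLYPLOIDIZATION)

#: daughter annotation emitted by the generator / a tracking step
TWO_OBJECTS = "two_objects"          # cytokinesis completed: two separate cells
ONE_OBJECT_TWO_NUCLEI = "one_object_two_nuclei"   # karyokinesis only


@dataclass
class CellTrace:
    """Per-cell background-subtracted FUCCI intensity time series.

    ``true_*`` fields are generator ground truth; no classification routine
    reads them.
    """

    cell_id: str
    time_h: np.ndarray
    mcherry: np.ndarray
    mvenus: np.ndarray
    post_mitosis_daughters: str | None = None
    true_fate: str | None = None
    true_t_onset_h: float | None = None
    true_t_offset_h: float | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.mcherry = np.asarray(self.mcherry, dtype=float)
        self.mvenus = np.asarray(self.mvenus, dtype=float)
        if not (len(self.time_h) == len(self.mcherry) == len(self.mvenus)):
            raise ValueError("time and channel arrays must have equal length")
        dt = np.diff(self.time_h)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9)):
            raise ValueError("time_h must be strictly increasing on a uniform grid")

    @property
    def sampling_interval_h(self) -> float:
        return float(self.time_h[1] - self.time_h[0])

    def rescaled(self, k: float) -> "CellTrace":
        """Uniformly rescale both intensity channels (unit change)."""
        return dataclasses.replace(self, mcherry=self.mcherry * k, mvenus=self.mvenus * k)


@dataclass
class FateClassifierConfig:
    """Tunable criteria of the fate classifier.

    onset/offset are fraction-of-plateau crossings; the sharp/slow cut
    separates the sub-hour mitotic mVenus collapse from the multi-hour decay
    of a G2-arrested cell.
    """

    onset_frac: float = 0.2
    offset_frac: float = 0.2
    sharp_drop_max_h: float = 1.0
    slow_decay_min_h: float = 5.0
    alignment_window_h: float = 40.0

    def __post_init__(self) -> None:
        if not (0 < self.onset_frac < 1 and 0 < self.offset_frac < 1):
            raise ValueError("onset_frac and offset_frac must lie in (0, 1)")
        if not self.sharp_drop_max_h < self.slow_decay_min_h:
            raise ValueError("sharp_drop_max_h must be < slow_decay_min_h")


@dataclass
class PhaseBoundaries:
    t_onset_h: float | None
    t_offset_h: float | None
    drop_sharpness_h: float | None
    mcherry_reentry: bool


@dataclass
class FateCall:
    cell_id: str
    fate: str
    t_onset_h: float | None = None
    t_offset_h: float | None = None
    sg2m_duration_h: float | None = None
    drop_sharpness_h: float | None = None
    mcherry_reentry_before_offset: bool = False


def _smooth(x: np.ndarray) -> np.ndarray:
    # centered 3-point median: kills single-frame spikes without moving
    # threshold crossings by more than one sampling interval
    if len(x) < 3:
        return np.asarray(x, dtype=float)
    return medfilt(np.asarray(x, dtype=float), kernel_size=3)


def _plateau_level(x: np.ndarray) -> float:
    """Robust plateau estimate: mean of samples within 20% of the maximum.

    Using the raw maximum would overestimate the plateau by the expected
    extreme of the noise, biasing fraction-of-peak crossing times; averaging
    the top of the trace is insensitive to that.
    """
    m = float(np.max(x))
    if m <= 0:
        return m
    top = x[x >= 0.8 * m]
    return float(np.mean(top))


def _noise_floor(x: np.ndarray) -> float:
    """Difference-based robust noise scale, valid regardless of trace shape."""
    if len(x) < 3:
        return 0.0
    d = np.diff(x)
    sigma = 1.4826 * float(np.median(np.abs(d))) / np.sqrt(2.0)
    return 5.0 * sigma


def detect_phase_boundaries(trace: CellTrace, config: FateClassifierConfig | None = None) -> PhaseBoundaries:
    """Locate mVenus onset/offset and characterise the terminal drop.

    Onset is the first crossing of ``onset_frac`` x plateau, offset the first
    fall below ``offset_frac`` x plateau after the peak; drop sharpness is the
    time from the last half-plateau sample to the offset.  A trace whose
    mVenus never exceeds the noise floor has undefined boundaries (the cell
    is non-cycling).
    """
    config = config or FateClassifierConfig()
    mv = _smooth(trace.mvenus)
    peak = _plateau_level(mv)
    floor = _noise_floor(trace.mvenus)
    if peak <= max(floor, 0.0) or peak <= 0:
        return PhaseBoundaries(None, None, None, False)

    t = trace.time_h
    on_thr = config.onset_frac * peak
    off_thr = config.offset_frac * peak
    above = np.nonzero(mv >= on_thr)[0]
    if len(above) == 0:
        return PhaseBoundaries(None, None, None, False)
    i_on = int(above[0])
    i_peak = int(np.argmax(mv))

    below = np.nonzero(mv[i_peak:] < off_thr)[0]
    if len(below) == 0:
        # signal still high at the end of the movie: offset unobserved
        return PhaseBoundaries(float(t[i_on]), None, None, False)
    i_off = i_peak + int(below[0])

    half = np.nonzero(mv[:i_off] >= 0.5 * peak)[0]
    i_half = int(half[-1]) if len(half) else i_peak
    sharpness = float(t[i_off] - t[i_half])

    # mCherry re-entry: an upward crossing of the mCherry threshold strictly
    # between onset and offset flags Cdt1 re-accumulation during G2 arrest.
    mc = _smooth(trace.mcherry)
    mc_peak = _plateau_level(mc)
    reentry = False
    if mc_peak > max(_noise_floor(trace.mcherry), 0.0):
        mc_thr = config.onset_frac * mc_peak
        seg = mc[i_on : i_off + 1]
        if len(seg) > 1:
            up = (seg[:-1] < mc_thr) & (seg[1:] >= mc_thr)
            reentry = bool(np.any(up))

    return PhaseBoundaries(float(t[i_on]), float(t[i_off]), sharpness, reentry)


def classify_fate(trace: CellTrace, config: FateClassifierConfig | None = None) -> FateCall:
    """Assign a cell-cycle outcome from the trace shape alone.

    The decision tree follows the biology: no mVenus onset -> non-cycling;
    slow terminal decay or mCherry re-entry without a sharp drop -> G2 arrest
    (polyploidization); otherwise mitotic, resolved into division vs.
    binucleation by the daughter-object annotation, or flagged
    ``mitotic-unresolved`` when that annotation is absent.
    """
    config = config or FateClassifierConfig()
    b = detect_phase_boundaries(trace, config)
    if b.t_onset_h is None:
        return FateCall(trace.cell_id, NONCYCLING)
    if b.t_offset_h is None:
        return FateCall(trace.cell_id, MITOTIC_UNRESOLVED, t_onset_h=b.t_onset_h)

    duration = b.t_offset_h - b.t_onset_h
    sharp = b.drop_sharpness_h is not None and b.drop_sharpness_h <= config.sharp_drop_max_h
    if (b.drop_sharpness_h is not None and b.drop_sharpness_h >= config.slow_decay_min_h) or (
        b.mcherry_reentry and not sharp
    ):
        fate = POLYPLOIDIZATION
    else:
        if trace.post_mitosis_daughters == TWO_OBJECTS:
            fate = DIVISION
        elif trace.post_mitosis_daughters == ONE_OBJECT_TWO_NUCLEI:
            fate = BINUCLEATION
        else:
            fate = MITOTIC_UNRESOLVED
    return FateCall(
        trace.cell_id,
        fate,
        t_onset_h=b.t_onset_h,
        t_offset_h=b.t_offset_h,
        sg2m_duration_h=duration,
        drop_sharpness_h=b.drop_sharpness_h,
        mcherry_reentry_before_offset=b.mcherry_reentry,
    )


def align_traces(
    traces: Sequence[CellTrace], config: FateClassifierConfig | None = None
) -> pd.DataFrame:
    """Align traces on their mVenus peak and average them.

    Each trace is shifted so its mVenus maximum sits at t = 0, cropped to
    +/- ``alignment_window_h``/2, and the mean and SEM over the non-missing
    entries are computed per timepoint and channel.
    """
    config = config or FateClassifierConfig()
    if len(traces) == 0:
        raise ValueError("align_traces requires at least one trace")
    dt = traces[0].sampling_interval_h
    half = config.alignment_window_h / 2.0
    n_side = int(round(half / dt))
    grid = np.arange(-n_side, n_side + 1) * dt

    mats = {"mvenus": [], "mcherry": []}
    for tr in traces:
        i_pk = int(np.argmax(tr.mvenus))
        for name, y in (("mvenus", tr.mvenus), ("mcherry", tr.mcherry)):
            row = np.full(len(grid), np.nan)
            lo = max(0, i_pk - n_side)
            hi = min(len(y), i_pk + n_side + 1)
            row[lo - (i_pk - n_side) : hi - (i_pk - n_side)] = y[lo:hi]
            mats[name].append(row)

    out = {"time_h": grid}
    for name, rows in mats.items():
        m = np.vstack(rows)
        n = np.sum(~np.isnan(m), axis=0)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # columns outside every trace's support are legitimately all-NaN
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean = np.nanmean(m, axis=0)
            sd = np.nanstd(m, axis=0, ddof=1) if m.shape[0] > 1 else np.zeros(len(grid))
        sem = np.where(n > 0, sd / np.sqrt(np.maximum(n, 1)), np.nan)
        out[f"{name}_mean"] = mean
        out[f"{name}_sem"] = sem
        out[f"{name}_n"] = n
    return pd.DataFrame(out)


def cohort_summary(calls: Iterable[FateCall]) -> dict:
    """Fate fractions over all calls and mean +/- SEM duration per cycling fate."""
    calls = list(calls)
    if len(calls) == 0:
        raise ValueError("cohort_summary requires at least one fate call")
    n = len(calls)
    fates = [c.fate for c in calls]
    fractions = {f: fates.count(f) / n for f in sorted(set(fates) | set(FATES))}
    durations = {}
    for fate in (DIVISION, BINUCLEATION, POLYPLOIDIZATION):
        d = np.array([c.sg2m_duration_h for c in calls if c.fate == fate and c.sg2m_duration_h is not None])
        if len(d):
            durations[fate] = {
                "mean_h": float(np.mean(d)),
                "sem_h": float(np.std(d, ddof=1) / np.sqrt(len(d))) if len(d) > 1 else 0.0,
                "n": int(len(d)),
            }
    return {"n": n, "fractions": fractions, "durations": durations}


def calls_to_frame(calls: Iterable[FateCall]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in calls])


def plot_aligned_profile(profile: pd.DataFrame, ax=None):
    """Mean +/- SEM plot of an aligned cohort (mVenus green, mCherry red)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, color in (("mvenus", "tab:green"), ("mcherry", "tab:red")):
        m = profile[f"{name}_mean"]
        s = profile[f"{name}_sem"]
        ax.plot(profile["time_h"], m, color=color, label=name)
        ax.fill_between(profile["time_h"], m - s, m + s, color=color, alpha=0.25, linewidth=0)
    ax.set_xlabel("time from mVenus peak (h)")
    ax.set_ylabel("background-subtracted intensity (a.u.)")
    ax.legend()
    return ax
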