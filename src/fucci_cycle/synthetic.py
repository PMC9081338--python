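"""Synthetic FUCCI imaging data with known ground truth.

Emulates the four data modalities of a FUCCI cardiomyocyte study:

* single-cell reporter traces sampled every 20 min over 72 h, for the four
  cell fates (non-cycling, division, binucleation, polyploidization);
* multi-channel snapshot images (DNA / mVenus / mCherry) of nuclei drawn
  from a stated phase mixture;
* 96-well screening plates with compound effects, control wells, replicate
  plates, site-level Poisson noise and focus-failure dropout;
* DNA-content populations with 2N/4N/8N mixture structure, Ki-67 flags and
  binucleated cells sharing a cell id.

Every generator is a pure function of (spec, seed) and emits ground truth
alongside the data; no analysis stage may read the truth columns.

Trace kinetics use a piecewise shape: mCherry high through G1, a linear
hand-over during the G1/S (yellow) overlap window while mVenus rises, an
mVenus plateau through S/G2, then a fate-specific exit — a sub-hour linear
collapse at mitosis, or an exponential decay with mCherry re-accumulation in
G2 arrest.  Ground-truth phase boundaries are recorded at the times the
mVenus signal crosses 20% of its plateau (the detectability convention used
throughout the package), so the configured S/G2(/M) duration is exactly the
onset-to-offset span of the noiseless trace.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .traces import (
    BINUCLEATION,
    DIVISION,
    FATES,
    NONCYCLING,
    ONE_OBJECT_TWO_NUCLEI,
    POLYPLOIDIZATION,
    TWO_OBJECTS,
    CellTrace,
)

#: fraction of plateau at which ground-truth phase boundaries are defined
DETECTION_FRAC = 0.2
#: fixed non-cardiomyocyte contamination in ploidy populations (marker-negative)
MARKER_NEG_FRAC = 0.05

STATE_BLUE = "BLUE"
STATE_RED = "RED"
STATE_YELLOW = "YELLOW"
STATE_GREEN = "GREEN"
SNAPSHOT_STATES = (STATE_RED, STATE_GREEN, STATE_YELLOW, STATE_BLUE)


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass
class KineticsParams:
    """Reporter kinetics of the trace generator.

    Per-fate S/G2(/M) duration means default to the values measured by live
    imaging of hiPSC-derived cardiomyocytes (16.38 h dividing, 17.29 h
    binucleating, 24.5 h polyploidizing).  The G1 duration has no measured
    value for these cells and is a free parameter.
    """

    g1_duration_mean_h: float = 10.0
    sg2m_division_h: float = 16.38
    sg2m_binucleation_h: float = 17.29
    sg2m_polyploidization_h: float = 24.5
    duration_cv: float = 0.15
    onset_overlap_h: float = 1.0      # yellow (double-positive) hand-over window
    sharp_drop_h: float = 0.5         # mVenus collapse at mitotic entry
    slow_decay_tau_h: float = 8.0     # mVenus decay constant in G2 arrest
    intensity_scale: float = 1000.0
    noise_sd_frac: float = 0.1
    background_level: float = 100.0
    sampling_interval_h: float = 1.0 / 3.0   # 20-min frames
    total_duration_h: float = 72.0

    def __post_init__(self) -> None:
        for name in (
            "g1_duration_mean_h", "sg2m_division_h", "sg2m_binucleation_h",
            "sg2m_polyploidization_h", "onset_overlap_h", "sharp_drop_h",
            "slow_decay_tau_h", "sampling_interval_h", "total_duration_h",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.sharp_drop_h < self.slow_decay_tau_h:
            raise ValueError("sharp_drop_h must be < slow_decay_tau_h")
        if not 0 <= self.noise_sd_frac < 1:
            raise ValueError("noise_sd_frac must lie in [0, 1)")
        if self.duration_cv < 0:
            raise ValueError("duration_cv must be >= 0")

    def sg2m_mean_h(self, fate: str) -> float:
        return {
            DIVISION: self.sg2m_division_h,
            BINUCLEATION: self.sg2m_binucleation_h,
            POLYPLOIDIZATION: self.sg2m_polyploidization_h,
        }[fate]


def _validated_probs(values, names, what: str) -> np.ndarray:
    p = np.asarray(values, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"{what} probabilities must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{what} probabilities must sum to 1 (got {p.sum():.12f})")
    return p


@dataclass
class FateMixture:
    """Cohort fate probabilities.

    Defaults encode the live-imaging pie chart (90.4 / 5.1 / 3.2 / 1.4 %,
    renormalized to sum exactly to one).
    """

    p_noncycling: float = 0.904 / 1.001
    p_division: float = 0.051 / 1.001
    p_binucleation: float = 0.032 / 1.001
    p_polyploidization: float = 0.014 / 1.001

    def probs(self) -> np.ndarray:
        return _validated_probs(
            [self.p_noncycling, self.p_division, self.p_binucleation, self.p_polyploidization],
            FATES, "fate mixture",
        )


@dataclass
class SnapshotMixture:
    """Snapshot phase-state probabilities (RED G0/G1, GREEN S/G2/M, YELLOW
    G1/S, BLUE reporter-negative).  Defaults follow the imaging-cytometry
    fractions 85.4 / 5.1 / 1.6 %, remainder reporter-negative."""

    p_red: float = 0.854
    p_green: float = 0.051
    p_yellow: float = 0.016
    p_blue: float = 0.079

    def probs(self) -> np.ndarray:
        return _validated_probs(
            [self.p_red, self.p_green, self.p_yellow, self.p_blue],
            SNAPSHOT_STATES, "snapshot mixture",
        )


@dataclass
class PlateSpec:
    """Layout and sampling model of a screening plate.

    ``compound_wells`` maps inner-well ids to ``(compound_id, effect)`` where
    the effect multiplies the cycling (mVenus+) probability; control wells
    carry compound id ``CTRL``.  Outer wells are never assigned.
    """

    n_rows: int = 8
    n_cols: int = 12
    compound_wells: dict = field(default_factory=dict)
    control_wells: tuple = ()
    n_sites_per_well: int = 5
    site_dropout_prob: float = 0.02
    mean_nuclei_per_site: float = 150.0
    timepoints_h: tuple = (0.0, 24.0, 48.0, 72.0)
    n_replicate_plates: int = 3
    base_cycling_frac: float = 0.10     # mVenus+ fraction of FUCCI+ in controls
    p_blue: float = 0.05                # reporter-negative fraction
    yellow_frac_of_cycling: float = 0.3
    dropout_count_factor: float = 0.1

    def __post_init__(self) -> None:
        inner = set(self.inner_wells())
        for w in list(self.compound_wells) + list(self.control_wells):
            if w not in inner:
                raise ValueError(f"well {w} is not an inner well; outer wells are left unused")
        overlap = set(self.compound_wells) & set(self.control_wells)
        if overlap:
            raise ValueError(f"wells assigned as both compound and control: {sorted(overlap)}")
        if not 0 <= self.site_dropout_prob <= 1:
            raise ValueError("site_dropout_prob must lie in [0, 1]")

    def inner_wells(self) -> list[str]:
        rows = [chr(ord("A") + r) for r in range(self.n_rows)]
        return [
            f"{rows[r]}{c + 1:02d}"
            for r in range(1, self.n_rows - 1)
            for c in range(1, self.n_cols - 1)
        ]


def default_plate_layout(
    n_compounds: int = 50,
    n_controls: int = 6,
    effects: dict[str, float] | None = None,
    **kwargs,
) -> PlateSpec:
    """Fill inner wells with ``n_compounds`` compounds and ``n_controls``
    controls in row-major order; ``effects`` overrides per-compound effect
    sizes (default 1.0, the null)."""
    spec = PlateSpec(**kwargs)
    inner = spec.inner_wells()
    if n_compounds + n_controls > len(inner):
        raise ValueError(
            f"{n_compounds} compounds + {n_controls} controls exceed "
            f"{len(inner)} inner wells"
        )
    effects = effects or {}
    compound_wells = {}
    for i in range(n_compounds):
        cid = f"C{i + 1:03d}"
        compound_wells[inner[i]] = (cid, float(effects.get(cid, 1.0)))
    control_wells = tuple(inner[n_compounds : n_compounds + n_controls])
    return dataclasses.replace(spec, compound_wells=compound_wells, control_wells=control_wells)


@dataclass
class PloidyPopulationSpec:
    """DNA-content population: log-normal classes with intensity means in the
    fixed ratio 1:2:4, a Ki-67+ (cycling) fraction and binucleated cells."""

    fractions_2n_4n_8n: tuple = (0.70, 0.27, 0.03)
    intensity_cv: float = 0.12
    n_nuclei: int = 5000
    frac_ki67_pos: float = 0.10
    frac_binucleated: float = 0.10
    intensity_scale: float = 1.0

    def __post_init__(self) -> None:
        _validated_probs(self.fractions_2n_4n_8n, ("2N", "4N", "8N"), "ploidy")
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be >= 0")


# --------------------------------------------------------------------------
# traces
# --------------------------------------------------------------------------

def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Strictly positive, right-skewed duration draw with the given mean/CV."""
    if cv == 0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mean=mu, sigma=np.sqrt(sigma2)))


def _ramp(t: np.ndarray, t0: float, t1: float, y0: float, y1: float) -> np.ndarray:
    """Linear segment from (t0, y0) to (t1, y1), clipped outside."""
    return np.interp(t, [t0, t1], [y0, y1])


def generate_trace(fate: str, params: KineticsParams | None = None, seed: int = 0) -> CellTrace:
    """Generate one 72-h FUCCI trace for the given cell fate.

    Ground-truth onset/offset (the 20%-of-plateau crossings of the noiseless
    mVenus profile) and the fate label travel with the trace.
    """
    params = params or KineticsParams()
    if fate not in FATES:
        raise ValueError(f"unknown fate label: {fate!r} (expected one of {FATES})")
    rng = substream(seed, "trace")
    dt = params.sampling_interval_h
    t = np.arange(0.0, params.total_duration_h + dt / 2, dt)
    scale = params.intensity_scale
    f = DETECTION_FRAC

    mv = np.zeros_like(t)
    mc = np.full_like(t, scale)
    t_on = t_off = None
    daughters = None

    if fate != NONCYCLING:
        d_g1 = _lognormal(rng, params.g1_duration_mean_h, params.duration_cv)
        d = _lognormal(rng, params.sg2m_mean_h(fate), params.duration_cv)
        t_on = d_g1
        t_off = t_on + d
        ov = params.onset_overlap_h
        rise0, rise1 = t_on - f * ov, t_on + (1 - f) * ov
        mc = _ramp(t, rise0, rise1, scale, 0.0)
        mv = _ramp(t, rise0, rise1, 0.0, scale)

        if fate in (DIVISION, BINUCLEATION):
            sh = params.sharp_drop_h
            drop0, drop1 = t_off - (1 - f) * sh, t_off + f * sh
            mv = np.where(t >= drop0, _ramp(t, drop0, drop1, scale, 0.0), mv)
            # daughters re-enter G1: Cdt1 re-accumulates after mitosis
            mc = np.where(t >= drop1 + 1.0, _ramp(t, drop1 + 1.0, drop1 + 6.0, 0.0, scale), mc)
            daughters = TWO_OBJECTS if fate == DIVISION else ONE_OBJECT_TWO_NUCLEI
        else:
            # G2 arrest: plateau ends so the exponential tail crosses the
            # detection fraction exactly at the configured offset
            tau = params.slow_decay_tau_h
            t_arrest = max(t_off - tau * np.log(1.0 / f), rise1)
            decay = scale * np.exp(-(t - t_arrest) / tau)
            mv = np.where(t >= t_arrest, decay, mv)
            # Cdt1 re-accumulation begins at arrest, well before mVenus loss
            mc = np.where(
                t >= t_arrest,
                np.minimum(scale, _ramp(t, t_arrest, t_arrest + 10.0, 0.0, scale)),
                mc,
            )

    if params.noise_sd_frac > 0:
        nf = params.noise_sd_frac
        bg = params.background_level
        mv = mv * (1.0 + rng.normal(0.0, nf, len(t))) + bg * rng.normal(0.0, nf, len(t))
        mc = mc * (1.0 + rng.normal(0.0, nf, len(t))) + bg * rng.normal(0.0, nf, len(t))

    return CellTrace(
        cell_id=f"cell{seed % 10**8:08d}",
        time_h=t,
        mcherry=mc,
        mvenus=mv,
        post_mitosis_daughters=daughters,
        true_fate=fate,
        true_t_onset_h=t_on,
        true_t_offset_h=t_off,
    )


def generate_trace_cohort(
    n: int,
    mixture: FateMixture | None = None,
    params: KineticsParams | None = None,
    seed: int = 0,
) -> list[CellTrace]:
    """Draw ``n`` cells i.i.d. from the fate mixture and generate their traces.

    Per-cell seeds are derived from the cohort seed by counter, so cohorts
    are reproducible and individual cells are independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mixture = mixture or FateMixture()
    params = params or KineticsParams()
    probs = mixture.probs()
    rng = substream(seed, "cohort-fates")
    fates = rng.choice(len(FATES), size=n, p=probs)
    traces = []
    for i, fi in enumerate(fates):
        child = int(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(915, i)).generate_state(1)[0]
        )
        tr = generate_trace(FATES[fi], params, seed=child)
        tr.cell_id = f"cell{i:05d}"
        traces.append(tr)
    return traces


def traces_to_frame(traces) -> pd.DataFrame:
    """Long-format table (cell_id, time_h, mcherry, mvenus, background)."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "time_h": tr.time_h,
                    "mcherry": tr.mcherry,
                    "mvenus": tr.mvenus,
                    "background": 0.0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def cohort_truth(traces) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [tr.cell_id for tr in traces],
            "true_fate": [tr.true_fate for tr in traces],
            "true_t_onset_h": [tr.true_t_onset_h for tr in traces],
            "true_t_offset_h": [tr.true_t_offset_h for tr in traces],
            "post_mitosis_daughters": [tr.post_mitosis_daughters for tr in traces],
        }
    )


# --------------------------------------------------------------------------
# snapshot images
# --------------------------------------------------------------------------

def render_snapshot_image(
    n_nuclei: int,
    mixture: SnapshotMixture | None = None,
    image_shape: tuple[int, int] = (480, 640),
    seed: int = 0,
    radius_range: tuple[int, int] = (5, 8),
    intensity_scale: float = 1000.0,
    background_level: float = 100.0,
    noise_sd: float = 20.0,
    gradient_amplitude: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a 3-channel snapshot (DNA, mVenus, mCherry) of disc nuclei.

    Nuclei are non-overlapping discs placed by rejection sampling; each is
    lit in the reporter channels according to its sampled FUCCI state.
    Returns the (3, H, W) float image stack and the ground-truth table
    (nucleus_id, row, col, radius, true_state).
    """
    from skimage.draw import disk as draw_disk

    mixture = mixture or SnapshotMixture()
    probs = mixture.probs()
    rng = substream(seed, "snapshot")
    h, w = image_shape
    r_lo, r_hi = radius_range

    centers: list[tuple[float, float, float]] = []
    rows, cols, radii = [], [], []
    for i in range(n_nuclei):
        placed = False
        for _ in range(1000):
            r = rng.integers(r_lo, r_hi + 1)
            y = rng.uniform(r + 1, h - r - 1)
            x = rng.uniform(r + 1, w - r - 1)
            if centers:
                c = np.array([(cy, cx) for cy, cx, _ in centers])
                rr = np.array([cr for _, _, cr in centers])
                d = np.hypot(c[:, 0] - y, c[:, 1] - x)
                if np.any(d <= rr + r + 1):
                    continue
            centers.append((y, x, float(r)))
            rows.append(y)
            cols.append(x)
            radii.append(int(r))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could only place {i} of {n_nuclei} nuclei in {image_shape}; "
                "use a larger image_shape"
            )

    states = rng.choice(len(SNAPSHOT_STATES), size=n_nuclei, p=probs)
    truth = pd.DataFrame(
        {
            "nucleus_id": np.arange(n_nuclei),
            "row": np.round(rows, 2),
            "col": np.round(cols, 2),
            "radius_px": radii,
            "true_state": [SNAPSHOT_STATES[s] for s in states],
        }
    )

    img = np.full((3, h, w), background_level, dtype=float)
    if gradient_amplitude > 0:
        ramp = gradient_amplitude * np.linspace(0, 1, w)[None, :]
        img += ramp[None, :, :]
    for i in range(n_nuclei):
        rr, cc = draw_disk((rows[i], cols[i]), radii[i], shape=(h, w))
        state = SNAPSHOT_STATES[states[i]]
        img[0, rr, cc] += intensity_scale                      # DNA stain
        if state in (STATE_GREEN, STATE_YELLOW):
            img[1, rr, cc] += intensity_scale                  # mVenus
        if state in (STATE_RED, STATE_YELLOW):
            img[2, rr, cc] += intensity_scale                  # mCherry
    img += rng.normal(0.0, noise_sd, img.shape)
    np.clip(img, 0, None, out=img)
    return img, truth


# --------------------------------------------------------------------------
# screening plates
# --------------------------------------------------------------------------

def generate_plate(
    spec: PlateSpec | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-site FUCCI state counts for replicate screening plates.

    Returns ``(sites, plate_map, truth)``: site-level counts per timepoint,
    the well->compound map shared across replicate plates, and the per-site
    ground truth (dropout flags, true effects).  Compound effects multiply
    the cycling probability at post-treatment timepoints (> 0 h); dropout
    sites have their nucleus counts collapsed to exercise site QC.
    """
    spec = spec or default_plate_layout()
    if len(spec.control_wells) == 0:
        raise ValueError("control_wells is empty: percent-of-control normalization impossible")
    rng = substream(seed, "plate")

    assignments = {w: (cid, eff) for w, (cid, eff) in spec.compound_wells.items()}
    for w in spec.control_wells:
        assignments[w] = ("CTRL", 1.0)

    plate_map = pd.DataFrame(
        [
            {
                "well_id": w,
                "compound_id": cid,
                "role": "control" if cid == "CTRL" else "compound",
            }
            for w, (cid, _) in sorted(assignments.items())
        ]
    )

    recs, truth = [], []
    for p in range(spec.n_replicate_plates):
        plate_id = f"P{p + 1}"
        for well, (cid, eff) in sorted(assignments.items()):
            for s in range(spec.n_sites_per_well):
                site_id = f"s{s + 1}"
                for tp in spec.timepoints_h:
                    dropout = bool(rng.random() < spec.site_dropout_prob)
                    lam = spec.mean_nuclei_per_site * (
                        spec.dropout_count_factor if dropout else 1.0
                    )
                    n = int(rng.poisson(lam))
                    effect = eff if tp > 0 else 1.0
                    p_cyc = min(spec.base_cycling_frac * effect, 0.95)
                    p_states = np.array(
                        [
                            spec.p_blue,
                            (1 - spec.p_blue) * (1 - p_cyc),
                            (1 - spec.p_blue) * p_cyc * spec.yellow_frac_of_cycling,
                            (1 - spec.p_blue) * p_cyc * (1 - spec.yellow_frac_of_cycling),
                        ]
                    )
                    counts = rng.multinomial(n, p_states / p_states.sum())
                    recs.append(
                        {
                            "plate_id": plate_id,
                            "well_id": well,
                            "site_id": site_id,
                            "timepoint_h": tp,
                            "n_nuclei": n,
                            "n_blue": counts[0],
                            "n_red": counts[1],
                            "n_yellow": counts[2],
                            "n_green": counts[3],
                        }
                    )
                    truth.append(
                        {
                            "plate_id": plate_id,
                            "well_id": well,
                            "site_id": site_id,
                            "timepoint_h": tp,
                            "compound_id": cid,
                            "true_effect": eff,
                            "is_dropout": dropout,
                        }
                    )
    return pd.DataFrame(recs), plate_map, pd.DataFrame(truth)


# --------------------------------------------------------------------------
# ploidy populations
# --------------------------------------------------------------------------

def generate_ploidy_population(
    spec: PloidyPopulationSpec | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-nucleus DNA-content table with Ki-67, marker and cell-id structure.

    DNA intensities are a log-normal mixture with class means in ratio 1:2:4.
    Binucleated cells contribute two nuclei sharing a cell id.  Truth columns
    (``true_class``, ``true_ki67_pos``, ``true_marker_pos``) are emitted for
    recovery testing only.
    """
    spec = spec or PloidyPopulationSpec()
    if spec.n_nuclei < 10:
        raise ValueError("n_nuclei must be >= 10 for histogram thresholding to be defined")
    rng = substream(seed, "ploidy")

    # assign nuclei to cells: binucleated cells take two consecutive nuclei
    nuclei_per_cell = []
    remaining = spec.n_nuclei
    while remaining > 0:
        if remaining >= 2 and rng.random() < spec.frac_binucleated:
            nuclei_per_cell.append(2)
            remaining -= 2
        else:
            nuclei_per_cell.append(1)
            remaining -= 1

    cell_ids, counts = [], []
    for ci, k in enumerate(nuclei_per_cell):
        cell_ids.extend([f"cell{ci:05d}"] * k)
        counts.extend([k] * k)
    n = spec.n_nuclei

    classes = rng.choice(3, size=n, p=np.asarray(spec.fractions_2n_4n_8n))
    means = spec.intensity_scale * np.array([1.0, 2.0, 4.0])[classes]
    cv = spec.intensity_cv
    if cv > 0:
        sigma2 = np.log1p(cv * cv)
        dna = rng.lognormal(np.log(means) - sigma2 / 2, np.sqrt(sigma2))
    else:
        dna = means.astype(float)

    ki67_pos = rng.random(n) < spec.frac_ki67_pos
    marker_pos = rng.random(n) >= MARKER_NEG_FRAC

    def bimodal(pos: np.ndarray, lo: float = 1.0, hi: float = 10.0, ccv: float = 0.3) -> np.ndarray:
        s2 = np.log1p(ccv * ccv)
        mu = np.where(pos, np.log(hi), np.log(lo)) - s2 / 2
        return rng.lognormal(mu, np.sqrt(s2))

    return pd.DataFrame(
        {
            "cell_id": cell_ids,
            "nucleus_id": [f"n{i:05d}" for i in range(n)],
            "dna_intensity": dna,
            "ki67_intensity": bimodal(ki67_pos),
            "marker_intensity": bimodal(marker_pos),
            "nuclei_in_cell": counts,
            "true_class": np.array(["2N", "4N", "8N+"])[classes],
            "true_ki67_pos": ki67_pos,
            "true_marker_pos": marker_pos,
        }
    )
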