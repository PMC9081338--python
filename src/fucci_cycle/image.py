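"""Nucleus segmentation and intensity/geometry measurements.

The DNA channel identifies all nuclei; reporter and marker intensities are
then measured inside each nucleus mask and background-subtracted.  Geometry
helpers cover the two fixed-cell morphology readouts: cell area from a mask
and sarcomere spacing from a line-intensity profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label, regionprops
from skimage.segmentation import expand_labels, watershed


@dataclass
class SegmentationConfig:
    """Nucleus segmentation settings.

    ``adaptive`` subtracts a Gaussian-smoothed background (scale set by
    ``block_size``) before Otsu thresholding, which tolerates uneven
    illumination; ``global-otsu`` thresholds the raw image.  Objects outside
    the area window are rejected.  ``split_touching`` enables a
    distance-transform watershed and is off by default.
    """

    method: str = "adaptive"
    block_size: int = 51
    min_area_px: int = 30
    max_area_px: int = 2000
    enhance_uneven_background: bool = False
    split_touching: bool = False
    exclude_border: bool = True   # border objects are partial and distort measurements

    def __post_init__(self) -> None:
        if self.method not in ("adaptive", "global-otsu"):
            raise ValueError(f"unknown segmentation method: {self.method!r}")
        if not self.min_area_px < self.max_area_px:
            raise ValueError("min_area_px must be < max_area_px")
        if self.block_size % 2 == 0:
            raise ValueError("block_size must be odd")


def segment_nuclei(
    dna_image: np.ndarray, config: SegmentationConfig | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment nuclei from the DNA channel.

    Returns a label image and a per-nucleus table with geometry columns
    (``nucleus_id``, ``row``, ``col``, ``area_px``).  An all-zero image
    yields an empty table, not an error.
    """
    config = config or SegmentationConfig()
    img = np.asarray(dna_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("dna_image must be 2-D")
    if np.any(img < 0):
        raise ValueError("dna_image must be nonnegative")

    work = img
    if config.enhance_uneven_background or config.method == "adaptive":
        bg = gaussian(img, sigma=config.block_size / 2.0, preserve_range=True)
        work = img - bg
    if np.ptp(work) == 0:
        labels = np.zeros(img.shape, dtype=np.int32)
        return labels, _empty_records()
    thr = threshold_otsu(work)
    binary = work > thr

    if config.split_touching:
        dist = ndimage.distance_transform_edt(binary)
        smoothed = gaussian(dist, sigma=2, preserve_range=True)
        markers = sk_label(smoothed > 0.6 * smoothed.max())
        labels = watershed(-dist, markers, mask=binary)
    else:
        labels = sk_label(binary)
    if config.exclude_border:
        from skimage.segmentation import clear_border

        labels = clear_border(labels)

    records = []
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    next_id = 1
    for rp in regionprops(labels):
        if config.min_area_px <= rp.area <= config.max_area_px:
            keep[rp.label] = next_id
            records.append(
                {
                    "nucleus_id": next_id,
                    "row": rp.centroid[0],
                    "col": rp.centroid[1],
                    "area_px": int(rp.area),
                }
            )
            next_id += 1
    labels = keep[labels]
    return labels.astype(np.int32), (
        pd.DataFrame(records) if records else _empty_records()
    )


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=["nucleus_id", "row", "col", "area_px"])


def measure_intensities(
    label_image: np.ndarray,
    channel_images: dict[str, np.ndarray],
    background_mode: str = "local-annulus",
    records: pd.DataFrame | None = None,
    annulus_px: int = 3,
    global_percentile: float = 5.0,
) -> pd.DataFrame:
    """Background-subtracted mean intensity per nucleus and channel.

    ``local-annulus`` estimates background per nucleus from a ring of
    non-nuclear pixels ``annulus_px`` beyond the nucleus boundary (an
    automatable stand-in for drawing a region around each cell);
    ``global-percentile`` uses one low percentile of the non-nuclear pixels.
    Subtracted intensities are floored at 0.
    """
    labels = np.asarray(label_image)
    ids = np.arange(1, labels.max() + 1)
    if records is None:
        records = pd.DataFrame({"nucleus_id": ids})
    out = records.copy()

    if background_mode not in ("local-annulus", "global-percentile"):
        raise ValueError(f"unknown background_mode: {background_mode!r}")

    ring_labels = None
    if background_mode == "local-annulus" and len(ids):
        grown = expand_labels(labels, distance=annulus_px)
        ring_labels = np.where(labels == 0, grown, 0)

    for name, channel in channel_images.items():
        channel = np.asarray(channel, dtype=float)
        if channel.shape != labels.shape:
            raise ValueError(
                f"channel {name!r} shape {channel.shape} does not match "
                f"label image shape {labels.shape}"
            )
        if len(ids) == 0:
            out[name] = pd.Series(dtype=float)
            continue
        means = ndimage.mean(channel, labels=labels, index=ids)
        if background_mode == "local-annulus":
            ring_px = np.asarray(ndimage.sum(np.ones_like(channel), ring_labels, index=ids))
            ring_sum = np.asarray(ndimage.sum(channel, ring_labels, index=ids))
            fallback = (
                float(np.percentile(channel[labels == 0], global_percentile))
                if np.any(labels == 0)
                else 0.0
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                bg = np.where(ring_px > 0, ring_sum / np.maximum(ring_px, 1), fallback)
        else:
            outside = channel[labels == 0]
            bg = float(np.percentile(outside, global_percentile)) if outside.size else 0.0
        out[name] = np.maximum(np.asarray(means) - bg, 0.0)
    return out


def measure_cell_area(cell_mask: np.ndarray, pixel_size_um: float) -> float:
    """Cell area in um^2 from a boolean mask: pixel count x pixel_size^2."""
    mask = np.asarray(cell_mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("cell mask is empty")
    return n * pixel_size_um**2


def sarcomere_spacing(
    intensity_profile: np.ndarray,
    pixel_size_um: float,
    min_peaks: int = 10,
) -> float:
    """Sarcomere spacing (um) from a line profile across the striations.

    The profile shows a series of peaks at the sarcomeric spatial frequency;
    spacing is the median inter-peak distance.  Peaks are local maxima with
    prominence of at least 10% of the profile range.
    """
    from scipy.signal import find_peaks

    profile = np.asarray(intensity_profile, dtype=float)
    prominence = 0.1 * np.ptp(profile)
    peaks, _ = find_peaks(profile, prominence=prominence if prominence > 0 else None)
    if len(peaks) < min_peaks:
        raise ValueError(
            f"found {len(peaks)} peaks, need at least {min_peaks} for a spacing estimate"
        )
    return float(np.median(np.diff(peaks)) * pixel_size_um)
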