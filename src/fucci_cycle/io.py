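"""Readers and writers for the package's on-disk formats.

Images travel as multi-page TIFF (one page per channel, order
DNA/mVenus/mCherry[/marker], 16-bit); tables as CSV with a header row;
traces in long format (cell_id, time_h, mcherry, mvenus, background).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .traces import CellTrace

CHANNEL_ORDER = ("dna", "mvenus", "mcherry")


def write_image_stack(path, stack: np.ndarray) -> None:
    """Write a (C, H, W) stack as a multi-page 16-bit TIFF."""
    arr = np.asarray(stack)
    arr = np.clip(arr, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_image_stack(path) -> np.ndarray:
    """Read a multi-page TIFF as a (C, H, W) float array."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return arr.astype(float)


def write_traces_csv(path, traces, background_level: float = 0.0) -> None:
    frames = [
        pd.DataFrame(
            {
                "cell_id": tr.cell_id,
                "time_h": tr.time_h,
                "mcherry": tr.mcherry,
                "mvenus": tr.mvenus,
                "background": background_level,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path, annotations: pd.DataFrame | None = None) -> list[CellTrace]:
    """Load long-format traces; ``annotations`` (cell_id,
    post_mitosis_daughters) restores the daughter-object annotation."""
    df = pd.read_csv(path)
    ann = {}
    if annotations is not None:
        ann = dict(
            zip(annotations["cell_id"], annotations["post_mitosis_daughters"])
        )
    traces = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_h")
        daughters = ann.get(cid)
        if isinstance(daughters, float) and np.isnan(daughters):
            daughters = None
        traces.append(
            CellTrace(
                cell_id=str(cid),
                time_h=grp["time_h"].to_numpy(),
                mcherry=grp["mcherry"].to_numpy(),
                mvenus=grp["mvenus"].to_numpy(),
                post_mitosis_daughters=daughters,
            )
        )
    return traces


def write_csv(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_plate_map(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"well_id", "compound_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate map is missing columns: {sorted(missing)}")
    return df
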