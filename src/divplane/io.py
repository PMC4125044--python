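"""File formats: multichannel TIFF images/stacks and tidy CSV tables.

Channel order in TIFFs follows :data:`divplane.synthgen.render.CHANNELS`
plus the pseudo-phase plane last; single images are written as (C, H, W)
and time-lapse stacks as (T, C, H, W).
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .synthgen.render import CHANNELS, SyntheticImage
from .synthgen.timelapse import TimelapseStack
from .synthgen.types import CellTruth

TIFF_CHANNELS = tuple(CHANNELS) + ("phase",)


def write_image(image: SyntheticImage, path: str | Path) -> None:
    """Write one rendered field as a (C, H, W) float32 TIFF."""
    planes = np.stack(
        [image.channels[c] for c in TIFF_CHANNELS], axis=0
    ).astype(np.float32)
    tifffile.imwrite(path, planes, metadata={"axes": "CYX"})


def read_image(path: str | Path) -> dict[str, np.ndarray]:
    """Read a (C, H, W) TIFF back into a channel dictionary."""
    planes = tifffile.imread(path)
    if planes.ndim != 3 or planes.shape[0] != len(TIFF_CHANNELS):
        raise ValueError(
            f"expected ({len(TIFF_CHANNELS)}, H, W) TIFF, got {planes.shape}"
        )
    return {c: planes[i].astype(float) for i, c in enumerate(TIFF_CHANNELS)}


def write_stack(stack: TimelapseStack, path: str | Path) -> None:
    """Write a time-lapse as a (T, C, H, W) float32 TIFF."""
    frames = np.stack(
        [
            np.stack([f.channels[c] for c in TIFF_CHANNELS], axis=0)
            for f in stack.frames
        ],
        axis=0,
    ).astype(np.float32)
    tifffile.imwrite(path, frames, metadata={"axes": "TCYX"})


def read_stack(path: str | Path) -> list[dict[str, np.ndarray]]:
    """Read a (T, C, H, W) TIFF into per-frame channel dictionaries."""
    frames = tifffile.imread(path)
    if frames.ndim != 4 or frames.shape[1] != len(TIFF_CHANNELS):
        raise ValueError(
            f"expected (T, {len(TIFF_CHANNELS)}, H, W) TIFF, got {frames.shape}"
        )
    return [
        {c: frames[t, i].astype(float) for i, c in enumerate(TIFF_CHANNELS)}
        for t in range(frames.shape[0])
    ]


def truth_table(truths: Sequence[CellTruth]) -> pd.DataFrame:
    """Ground-truth CSV table: one row per cell, lists joined with ';'."""

    def join(vals) -> str:
        return ";".join(f"{v:.6g}" if not isinstance(v, str) else v
                        for v in vals)

    return pd.DataFrame(
        {
            "cell_id": np.arange(len(truths)),
            "length": [t.length for t in truths],
            "radius": [t.radius for t in truths],
            "center_x": [t.center[0] for t in truths],
            "center_y": [t.center[1] for t in truths],
            "angle": [t.angle for t in truths],
            "curvature": [t.curvature for t in truths],
            "nucleoid_centers": [join(t.nucleoid_centers) for t in truths],
            "nucleoid_modes": [join(t.nucleoid_modes) for t in truths],
            "ring_offsets": [join(t.ring_offsets) for t in truths],
            "matp_offsets": [join(t.matp_offsets) for t in truths],
            "division_fraction": [
                np.nan if t.division_fraction is None else t.division_fraction
                for t in truths
            ],
        }
    )


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministically formatted CSV (stable float text, no index)."""
    df.to_csv(path, index=False, float_format="%.8g")
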