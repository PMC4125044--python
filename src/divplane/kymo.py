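"""Time-lapse analysis: kymographs, midcell arrival times, lag statistics.

A kymograph stacks the axial line profile of one tracked cell over time.
Event timing is extracted from the midcell window signal: the arrival of a
channel is the first time its rescaled window signal stays above a
threshold, and the ring-after-Ter lag is the difference of the two arrival
times in doubling-time units.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import geometry
from .geometry import CellRecord, ProfileSet

MIDCELL_HALFWIDTH = 0.05       # fraction of L
MIDCELL_MAX_HALFWIDTH = 0.15   # um; cap so the window stays structure-sized
ARRIVAL_THETA = 0.5            # threshold on the rescaled midcell signal
ARRIVAL_K = 2                  # consecutive frames required above threshold


@dataclass
class Kymograph:
    """x-t intensity matrices for one cell, one row per frame."""

    x: np.ndarray                         # axial grid; um from cell center,
                                          # or x/L in [-0.5, 0.5] if normalized
    t: np.ndarray                         # frame times (frames or minutes)
    data: dict[str, np.ndarray]           # channel -> (T, X); NaN outside cell
    lengths: np.ndarray                   # per-frame cell length, um
    t_d: float                            # doubling time, same units as t
    normalized: bool = False
    truncated: bool = False               # track lost before the stack ended
    midcell_halfwidth: float = MIDCELL_HALFWIDTH
    midcell_max_halfwidth_um: float = MIDCELL_MAX_HALFWIDTH

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def midcell_signal(self, channel: str) -> np.ndarray:
        """Flank-corrected integrated intensity in the midcell window.

        The window half-width is a fixed fraction of the (growing) cell
        length, capped at an absolute size of the order of one
        diffraction-limited structure image so that a growing cell does
        not sweep ever more of a fixed-width band into the window.  The
        signal is the window integral minus the flanking
        intensity level (median per unit length in the bands between 1.5
        and 3 window half-widths on either side) times the window size.
        Flank correction keeps the trace of a compact midcell structure
        flat after arrival instead of drifting with cell growth, which
        would distort the rescaled onset used for arrival timing.
        """
        m = np.empty(self.n_frames)
        arr = self.data[channel]
        dx = float(self.x[1] - self.x[0]) if len(self.x) > 1 else 1.0
        for i in range(self.n_frames):
            if self.normalized:
                hw = self.midcell_halfwidth
            else:
                hw = min(
                    self.midcell_halfwidth * self.lengths[i],
                    self.midcell_max_halfwidth_um,
                )
            ax = np.abs(self.x)
            sel = ax <= hw
            flank = (ax > 1.5 * hw) & (ax <= 3.0 * hw)
            row = arr[i]
            flank_vals = row[flank]
            flank_vals = flank_vals[np.isfinite(flank_vals)]
            level = float(np.median(flank_vals)) if flank_vals.size else 0.0
            m[i] = (np.nansum(row[sel]) - level * sel.sum()) * dx
        return m


@dataclass
class ArrivalRecord:
    """Arrival times of the Ter focus and the ring at midcell for one cell."""

    t_matp: float
    t_z: float
    t_d: float

    @property
    def lag(self) -> float:
        """(t_z - t_matp) / T_d, dimensionless."""
        return (self.t_z - self.t_matp) / self.t_d


@dataclass
class LagSummary:
    mean: float
    sd: float
    n: int
    bin_edges: np.ndarray
    counts: np.ndarray


class TrackLostError(RuntimeError):
    """No matching cell found in a frame while building a kymograph."""


def profiles_over_time(
    stack_channels: Sequence[dict[str, np.ndarray]],
    pixel_size: float,
    channels: Sequence[str] = ("cyto", "ring", "matp"),
) -> tuple[list[ProfileSet], bool]:
    """Segment and profile the tracked cell in every frame.

    Frames are matched by nearest centroid to the previous frame's cell.
    Returns the per-frame profiles and a flag that is True when the track
    was lost before the last frame (the kymograph is then truncated).
    """
    profs: list[ProfileSet] = []
    prev_centroid: Optional[np.ndarray] = None
    truncated = False
    for frame in stack_channels:
        recs = geometry.segment_cells(
            frame, pixel_size=pixel_size, flag_division_pairs=False
        )
        if not recs:
            truncated = True
            break
        cents = [np.argwhere(r.mask).mean(axis=0) for r in recs]
        if prev_centroid is None:
            i = int(np.argmax([r.mask.sum() for r in recs]))
        else:
            i = int(
                np.argmin([np.linalg.norm(c - prev_centroid) for c in cents])
            )
        prev_centroid = cents[i]
        rec = recs[i]
        try:
            geometry.extract_axis(rec, image=frame)
        except geometry.ShapeError:
            truncated = True
            break
        profs.append(
            geometry.line_profiles(frame, rec, channels=list(channels))
        )
    if not profs:
        raise TrackLostError("no cell found in the first frame")
    return profs, truncated


def build_kymograph(
    profiles: Sequence[ProfileSet],
    t_d: float,
    channels: Optional[Sequence[str]] = None,
    normalized: bool = False,
    frame_interval: float = 1.0,
    n_columns: int = 121,
    truncated: bool = False,
) -> Kymograph:
    """Resample per-frame profiles onto a common axial grid.

    Absolute mode anchors the grid at each frame's cell center (um);
    normalized mode uses x/L so a structure at fixed relative position
    stays in one column while the cell grows.  Positions outside a frame's
    cell are NaN.
    """
    if channels is None:
        channels = list(profiles[0].intensity)
    lengths = np.array([p.length for p in profiles])
    if normalized:
        x = np.linspace(-0.5, 0.5, n_columns)
    else:
        half = lengths.max() / 2.0
        x = np.linspace(-half, half, n_columns)
    data = {c: np.full((len(profiles), n_columns), np.nan) for c in channels}
    for i, p in enumerate(profiles):
        rel = (p.s - p.length / 2.0) / (p.length if normalized else 1.0)
        inside = (x >= rel[0]) & (x <= rel[-1])
        for c in channels:
            data[c][i, inside] = np.interp(x[inside], rel, p.intensity[c])
    return Kymograph(
        x=x,
        t=np.arange(len(profiles)) * frame_interval,
        data=data,
        lengths=lengths,
        t_d=t_d * frame_interval,
        normalized=normalized,
        truncated=truncated,
    )


def arrival_time(
    kym: Kymograph,
    channel: str,
    theta: float = ARRIVAL_THETA,
    k: int = ARRIVAL_K,
) -> Optional[float]:
    """First time the rescaled midcell signal stays above ``theta``.

    The raw window signal is rescaled to [0, 1] between its baseline (10th
    percentile) and plateau (90th percentile); deciles rather than min/max
    keep the rescaling robust to noise spikes while leaving room for an
    arrival as early as ~0.1 of the observed span.  Arrival requires
    ``k`` consecutive frames at or above ``theta``; the reported time
    interpolates the crossing between the preceding frame and the first
    frame of the run.  Returns ``None`` when the signal never qualifies.
    """
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie in (0, 1)")
    m = kym.midcell_signal(channel)
    lo, hi = np.nanpercentile(m, [10.0, 90.0])
    if hi - lo <= 0:
        return None
    r = (m - lo) / (hi - lo)
    above = r >= theta
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= k:
            start = i - k + 1
            if start == 0:
                return float(kym.t[0])
            t0, t1 = kym.t[start - 1], kym.t[start]
            r0, r1 = r[start - 1], r[start]
            if r1 > r0:
                frac = np.clip((theta - r0) / (r1 - r0), 0.0, 1.0)
            else:
                frac = 1.0
            return float(t0 + frac * (t1 - t0))
    return None


def arrival_record(
    kym: Kymograph,
    matp_channel: str = "matp",
    ring_channel: str = "ring",
    theta: float = ARRIVAL_THETA,
    k: int = ARRIVAL_K,
) -> Optional[ArrivalRecord]:
    """Both arrivals for one cell; ``None`` unless both are detected."""
    t_m = arrival_time(kym, matp_channel, theta=theta, k=k)
    t_z = arrival_time(kym, ring_channel, theta=theta, k=k)
    if t_m is None or t_z is None:
        return None
    return ArrivalRecord(t_matp=t_m, t_z=t_z, t_d=kym.t_d)


def arrival_lag(
    records: Sequence[ArrivalRecord],
    bin_width: float = 0.05,
    min_cells: int = 10,
) -> LagSummary:
    """Population lag histogram and mean +/- SD in doubling-time units."""
    lags = np.array([r.lag for r in records], dtype=float)
    if len(lags) < min_cells:
        raise ValueError(f"need >= {min_cells} cells with both arrivals")
    lo = np.floor(lags.min() / bin_width) * bin_width
    hi = np.ceil(lags.max() / bin_width) * bin_width + bin_width / 2
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(lags, bins=edges)
    return LagSummary(
        mean=float(lags.mean()),
        sd=float(lags.std(ddof=1)),
        n=len(lags),
        bin_edges=edges,
        counts=counts,
    )


def accumulation_curves(
    kymographs: Sequence[Kymograph],
    channels: Sequence[str] = ("matp", "ring"),
    n_bins: int = 20,
) -> pd.DataFrame:
    """Mean rescaled midcell intensity vs cell-cycle time, with SE.

    Each cell's window signal is rescaled to [0, 1] (quintile scaling) and
    its times normalized by its own doubling time before averaging across
    cells in ``n_bins`` bins of t/T_d.  The SE column is NaN wherever only
    a single cell contributes.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    rows = []
    for c in channels:
        # one row of bin means per cell, so the SE is across cells
        cell_means = np.full((len(kymographs), n_bins), np.nan)
        for ci, kym in enumerate(kymographs):
            m = kym.midcell_signal(c)
            lo, hi = np.nanpercentile(m, [10.0, 90.0])
            if hi - lo <= 0:
                continue
            r = np.clip((m - lo) / (hi - lo), 0.0, 1.0)
            tt = kym.t / kym.t_d
            idx = np.clip(np.digitize(tt, edges) - 1, 0, n_bins - 1)
            for i in range(n_bins):
                sel = idx == i
                if sel.any():
                    cell_means[ci, i] = r[sel].mean()
        for i in range(n_bins):
            vals = cell_means[:, i]
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "channel": c,
                    "t_over_td": float(centers[i]),
                    "mean": float(vals.mean()) if vals.size else np.nan,
                    "se": (
                        float(vals.std(ddof=1) / np.sqrt(vals.size))
                        if vals.size > 1
                        else np.nan
                    ),
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(rows)
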