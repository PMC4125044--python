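"""Axial localization of nucleoids, division rings, and Ter foci.

All centers are reported as signed displacements from the cell center
(``dx = s_center - L/2``, um, positive toward pole *b*), the quantities the
downstream co-localization statistics consume.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .geometry import ProfileSet

#: fraction of the profile maximum defining the nucleoid extent
NUCLEOID_EXTENT_FRACTION = 0.20
#: relative dip depth separating bilobed from compact nucleoids
DIP_DEPTH_MIN = 0.10
#: |dx|/L beyond which a ring is polar
C_POLAR = 0.30


@dataclass
class NucleoidResult:
    """Nucleoid centers and their supra-threshold extents along the axis."""

    centers: list[float]                  # dx values, um
    extents: list[tuple[float, float]]    # (s_start, s_end), um
    missing: bool = False

    @property
    def n(self) -> int:
        return len(self.centers)


@dataclass
class PeakFitResult:
    """One fitted ring/focus: center, amplitude, and fit provenance."""

    dx: float             # um from cell center
    amplitude: float
    sigma: float          # um, Gaussian width of the image of the structure
    fallback: bool = False  # True when the Gaussian fit fell back to centroid


@dataclass
class LocalizationRecord:
    """Per-cell localization summary consumed by the statistics modules."""

    length: float
    dx_n: float = np.nan
    dx_z: float = np.nan
    dx_matp: float = np.nan
    nucleoid_class: Optional[str] = None   # compact | bilobed
    ring_class: Optional[str] = None       # central | polar
    n_nucleoids: int = 0
    n_rings: int = 0
    nucleoid_centers: list[float] = field(default_factory=list)
    ring_centers: list[float] = field(default_factory=list)
    matp_centers: list[float] = field(default_factory=list)
    cell_id: int = -1


def _smooth(y: np.ndarray, window: int = 3) -> np.ndarray:
    if window < 2 or len(y) < window:
        return y
    k = np.ones(window) / window
    return np.convolve(np.pad(y, window // 2, mode="edge"), k, mode="valid")


def nucleoid_center(
    profiles: ProfileSet,
    channel: str = "dapi",
    extent_fraction: float = NUCLEOID_EXTENT_FRACTION,
) -> NucleoidResult:
    """Intensity-weighted centroids of supra-threshold nucleoid regions.

    The nucleoid extent is the contiguous run of the profile above
    ``extent_fraction`` of its maximum; well-separated runs count as
    separate nucleoids, each with its own center.
    """
    s = profiles.s
    y = _smooth(np.clip(profiles.channel(channel), 0.0, None))
    if y.max() <= 0:
        return NucleoidResult(centers=[], extents=[], missing=True)
    above = y >= extent_fraction * y.max()
    # split into contiguous runs
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    centers, extents = [], []
    mid = profiles.length / 2.0
    for i0, i1 in zip(starts, ends):
        if i1 - i0 < 2:
            continue
        seg_s, seg_y = s[i0:i1], y[i0:i1]
        centers.append(float((seg_s * seg_y).sum() / seg_y.sum() - mid))
        extents.append((float(s[i0]), float(s[i1 - 1])))
    return NucleoidResult(centers=centers, extents=extents, missing=not centers)


def classify_nucleoid(
    profiles: ProfileSet,
    channel: str = "dapi",
    dip_depth_min: float = DIP_DEPTH_MIN,
    extent: Optional[tuple[float, float]] = None,
) -> str:
    """Compact vs bilobed: does the central profile show a discernible dip?

    A nucleoid is bilobed iff the smoothed profile has a local minimum
    within the central 40% of the nucleoid extent whose relative depth,
    measured against the lower of the two flanking maxima, reaches
    ``dip_depth_min``; otherwise it is compact.
    """
    if extent is None:
        res = nucleoid_center(profiles, channel=channel)
        if res.missing:
            return "compact"
        extent = res.extents[int(np.argmax(
            [e[1] - e[0] for e in res.extents]
        ))]
    s = profiles.s
    y = _smooth(np.clip(profiles.channel(channel), 0.0, None))
    s0, s1 = extent
    center, span = (s0 + s1) / 2.0, (s1 - s0)
    core = (s >= center - 0.2 * span) & (s <= center + 0.2 * span)
    idx = np.flatnonzero(core)
    if len(idx) < 3:
        return "compact"
    best_depth = 0.0
    for i in idx:
        if i == 0 or i == len(y) - 1:
            continue
        if not (y[i] <= y[i - 1] and y[i] <= y[i + 1]):
            continue
        in_extent = (s >= s0) & (s <= s1)
        left = y[in_extent & (s <= s[i])].max()
        right = y[in_extent & (s >= s[i])].max()
        flank = min(left, right)
        if flank > 0:
            best_depth = max(best_depth, 1.0 - y[i] / flank)
    return "bilobed" if best_depth >= dip_depth_min else "compact"


def _gauss_offset(x, amp, mu, sig, base):
    return amp * np.exp(-((x - mu) ** 2) / (2 * sig**2)) + base


def _fit_peaks(
    profiles: ProfileSet,
    channel: str,
    prominence_fraction: float = 0.15,
    window_um: float = 0.5,
    min_amplitude_fraction: float = 0.10,
) -> list[PeakFitResult]:
    """Candidate maxima refined by single-Gaussian fits in a local window."""
    s = profiles.s
    y = np.clip(profiles.channel(channel), 0.0, None)
    if y.max() <= 0:
        return []
    ys = _smooth(y)
    peaks, props = find_peaks(
        ys,
        prominence=prominence_fraction * ys.max(),
        height=min_amplitude_fraction * ys.max(),
    )
    mid = profiles.length / 2.0
    out: list[PeakFitResult] = []
    for p in peaks:
        sel = np.abs(s - s[p]) <= window_um
        xs, yw = s[sel], y[sel]
        amp0 = float(ys[p])
        try:
            popt, _ = curve_fit(
                _gauss_offset,
                xs,
                yw,
                p0=[amp0, s[p], 0.12, float(yw.min())],
                bounds=(
                    [0.0, xs[0], 0.02, -np.inf],
                    [np.inf, xs[-1], window_um, np.inf],
                ),
                maxfev=4000,
            )
            out.append(
                PeakFitResult(
                    dx=float(popt[1] - mid),
                    amplitude=float(popt[0]),
                    sigma=float(popt[2]),
                )
            )
        except (RuntimeError, ValueError):
            base = yw.min()
            wgt = np.clip(yw - base, 0.0, None)
            mu = float((xs * wgt).sum() / wgt.sum()) if wgt.sum() else s[p]
            out.append(
                PeakFitResult(
                    dx=float(mu - mid),
                    amplitude=amp0,
                    sigma=np.nan,
                    fallback=True,
                )
            )
    out.sort(key=lambda r: r.dx)
    return out


def ring_center(profiles: ProfileSet, channel: str = "ring", **kw) -> list[PeakFitResult]:
    """Z-ring centers from the ring-label channel."""
    return _fit_peaks(profiles, channel, **kw)


def focus_center(profiles: ProfileSet, channel: str = "matp", **kw) -> list[PeakFitResult]:
    """Ter-focus centers from the focus-label channel (axial projection)."""
    return _fit_peaks(profiles, channel, **kw)


def classify_ring(dx: float, length: float, c_polar: float = C_POLAR) -> str:
    """A ring is polar when it sits within ``(0.5 - c_polar) * L`` of a pole."""
    return "polar" if abs(dx) / length > c_polar else "central"


def localize_cell(
    profiles: ProfileSet,
    cell_id: int = -1,
    c_polar: float = C_POLAR,
    dip_depth_min: float = DIP_DEPTH_MIN,
) -> LocalizationRecord:
    """Full per-cell localization: nucleoid(s), ring(s), focus (if present).

    The principal ring is the brightest one; the principal nucleoid is the
    one nearest the principal ring (ties toward lower s).  Class labels are
    set only when the corresponding channel carries signal.
    """
    rec = LocalizationRecord(length=profiles.length, cell_id=cell_id)
    if "dapi" in profiles.intensity:
        nres = nucleoid_center(profiles)
        rec.nucleoid_centers = nres.centers
        rec.n_nucleoids = nres.n
    rings: list[PeakFitResult] = []
    if "ring" in profiles.intensity:
        rings = ring_center(profiles)
        rec.ring_centers = [r.dx for r in rings]
        rec.n_rings = len(rings)
    if rings:
        main = max(rings, key=lambda r: r.amplitude)
        rec.dx_z = main.dx
        rec.ring_class = classify_ring(main.dx, profiles.length, c_polar)
    if rec.nucleoid_centers:
        if np.isfinite(rec.dx_z):
            dists = [abs(c - rec.dx_z) for c in rec.nucleoid_centers]
            rec.dx_n = rec.nucleoid_centers[int(np.argmin(dists))]
        else:
            rec.dx_n = rec.nucleoid_centers[0]
        if rec.n_nucleoids == 1:
            rec.nucleoid_class = classify_nucleoid(
                profiles, dip_depth_min=dip_depth_min
            )
    if "matp" in profiles.intensity:
        foci = focus_center(profiles)
        rec.matp_centers = [f.dx for f in foci]
        if foci:
            if np.isfinite(rec.dx_z):
                rec.dx_matp = min(
                    (f.dx for f in foci), key=lambda d: abs(d - rec.dx_z)
                )
            else:
                rec.dx_matp = max(foci, key=lambda f: f.amplitude).dx
    return rec
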