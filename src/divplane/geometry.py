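"""Cell geometry: segmentation, medial axis, length, and line profiles.

The axial coordinate convention used everywhere downstream: ``s`` runs from
0 at pole *a* to ``L`` at pole *b* along the medial axis; signed
displacements are measured from the cell center ``s = L/2`` and reported in
micrometres.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.ndimage import map_coordinates
from scipy.signal import savgol_filter
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import skeletonize
from skimage.segmentation import clear_border


class ShapeError(ValueError):
    """Mask geometry incompatible with a single rod-shaped cell."""


@dataclass
class CellRecord:
    """One segmented cell: mask, medial axis, poles, and length."""

    mask: np.ndarray                       # boolean, full-image frame
    pixel_size: float                      # um / px
    label: int = 0
    axis_px: Optional[np.ndarray] = None   # (N, 2) float (row, col)
    division_candidate: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def length(self) -> float:
        """Arc length of the medial axis in um."""
        if self.axis_px is None:
            raise ShapeError("axis not extracted yet")
        steps = np.linalg.norm(np.diff(self.axis_px, axis=0), axis=1)
        return float(steps.sum() * self.pixel_size)

    @property
    def pole_a(self) -> np.ndarray:
        """(x, y) of the first pole in um."""
        return self.axis_px[0][::-1] * self.pixel_size

    @property
    def pole_b(self) -> np.ndarray:
        return self.axis_px[-1][::-1] * self.pixel_size

    @property
    def arc_s(self) -> np.ndarray:
        """Axial coordinate of each axis sample, um, in [0, L]."""
        steps = np.linalg.norm(np.diff(self.axis_px, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)]) * self.pixel_size


@dataclass
class ProfileSet:
    """Per-channel background-subtracted intensity along the cell axis."""

    s: np.ndarray                      # um, strictly increasing, in [0, L]
    intensity: dict[str, np.ndarray]
    background: dict[str, float]
    band_width: np.ndarray             # um of in-mask band sampled at each s
    pixel_size: float
    length: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("profile coordinate must be strictly increasing")

    def channel(self, name: str) -> np.ndarray:
        return self.intensity[name]


@dataclass
class Constriction:
    """A detected waist in the cell width profile."""

    s: float                  # um from pole a
    depth: float              # 1 - w_min / lower flanking max
    width_at_waist: float     # um
    length: float             # cell length, um

    @property
    def from_poles(self) -> tuple[float, float]:
        """Waist position measured from each pole (two symmetric values)."""
        return (self.s, self.length - self.s)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _as_array(image, channel: str) -> np.ndarray:
    if hasattr(image, "channels"):
        return np.asarray(image.channels[channel], dtype=float)
    if isinstance(image, dict):
        return np.asarray(image[channel], dtype=float)
    return np.asarray(image, dtype=float)


def segment_cells(
    image,
    channel: str = "cyto",
    pixel_size: Optional[float] = None,
    min_area_um2: float = 0.5,
    flag_division_pairs: bool = True,
    constriction_min_depth: float = 0.15,
) -> list[CellRecord]:
    """Segment fluorescent cells by Otsu thresholding the chosen channel.

    Regions are hole-filled, border-touching regions are dropped, and
    regions smaller than ``min_area_um2`` are removed.  An adhered daughter
    pair segments as one region; when ``flag_division_pairs`` is set, a
    pronounced waist in the width profile marks the record as a division
    candidate.  A blank image yields an empty list, not an error.
    """
    if pixel_size is None:
        pixel_size = getattr(image, "pixel_size", None)
    if pixel_size is None:
        raise ValueError("pixel_size required when image carries none")
    img = _as_array(image, channel)
    if img.size == 0 or np.ptp(img) == 0:
        return []
    thresh = threshold_otsu(img)
    fg = img > thresh
    if not fg.any() or fg.all():
        return []
    # reject pure-noise splits: demand genuine foreground contrast
    bg_vals = img[~fg]
    bg_mean = bg_vals.mean()
    if img[fg].mean() - bg_mean < 5.0 * (bg_vals.std() + 1e-12):
        return []
    # Otsu seeds the foreground; the outline itself comes from a low
    # fractional threshold, because a rod's projected intensity falls off
    # toward the membrane and Otsu alone clips the dim cell rim.
    peak = np.percentile(img[fg], 90)
    fg = img > bg_mean + 0.15 * (peak - bg_mean)
    fg = ndi.binary_fill_holes(fg)
    fg = clear_border(fg)
    labels = sk_label(fg, connectivity=2)
    min_px = max(int(round(min_area_um2 / pixel_size**2)), 1)
    records: list[CellRecord] = []
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        if mask.sum() < min_px:
            continue
        rec = CellRecord(mask=mask, pixel_size=pixel_size, label=lab)
        if flag_division_pairs:
            try:
                extract_axis(rec, image=image)
                c = detect_constriction(
                    rec, min_depth=constriction_min_depth, image=image
                )
                rec.division_candidate = c is not None
            except ShapeError as err:
                rec.notes.append(f"axis failed during flagging: {err}")
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# medial axis
# ---------------------------------------------------------------------------

def _skeleton_longest_path(skel: np.ndarray) -> np.ndarray:
    """Longest geodesic path through the skeleton, as (N, 2) pixel coords."""
    coords = np.argwhere(skel)
    if len(coords) == 0:
        raise ShapeError("empty skeleton")
    if len(coords) == 1:
        return coords.astype(float)
    index = {tuple(c): i for i, c in enumerate(coords)}
    rows, cols, data = [], [], []
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for i, (r, c) in enumerate(coords):
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
                data.append(float(np.hypot(dr, dc)))
    graph = csr_matrix((data, (rows, cols)), shape=(len(coords),) * 2)
    degree = np.diff(graph.indptr)
    endpoints = np.flatnonzero(degree <= 1)
    if len(endpoints) < 2:
        raise ShapeError("skeleton has no two endpoints (closed or blob-like)")
    dist, pred = dijkstra(
        graph, indices=endpoints, return_predecessors=True, directed=False
    )
    sub = dist[:, endpoints]
    sub[~np.isfinite(sub)] = -1.0
    a, b = np.unravel_index(np.argmax(sub), sub.shape)
    if sub[a, b] < 0:
        raise ShapeError("skeleton is disconnected")
    start, goal = endpoints[a], endpoints[b]
    path = [goal]
    while path[-1] != start:
        nxt = pred[a, path[-1]]
        if nxt < 0:
            raise ShapeError("skeleton path reconstruction failed")
        path.append(nxt)
    return coords[np.array(path[::-1])].astype(float)


def _smooth_path(path: np.ndarray, window: int = 7) -> np.ndarray:
    """Local-quadratic (Savitzky-Golay) smoothing of the pixel path.

    A quadratic window removes skeleton jaggedness without flattening the
    gentle curvature of bent cells, which a plain moving average would
    shorten measurably.
    """
    if len(path) < 5 or window < 5:
        return path
    window = min(window if window % 2 else window + 1, len(path) // 2 * 2 + 1)
    if window < 5:
        return path
    return savgol_filter(path, window, polyorder=2, axis=0, mode="nearest")


def _march_to_boundary(
    surface: np.ndarray,
    start: np.ndarray,
    direction: np.ndarray,
    max_steps: float,
    level: float = 0.5,
) -> np.ndarray:
    """Walk from ``start`` along ``direction`` to the ``level`` crossing."""
    direction = direction / (np.linalg.norm(direction) + 1e-12)
    step = 0.1
    t_vals = np.arange(step, max_steps + 3.0, step)
    pts = start[None, :] + t_vals[:, None] * direction[None, :]
    vals = map_coordinates(surface, pts.T, order=1, mode="constant")
    out = np.flatnonzero(vals < level)
    if len(out) == 0:
        t_exit = t_vals[-1]
    else:
        j = out[0]
        t_exit = t_vals[j]
        if j > 0 and vals[j - 1] > vals[j]:
            t_exit -= step * (level - vals[j]) / (vals[j - 1] - vals[j])
    return start + t_exit * direction


def _recenter_path(
    path: np.ndarray, surface: np.ndarray, level: float, reach: float
) -> np.ndarray:
    """Slide each path point to the midpoint of its perpendicular outline.

    One centerline-correction pass removes the lateral quantization of the
    pixel skeleton: each point moves to the midpoint between the two
    ``level`` crossings of the outline along its perpendicular.  Points
    whose crossings cannot be bracketed stay put.
    """
    if len(path) < 3:
        return path
    perp = _perpendiculars(path)
    step = 0.2
    offsets = np.arange(-reach, reach + 1e-9, step)
    pts = path[:, None, :] + offsets[None, :, None] * perp[:, None, :]
    vals = map_coordinates(
        surface, pts.reshape(-1, 2).T, order=1, mode="constant"
    ).reshape(len(path), len(offsets))
    mid_idx = len(offsets) // 2
    out = path.copy()
    for i in range(len(path)):
        row = vals[i]
        if row[mid_idx] < level:
            continue
        left = np.flatnonzero(row[:mid_idx + 1] < level)
        right = np.flatnonzero(row[mid_idx:] < level)
        if left.size == 0 or right.size == 0:
            continue
        jl = left[-1]
        lo = offsets[jl] + step * (level - row[jl]) / (row[jl + 1] - row[jl])
        jr = right[0] + mid_idx
        hi = offsets[jr] - step * (level - row[jr]) / (row[jr - 1] - row[jr])
        out[i] = path[i] + ((lo + hi) / 2.0) * perp[i]
    return out


def extract_axis(
    record: CellRecord,
    smooth_window: int = 7,
    image=None,
    channel: str = "cyto",
    threshold_fraction: float = 0.30,
) -> CellRecord:
    """Fit the medial axis of the mask and extend it to the poles.

    Skeletonizes the mask, prunes to the longest geodesic path, smooths it
    with a local-quadratic filter, extends both ends to the cell boundary
    along the end tangents, and resamples to even (0.5 px) arc spacing.
    When ``image`` is given the pole positions come from the sub-pixel
    crossing of the smooth intensity outline (the segmentation threshold
    level) instead of the pixelated mask edge, which removes the
    grid-phase quantization of the cell length.  Raises
    :class:`ShapeError` for blob-like regions without a usable axis.
    """
    mask = record.mask
    if mask.sum() == 0:
        raise ShapeError("empty mask")
    skel = skeletonize(mask)
    path = _skeleton_longest_path(skel)
    path = _smooth_path(path, window=smooth_window)
    edt = ndi.distance_transform_edt(mask)
    max_half = float(edt.max())
    if image is not None:
        img = _as_array(image, channel)
        bg = estimate_background(image, channel, mask)
        surface = img - bg
        level = threshold_fraction * float(
            np.percentile(surface[mask], 90.0)
        )
    else:
        surface, level = mask.astype(float), 0.5
    path = _recenter_path(path, surface, level, reach=max_half * 2.2 + 2.0)
    path = _smooth_path(path, window=smooth_window)
    k = min(5, len(path) - 1)
    if k >= 1:
        tip_a = _march_to_boundary(
            surface, path[0], path[0] - path[k],
            max_steps=2.5 * max_half, level=level,
        )
        tip_b = _march_to_boundary(
            surface, path[-1], path[-1] - path[-1 - k],
            max_steps=2.5 * max_half, level=level,
        )
        path = np.vstack([tip_a, path, tip_b])
    # resample to even arc spacing of 0.5 px
    steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    total = arc[-1]
    if total <= 0:
        raise ShapeError("degenerate axis")
    n = max(int(np.ceil(total / 0.5)) + 1, 2)
    even = np.linspace(0.0, total, n)
    resampled = np.stack(
        [np.interp(even, arc, path[:, k]) for k in range(2)], axis=1
    )
    # canonical orientation: pole a is the endpoint with the smaller
    # (col, row); keeps the sign of axial displacements deterministic
    first, last = resampled[0], resampled[-1]
    if (first[1], first[0]) > (last[1], last[0]):
        resampled = resampled[::-1]
    length_um = total * record.pixel_size
    if length_um < 3.0 * max_half * record.pixel_size:
        raise ShapeError(
            f"region aspect too low for a rod (L={length_um:.2f} um, "
            f"half-width={max_half * record.pixel_size:.2f} um)"
        )
    record.axis_px = resampled
    return record


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def estimate_background(
    image, channel: str, cell_mask: np.ndarray, dilate_px: int = 3
) -> float:
    """Background level: mode of pixels well outside every cell."""
    img = _as_array(image, channel)
    outside = ~ndi.binary_dilation(cell_mask, iterations=dilate_px)
    vals = img[outside]
    if vals.size < 16:
        return float(np.median(img))
    lo, hi = np.percentile(vals, [0.5, 99.5])
    if hi - lo < 1e-9:
        return float(np.median(vals))
    hist, edges = np.histogram(vals, bins=64, range=(lo, hi))
    i = int(np.argmax(hist))
    return float((edges[i] + edges[i + 1]) / 2.0)


def _perpendiculars(axis_px: np.ndarray) -> np.ndarray:
    grad = np.gradient(axis_px, axis=0)
    norm = np.linalg.norm(grad, axis=1, keepdims=True)
    tangent = grad / (norm + 1e-12)
    return np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)


def line_profiles(
    image,
    record: CellRecord,
    half_width: float = 0.35,
    channels: Optional[Sequence[str]] = None,
    step_px: float = 1.0,
    all_cells_mask: Optional[np.ndarray] = None,
) -> ProfileSet:
    """Axial intensity profiles: perpendicular in-mask means along the axis.

    At each axial sample the intensity is the mean of (bilinearly
    interpolated) pixels lying within ``half_width`` um of the axis point,
    perpendicular to the axis and inside the mask.  One global background
    per channel (mode of non-cell pixels) is subtracted.
    """
    if record.axis_px is None:
        extract_axis(record)
    if channels is None:
        if hasattr(image, "channels"):
            channels = [c for c in image.channels if c != "phase"]
        else:
            raise ValueError("explicit channel list required for raw arrays")
    px = record.pixel_size
    edt = ndi.distance_transform_edt(record.mask)
    radius_um = float(edt.max()) * px
    if half_width > radius_um:
        warnings.warn(
            "half_width exceeds the cell radius; sampling clipped to the mask",
            stacklevel=2,
        )
    # resample axis at step_px spacing
    arc = record.arc_s / px
    n = max(int(np.floor(arc[-1] / step_px)) + 1, 2)
    s_px = np.linspace(0.0, arc[-1], n)
    axis = np.stack(
        [np.interp(s_px, arc, record.axis_px[:, k]) for k in range(2)], axis=1
    )
    perp = _perpendiculars(axis)
    hw_px = half_width / px
    offsets = np.arange(-hw_px, hw_px + 1e-9, 0.5)
    # sample grid: (n_s, n_offsets, 2)
    pts = axis[:, None, :] + offsets[None, :, None] * perp[:, None, :]
    flat = pts.reshape(-1, 2).T
    in_mask = map_coordinates(
        record.mask.astype(float), flat, order=1, mode="constant"
    ).reshape(n, len(offsets))
    weights = (in_mask >= 0.5).astype(float)
    n_in = weights.sum(axis=1)
    n_in_safe = np.where(n_in > 0, n_in, 1.0)
    cell_mask = all_cells_mask if all_cells_mask is not None else record.mask
    intensity: dict[str, np.ndarray] = {}
    background: dict[str, float] = {}
    for ch in channels:
        img = _as_array(image, ch)
        bg = estimate_background(image, ch, cell_mask)
        vals = map_coordinates(img, flat, order=1, mode="nearest").reshape(
            n, len(offsets)
        )
        prof = (vals * weights).sum(axis=1) / n_in_safe - bg
        prof[n_in == 0] = 0.0
        intensity[ch] = prof
        background[ch] = bg
    return ProfileSet(
        s=s_px * px,
        intensity=intensity,
        background=background,
        band_width=n_in * 0.5 * px,
        pixel_size=px,
        length=record.length,
    )


def width_profile(
    record: CellRecord,
    image=None,
    channel: str = "cyto",
    step_px: float = 1.0,
    threshold_fraction: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Sub-pixel cell width at each axial position.

    The width is the distance between the two outline crossings along the
    perpendicular through each axis point, found by linear interpolation
    scanning outward from the axis.  When ``image`` is given the outline
    is the ``threshold_fraction`` level (of the bright-cell intensity,
    background-subtracted) on the smooth intensity surface — the same
    convention the segmentation uses — which avoids the sub-pixel
    quantization of a binary mask edge.  Without an image the 0.5 level of
    the interpolated mask is used.
    """
    if record.axis_px is None:
        extract_axis(record)
    px = record.pixel_size
    arc = record.arc_s / px
    n = max(int(np.floor(arc[-1] / step_px)) + 1, 2)
    s_px = np.linspace(0.0, arc[-1], n)
    axis = np.stack(
        [np.interp(s_px, arc, record.axis_px[:, k]) for k in range(2)], axis=1
    )
    perp = _perpendiculars(axis)
    edt = ndi.distance_transform_edt(record.mask)
    reach = float(edt.max()) * 2.2 + 2.0
    step = 0.2
    offsets = np.arange(0.0, reach + 1e-9, step)
    if image is not None:
        img = _as_array(image, channel)
        bg = estimate_background(image, channel, record.mask)
        surface = img - bg
        level = threshold_fraction * (
            float(np.percentile(surface[record.mask], 90.0))
        )
    else:
        surface = record.mask.astype(float)
        level = 0.5
    width = np.zeros(n)
    for sign in (1.0, -1.0):
        pts = axis[:, None, :] + sign * offsets[None, :, None] * perp[:, None, :]
        flat = pts.reshape(-1, 2).T
        vals = map_coordinates(
            surface, flat, order=1, mode="constant"
        ).reshape(n, len(offsets))
        for i in range(n):
            row = vals[i]
            below = np.flatnonzero(row < level)
            if below.size == 0 or below[0] == 0:
                continue
            j = below[0]
            frac = (row[j - 1] - level) / (row[j - 1] - row[j])
            width[i] += (offsets[j - 1] + frac * step)
    return s_px * px, width * px


# ---------------------------------------------------------------------------
# constriction
# ---------------------------------------------------------------------------

def detect_constriction(
    record: CellRecord,
    min_depth: float = 0.15,
    smooth_window: int = 3,
    image=None,
) -> Optional[Constriction]:
    """Deepest sufficiently pronounced local minimum of the width profile.

    The waist position is reported from pole *a*; :attr:`Constriction.from_poles`
    gives the two symmetric per-pole distances.  Pole caps (within one cell
    radius plus a small guard of each end) are excluded.  Returns ``None``
    when no candidate reaches ``min_depth``.
    """
    s, w = width_profile(record, image=image)
    if len(s) < 7:
        return None
    if smooth_window >= 3:
        k = np.ones(smooth_window) / smooth_window
        w = np.convolve(
            np.pad(w, smooth_window // 2, mode="edge"), k, mode="valid"
        )
    radius = w.max() / 2.0
    guard = radius + 0.05  # just past the cap; a waist can sit near a pole
    interior = (s > guard) & (s < s[-1] - guard)
    if interior.sum() < 3:
        return None
    idx = np.flatnonzero(interior)
    best: Optional[Constriction] = None
    for i in idx:
        if i == 0 or i == len(w) - 1:
            continue
        if not (w[i] <= w[i - 1] and w[i] <= w[i + 1]):
            continue
        # depth against the higher flank, so a waist close to one pole
        # (a minicelling constriction) is still scored against the body
        left_max = w[idx[0]: i + 1].max()
        right_max = w[i: idx[-1] + 1].max()
        flank = max(left_max, right_max)
        if flank <= 0:
            continue
        depth = 1.0 - w[i] / flank
        if depth >= min_depth and (best is None or depth > best.depth):
            best = Constriction(
                s=float(s[i]),
                depth=float(depth),
                width_at_waist=float(w[i]),
                length=record.length,
            )
    if best is not None:
        best.s = _refine_waist(s, w, best.s)
    return best


def _refine_waist(
    s: np.ndarray, w: np.ndarray, s0: float, window: float = 0.6
) -> float:
    """Sub-sample waist center: symmetric Gaussian-notch fit around s0.

    The raw argmin of the width profile is pulled sideways when the two
    flanking bodies differ in size (the heavier flank fills the waist
    asymmetrically under blur); fitting a symmetric notch re-centers it.
    """
    from scipy.optimize import curve_fit

    sel = np.abs(s - s0) <= window
    if sel.sum() < 6:
        return s0
    xs, ys = s[sel], w[sel]

    def notch(x, a, b, c, sig):
        return a - b * np.exp(-((x - c) ** 2) / (2 * sig**2))

    try:
        popt, _ = curve_fit(
            notch,
            xs,
            ys,
            p0=[float(ys.max()), float(ys.max() - ys.min()), s0, 0.25],
            bounds=(
                [0.0, 0.0, xs[0], 0.05],
                [np.inf, np.inf, xs[-1], window],
            ),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return s0
    return float(popt[2])
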