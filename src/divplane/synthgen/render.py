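"""Rendering of synthetic multichannel fluorescence micrographs.

Each cell is a solid of revolution around its (possibly bent) centerline.
Per-channel emitter densities are computed analytically on the pixel grid,
blurred by a Gaussian PSF, scaled to expected counts, Poisson-sampled, and
corrupted with constant background plus Gaussian read noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .types import CellTruth, ConfigError, ScopeConfig

CHANNELS = ("cyto", "dapi", "ring", "matp")

#: Relative brightness of each labelled structure at unit emitter density.
CHANNEL_GAIN = {"cyto": 1.0, "dapi": 1.5, "ring": 1.5, "matp": 2.5}

RING_AXIAL_WIDTH = 0.25     # um FWHM-ish band width of a diffraction-limited ring
MATP_SPOT_SIGMA = 0.08      # um, sub-diffraction focus before PSF blur
NUCLEOID_RADIUS_FRACTION = 0.8


@dataclass
class SyntheticImage:
    """A rendered field: channel images, label mask, and provenance."""

    channels: dict[str, np.ndarray]
    labels: np.ndarray                    # 0 = background, i = truths[i-1]
    origin: tuple[float, float]           # um coordinates of pixel (0, 0) center
    pixel_size: float
    truths: list[CellTruth]
    scope: ScopeConfig
    densities: Optional[dict[str, np.ndarray]] = None  # pre-blur, scaled

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask_of(self, index: int) -> np.ndarray:
        """Boolean ground-truth mask of cell ``index`` (0-based)."""
        return self.labels == index + 1


def _axial_frame(
    truth: CellTruth, xx: np.ndarray, yy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Axial coordinate s in [0, L] and unsigned distance d for each pixel."""
    if truth.curvature == 0.0:
        ca, sa = np.cos(truth.angle), np.sin(truth.angle)
        rx = xx - truth.center[0]
        ry = yy - truth.center[1]
        u = ca * rx + sa * ry
        w = -sa * rx + ca * ry
        return u + truth.length / 2.0, np.abs(w)
    step = 0.02
    line = truth.centerline(step=step)
    tree = cKDTree(line)
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    d, idx = tree.query(pts, workers=1)
    s_line = np.linalg.norm(np.diff(line, axis=0), axis=1)
    s_cum = np.concatenate([[0.0], np.cumsum(s_line)])
    return s_cum[idx].reshape(xx.shape), d.reshape(xx.shape)


def emitter_densities(
    truth: CellTruth, xx: np.ndarray, yy: np.ndarray
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-channel emitter density on the pixel grid, plus the body mask."""
    s, d = _axial_frame(truth, xx, yy)
    h = truth.half_width(s)
    inside = d <= h
    dens = {c: np.zeros_like(xx) for c in CHANNELS}

    chord = np.zeros_like(xx)
    chord[inside] = 2.0 * np.sqrt(h[inside] ** 2 - d[inside] ** 2)
    dens["cyto"] = chord

    r_n = NUCLEOID_RADIUS_FRACTION * truth.radius
    in_n = d <= r_n
    chord_n = np.zeros_like(xx)
    chord_n[in_n] = 2.0 * np.sqrt(r_n**2 - d[in_n] ** 2) / (2.0 * r_n)
    mid = truth.length / 2.0
    for c0, mode in zip(truth.nucleoid_centers, truth.nucleoid_modes):
        sig = truth.nucleoid_sigma
        if mode == "bilobed":
            sep = truth.lobe_separation
            ax = np.exp(-((s - (mid + c0 - sep / 2)) ** 2) / (2 * sig**2))
            ax += np.exp(-((s - (mid + c0 + sep / 2)) ** 2) / (2 * sig**2))
        else:
            ax = np.exp(-((s - (mid + c0)) ** 2) / (2 * sig**2))
        dens["dapi"] += ax * chord_n

    sig_r = RING_AXIAL_WIDTH / 2.355
    for z0, amp in zip(truth.ring_offsets, truth.ring_amplitudes):
        ax = amp * np.exp(-((s - (mid + z0)) ** 2) / (2 * sig_r**2))
        dens["ring"] += ax * chord / (2.0 * truth.radius)

    for m0 in truth.matp_offsets:
        dens["matp"] += np.exp(
            -((s - (mid + m0)) ** 2 + d**2) / (2 * MATP_SPOT_SIGMA**2)
        )
    return dens, inside


def _canvas_geometry(
    truths: Sequence[CellTruth], scope: ScopeConfig
) -> tuple[tuple[int, int], tuple[float, float]]:
    pts = np.concatenate([t.centerline(step=0.1) for t in truths], axis=0)
    margin = max(4.0 * scope.psf_sigma, 0.3) + max(t.radius for t in truths)
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    n_cols = int(np.ceil((hi[0] - lo[0]) / scope.pixel_size)) + 1
    n_rows = int(np.ceil((hi[1] - lo[1]) / scope.pixel_size)) + 1
    return (n_rows, n_cols), (float(lo[0]), float(lo[1]))


def render_field(
    truths: Sequence[CellTruth],
    scope: ScopeConfig,
    rng: Optional[np.random.Generator] = None,
    noise: bool = True,
    canvas: Optional[tuple[tuple[int, int], tuple[float, float]]] = None,
    keep_density: bool = False,
) -> SyntheticImage:
    """Render one or more cells onto a shared canvas.

    ``canvas`` may fix ``(shape, origin)`` explicitly (used for time-lapse
    stacks); otherwise the canvas bounds all cells plus a 4-sigma PSF margin
    so that blur leaks a negligible fraction of photons off the image.
    """
    truths = list(truths)
    if not truths:
        raise ConfigError("render_field needs at least one cell")
    if canvas is None:
        shape, origin = _canvas_geometry(truths, scope)
    else:
        shape, origin = canvas
    cols = origin[0] + np.arange(shape[1]) * scope.pixel_size
    rows = origin[1] + np.arange(shape[0]) * scope.pixel_size
    xx, yy = np.meshgrid(cols, rows)

    total = {c: np.zeros(shape) for c in CHANNELS}
    labels = np.zeros(shape, dtype=np.int32)
    for i, truth in enumerate(truths):
        dens, inside = emitter_densities(truth, xx, yy)
        if inside.any() and (
            inside[0].any() or inside[-1].any()
            or inside[:, 0].any() or inside[:, -1].any()
        ):
            raise ConfigError("cell overflows the canvas; enlarge it")
        for c in CHANNELS:
            total[c] += dens[c] * CHANNEL_GAIN[c]
        labels[inside & (labels == 0)] = i + 1

    sigma_px = scope.psf_sigma / scope.pixel_size
    if rng is None:
        rng = np.random.default_rng(scope.rng_seed)
    channels: dict[str, np.ndarray] = {}
    for c in CHANNELS:
        expected = (
            gaussian_filter(total[c], sigma_px, mode="constant")
            * scope.photon_scale
        )
        if noise:
            img = rng.poisson(expected).astype(float)
            img += rng.normal(0.0, scope.read_noise_sd, size=shape)
            img += scope.background
        else:
            img = expected + scope.background
        channels[c] = img

    # pseudo phase contrast: inverted, blurred body mask
    phase = 1.0 - gaussian_filter(
        (labels > 0).astype(float), sigma_px, mode="constant"
    )
    channels["phase"] = phase * 100.0

    return SyntheticImage(
        channels=channels,
        labels=labels,
        origin=origin,
        pixel_size=scope.pixel_size,
        truths=truths,
        scope=scope,
        densities=(
            {c: total[c] * scope.photon_scale for c in CHANNELS}
            if keep_density
            else None
        ),
    )


def render_cell(
    truth: CellTruth,
    scope: ScopeConfig,
    rng: Optional[np.random.Generator] = None,
    noise: bool = True,
    keep_density: bool = False,
) -> SyntheticImage:
    """Render a single cell on its own canvas."""
    return render_field(
        [truth], scope, rng=rng, noise=noise, keep_density=keep_density
    )


def arrange_in_rows(
    truths: Sequence[CellTruth],
    spacing: float = 2.0,
    per_row: int = 5,
) -> list[CellTruth]:
    """Lay out cells on a grid so they render well-separated in one field."""
    from dataclasses import replace

    out = []
    max_len = max(t.length for t in truths)
    for i, t in enumerate(truths):
        r, c = divmod(i, per_row)
        out.append(replace(t, center=(c * (max_len + spacing), r * spacing)))
    return out
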