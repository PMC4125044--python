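"""Ground-truth containers for the synthetic microscopy generator.

All lengths are micrometres unless a field name says otherwise; placement
precisions (``sigma_*``) follow the field convention of quoting localization
spreads in nanometres.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

NM_PER_UM = 1000.0

#: Canonical division sites used throughout: quarter, third, half, two-thirds,
#: three-quarters of the mother length.
DIVISION_SITES = (0.25, 1.0 / 3.0, 0.5, 2.0 / 3.0, 0.75)


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class ScopeConfig:
    """Virtual widefield microscope.

    Defaults emulate a 100x objective with 16 um camera pixels
    (0.16 um/px), a diffraction-limited Gaussian PSF, and an EMCCD-like
    counts budget chosen so that single-structure localization error stays
    well below the smallest placement spread the analysis must resolve
    (~40 nm).
    """

    pixel_size: float = 0.16       # um per pixel
    psf_sigma: float = 0.10        # um
    photon_scale: float = 600.0    # expected counts at unit emitter density
    read_noise_sd: float = 2.0     # counts
    background: float = 10.0       # counts
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be > 0")
        if self.psf_sigma < 0:
            raise ConfigError("psf_sigma must be >= 0")
        if self.photon_scale < 0:
            raise ConfigError("photon_scale must be >= 0")
        if self.read_noise_sd < 0:
            raise ConfigError("read_noise_sd must be >= 0")


@dataclass
class CellTruth:
    """Geometry and marker placement for one synthetic cell.

    The cell body is a spherocylinder of half-width ``radius`` whose
    centerline may be gently bent (constant ``curvature``, 1/um).  Axial
    offsets are measured from the cell center, positive toward pole *b*.
    """

    length: float
    radius: float = 0.45
    center: tuple[float, float] = (0.0, 0.0)   # (x, y) in um
    angle: float = 0.0                         # orientation, radians
    curvature: float = 0.0                     # 1/um, 0 = straight rod
    nucleoid_centers: list[float] = field(default_factory=list)
    nucleoid_modes: list[str] = field(default_factory=list)   # compact|bilobed
    nucleoid_sigma: float = 0.45               # axial sigma of one blob (um)
    lobe_separation: float = 0.9               # center-to-center, bilobed (um)
    ring_offsets: list[float] = field(default_factory=list)
    ring_amplitudes: list[float] = field(default_factory=list)  # default 1.0
    matp_offsets: list[float] = field(default_factory=list)
    division_fraction: Optional[float] = None  # v of an adhered daughter pair
    waist_depth: float = 0.0                   # relative depth of constriction
    waist_sigma: float = 0.25                  # axial width of constriction (um)

    def __post_init__(self) -> None:
        if self.length < 2.0 * self.radius:
            raise ConfigError(
                f"cell length {self.length} shorter than its diameter"
            )
        if not self.nucleoid_modes:
            self.nucleoid_modes = ["compact"] * len(self.nucleoid_centers)
        if not self.ring_amplitudes:
            self.ring_amplitudes = [1.0] * len(self.ring_offsets)
        if len(self.ring_amplitudes) != len(self.ring_offsets):
            raise ConfigError("one ring_amplitude per ring_offset required")
        if len(self.nucleoid_modes) != len(self.nucleoid_centers):
            raise ConfigError("one nucleoid_mode per nucleoid_center required")
        half = self.length / 2.0
        for name in ("nucleoid_centers", "ring_offsets", "matp_offsets"):
            for x in getattr(self, name):
                if abs(x) > half:
                    raise ConfigError(f"{name} offset {x} outside [-L/2, L/2]")
        if self.division_fraction is not None and not (
            0.0 < self.division_fraction < 1.0
        ):
            raise ConfigError("division_fraction must lie in (0, 1)")
        if not (0.0 <= self.waist_depth < 1.0):
            raise ConfigError("waist_depth must lie in [0, 1)")

    # -- centerline geometry -------------------------------------------------

    def centerline(self, step: float = 0.02) -> np.ndarray:
        """Sampled centerline as an (N, 2) array of (x, y) in um.

        For ``curvature != 0`` the centerline is a circular arc of the given
        arc length; the chord midpoint sits at ``center``.
        """
        n = max(int(np.ceil(self.length / step)) + 1, 2)
        s = np.linspace(-self.length / 2.0, self.length / 2.0, n)
        if self.curvature == 0.0:
            x = s
            y = np.zeros_like(s)
        else:
            r = 1.0 / self.curvature
            phi = s / r
            x = r * np.sin(phi)
            y = r * (1.0 - np.cos(phi))
            y -= y.min() + (y.max() - y.min()) / 2.0
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        pts = np.stack([ca * x - sa * y, sa * x + ca * y], axis=1)
        pts += np.asarray(self.center)
        return pts

    @property
    def pole_a(self) -> np.ndarray:
        return self.centerline()[0]

    @property
    def pole_b(self) -> np.ndarray:
        return self.centerline()[-1]

    # -- solid-of-revolution half-width profile ------------------------------

    def half_width(self, s: np.ndarray) -> np.ndarray:
        """Half-width of the body at axial coordinate ``s`` in [0, L].

        Spherocylinder caps, optionally multiplied by a Gaussian waist notch
        (the constriction of an adhered daughter pair).
        """
        s = np.asarray(s, dtype=float)
        r = self.radius
        h = np.full_like(s, r)
        cap_a = s < r
        cap_b = s > self.length - r
        h[cap_a] = np.sqrt(np.clip(r**2 - (r - s[cap_a]) ** 2, 0.0, None))
        h[cap_b] = np.sqrt(
            np.clip(r**2 - (s[cap_b] - (self.length - r)) ** 2, 0.0, None)
        )
        h[(s < 0) | (s > self.length)] = 0.0
        if self.waist_depth > 0.0 and self.division_fraction is not None:
            s_c = self.constriction_position()
            h = h * (
                1.0
                - self.waist_depth
                * np.exp(-((s - s_c) ** 2) / (2.0 * self.waist_sigma**2))
            )
        return h

    def _volume_cumulative(self, s_grid: np.ndarray) -> np.ndarray:
        """Cumulative solid-of-revolution volume pi * int h(s)^2 ds."""
        h = self.half_width(s_grid)
        dv = np.pi * h**2
        return np.concatenate(
            [[0.0], np.cumsum((dv[1:] + dv[:-1]) / 2.0 * np.diff(s_grid))]
        )

    def constriction_position(self, n_grid: int = 4096) -> float:
        """Axial position of the waist for a pair dividing at ``v``.

        Chosen so that the volume on the pole-*a* side of the waist is the
        fraction ``division_fraction`` of the *unconstricted* body volume;
        the notch itself is volume-symmetric to first order, so the rendered
        pair's daughter volumes match ``v`` closely.
        """
        if self.division_fraction is None:
            raise ConfigError("constriction_position needs division_fraction")
        s_grid = np.linspace(0.0, self.length, n_grid)
        # unconstricted profile: temporarily ignore the notch
        depth, self.waist_depth = self.waist_depth, 0.0
        try:
            cum = self._volume_cumulative(s_grid)
        finally:
            self.waist_depth = depth
        target = self.division_fraction * cum[-1]
        return float(np.interp(target, cum, s_grid))

    def daughter_volumes(self, n_grid: int = 8192) -> tuple[float, float]:
        """Analytic daughter volumes of the constricted body, split at the waist."""
        s_c = self.constriction_position()
        s_grid = np.linspace(0.0, self.length, n_grid)
        cum = self._volume_cumulative(s_grid)
        v_a = float(np.interp(s_c, s_grid, cum))
        return v_a, float(cum[-1] - v_a)


@dataclass
class PlacementModel:
    """Statistical model of nucleoid, Z-ring, MatP and division-site placement.

    Defaults reproduce the slow-growing minC/slmA double-deletion regime:
    nucleoid centers scatter about the cell center with ~150 nm SD, the ring
    tracks the nucleoid center to ~45 nm, the Ter focus tracks the ring to
    ~56 nm, and division sites concentrate at 1/2 (75%) and 1/4, 3/4
    (6.5% each) with the remainder spread elsewhere.
    """

    sigma_ring_given_nucleoid: float = 45.0    # nm
    sigma_nucleoid: float = 150.0              # nm
    sigma_matp: float = 56.0                   # nm
    p_polar_ring: float = 0.05
    polar_zone: tuple[float, float] = (0.33, 0.45)  # |offset|/L range
    mixture_weights: dict[float, float] = field(
        default_factory=lambda: {0.5: 0.75, 0.25: 0.065, 0.75: 0.065}
    )
    mixture_sd: float = 0.02
    transition_length: Optional[float] = None  # um; long cells -> 1/4 sites

    def __post_init__(self) -> None:
        for name in ("sigma_ring_given_nucleoid", "sigma_nucleoid",
                     "sigma_matp", "mixture_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.p_polar_ring <= 1.0):
            raise ConfigError("p_polar_ring must lie in [0, 1]")
        w = np.array(list(self.mixture_weights.values()), dtype=float)
        if np.any(w < 0):
            raise ConfigError("mixture weights must be nonnegative")
        if w.sum() > 1.0 + 1e-9:
            raise ConfigError("mixture weights must sum to <= 1")
        for c in self.mixture_weights:
            if not (0.0 < c < 1.0):
                raise ConfigError("mixture centers must lie in (0, 1)")

    @property
    def uniform_weight(self) -> float:
        """Mass assigned to 'other' (uniformly placed) divisions."""
        return 1.0 - float(sum(self.mixture_weights.values()))


@dataclass(frozen=True)
class TimelapseTruth:
    """Event timing for one synthetic cell cycle.

    Times are in frames; ``frame_interval`` (minutes) converts to wall time.
    ``t_matp`` and ``t_z`` are defined as the half-rise times of the
    noise-free midcell signal of the respective channel.
    """

    t_d: float                    # doubling time, frames
    t_matp: float                 # Ter-focus midcell arrival, frames
    t_z: float                    # ring assembly onset at midcell, frames
    frame_interval: float = 2.5   # minutes per frame

    def __post_init__(self) -> None:
        if self.t_d <= 0:
            raise ConfigError("t_d must be > 0")
        for name in ("t_matp", "t_z"):
            t = getattr(self, name)
            if not (0.0 <= t <= self.t_d):
                raise ConfigError(f"{name} must lie in [0, t_d]")

    @property
    def lag(self) -> float:
        """Generative ring-after-Ter lag in doubling-time units."""
        return (self.t_z - self.t_matp) / self.t_d


def bilobed_separation_for_depth(depth: float, sigma: float) -> float:
    """Lobe separation giving a stated relative central dip depth.

    For two equal Gaussian lobes of width ``sigma`` separated by ``d`` the
    axial profile has a central minimum; this returns the ``d`` at which
    ``1 - I(mid)/I(peak)`` equals ``depth``.  Inverted numerically on a
    monotone grid.
    """
    if not (0.0 <= depth < 1.0):
        raise ConfigError("depth must lie in [0, 1)")
    if depth == 0.0:
        return 2.0 * sigma  # shallowest dip-free doublet
    return sigma * float(np.interp(depth, *_DOUBLET_DEPTH_TABLE()))


_doublet_table_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def _DOUBLET_DEPTH_TABLE() -> tuple[np.ndarray, np.ndarray]:
    """Monotone (depth, separation/sigma) lookup for the doublet dip."""
    if "table" not in _doublet_table_cache:
        seps = np.linspace(2.0, 8.0, 601)          # separation in sigma units
        x = np.linspace(-6.0, 6.0, 1201)
        prof = (
            np.exp(-((x[None, :] - seps[:, None] / 2) ** 2) / 2.0)
            + np.exp(-((x[None, :] + seps[:, None] / 2) ** 2) / 2.0)
        )
        depths = 1.0 - prof[:, 600] / prof.max(axis=1)
        _doublet_table_cache["table"] = (depths, seps)
    return _doublet_table_cache["table"]
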