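"""Synthetic time-lapse stacks: Ter-focus relocation and ring assembly onset.

The generative timing convention: ``t_matp`` and ``t_z`` of a
:class:`~divplane.synthgen.types.TimelapseTruth` are the half-rise times of
the *noise-free* midcell signal of the matp and ring channels.  The MatP
focus physically travels from the old pole to midcell; its trajectory is
constructed by inverting the midcell-window response so that the window
signal follows a logistic with half-rise exactly at ``t_matp``.  The ring
appears at midcell with a logistic amplitude whose half-rise is ``t_z``.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr

from .render import MATP_SPOT_SIGMA, SyntheticImage, _canvas_geometry, render_field
from .types import CellTruth, ConfigError, ScopeConfig, TimelapseTruth

RING_BASELINE = 0.05     # diffuse unassembled ring-protein signal
ONSET_TAU_FRACTION = 0.02  # logistic time constant, in units of T_d


@dataclass
class TimelapseStack:
    """A rendered cell cycle: per-frame fields plus the generative timing."""

    frames: list[SyntheticImage]
    truths: list[CellTruth]
    timing: TimelapseTruth
    midcell_halfwidth: float = 0.05  # fraction of L

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def channel_stack(self, channel: str) -> np.ndarray:
        return np.stack([f.channels[channel] for f in self.frames])


def _logistic(t: np.ndarray | float, t0: float, tau: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(np.asarray(t, dtype=float) - t0) / tau))


def _window_response(x: np.ndarray, w: float, sigma_eff: float) -> np.ndarray:
    """Midcell-window integral of a focus image centered at offset x."""
    return ndtr((w - x) / sigma_eff) - ndtr((-w - x) / sigma_eff)


def _focus_position(
    target_frac: float, half_window: float, sigma_eff: float, x_min: float
) -> float:
    """Invert the window response: offset (<= 0) giving the target fraction."""
    if target_frac >= 0.999:
        return 0.0
    grid = np.linspace(x_min, 0.0, 400)
    resp = _window_response(grid, half_window, sigma_eff)
    resp /= resp[-1]
    if target_frac <= resp[0]:
        return float(x_min)
    return float(np.interp(target_frac, resp, grid))


def make_cycle_truths(
    timing: TimelapseTruth,
    scope: ScopeConfig,
    birth_length: float = 2.4,
    radius: float = 0.45,
    midcell_halfwidth: float = 0.05,
    onset_tau: Optional[float] = None,
) -> list[CellTruth]:
    """Per-frame ground truth for one exponentially growing cell cycle."""
    n = int(np.floor(timing.t_d)) + 1
    tau = onset_tau if onset_tau is not None else ONSET_TAU_FRACTION * timing.t_d
    sigma_eff = float(np.hypot(MATP_SPOT_SIGMA, scope.psf_sigma))
    truths: list[CellTruth] = []
    for t in range(n):
        length = birth_length * 2.0 ** (t / timing.t_d)
        # mirror the analysis convention: fractional window, capped at a
        # structure-sized absolute half-width
        half_window = min(midcell_halfwidth * length, 0.15)
        x_min = -(length / 2.0 - radius)
        target = float(_logistic(t, timing.t_matp, tau))
        x_f = _focus_position(target, half_window, sigma_eff, x_min)
        ring_amp = RING_BASELINE + (1.0 - RING_BASELINE) * float(
            _logistic(t, timing.t_z, tau)
        )
        truths.append(
            CellTruth(
                length=length,
                radius=radius,
                nucleoid_centers=[0.0],
                nucleoid_sigma=0.35 + 0.05 * length,
                ring_offsets=[0.0],
                ring_amplitudes=[ring_amp],
                matp_offsets=[x_f],
            )
        )
    return truths


def render_timelapse(
    truths: Sequence[CellTruth],
    timing: TimelapseTruth,
    scope: ScopeConfig,
    rng: Optional[np.random.Generator] = None,
    noise: bool = True,
    midcell_halfwidth: float = 0.05,
) -> TimelapseStack:
    """Render a frame sequence on a common canvas sized for the final frame.

    The length sequence must be non-decreasing (a single growing cell).
    """
    truths = list(truths)
    lengths = np.array([t.length for t in truths])
    if np.any(np.diff(lengths) < -1e-9):
        raise ConfigError("cell length sequence must be non-decreasing")
    if rng is None:
        rng = np.random.default_rng(scope.rng_seed)
    canvas = _canvas_geometry([truths[-1]], scope)
    frames = [
        render_field([t], scope, rng=rng, noise=noise, canvas=canvas)
        for t in truths
    ]
    return TimelapseStack(
        frames=frames,
        truths=truths,
        timing=timing,
        midcell_halfwidth=midcell_halfwidth,
    )


def simulate_cell_cycle(
    timing: TimelapseTruth,
    scope: ScopeConfig,
    rng: Optional[np.random.Generator] = None,
    noise: bool = True,
    birth_length: float = 2.4,
    midcell_halfwidth: float = 0.05,
) -> TimelapseStack:
    """Convenience: build per-frame truths and render the full cycle."""
    truths = make_cycle_truths(
        timing,
        scope,
        birth_length=birth_length,
        midcell_halfwidth=midcell_halfwidth,
    )
    return render_timelapse(
        truths,
        timing,
        scope,
        rng=rng,
        noise=noise,
        midcell_halfwidth=midcell_halfwidth,
    )
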