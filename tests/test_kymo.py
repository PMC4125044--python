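"""Kymograph construction, arrival detection, lag and accumulation curves."""
import numpy as np
import pytest

from divplane import kymo
from divplane.synthgen import (
    CellTruth,
    ScopeConfig,
    TimelapseTruth,
    render_field,
    simulate_cell_cycle,
)
from divplane.synthgen.render import _canvas_geometry


def _cycle_kymo(scope, timing, seed=0, noise=True, normalized=False):
    stack = simulate_cell_cycle(
        timing, scope, rng=np.random.default_rng(seed), noise=noise
    )
    frames = [f.channels for f in stack.frames]
    profs, truncated = kymo.profiles_over_time(frames, scope.pixel_size)
    return kymo.build_kymograph(
        profs, t_d=timing.t_d, truncated=truncated, normalized=normalized
    )


def test_static_cell_gives_identical_rows_within_noise(scope):
    truth = CellTruth(length=4.0, ring_offsets=[0.0], matp_offsets=[0.0],
                      nucleoid_centers=[0.0])
    canvas = _canvas_geometry([truth], scope)
    rng = np.random.default_rng(0)
    frames = [
        render_field([truth], scope, rng=rng, canvas=canvas).channels
        for _ in range(10)
    ]
    profs, truncated = kymo.profiles_over_time(frames, scope.pixel_size)
    k = kymo.build_kymograph(profs, t_d=10, truncated=truncated)
    ring = k.data["ring"]
    has_data = np.isfinite(ring).all(axis=0)
    col_sd = ring[:, has_data].std(axis=0)
    peak = ring[:, has_data].mean(axis=0).max()
    assert col_sd.max() < 0.1 * peak


def test_moving_ring_trajectory_tracked(scope):
    canvas_truth = CellTruth(length=5.0, ring_offsets=[0.0])
    canvas = _canvas_geometry([canvas_truth], scope)
    offsets = np.linspace(-1.8, 0.0, 12)
    rng = np.random.default_rng(1)
    frames = []
    for off in offsets:
        t = CellTruth(length=5.0, ring_offsets=[float(off)],
                      nucleoid_centers=[0.0])
        frames.append(render_field([t], scope, rng=rng, canvas=canvas).channels)
    profs, truncated = kymo.profiles_over_time(frames, scope.pixel_size)
    k = kymo.build_kymograph(profs, t_d=12, truncated=truncated)
    dx = k.x[1] - k.x[0]
    for i, off in enumerate(offsets):
        row = k.data["ring"][i]
        x_peak = k.x[np.nanargmax(row)]
        assert abs(x_peak - off) <= scope.pixel_size + dx


def test_normalized_mode_keeps_relative_position_constant(scope):
    timing = TimelapseTruth(t_d=30, t_matp=2, t_z=2)
    k = _cycle_kymo(scope, timing, seed=2, noise=False, normalized=True)
    for row in k.data["ring"][5:]:
        w = np.nan_to_num(row)
        centroid = (k.x * w).sum() / w.sum()
        assert abs(centroid) < 0.02  # ring stays at x/L = 0 while L doubles


def test_kymograph_conserves_profile_mass(scope):
    timing = TimelapseTruth(t_d=20, t_matp=5, t_z=8)
    stack = simulate_cell_cycle(
        timing, scope, rng=np.random.default_rng(3), noise=False
    )
    frames = [f.channels for f in stack.frames]
    profs, truncated = kymo.profiles_over_time(frames, scope.pixel_size)
    k = kymo.build_kymograph(profs, t_d=timing.t_d, truncated=truncated)
    dx = k.x[1] - k.x[0]
    for i, p in enumerate(profs):
        ds = np.gradient(p.s)
        target = (p.intensity["ring"] * ds).sum()
        got = np.nansum(k.data["ring"][i]) * dx
        assert got == pytest.approx(target, rel=0.02)


def test_sharp_onset_detected_within_one_frame(scope):
    timing = TimelapseTruth(t_d=48, t_matp=9.6, t_z=15.36)
    k = _cycle_kymo(scope, timing, seed=4, noise=False)
    t_z = kymo.arrival_time(k, "ring")
    assert t_z == pytest.approx(timing.t_z, abs=1.0)


def test_constant_zero_channel_has_no_arrival(scope):
    timing = TimelapseTruth(t_d=20, t_matp=5, t_z=8)
    k = _cycle_kymo(scope, timing, seed=5, noise=False)
    k.data["ring"] = np.zeros_like(k.data["ring"])
    assert kymo.arrival_time(k, "ring") is None


def test_arrival_time_monotone_in_theta(scope):
    timing = TimelapseTruth(t_d=48, t_matp=9.6, t_z=15.36)
    k = _cycle_kymo(scope, timing, seed=6, noise=False)
    times = [
        kymo.arrival_time(k, "ring", theta=th)
        for th in (0.3, 0.4, 0.5, 0.6, 0.7)
    ]
    assert all(t is not None for t in times)
    assert all(b >= a for a, b in zip(times, times[1:]))
    # sensitivity: theta sweep moves the estimate by < 0.05 T_d
    assert times[-1] - times[0] < 0.05 * timing.t_d


def test_identical_channels_give_zero_lag(scope):
    timing = TimelapseTruth(t_d=30, t_matp=8, t_z=12)
    k = _cycle_kymo(scope, timing, seed=7)
    k.data["matp"] = k.data["ring"].copy()
    rec = kymo.arrival_record(k)
    assert rec is not None
    assert rec.lag == pytest.approx(0.0, abs=1e-12)


def test_lag_summary_statistics(scope):
    timing = TimelapseTruth(t_d=30, t_matp=6, t_z=9.6)
    recs = []
    for seed in range(10):
        k = _cycle_kymo(scope, timing, seed=20 + seed)
        r = kymo.arrival_record(k)
        assert r is not None
        recs.append(r)
    lag = kymo.arrival_lag(recs, min_cells=10)
    assert lag.n == 10
    assert lag.mean == pytest.approx(0.12, abs=0.03)
    assert lag.counts.sum() == 10


def test_lag_invariant_under_frame_interval(scope):
    """Lag in doubling-time units does not depend on temporal sampling."""
    means = []
    for t_d in (30, 60):
        timing = TimelapseTruth(t_d=t_d, t_matp=0.2 * t_d, t_z=0.32 * t_d)
        lags = [
            kymo.arrival_record(_cycle_kymo(scope, timing, seed=40 + s)).lag
            for s in range(5)
        ]
        means.append(np.mean(lags))
    assert means[0] == pytest.approx(means[1], abs=0.02)


def test_accumulation_identical_cells_zero_se(scope):
    timing = TimelapseTruth(t_d=24, t_matp=5, t_z=8)
    k = _cycle_kymo(scope, timing, seed=8, noise=False)
    curves = kymo.accumulation_curves([k, k, k], channels=("ring",))
    se = curves["se"].dropna()
    assert (se < 1e-12).all()


def test_matp_precedes_ring_in_accumulation(scope):
    timing = TimelapseTruth(t_d=36, t_matp=7.2, t_z=11.5)
    kyms = [_cycle_kymo(scope, timing, seed=60 + s) for s in range(5)]
    curves = kymo.accumulation_curves(kyms, channels=("matp", "ring"))

    def first_half_crossing(channel):
        sub = curves[curves["channel"] == channel].sort_values("t_over_td")
        above = sub[sub["mean"] >= 0.5]
        return above["t_over_td"].iloc[0]

    assert first_half_crossing("matp") < first_half_crossing("ring")


def test_accumulation_se_shrinks_with_cells(scope):
    timing = TimelapseTruth(t_d=24, t_matp=5, t_z=8)
    kyms = [_cycle_kymo(scope, timing, seed=80 + s) for s in range(15)]
    c5 = kymo.accumulation_curves(kyms[:5], channels=("ring",))
    c15 = kymo.accumulation_curves(kyms, channels=("ring",))
    m5 = c5["se"].mean(skipna=True)
    m15 = c15["se"].mean(skipna=True)
    assert m15 < m5


def test_lag_requires_minimum_cells(scope):
    with pytest.raises(ValueError):
        kymo.arrival_lag([], min_cells=10)
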