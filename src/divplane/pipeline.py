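"""End-to-end driver: generate -> segment -> localize -> statistics.

Three modes mirror the three kinds of experiment the analysis supports:

``stills``
    a population of single-cell snapshots plus a multi-nucleoid batch;
    produces per-cell geometry and localization tables, co-localization
    summaries per subset, and the N/O site-occupancy table.
``divisions``
    adhered daughter pairs; produces the division-event table, the
    fixed-center mixture fit, and division frequency vs mother length.
``timelapse``
    growing cells over one cell cycle each; produces kymographs, arrival
    times, the lag summary, and midcell accumulation curves.

Every run writes a YAML snapshot of its configuration and a log of
per-cell exclusions; partial per-cell failures are logged, not fatal.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import colocstats, divstats, geometry, io, kymo, localize
from .config import RunConfig
from .synthgen import (
    CellTruth,
    TimelapseTruth,
    render_cell,
    sample_divisions,
    sample_multinucleoid_population,
    sample_population,
    simulate_cell_cycle,
)

logger = logging.getLogger("divplane")

MODES = ("stills", "divisions", "timelapse")


def _setup_logging(out: Path) -> logging.Handler:
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1, allow_nan=True)
        fh.write("\n")


def analyze_still(
    image,
    config: RunConfig,
    cell_id: int = 0,
) -> tuple[list[localize.LocalizationRecord], list[geometry.CellRecord]]:
    """Segment one field and localize every cell in it."""
    records = geometry.segment_cells(
        image,
        channel=config.channels["cyto"],
        constriction_min_depth=config.constriction_min_depth,
    )
    locs: list[localize.LocalizationRecord] = []
    kept: list[geometry.CellRecord] = []
    for j, rec in enumerate(records):
        try:
            if rec.axis_px is None:
                geometry.extract_axis(rec, image=image)
            prof = geometry.line_profiles(
                image, rec, half_width=config.half_width_um
            )
            loc = localize.localize_cell(
                prof,
                cell_id=cell_id + j,
                c_polar=config.c_polar,
                dip_depth_min=config.dip_depth_min,
            )
        except geometry.ShapeError as err:
            logger.info("cell %d excluded: %s", cell_id + j, err)
            continue
        locs.append(loc)
        kept.append(rec)
    return locs, kept


def _run_stills(config: RunConfig, out: Path, rng: np.random.Generator) -> dict:
    model = config.placement_model()
    pop = sample_population(model, config.n_cells, seed=rng)
    n_multi = max(config.n_cells // 3, 30)
    multi = sample_multinucleoid_population(
        n_multi, model=model, seed=rng
    )
    scope = config.scope_config(seed=int(rng.integers(2**31)))
    all_locs: list[localize.LocalizationRecord] = []
    cell_rows = []
    truths = list(pop.cells) + list(multi.cells)
    for i, truth in enumerate(truths):
        img = render_cell(truth, scope, rng=rng)
        locs, recs = analyze_still(img, config, cell_id=i)
        if not locs:
            logger.info("cell %d: segmentation found no usable cell", i)
            continue
        all_locs.extend(locs)
        for rec, loc in zip(recs, locs):
            cell_rows.append(
                {
                    "cell_id": loc.cell_id,
                    "length": rec.length,
                    "pole_a_x": rec.pole_a[0],
                    "pole_a_y": rec.pole_a[1],
                    "pole_b_x": rec.pole_b[0],
                    "pole_b_y": rec.pole_b[1],
                }
            )
    io.write_csv(io.truth_table(truths), out / "truth.csv")
    io.write_csv(pd.DataFrame(cell_rows), out / "cells.csv")
    loc_df = colocstats.records_to_frame(all_locs)
    io.write_csv(loc_df, out / "localizations.csv")
    summaries = {
        subset: vars(colocstats.coloc_summary(all_locs, subset=subset))
        for subset in ("all", "compact", "central")
    }
    _write_json(summaries, out / "coloc_summary.json")
    occ = colocstats.site_occupancy(
        all_locs, tolerance=config.occupancy_tolerance
    )
    io.write_csv(occ.as_frame(), out / "occupancy.csv")
    return {"localizations": all_locs, "summaries": summaries, "occupancy": occ}


def _run_divisions(
    config: RunConfig, out: Path, rng: np.random.Generator
) -> dict:
    model = config.placement_model()
    events_truth = sample_divisions(model, config.n_divisions, seed=rng)
    scope = config.scope_config(seed=int(rng.integers(2**31)))
    measured = []
    for i, ev in enumerate(events_truth):
        truth = CellTruth(
            length=ev.mother_length,
            division_fraction=ev.v,
            waist_depth=0.45,
            nucleoid_centers=[],
        )
        img = render_cell(truth, scope, rng=rng)
        recs = geometry.segment_cells(
            img,
            constriction_min_depth=config.constriction_min_depth,
        )
        if len(recs) != 1:
            logger.info("division %d: expected 1 region, got %d", i, len(recs))
            continue
        rec = recs[0]
        if rec.axis_px is None:
            geometry.extract_axis(rec, image=img)
        prof = geometry.line_profiles(
            img, rec, half_width=config.half_width_um
        )
        est = divstats.volume_fraction(
            rec, image=img, profiles=prof,
            min_depth=config.constriction_min_depth,
        )
        if est is None:
            logger.info("division %d: no constriction detected", i)
            continue
        measured.append(
            {
                "event_id": i,
                "v": est.v,
                "v_intensity": est.v_intensity,
                "v_truth": ev.v,
                "mother_length": rec.length,
                "daughter_a": est.daughter_lengths[0],
                "daughter_b": est.daughter_lengths[1],
                "minicell": est.minicell_flag,
                "class": divstats.classify_division(est.v, config.v_mini),
            }
        )
    df = pd.DataFrame(measured)
    io.write_csv(df, out / "division_events.csv")
    fit = divstats.fit_fixed_peaks(df["v"].to_numpy(), seed=config.seed)
    _write_json(
        {
            "weights": {str(k): v for k, v in fit.weights.items()},
            "uniform_weight": fit.uniform_weight,
            "sigma": {str(k): v for k, v in fit.sigma.items()},
            "loglik": fit.loglik,
            "n": fit.n,
            "converged": fit.converged,
            "window_fractions": fit.window_fractions,
        },
        out / "peak_fit.json",
    )
    ev_objs = [
        divstats.DivisionEvent(v=row["v"], mother_length=row["mother_length"])
        for _, row in df.iterrows()
    ]
    freq = divstats.frequency_vs_length(ev_objs, bin_width=config.length_bin_um)
    io.write_csv(freq, out / "frequency_vs_length.csv")
    from .plots import plot_volume_fractions

    plot_volume_fractions(df["v"], fit, out / "volume_fractions.png")
    return {"events": df, "fit": fit, "frequency": freq}


def _run_timelapse(
    config: RunConfig, out: Path, rng: np.random.Generator
) -> dict:
    timing = TimelapseTruth(
        t_d=config.t_d_frames,
        t_matp=config.t_matp_fraction * config.t_d_frames,
        t_z=(config.t_matp_fraction + config.lag_fraction)
        * config.t_d_frames,
        frame_interval=config.frame_interval_min,
    )
    scope = config.scope_config(seed=int(rng.integers(2**31)))
    arrivals = []
    kymographs = []
    for i in range(config.n_timelapse_cells):
        stack = simulate_cell_cycle(timing, scope, rng=rng)
        frames = [f.channels for f in stack.frames]
        try:
            profs, truncated = kymo.profiles_over_time(
                frames, scope.pixel_size
            )
        except kymo.TrackLostError as err:
            logger.info("timelapse cell %d excluded: %s", i, err)
            continue
        k = kymo.build_kymograph(
            profs, t_d=timing.t_d, truncated=truncated
        )
        kymographs.append(k)
        rec = kymo.arrival_record(
            k, theta=config.arrival_theta, k=config.arrival_k
        )
        if rec is None:
            logger.info("timelapse cell %d: no arrival detected", i)
            continue
        arrivals.append(
            {
                "cell_id": i,
                "t_matp": rec.t_matp,
                "t_z": rec.t_z,
                "t_d": rec.t_d,
                "lag": rec.lag,
            }
        )
        np.savetxt(
            out / f"kymograph_ring_{i:02d}.csv",
            k.data["ring"],
            delimiter=",",
            fmt="%.6g",
        )
    df = pd.DataFrame(arrivals)
    io.write_csv(df, out / "arrivals.csv")
    recs = [
        kymo.ArrivalRecord(r["t_matp"], r["t_z"], r["t_d"])
        for r in arrivals
    ]
    lag = kymo.arrival_lag(recs, bin_width=config.lag_bin, min_cells=2)
    _write_json(
        {
            "mean": lag.mean,
            "sd": lag.sd,
            "n": lag.n,
            "bin_edges": list(lag.bin_edges),
            "counts": [int(c) for c in lag.counts],
        },
        out / "lag.json",
    )
    curves = kymo.accumulation_curves(kymographs)
    io.write_csv(curves, out / "accumulation.csv")
    from .plots import plot_kymograph, plot_lag_histogram

    plot_lag_histogram(lag, out / "lag_histogram.png")
    if kymographs:
        plot_kymograph(kymographs[0], "ring", out / "kymograph_ring.png")
    return {"arrivals": df, "lag": lag, "curves": curves}


def run_pipeline(
    config: RunConfig,
    mode: str,
    out_dir: Optional[str | Path] = None,
    seed: Optional[int] = None,
) -> dict:
    """Run one pipeline mode, writing all outputs under the out directory."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_snapshot.yaml")
    handler = _setup_logging(out)
    try:
        rng = np.random.default_rng(
            seed if seed is not None else config.seed
        )
        if mode == "stills":
            return _run_stills(config, out, rng)
        if mode == "divisions":
            return _run_divisions(config, out, rng)
        return _run_timelapse(config, out, rng)
    finally:
        logger.removeHandler(handler)
        handler.close()
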