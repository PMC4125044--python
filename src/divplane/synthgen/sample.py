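"""Population sampling: cells, division events, and multi-nucleoid layouts."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import (
    DIVISION_SITES,
    NM_PER_UM,
    CellTruth,
    ConfigError,
    PlacementModel,
    bilobed_separation_for_depth,
)


@dataclass
class DivisionEvent:
    """One division: daughter volume fraction plus mother geometry."""

    v: float
    mother_length: float
    daughter_lengths: tuple[float, float] = (np.nan, np.nan)
    minicell_flag: bool = False
    v_intensity: Optional[float] = None  # filled by the intensity estimator

    def __post_init__(self) -> None:
        if not (0.0 < self.v < 1.0):
            raise ConfigError("volume fraction must lie in (0, 1)")


@dataclass
class Population:
    """A sampled cell population with generation metadata."""

    cells: list[CellTruth]
    n_truncated: int = 0
    meta: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.cells)

    def __len__(self) -> int:
        return len(self.cells)


def _length_sampler(spec, rng: np.random.Generator, radius: float):
    """Build a mother/cell length sampler from a distribution spec.

    ``spec`` may be a number (fixed length), a callable ``f(rng) -> float``,
    or a dict like ``{"kind": "normal", "mean": 3.6, "sd": 0.6,
    "min": 2.4, "max": 9.5}``.  Out-of-range draws are rejected and redrawn.
    """
    if callable(spec):
        return spec
    if np.isscalar(spec):
        val = float(spec)
        if val < 2 * radius:
            raise ConfigError("fixed length shorter than cell diameter")
        return lambda _rng: val
    if not isinstance(spec, dict):
        raise ConfigError(f"unrecognized length distribution spec: {spec!r}")
    kind = spec.get("kind", "normal")
    lo = float(spec.get("min", max(2.0 * radius + 0.2, 1.5)))
    hi = float(spec.get("max", 10.0))
    if hi <= lo:
        raise ConfigError("length max must exceed min")

    def draw(rng: np.random.Generator) -> float:
        for _ in range(1000):
            if kind == "normal":
                x = rng.normal(spec.get("mean", 3.6), spec.get("sd", 0.6))
            elif kind == "lognormal":
                x = rng.lognormal(
                    spec.get("mu", np.log(3.5)), spec.get("sigma", 0.25)
                )
            elif kind == "uniform":
                x = rng.uniform(lo, hi)
            else:
                raise ConfigError(f"unknown length distribution kind {kind!r}")
            if lo <= x <= hi:
                return float(x)
        raise ConfigError(
            "length distribution places almost no mass inside [min, max]"
        )

    return draw


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    counter: list[int],
) -> float:
    """Normal draw resampled into [lo, hi]; rejections are counted.

    Resampling (not clipping) avoids piling probability mass on the cell
    boundary, which would mimic spurious polar structures.
    """
    if sd == 0.0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
        counter[0] += 1
    return float(np.clip(mean, lo, hi))


def sample_population(
    model: PlacementModel,
    n: int,
    length_dist=None,
    seed: int | np.random.Generator = 0,
    radius: float = 0.45,
    p_bilobed: float = 0.0,
    bilobed_depth: float = 0.4,
) -> Population:
    """Draw ``n`` single-nucleoid cells with correlated marker placement.

    Nucleoid center ~ N(0, sigma_nucleoid); ring = nucleoid +
    N(0, sigma_ring_given_nucleoid); MatP = ring + N(0, sigma_matp); all
    truncated (by resampling) to the cylindrical interior of the cell.  With
    probability ``p_polar_ring`` an extra ring lands in the polar zone.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    draw_length = _length_sampler(
        length_dist if length_dist is not None else
        {"kind": "normal", "mean": 3.6, "sd": 0.5, "min": 2.6, "max": 6.0},
        rng,
        radius,
    )
    s_n = model.sigma_nucleoid / NM_PER_UM
    s_r = model.sigma_ring_given_nucleoid / NM_PER_UM
    s_m = model.sigma_matp / NM_PER_UM
    trunc = [0]
    cells: list[CellTruth] = []
    for _ in range(n):
        length = draw_length(rng)
        half = length / 2.0 - radius  # keep structures in the cylinder body
        x_n = _truncated_normal(rng, 0.0, s_n, -half, half, trunc)
        x_z = _truncated_normal(rng, x_n, s_r, -half, half, trunc)
        x_m = _truncated_normal(rng, x_z, s_m, -half, half, trunc)
        rings = [x_z]
        if model.p_polar_ring > 0 and rng.random() < model.p_polar_ring:
            zone_lo, zone_hi = model.polar_zone
            pos = rng.uniform(zone_lo * length, zone_hi * length)
            rings.append(float(pos * rng.choice([-1.0, 1.0])))
        mode = "bilobed" if rng.random() < p_bilobed else "compact"
        sigma_blob = 0.45 if mode == "compact" else 0.30
        cells.append(
            CellTruth(
                length=length,
                radius=radius,
                nucleoid_centers=[x_n],
                nucleoid_modes=[mode],
                nucleoid_sigma=sigma_blob,
                lobe_separation=bilobed_separation_for_depth(
                    bilobed_depth, sigma_blob
                ),
                ring_offsets=rings,
                matp_offsets=[x_m],
            )
        )
    return Population(cells=cells, n_truncated=trunc[0])


def sample_divisions(
    model: PlacementModel,
    n: int,
    mother_length_dist=None,
    seed: int | np.random.Generator = 0,
    radius: float = 0.45,
) -> list[DivisionEvent]:
    """Draw ``n`` division events from the fixed-site mixture.

    Each fraction ``v`` comes from a Gaussian around one of the canonical
    sites (weights from the model; leftover mass is uniform "other"), then
    is mirrored v <-> 1-v with probability 1/2 so that, with both daughters
    counted, the sample is symmetric about 1/2 in expectation.  When
    ``model.transition_length`` is set, mothers longer than it draw their
    site from a quarter-dominant mixture, emulating the shift of the
    division plane to 1/4 positions in long cells.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    draw_length = _length_sampler(
        mother_length_dist if mother_length_dist is not None else
        {"kind": "normal", "mean": 4.4, "sd": 1.1, "min": 2.6, "max": 9.5},
        rng,
        radius,
    )
    sites = np.array(list(model.mixture_weights.keys()))
    weights = np.array(list(model.mixture_weights.values()))
    long_sites = np.array([0.25, 0.75])
    long_weights = np.array([0.45, 0.45])
    events: list[DivisionEvent] = []
    for _ in range(n):
        length = draw_length(rng)
        if (
            model.transition_length is not None
            and length > model.transition_length
        ):
            s, w = long_sites, long_weights
        else:
            s, w = sites, weights
        u = rng.random()
        cum = np.cumsum(w)
        if len(s) and u < cum[-1]:
            center = s[int(np.searchsorted(cum, u))]
            for _ in range(1000):
                v = rng.normal(center, model.mixture_sd)
                if 0.02 < v < 0.98:
                    break
        else:
            v = rng.uniform(0.02, 0.98)
        if rng.random() < 0.5:
            v = 1.0 - v
        events.append(
            DivisionEvent(
                v=float(v),
                mother_length=length,
                daughter_lengths=(v * length, (1.0 - v) * length),
                minicell_flag=min(v, 1.0 - v) < 0.10,
            )
        )
    return events


def sample_multinucleoid_population(
    n: int,
    p_ring_n: float = 0.98,
    p_ring_o: float = 0.59,
    n_nucleoids: int = 2,
    model: Optional[PlacementModel] = None,
    length_per_nucleoid: float = 3.2,
    seed: int | np.random.Generator = 0,
    radius: float = 0.45,
) -> Population:
    """Long cells with several well-separated nucleoids and site-wise rings.

    Emulates elongated multi-nucleoid cells: nucleoids are evenly spaced
    along the axis; a ring is placed over each nucleoid center ("new" N
    site) with probability ``p_ring_n`` and over each midpoint between
    adjacent nucleoids ("old" O site) with probability ``p_ring_o``,
    jittered by the ring-placement precision of ``model``.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if n_nucleoids < 2:
        raise ConfigError("multi-nucleoid cells need >= 2 nucleoids")
    model = model or PlacementModel()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    s_r = model.sigma_ring_given_nucleoid / NM_PER_UM
    trunc = [0]
    cells: list[CellTruth] = []
    n_sites_true = {"N": 0, "O": 0}
    occupied_true = {"N": 0, "O": 0}
    for _ in range(n):
        length = n_nucleoids * length_per_nucleoid * rng.uniform(0.9, 1.1)
        half = length / 2.0 - radius
        centers = (
            (np.arange(n_nucleoids) - (n_nucleoids - 1) / 2.0)
            * length
            / n_nucleoids
        )
        o_sites = (centers[:-1] + centers[1:]) / 2.0
        rings: list[float] = []
        for c in centers:
            n_sites_true["N"] += 1
            if rng.random() < p_ring_n:
                occupied_true["N"] += 1
                rings.append(
                    _truncated_normal(rng, c, s_r, -half, half, trunc)
                )
        for o in o_sites:
            n_sites_true["O"] += 1
            if rng.random() < p_ring_o:
                occupied_true["O"] += 1
                rings.append(
                    _truncated_normal(rng, o, s_r, -half, half, trunc)
                )
        cells.append(
            CellTruth(
                length=length,
                radius=radius,
                nucleoid_centers=list(centers),
                nucleoid_modes=["compact"] * n_nucleoids,
                nucleoid_sigma=0.45,
                ring_offsets=rings,
            )
        )
    meta = {"n_sites": n_sites_true, "occupied": occupied_true}
    return Population(cells=cells, n_truncated=trunc[0], meta=meta)
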