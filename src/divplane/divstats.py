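"""Division statistics: daughter volume fractions, fixed-center peak
decomposition of their histogram, and division-frequency-vs-length curves.

The volume-fraction histogram of adhered daughter pairs concentrates at
v = 1/2, 1/4, 3/4 (and more weakly 1/3, 2/3) of the mother volume; the
mixture fit quantifies how much mass sits at each canonical site.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import CellRecord, ProfileSet, detect_constriction, width_profile
from .synthgen.sample import DivisionEvent
from .synthgen.types import DIVISION_SITES

V_MINI = 0.10          # min(v, 1-v) below this is a minicelling division
CENTRAL_WINDOW = (0.40, 0.60)
QUARTER_HALFWIDTH = 0.05      # v within 0.25 +/- 0.05 (and mirror)
THIRD_HALFWIDTH = 0.05        # v within 1/3 +/- 0.05 (and mirror)


def classify_division(v: float, v_mini: float = V_MINI) -> str:
    """Window classification of a division by its volume fraction.

    Precedence: minicell > central > quarter > third > other.  Windows:
    central = 0.50 +/- 0.10, quarter = 0.25 +/- 0.05 (mirrored), third =
    1/3 +/- 0.05 (mirrored, quarter takes precedence on overlap).
    """
    if not (0.0 < v < 1.0):
        raise ValueError("volume fraction must lie in (0, 1)")
    # classify on the mirrored fraction so v and 1-v always agree;
    # rounding guards the window edges against float representation noise
    m = round(min(v, 1.0 - v), 12)
    if m < v_mini:
        return "minicell"
    if m >= CENTRAL_WINDOW[0]:
        return "central"
    if abs(m - 0.25) <= QUARTER_HALFWIDTH:
        return "quarter"
    if abs(m - 1.0 / 3.0) <= THIRD_HALFWIDTH:
        return "third"
    return "other"


def volume_fraction(
    record: CellRecord,
    image=None,
    profiles: Optional[ProfileSet] = None,
    min_depth: float = 0.15,
) -> Optional[DivisionEvent]:
    """Daughter volume fraction of an adhered pair, split at the waist.

    Geometric estimator (the default ``v``): each daughter is treated as a
    solid of revolution around the axis, ``V_i = sum pi (w/2)^2 ds`` over
    its side of the deepest constriction.  Passing the ``image`` lets the
    widths come from sub-pixel outline crossings of the smooth intensity
    surface rather than the pixelated mask, which materially improves the
    volume split.  When cytosolic ``profiles`` are given, the integrated
    background-subtracted intensity ratio is reported alongside as
    ``v_intensity``.  Returns ``None`` when no constriction is found (not
    a division event).
    """
    constriction = detect_constriction(record, min_depth=min_depth, image=image)
    if constriction is None:
        return None
    s, w = width_profile(record, image=image)
    ds = np.gradient(s)
    dv = np.pi * (w / 2.0) ** 2 * ds
    left = s < constriction.s
    v_geo = float(dv[left].sum() / dv.sum())
    v_int = None
    if profiles is not None and "cyto" in profiles.intensity:
        y = np.clip(profiles.channel("cyto"), 0.0, None)
        mass = y * profiles.band_width * np.gradient(profiles.s)
        lmask = profiles.s < constriction.s
        tot = mass.sum()
        if tot > 0:
            v_int = float(mass[lmask].sum() / tot)
    return DivisionEvent(
        v=v_geo,
        mother_length=record.length,
        daughter_lengths=(constriction.s, record.length - constriction.s),
        minicell_flag=min(v_geo, 1.0 - v_geo) < V_MINI,
        v_intensity=v_int,
    )


# ---------------------------------------------------------------------------
# fixed-center Gaussian mixture
# ---------------------------------------------------------------------------

@dataclass
class PeakFit:
    """Maximum-likelihood weights of the fixed-center site mixture."""

    centers: tuple[float, ...]
    weights: dict[float, float]
    uniform_weight: float
    sigma: dict[float, float]          # per center (shared value if common)
    loglik: float
    n: int
    converged: bool
    width_floored: bool = False
    window_fractions: dict[str, float] = field(default_factory=dict)

    def weight(self, center: float) -> float:
        return self.weights[center]


def _em_once(
    x: np.ndarray,
    centers: np.ndarray,
    mirror_pairs: Sequence[tuple[int, int]],
    w0: np.ndarray,
    sigma0: float,
    widths: str,
    sigma_floor: float,
    sigma_max: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, bool, bool]:
    k = len(centers)
    w = w0.copy()
    sig = np.full(k, sigma0)
    floored = False
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # responsibilities: k Gaussians + uniform(0,1) as component k
        dens = np.empty((len(x), k + 1))
        for j in range(k):
            dens[:, j] = (
                w[j]
                / (np.sqrt(2 * np.pi) * sig[j])
                * np.exp(-((x - centers[j]) ** 2) / (2 * sig[j] ** 2))
            )
        dens[:, k] = w[k]  # uniform density = 1 on (0, 1)
        tot = dens.sum(axis=1)
        tot = np.where(tot > 0, tot, 1e-300)
        ll = float(np.log(tot).sum())
        gamma = dens / tot[:, None]
        nk = gamma.sum(axis=0)
        w = nk / len(x)
        for a, b in mirror_pairs:
            m = (w[a] + w[b]) / 2.0
            w[a] = w[b] = m
        # width update
        if widths == "common":
            num = sum(
                (gamma[:, j] * (x - centers[j]) ** 2).sum() for j in range(k)
            )
            den = nk[:k].sum()
            s = np.sqrt(num / den) if den > 0 else sigma_floor
            if s < sigma_floor:
                s, floored = sigma_floor, True
            sig[:] = min(s, sigma_max)
        else:
            for j in range(k):
                if nk[j] > 1e-12:
                    s = np.sqrt(
                        (gamma[:, j] * (x - centers[j]) ** 2).sum() / nk[j]
                    )
                else:
                    s = sigma_floor
                if s < sigma_floor:
                    s, floored = sigma_floor, True
                sig[j] = min(s, sigma_max)
            for a, b in mirror_pairs:
                s = np.sqrt((sig[a] ** 2 + sig[b] ** 2) / 2.0)
                sig[a] = sig[b] = s
        if abs(ll - prev) < tol * (1 + abs(ll)):
            converged = True
            break
        prev = ll
    return w, sig, ll, converged, floored


def fit_fixed_peaks(
    v_values: Sequence[float],
    widths: str = "common",
    n_restarts: int = 10,
    seed: int = 0,
    sigma_floor: float = 0.008,
    sigma_max: float = 0.06,
    max_iter: int = 500,
    tol: float = 1e-10,
    min_events: int = 50,
) -> PeakFit:
    """EM fit of Gaussians fixed at {1/4, 1/3, 1/2, 2/3, 3/4} plus uniform.

    Weights of mirrored peaks (1/4 with 3/4, 1/3 with 2/3) are constrained
    equal, matching the symmetry of a histogram that counts both daughters.
    Peak widths are bounded to ``sigma_max`` so a site peak cannot widen
    into a surrogate for the uniform background, and floored at
    ``sigma_floor`` (about one histogram bin) against degenerate spikes.
    Maximum likelihood on the raw fractions avoids the bin-width dependence
    of a least-squares histogram fit; the window-count fractions
    (``window_fractions``) are reported alongside for comparability.
    """
    x = np.asarray(list(v_values), dtype=float)
    if len(x) < min_events:
        raise ValueError(f"need >= {min_events} events, got {len(x)}")
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError("volume fractions must lie strictly in (0, 1)")
    centers = np.asarray(DIVISION_SITES)
    mirror_pairs = [(0, 4), (1, 3)]  # (1/4, 3/4), (1/3, 2/3)
    k = len(centers)
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        if r == 0:
            w0 = np.full(k + 1, 1.0 / (k + 1))
        else:
            w0 = rng.dirichlet(np.ones(k + 1))
        w, sig, ll, conv, floored = _em_once(
            x, centers, mirror_pairs, w0, 0.03, widths,
            sigma_floor, sigma_max, max_iter, tol,
        )
        if best is None or ll > best[2]:
            best = (w, sig, ll, conv, floored)
    w, sig, ll, conv, floored = best
    counts = pd.Series([classify_division(v) for v in x]).value_counts()
    window_fractions = {
        c: float(counts.get(c, 0)) / len(x)
        for c in ("central", "quarter", "third", "minicell", "other")
    }
    return PeakFit(
        centers=tuple(centers),
        weights={float(c): float(w[j]) for j, c in enumerate(centers)},
        uniform_weight=float(w[k]),
        sigma={float(c): float(sig[j]) for j, c in enumerate(centers)},
        loglik=ll,
        n=len(x),
        converged=conv,
        width_floored=floored,
        window_fractions=window_fractions,
    )


# ---------------------------------------------------------------------------
# division frequency vs mother length
# ---------------------------------------------------------------------------

def _wilson_ci(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(center - half, 0.0), min(center + half, 1.0))


def frequency_vs_length(
    events: Sequence[DivisionEvent],
    bin_width: float = 0.25,
    min_count: int = 5,
) -> pd.DataFrame:
    """Central and quarter division frequencies per mother-length bin.

    Returns one row per ``bin_width``-um bin with Wilson confidence
    intervals; bins with fewer than ``min_count`` events are masked (NaN
    frequencies).  The attribute ``df.attrs['transition_length']`` holds
    the left edge of the first unmasked bin where the quarter frequency
    exceeds the central frequency (NaN when none does).
    """
    if not events:
        df = pd.DataFrame(
            columns=[
                "bin_left", "bin_center", "n",
                "f_central", "central_lo", "central_hi",
                "f_quarter", "quarter_lo", "quarter_hi",
            ]
        )
        df.attrs["transition_length"] = np.nan
        return df
    lengths = np.array([e.mother_length for e in events])
    classes = np.array([classify_division(e.v) for e in events])
    lo = np.floor(lengths.min() / bin_width) * bin_width
    edges = np.arange(lo, lengths.max() + bin_width, bin_width)
    rows = []
    transition = np.nan
    for left in edges:
        sel = (lengths >= left) & (lengths < left + bin_width)
        n = int(sel.sum())
        row = {
            "bin_left": float(left),
            "bin_center": float(left + bin_width / 2),
            "n": n,
        }
        if n >= min_count:
            kc = int((classes[sel] == "central").sum())
            kq = int((classes[sel] == "quarter").sum())
            row["f_central"] = kc / n
            row["central_lo"], row["central_hi"] = _wilson_ci(kc, n)
            row["f_quarter"] = kq / n
            row["quarter_lo"], row["quarter_hi"] = _wilson_ci(kq, n)
            if (
                np.isnan(transition)
                and row["f_quarter"] > row["f_central"]
                and row["quarter_lo"] > row["central_hi"]
            ):
                transition = float(left)
        else:
            for c in ("f_central", "central_lo", "central_hi",
                      "f_quarter", "quarter_lo", "quarter_hi"):
                row[c] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["transition_length"] = transition
    return df
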