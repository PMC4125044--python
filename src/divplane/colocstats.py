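"""Co-localization statistics for ring, nucleoid, and Ter-focus positions.

The central quantities are standard deviations of per-cell displacement
differences (sigma_{Xz-Xn}, sigma_{Xz-XMatP}), quoted in nanometres, the
goodness of fit R^2 of the fixed model dx_z = dx_n, a rank-based dispersion
test (Ansari-Bradley) with exact small-sample p-values, the classical
variance-ratio F test, and Z-ring occupancy of new (N) vs old (O) division
sites in multi-nucleoid cells.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .localize import LocalizationRecord

NM_PER_UM = 1000.0


@dataclass
class ColocSummary:
    """Dispersion summary for one strain/condition subset."""

    n: int
    sigma_zn_nm: float            # SD of (dx_z - dx_n), nm
    sigma_z_nm: float             # SD of dx_z, nm
    sigma_zm_nm: float            # SD of (dx_z - dx_matp), nm; NaN if absent
    r_squared: float              # for the fixed model dx_z = dx_n
    ols_slope: float              # descriptive only
    subset: str = "all"
    low_power: bool = False


def records_to_frame(records: Sequence[LocalizationRecord]) -> pd.DataFrame:
    """Tidy one-row-per-cell table of localization results."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "length": [r.length for r in records],
            "dx_n": [r.dx_n for r in records],
            "dx_z": [r.dx_z for r in records],
            "dx_matp": [r.dx_matp for r in records],
            "nucleoid_class": [r.nucleoid_class for r in records],
            "ring_class": [r.ring_class for r in records],
            "n_nucleoids": [r.n_nucleoids for r in records],
            "n_rings": [r.n_rings for r in records],
        }
    )


def coloc_summary(
    records: Sequence[LocalizationRecord] | pd.DataFrame,
    subset: str = "all",
) -> ColocSummary:
    """Dispersion statistics of ring-vs-nucleoid (and ring-vs-focus) offsets.

    ``subset`` restricts the cells entering the summary: ``all`` =
    single-nucleoid cells, ``compact`` additionally requires a compact
    nucleoid, ``central`` additionally requires a central principal ring.
    R^2 is computed against the fixed line dx_z = dx_n (no fitted slope):
    ``1 - sum (dx_z - dx_n)^2 / sum (dx_z - mean dx_z)^2``; it may be
    negative when the model fits worse than the mean.
    """
    df = (
        records
        if isinstance(records, pd.DataFrame)
        else records_to_frame(records)
    )
    df = df[np.isfinite(df["dx_z"]) & np.isfinite(df["dx_n"])]
    df = df[df["n_nucleoids"] == 1]
    if subset == "compact":
        df = df[df["nucleoid_class"] == "compact"]
    elif subset == "central":
        df = df[df["ring_class"] == "central"]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    n = len(df)
    if n < 2:
        return ColocSummary(
            n=n, sigma_zn_nm=np.nan, sigma_z_nm=np.nan, sigma_zm_nm=np.nan,
            r_squared=np.nan, ols_slope=np.nan, subset=subset, low_power=True,
        )
    dz = df["dx_z"].to_numpy()
    dn = df["dx_n"].to_numpy()
    diff = dz - dn
    ss_res = float((diff**2).sum())
    ss_tot = float(((dz - dz.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    slope = (
        float(np.polyfit(dn, dz, 1)[0]) if np.ptp(dn) > 0 else np.nan
    )
    dm = df["dx_matp"].to_numpy()
    has_m = np.isfinite(dm)
    sigma_zm = (
        float(np.std(dz[has_m] - dm[has_m], ddof=1)) * NM_PER_UM
        if has_m.sum() >= 2
        else np.nan
    )
    return ColocSummary(
        n=n,
        sigma_zn_nm=float(np.std(diff, ddof=1)) * NM_PER_UM,
        sigma_z_nm=float(np.std(dz, ddof=1)) * NM_PER_UM,
        sigma_zm_nm=sigma_zm,
        r_squared=r2,
        ols_slope=slope,
        subset=subset,
        low_power=n < 10,
    )


# ---------------------------------------------------------------------------
# Ansari-Bradley dispersion test
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str
    n_a: int
    n_b: int
    degenerate: bool = False


def _ab_scores(pooled: np.ndarray) -> np.ndarray:
    """Ansari-Bradley scores: 1, 2, ... from both extremes inward.

    Sorted position i (1-based) of N values receives min(i, N + 1 - i);
    tied values share the mean score of their positions (midranks).
    """
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    pos_scores = np.minimum(np.arange(1, n + 1), n - np.arange(n))
    scores = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        scores[order[i: j + 1]] = pos_scores[i: j + 1].mean()
        i = j + 1
    return scores


def ansari_bradley(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "less_dispersed",
    center: bool = True,
    exact: Optional[bool] = None,
    max_exact_n: int = 20,
) -> TestResult:
    """Rank-based test for a difference in dispersion.

    Scores rank the pooled sample from both extremes inward, so compact
    samples collect *large* scores.  ``alternative='less_dispersed'`` tests
    whether ``sample_a`` is less dispersed than ``sample_b`` (one-sided);
    ``'greater_dispersed'`` tests the reverse.  With ``center=True`` each
    sample is median-aligned first, the usual convention when the two
    location parameters are unknown.  The p-value is exact (full
    enumeration over assignments) when the pooled size is at most
    ``max_exact_n``, otherwise a normal approximation with tie-corrected
    permutation moments and continuity correction is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if center:
        a = a - np.median(a)
        b = b - np.median(b)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return TestResult(
            statistic=np.nan, pvalue=1.0, method="degenerate",
            n_a=a.size, n_b=b.size, degenerate=True,
        )
    scores = _ab_scores(pooled)
    n1, n2 = a.size, b.size
    n = n1 + n2
    ab = float(scores[:n1].sum())
    if exact is None:
        exact = n <= max_exact_n
    if exact:
        stat_all = np.fromiter(
            (
                scores[list(idx)].sum()
                for idx in itertools.combinations(range(n), n1)
            ),
            dtype=float,
        )
        if alternative == "less_dispersed":
            p = float((stat_all >= ab - 1e-12).mean())
        elif alternative == "greater_dispersed":
            p = float((stat_all <= ab + 1e-12).mean())
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return TestResult(ab, p, "exact", n1, n2)
    s_sum = scores.sum()
    s_sq = (scores**2).sum()
    mean = n1 * s_sum / n
    var = n1 * n2 * (n * s_sq - s_sum**2) / (n**2 * (n - 1))
    if var <= 0:
        return TestResult(ab, 1.0, "degenerate", n1, n2, degenerate=True)
    if alternative == "less_dispersed":
        z = (ab - mean - 0.5) / np.sqrt(var)
        p = float(stats.norm.sf(z))
    elif alternative == "greater_dispersed":
        z = (ab - mean + 0.5) / np.sqrt(var)
        p = float(stats.norm.cdf(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(ab, p, "normal", n1, n2)


def variance_f_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Classical variance-ratio F test, F = s_a^2 / s_b^2."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        return TestResult(np.inf, 0.0, "degenerate", a.size, b.size, True)
    f = float(va / vb)
    dist = stats.f(a.size - 1, b.size - 1)
    if alternative == "greater":
        p = float(dist.sf(f))
    elif alternative == "less":
        p = float(dist.cdf(f))
    elif alternative == "two-sided":
        p = float(2 * min(dist.sf(f), dist.cdf(f)))
        p = min(p, 1.0)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(f, p, "f", a.size, b.size)


# ---------------------------------------------------------------------------
# N / O site occupancy
# ---------------------------------------------------------------------------

@dataclass
class OccupancyTable:
    """Z-ring occupancy of new (N) and old (O) division sites."""

    frequency: dict[str, float]          # overall fraction of occupied sites
    sd: dict[str, float]                 # SD across replicate groups
    n_sites: dict[str, int]
    n_cells: int
    n_excluded: int
    replicate_frequencies: dict[str, list[float]] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": list(self.frequency),
                "frequency": [self.frequency[k] for k in self.frequency],
                "sd": [self.sd[k] for k in self.frequency],
                "n_sites": [self.n_sites[k] for k in self.frequency],
            }
        )


def site_occupancy(
    records: Sequence[LocalizationRecord],
    tolerance: float = 0.25,
    n_replicates: int = 3,
    min_nucleoid_gap: float = 1.0,
) -> OccupancyTable:
    """Fraction of N (nucleoid-center) and O (inter-nucleoid) sites with a ring.

    Only cells with >= 2 distinct nucleoids enter.  N sites are the
    nucleoid centers; O sites the midpoints between adjacent centers.  A
    site counts as occupied when some detected ring lies within
    ``tolerance`` um of it.  Cells whose adjacent nucleoids are closer than
    ``min_nucleoid_gap`` um (no old site definable between overlapping
    nucleoids) are excluded.  Replicate SDs come from splitting the cells
    into ``n_replicates`` contiguous groups, mimicking repeated
    measurements of ~equal size.
    """
    per_cell: list[tuple[int, int, int, int]] = []  # occN, totN, occO, totO
    n_excluded = 0
    for rec in records:
        centers = sorted(rec.nucleoid_centers)
        if len(centers) < 2:
            continue
        gaps = np.diff(centers)
        if np.any(gaps < min_nucleoid_gap):
            n_excluded += 1
            continue
        rings = np.asarray(rec.ring_centers, dtype=float)
        o_sites = [(c1 + c2) / 2.0 for c1, c2 in zip(centers, centers[1:])]

        def occupied(site: float) -> bool:
            return bool(
                rings.size and np.min(np.abs(rings - site)) <= tolerance
            )

        occ_n = sum(occupied(c) for c in centers)
        occ_o = sum(occupied(o) for o in o_sites)
        per_cell.append((occ_n, len(centers), occ_o, len(o_sites)))
    if not per_cell:
        return OccupancyTable(
            frequency={"N": np.nan, "O": np.nan},
            sd={"N": np.nan, "O": np.nan},
            n_sites={"N": 0, "O": 0},
            n_cells=0,
            n_excluded=n_excluded,
        )
    arr = np.array(per_cell, dtype=float)
    freq = {
        "N": float(arr[:, 0].sum() / arr[:, 1].sum()),
        "O": float(arr[:, 2].sum() / arr[:, 3].sum()),
    }
    groups = np.array_split(arr, min(n_replicates, len(per_cell)))
    reps: dict[str, list[float]] = {"N": [], "O": []}
    for g in groups:
        if g[:, 1].sum() > 0:
            reps["N"].append(float(g[:, 0].sum() / g[:, 1].sum()))
        if g[:, 3].sum() > 0:
            reps["O"].append(float(g[:, 2].sum() / g[:, 3].sum()))
    sd = {
        k: (float(np.std(v, ddof=1)) if len(v) >= 2 else np.nan)
        for k, v in reps.items()
    }
    return OccupancyTable(
        frequency=freq,
        sd=sd,
        n_sites={"N": int(arr[:, 1].sum()), "O": int(arr[:, 3].sum())},
        n_cells=len(per_cell),
        n_excluded=n_excluded,
        replicate_frequencies=reps,
    )
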