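"""Figure helpers: volume-fraction histograms with fitted peaks, lag
histograms, and kymograph heat maps.  All functions write a file and
return the path; they use the Agg backend so they run headless."""
from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .divstats import PeakFit  # noqa: E402
from .kymo import Kymograph, LagSummary  # noqa: E402


def plot_volume_fractions(
    v_values: Sequence[float],
    fit: Optional[PeakFit],
    path: str | Path,
    bin_width: float = 0.01,
) -> Path:
    """Histogram of daughter volume fractions with the fitted mixture."""
    v = np.asarray(list(v_values))
    fig, ax = plt.subplots(figsize=(6, 3.2))
    bins = np.arange(0.0, 1.0 + bin_width, bin_width)
    ax.hist(v, bins=bins, color="0.7", edgecolor="0.4", lw=0.3,
            density=True, label=f"n = {len(v)}")
    if fit is not None:
        x = np.linspace(0.0, 1.0, 801)
        total = np.full_like(x, fit.uniform_weight)
        for c, w in fit.weights.items():
            sig = fit.sigma[c]
            comp = w / (np.sqrt(2 * np.pi) * sig) * np.exp(
                -((x - c) ** 2) / (2 * sig**2)
            )
            ax.plot(x, comp, "r--", lw=0.8)
            total += comp
        ax.plot(x, total, "r-", lw=1.2, label="fixed-site mixture")
    for c in (0.25, 1 / 3, 0.5, 2 / 3, 0.75):
        ax.axvline(c, color="0.85", lw=0.5, zorder=0)
    ax.set_xlabel("daughter volume fraction v")
    ax.set_ylabel("density")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_lag_histogram(lag: LagSummary, path: str | Path) -> Path:
    """Histogram of per-cell ring-after-Ter lags in doubling-time units."""
    fig, ax = plt.subplots(figsize=(4.2, 3.0))
    ax.bar(
        lag.bin_edges[:-1],
        lag.counts,
        width=np.diff(lag.bin_edges),
        align="edge",
        color="0.6",
        edgecolor="0.3",
    )
    ax.axvline(lag.mean, color="r", lw=1.0,
               label=f"mean {lag.mean:.3f} $T_d$")
    ax.set_xlabel(r"lag $(t_z - t_{MatP})/T_d$")
    ax.set_ylabel("cells")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_kymograph(
    kym: Kymograph, channel: str, path: str | Path
) -> Path:
    """x-t heat map of one channel (blue = low, red = high)."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    arr = kym.data[channel]
    im = ax.imshow(
        arr,
        aspect="auto",
        origin="lower",
        cmap="jet",
        extent=[kym.x[0], kym.x[-1], kym.t[0], kym.t[-1]],
    )
    ax.set_xlabel("x/L" if kym.normalized else "x (um)")
    ax.set_ylabel("t")
    fig.colorbar(im, ax=ax, label=channel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
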