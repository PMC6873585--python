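"""Standard figures: CE plane, CEAC, tornado diagram, two-way map, BIA bars."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless rendering; figures are written to files

import matplotlib.pyplot as plt
import numpy as np

from .budget import BIAResult
from .markov import ARM_TRASTUZUMAB
from .sensitivity import CEACCurve, PSAResult, TornadoEntry

__all__ = ["bia_bars", "ce_plane", "ceac_curve", "tornado", "two_way_map"]


def ce_plane(psa: PSAResult, threshold: float, perspective, path=None):
    """Incremental cost vs incremental QALY scatter with the threshold line."""
    fig, ax = plt.subplots(figsize=(6, 5))
    dq = psa.data["delta_qaly"]
    dc = psa.delta_cost(perspective)
    ax.scatter(dq, dc, s=2, alpha=0.2, color="tab:blue", rasterized=True)
    lim = max(abs(dq.min()), abs(dq.max())) * 1.05
    xs = np.linspace(-lim, lim, 3)
    ax.plot(xs, threshold * xs, color="tab:green", label=f"threshold {threshold:,.0f} PHP/QALY")
    mean_icer = psa.icer_per_qaly(perspective)
    ax.plot(xs, mean_icer * xs, color="black", label=f"mean ICER {mean_icer:,.0f} PHP/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (PHP)")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def ceac_curve(curve: CEACCurve, mark: float | None = None, path=None):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.thresholds, curve.prob_trastuzumab, label="trastuzumab + CT")
    ax.plot(curve.thresholds, curve.prob_chemotherapy, label="CT alone")
    if mark is not None:
        ax.axvline(mark, color="tab:green", ls="--", lw=1)
    ax.set_xlabel("Willingness-to-pay threshold (PHP per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def tornado(entries: list[TornadoEntry], base_icer: float, top: int = 15, path=None):
    entries = entries[:top]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(entries) + 1.5))
    ypos = np.arange(len(entries))[::-1]
    for y, e in zip(ypos, entries):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(y, hi - base_icer, left=base_icer, color="tab:green", height=0.6)
        ax.barh(y, lo - base_icer, left=base_icer, color="gold", height=0.6)
    ax.axvline(base_icer, color="black", lw=1)
    ax.set_yticks(ypos, [e.parameter for e in entries], fontsize=8)
    ax.set_xlabel("ICER (PHP per QALY)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def two_way_map(grid_df, path=None):
    """Heat map of the winning strategy over (hazard ratio, duration) cells."""
    z = (grid_df == ARM_TRASTUZUMAB).to_numpy().astype(int)
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.pcolormesh(
        grid_df.columns.to_numpy(float), grid_df.index.to_numpy(float), z,
        cmap="RdYlGn", vmin=0, vmax=1, shading="nearest",
    )
    ax.set_xlabel("Efficacy duration (years)")
    ax.set_ylabel("DFS hazard ratio")
    fig.colorbar(im, ax=ax, label="1 = trastuzumab cost-effective")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def bia_bars(result: BIAResult, path=None):
    df = result.to_frame()
    years = df["fiscal_year"]
    width = 0.35
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(years - width / 2, df["trastuzumab_total"] / 1e6, width, label="trastuzumab + CT")
    ax.bar(years + width / 2, df["chemotherapy_total"] / 1e6, width, label="CT alone")
    ax.plot(years, df["incremental"] / 1e6, "k.-", label="incremental")
    ax.set_xlabel("Fiscal year")
    ax.set_ylabel("Budget (PHP millions)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
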