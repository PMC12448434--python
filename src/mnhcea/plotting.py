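"""Matplotlib views of the sensitivity outputs: tornado, CE plane, CEAC."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_tornado", "plot_ce_plane", "plot_ceac"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_tornado(entries, base: float, ax=None):
    """Horizontal bars of the ICER range per parameter, widest on top."""
    ax = _get_ax(ax)
    entries = list(entries)
    ys = np.arange(len(entries))[::-1]
    for y, e in zip(ys, entries):
        lo, hi = sorted((e.low_icer, e.high_icer))
        ax.barh(y, hi - lo, left=lo, color="#b2182b", alpha=0.7)
    ax.axvline(base, ls="--", color="k", lw=1)
    ax.set_yticks(ys)
    ax.set_yticklabels([e.parameter for e in entries], fontsize=7)
    ax.set_xlabel("Cost per DALY averted (USD)")
    return ax


def plot_ce_plane(points: np.ndarray, wtp: float | None = None, ax=None):
    """Scatter of (DALYs averted, net cost) PSA draws."""
    ax = _get_ax(ax)
    ax.scatter(points[:, 0], points[:, 1], s=6, alpha=0.4)
    if wtp is not None:
        xs = np.linspace(0, points[:, 0].max() * 1.05, 50)
        ax.plot(xs, wtp * xs, ls="--", color="k", lw=1, label=f"WTP = {wtp:,.0f} USD/DALY")
        ax.legend()
    ax.set_xlabel("DALYs averted")
    ax.set_ylabel("Incremental cost (USD)")
    return ax


def plot_ceac(curves, ax=None):
    """Cost-effectiveness acceptability curves, one per perspective."""
    ax = _get_ax(ax)
    for curve in curves:
        ax.plot(curve.wtp_grid, curve.probability, label=curve.perspective.title())
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("Willingness to pay (USD per DALY averted)")
    ax.set_ylabel("Probability cost-effective")
    ax.legend()
    return ax
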