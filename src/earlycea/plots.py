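"""Optional plotting: cost-effectiveness plane, acceptability curve, tornado.

Requires matplotlib (the ``plot`` extra); everything else in the package
works without it.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .uncertainty import PsaDraws, TornadoEntry, ceac


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_ce_plane(draws: PsaDraws, wtp: float | None = None, ax=None):
    """Scatter the incremental (QALY, cost) cloud, origin axes and,
    optionally, the willingness-to-pay ray."""
    ax = _axes(ax)
    ax.scatter(draws.delta_qaly, draws.delta_cost, s=6, alpha=0.4)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axvline(0.0, color="grey", lw=0.8)
    if wtp is not None:
        xs = np.array(ax.get_xlim())
        ax.plot(xs, wtp * xs, color="tab:red", lw=0.8, label=f"λ = {wtp:,.0f}")
        ax.legend()
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental costs (EUR)")
    ax.set_title(draws.strategy_label)
    return ax


def plot_ceac(draws: PsaDraws, wtp_grid: Sequence[float], ax=None):
    """Acceptability curve over a willingness-to-pay grid."""
    ax = _axes(ax)
    grid = np.asarray(list(wtp_grid), dtype=float)
    ax.plot(grid, ceac(draws, grid))
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("willingness to pay (EUR/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_title(draws.strategy_label)
    return ax


def plot_tornado(entries: Sequence[TornadoEntry], ax=None):
    """Horizontal tornado bars of the one-way ICER ranges."""
    ax = _axes(ax)
    entries = list(entries)
    for i, e in enumerate(reversed(entries)):
        lo, hi = sorted((e.raw_low, e.raw_high))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="tab:blue", alpha=0.7)
    base = entries[0].icer_base
    if isinstance(base, (int, float)):
        ax.axvline(base, color="black", lw=0.8, label="base case")
        ax.legend()
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.parameter for e in reversed(entries)])
    ax.set_xlabel("ICER (EUR/QALY)")
    return ax
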