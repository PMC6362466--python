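"""Plots of the identification region: bounds curve and sensitivity fan."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .bounds import BoundsCurve

__all__ = ["plot_bounds_curve", "plot_sensitivity_curves"]


def plot_bounds_curve(curve: BoundsCurve, ax=None):
    """Shaded identification region for Pr(M, V) against the assumed
    overdiagnosis percentage."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.2))
    df = curve.to_frame()
    x = 100 * df["q"]
    ax.fill_between(x, 100 * df["lower"], 100 * df["upper"],
                    alpha=0.35, color="tab:blue", label="consistent values")
    ax.plot(x, 100 * df["lower"], color="tab:blue", lw=1.2)
    ax.plot(x, 100 * df["upper"], color="tab:blue", lw=1.2)
    ax.set_xlabel("% of study population overdiagnosed")
    ax.set_ylabel("% undergoing mastectomy\nfor overdiagnosed cancer")
    ax.set_ylim(bottom=0)
    ax.legend(loc="upper left", frameon=False)
    return ax


def plot_sensitivity_curves(curves: Mapping[float, BoundsCurve], ax=None):
    """Nested bounds for a family of sensitivity odds ratios."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.2))
    cmap = plt.get_cmap("viridis")
    lams = sorted(curves)
    for i, lam in enumerate(reversed(lams)):
        df = curves[lam].to_frame()
        color = cmap(0.15 + 0.7 * (len(lams) - 1 - i) / max(len(lams) - 1, 1))
        ax.fill_between(100 * df["q"], 100 * df["lower"], 100 * df["upper"],
                        alpha=0.5, color=color, label=f"OR = {lam:g}")
    ax.set_xlabel("% of study population overdiagnosed")
    ax.set_ylabel("% undergoing mastectomy\nfor overdiagnosed cancer")
    ax.set_ylim(bottom=0)
    ax.legend(loc="upper left", frameon=False, fontsize=8)
    return ax
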