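"""Headless-safe diagnostic figures: MM overlay, Dixon and S/v plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .core import mm_velocity
from .fitting import MMFitResult
from .graphical import SecondaryLine, IntersectionEstimate
from .rates import RateTable

__all__ = ["plot_michaelis_menten", "plot_secondary"]


def plot_michaelis_menten(table: RateTable, fits: list[MMFitResult], path) -> None:
    """Rates vs S with the fitted curve per inhibitor level."""
    fig, ax = plt.subplots(figsize=(5, 4))
    s_dense = np.linspace(0, table.data["S_uM"].max() * 1.05, 200)
    for fit in fits:
        sub = table.at_inhibitor(fit.i)
        pts = ax.errorbar(
            sub["S_uM"], sub["v_pmol_min_ug"], yerr=sub["sem"],
            fmt="o", ms=4, capsize=2, label=f"I = {fit.i:g} uM",
        )
        ax.plot(s_dense[1:], mm_velocity(s_dense[1:], fit.km_app, fit.vmax_app),
                color=pts[0].get_color(), lw=1)
    ax.set_xlabel("[S] (uM)")
    ax.set_ylabel("v (pmol min$^{-1}$ ug$^{-1}$)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_secondary(
    lines: list[SecondaryLine],
    path,
    intersection: IntersectionEstimate | None = None,
) -> None:
    """Secondary plot (Dixon or S/v) with fitted lines and the crossing."""
    fig, ax = plt.subplots(figsize=(5, 4))
    kind = lines[0].kind
    i_max = max(ln.i_values.max() for ln in lines)
    x_lo = intersection.x * 1.2 if intersection is not None and intersection.x < 0 else 0.0
    x = np.linspace(min(x_lo, -0.05 * i_max), i_max * 1.05, 100)
    for ln in lines:
        ax.plot(ln.i_values, ln.y_values, "o", ms=4)
        ax.plot(x, ln.slope * x + ln.intercept, lw=1,
                label=f"S = {ln.s:g} uM")
    if intersection is not None:
        ax.axvline(intersection.x, color="red", ls="--", lw=1)
        ax.axhline(intersection.y, color="red", ls="--", lw=1)
    ax.set_xlabel("[I] (uM)")
    ax.set_ylabel("1/v (min ug pmol$^{-1}$)" if kind == "dixon" else "[S]/v (min ug)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
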