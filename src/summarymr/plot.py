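"""Generic plotting helpers: per-SNP effect scatter and power curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .types import HarmonisedInstrument, MRResult

__all__ = ["effect_scatter", "power_curve"]


def effect_scatter(
    instruments: list[HarmonisedInstrument],
    result: MRResult | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Exposure effect vs outcome effect per SNP, with 1-SE error bars.

    The pooled causal estimate, if given, is drawn as a dashed line through
    the origin with slope b_xy_hat.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    b_zx = np.array([i.b_zx for i in instruments])
    b_zy = np.array([i.b_zy for i in instruments])
    ax.errorbar(
        b_zx,
        b_zy,
        xerr=[i.se_zx for i in instruments],
        yerr=[i.se_zy for i in instruments],
        fmt="o",
        ms=3,
        lw=0.8,
        color="tab:blue",
        ecolor="0.6",
    )
    if result is not None:
        xs = np.linspace(min(0, b_zx.min()), max(0, b_zx.max()), 50)
        ax.plot(xs, result.b_xy_hat * xs, "--", color="tab:red", label=f"slope = {result.b_xy_hat:.3f}")
        ax.legend(frameon=False)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel("SNP effect on exposure (SD units)")
    ax.set_ylabel("SNP effect on outcome (log OR)")
    return ax


def power_curve(
    or_grid: np.ndarray,
    power: np.ndarray,
    label: str | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Power against the assumed OR per exposure SD, with an 80% guide line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(or_grid, power, label=label)
    ax.axhline(0.8, color="0.7", ls=":", lw=1)
    ax.set_xlabel("odds ratio per exposure SD")
    ax.set_ylabel("power")
    ax.set_ylim(0, 1.02)
    if label:
        ax.legend(frameon=False, fontsize=8)
    return ax
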