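"""Figure export: tachometric curves and minimum-drop bar panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .curves import BootstrapSE, CurveMinimum, TachometricCurve  # noqa: E402

_COLORS = {"congruent": "#1b7837", "incongruent": "#762a83"}


def plot_curves(
    curves: dict[str, TachometricCurve],
    minima: dict[str, CurveMinimum] | None = None,
    ses: dict[str, BootstrapSE] | None = None,
    out: str | Path = "tachometric",
    formats: tuple[str, ...] = ("svg", "png"),
) -> list[Path]:
    """Two-panel figure: smoothed curves (left) and minimum-minus-chance bars.

    The left panel shows both smoothed tachometric functions against a
    dashed chance line at 0.5, x-limits set by the curve grids; the right
    panel shows each condition's minimum accuracy minus chance, with
    bootstrap SE error bars when available. One file per requested format.
    """
    fig, (ax1, ax2) = plt.subplots(
        1, 2, figsize=(9, 3.6), width_ratios=[2.2, 1.0]
    )
    xlo = min(c.rpt_grid.min() for c in curves.values())
    xhi = max(c.rpt_grid.max() for c in curves.values())
    for cond, c in curves.items():
        ax1.plot(c.rpt_grid, c.fitted, color=_COLORS.get(cond, "k"), label=cond)
    ax1.axhline(0.5, ls="--", c="gray", lw=0.8)
    ax1.set_xlim(xlo, xhi)
    ax1.set_ylim(0, 1)
    ax1.set_xlabel("raw processing time (ms)")
    ax1.set_ylabel("proportion correct")
    ax1.legend(frameon=False)

    if minima:
        conds = list(minima)
        heights = [minima[c].value - 0.5 for c in conds]
        errs = [ses[c].se if ses and c in ses else 0.0 for c in conds]
        ax2.bar(conds, heights, yerr=errs, capsize=4,
                color=[_COLORS.get(c, "k") for c in conds])
        ax2.axhline(0.0, c="k", lw=0.8)
        ax2.set_ylabel("curve minimum - chance")
        ax2.tick_params(axis="x", rotation=20)
    else:
        ax2.set_axis_off()
    fig.tight_layout()
    out = Path(out)
    written = []
    for fmt in formats:
        p = out.with_suffix(f".{fmt}")
        fig.savefig(p, dpi=150)
        written.append(p)
    plt.close(fig)
    return written


def plot_congruency_effect(
    effect, out: str | Path = "congruency_effect",
    formats: tuple[str, ...] = ("svg", "png"),
) -> list[Path]:
    """Mean congruency effect (congruent - incongruent accuracy) per rPT bin."""
    mean = effect.mean(axis=0)
    sem = effect.std(axis=0, ddof=1) / (len(effect) ** 0.5)
    fig, ax = plt.subplots(figsize=(5, 3.4))
    ax.errorbar(mean.index, mean.to_numpy(), yerr=sem.to_numpy(),
                marker="o", capsize=3, color="#2166ac")
    ax.axhline(0.0, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("rPT bin center (ms)")
    ax.set_ylabel("congruency effect (accuracy)")
    fig.tight_layout()
    out = Path(out)
    written = []
    for fmt in formats:
        p = out.with_suffix(f".{fmt}")
        fig.savefig(p, dpi=150)
        written.append(p)
    plt.close(fig)
    return written
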