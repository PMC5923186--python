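"""Posterior summaries: lag curves, sensitive windows, cumulative effects.

The distributed lag function delta_{g,t} = beta_g * w_{g,t} is summarized
per gestational week by its posterior mean and an equal-tailed pointwise
credible interval.  A *sensitive window* is a maximal run of consecutive
weeks whose pointwise interval excludes zero.  The *cumulative effect*
CE_g = sum_t delta_{g,t} = beta_g * sum_t w_{g,t} is the outcome change
per 1 ug/m3 increase in exposure sustained across the whole pregnancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, InvalidLevelError
from .model import BDLIMFit


def lag_effect_draws(fit: BDLIMFit, group) -> np.ndarray:
    """(draws x T) matrix of delta_{g,t} = beta_g draw * w_{g,t} draw."""
    if group not in fit.beta:
        raise KeyError(f"group {group!r} not in fit (has {list(fit.beta)})")
    return fit.beta[group][:, None] * fit.weights[group]


def _check_level(level: float) -> None:
    if not (0.5 < level < 1.0):
        raise InvalidLevelError(f"credible level must be in (0.5, 1), got {level}")


def pointwise_intervals(draws: np.ndarray, level: float = 0.95):
    """Equal-tailed pointwise intervals from draw percentiles per week."""
    _check_level(level)
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise EmptyInputError("empty draw matrix")
    alpha = 1.0 - level
    lower = np.quantile(draws, alpha / 2.0, axis=0)
    upper = np.quantile(draws, 1.0 - alpha / 2.0, axis=0)
    return draws.mean(axis=0), lower, upper


def identify_sensitive_windows(draws: np.ndarray, level: float = 0.95):
    """Maximal runs of consecutive weeks whose interval excludes zero.

    Returns a list of closed integer week ranges, e.g. ``[(35, 40)]``.
    """
    _check_level(level)
    draws = np.asarray(draws, dtype=float)
    if draws.shape[0] < 100:
        raise EmptyInputError(
            f"need >= 100 draws for interval estimation, have {draws.shape[0]}"
        )
    _, lower, upper = pointwise_intervals(draws, level)
    significant = (lower > 0.0) | (upper < 0.0)
    windows = []
    start = None
    for t, sig in enumerate(significant, start=1):
        if sig and start is None:
            start = t
        elif not sig and start is not None:
            windows.append((start, t - 1))
            start = None
    if start is not None:
        windows.append((start, len(significant)))
    return windows


def cumulative_effect(draws: np.ndarray, level: float = 0.95):
    """Posterior mean and equal-tailed interval of CE = sum_t delta_t.

    Returns ``(mean, lower, upper, ce_draws)``.
    """
    _check_level(level)
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise EmptyInputError("empty draw matrix")
    ce = draws.sum(axis=1)
    alpha = 1.0 - level
    return (
        float(ce.mean()),
        float(np.quantile(ce, alpha / 2.0)),
        float(np.quantile(ce, 1.0 - alpha / 2.0)),
        ce,
    )


@dataclass
class WindowReport:
    """Per-week lag effects with credible bands, windows, cumulative effects."""

    level: float
    groups: tuple
    mean: dict = field(default_factory=dict)     # group -> (T,)
    lower: dict = field(default_factory=dict)
    upper: dict = field(default_factory=dict)
    windows: dict = field(default_factory=dict)  # group -> [(lo, hi), ...]
    ce: dict = field(default_factory=dict)       # group -> (mean, lo, hi)

    def to_table(self) -> pd.DataFrame:
        """Tidy (group, week, mean, lower, upper, in_window) table."""
        rows = []
        for g in self.groups:
            T = len(self.mean[g])
            in_win = np.zeros(T, dtype=bool)
            for lo, hi in self.windows[g]:
                in_win[lo - 1 : hi] = True
            for t in range(T):
                rows.append(
                    {
                        "group": g,
                        "week": t + 1,
                        "mean": self.mean[g][t],
                        "lower": self.lower[g][t],
                        "upper": self.upper[g][t],
                        "in_window": bool(in_win[t]),
                    }
                )
        return pd.DataFrame(rows)

    def ce_table(self) -> pd.DataFrame:
        rows = [
            {
                "group": g,
                "cumulative_effect": self.ce[g][0],
                "lower": self.ce[g][1],
                "upper": self.ce[g][2],
                "level": self.level,
            }
            for g in self.groups
        ]
        return pd.DataFrame(rows)


def window_report(fit: BDLIMFit, level: float = 0.95) -> WindowReport:
    """Full posterior summary of a fit: curves, windows, cumulative effects."""
    _check_level(level)
    report = WindowReport(level=level, groups=tuple(fit.groups))
    for g in fit.groups:
        draws = lag_effect_draws(fit, g)
        mean, lower, upper = pointwise_intervals(draws, level)
        report.mean[g] = mean
        report.lower[g] = lower
        report.upper[g] = upper
        report.windows[g] = identify_sensitive_windows(draws, level)
        ce_mean, ce_lo, ce_hi, _ = cumulative_effect(draws, level)
        report.ce[g] = (ce_mean, ce_lo, ce_hi)
    return report


def lag_curve_table(report: WindowReport) -> pd.DataFrame:
    """Export-ready tidy table of the per-week lag curves."""
    return report.to_table()


def plot_lag_curves(report: WindowReport, outcome_label: str = "z-score", path=None):
    """Curve-with-band figure per group (one panel each).

    Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    matplotlib.rcParams["svg.hashsalt"] = "bdlim"  # reproducible svg ids
    import matplotlib.pyplot as plt

    groups = report.groups
    fig, axes = plt.subplots(
        1, len(groups), figsize=(5.0 * len(groups), 3.5), squeeze=False, sharey=True
    )
    for ax, g in zip(axes[0], groups):
        T = len(report.mean[g])
        weeks = np.arange(1, T + 1)
        ax.fill_between(weeks, report.lower[g], report.upper[g], alpha=0.3, color="gray")
        ax.plot(weeks, report.mean[g], color="black")
        ax.axhline(0.0, color="red", linewidth=0.8, linestyle="--")
        for lo, hi in report.windows[g]:
            ax.axvspan(lo - 0.5, hi + 0.5, color="tab:blue", alpha=0.15)
        ax.set_xlabel("gestational week")
        ax.set_title(str(g))
    axes[0][0].set_ylabel(f"change in {outcome_label} per 1 µg/m³ PM$_{{2.5}}$")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
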