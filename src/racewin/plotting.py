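"""Plot helpers: racer density curves with bootstrap error bars, and
contribution bars per double condition."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_densities", "plot_contributions"]

_COLORS = {"C": "tab:green", "O": "tab:blue", "M": "tab:orange",
           "CO": "tab:red", "MO": "tab:purple", "CM": "tab:brown"}


def _bin_centers_and_density(boundaries: list, probs: np.ndarray):
    b = np.asarray([x for x in boundaries if x != "inf"], dtype=float)
    widths = np.diff(b)
    centers = 0.5 * (b[:-1] + b[1:])
    # last (reservoir) bin omitted: it is infinite and empty of observed RTs
    return centers, probs[: centers.size] / widths


def plot_densities(report: dict, double_condition: str, path: str | Path) -> None:
    """Piecewise-linear densities of the two singles, the conjunctive racer
    and the observed double-condition histogram, with bootstrap bars if the
    report carries them."""
    boundaries = report["grid"]["boundaries"]
    fig, ax = plt.subplots(figsize=(6, 4))
    singles = {"CO": ("C", "O"), "MO": ("M", "O"), "CM": ("C", "M")}[double_condition]
    for cond in (*singles, double_condition):
        p = np.asarray(report["fit"]["dists"][cond])
        x, d = _bin_centers_and_density(boundaries, p)
        ax.plot(x, d, marker="o", ms=3, label=f"P_{cond} (fitted)", color=_COLORS[cond])
        if "bootstrap" in report:
            lo = np.asarray(report["bootstrap"]["dist_lower"][cond])[: x.size]
            hi = np.asarray(report["bootstrap"]["dist_upper"][cond])[: x.size]
            _, dlo = _bin_centers_and_density(boundaries, lo)
            _, dhi = _bin_centers_and_density(boundaries, hi)
            ax.fill_between(x, dlo, dhi, alpha=0.15, color=_COLORS[cond])
    counts = np.asarray(report["counts"][double_condition], dtype=float)
    x, d = _bin_centers_and_density(boundaries, counts / counts.sum())
    ax.plot(x, d, "k--", label=f"{double_condition} observed")
    ax.set_xlabel("RT (s)")
    ax.set_ylabel("probability density (1/s)")
    ax.legend(fontsize=8)
    ax.set_title(f"subject {report['subject_id']}: {double_condition} race")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_contributions(summary: dict, path: str | Path) -> None:
    """Subject-averaged contributions per double condition with SEM bars."""
    conds = list(summary["conditions"])
    fig, axes = plt.subplots(1, max(len(conds), 1), figsize=(3.2 * len(conds), 3.6))
    if len(conds) == 1:
        axes = [axes]
    for ax, dc in zip(axes, conds):
        entry = summary["conditions"][dc]
        labels = [k for k in entry["mean"] if k != "chance"]
        means = [entry["mean"][k] for k in labels]
        sems = [entry["sem"][k] for k in labels]
        ax.bar(labels, means, yerr=sems, capsize=4, color="lightgray", edgecolor="k")
        ax.axhline(entry["mean"]["chance"], color="magenta", ls=":", label="mean chance")
        ax.set_title(dc)
        ax.set_ylabel("contribution")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
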