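"""Distribution and interaction figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .design import encode_mains

__all__ = ["ite_histogram", "interaction_plot"]


def ite_histogram(summary, path: str | Path) -> Path:
    """Histogram of delta point estimates (percentage-point axis)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    edges = np.asarray(summary.bin_edges, float)
    counts = np.asarray(summary.bin_counts, float)
    widths = np.diff(edges)
    if widths.size and widths.max() == 0:  # degenerate all-equal estimates
        ax.bar(edges[:-1], counts, width=0.5)
    else:
        ax.bar(edges[:-1], counts, width=widths, align="edge", edgecolor="white")
    ax.axvline(0.0, color="black", lw=0.8, ls="--")
    ax.set_xlabel("individualized effect (percentage points)")
    ax.set_ylabel("participants")
    ax.set_title(
        f"{summary.outcome} at {summary.timepoint}: "
        f"mean {summary.mean_pp:.1f} (SD {summary.sd_pp:.1f}) pp"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def interaction_plot(
    estimates: list,
    baseline: pd.DataFrame,
    pair: tuple[str, str],
    path: str | Path,
    grid: int = 50,
) -> Path:
    """Predicted standardized effect vs the second covariate, one line per
    level/value of the first (e.g. importance on x, gender as lines)."""
    cov_a, cov_b = pair
    terms = {e.term: e.median for e in estimates}
    _, names_a = encode_mains(baseline, [cov_a])
    _, names_b = encode_mains(baseline, [cov_b])
    b_vals = baseline[cov_b].astype(float)
    center_b = float(b_vals.mean())
    xs = np.linspace(float(b_vals.min()), float(b_vals.max()), grid)

    fig, ax = plt.subplots(figsize=(6, 4))
    # reference level of a: all dummies zero
    levels = ["reference"] + names_a
    for level in levels:
        ys = np.zeros_like(xs)
        for nb in names_b:
            ys = ys + terms.get(nb, 0.0) * (xs - center_b)
        if level != "reference":
            ys = ys + terms.get(level, 0.0)
            for nb in names_b:
                ys = ys + terms.get(f"{level}:{nb}", 0.0) * (xs - center_b)
        ax.plot(xs, ys, label=level)
    ax.set_xlabel(cov_b)
    ax.set_ylabel("predicted standardized effect")
    ax.legend(title=cov_a)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
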