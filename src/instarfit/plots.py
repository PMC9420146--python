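"""Optional plot artifacts: fitted frequency distribution and Dyar line.

Presentation only — nothing in the analysis depends on these figures.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .data_io import HCWDataset, make_histogram
from .mixture import MixtureModel, component_density
from .validation import DyarRegressionResult


def plot_fit(
    data: HCWDataset,
    model: MixtureModel,
    path: str | Path,
    bin_width: float | str = "auto",
) -> None:
    """Histogram of widths with the fitted weighted normal curves overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = make_histogram(data, bin_width=bin_width)
    scale = len(data) * hist.bin_width  # density → expected counts per bin
    grid = np.linspace(hist.bin_edges[0], hist.bin_edges[-1], 500)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.bar(
        hist.bin_edges[:-1], hist.counts, width=hist.bin_width, align="edge",
        color="#c8d8e8", edgecolor="#5a7a9a", label="observed",
    )
    for i, comp in enumerate(model.components, start=1):
        ax.plot(grid, scale * component_density(comp, grid), label=f"instar {i}")
    ax.plot(grid, scale * model.pdf(grid), "k--", lw=1, label="mixture")
    ax.set_xlabel("head capsule width (μm)")
    ax.set_ylabel("frequency")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dyar(
    means: np.ndarray, result: DyarRegressionResult, path: str | Path
) -> None:
    """ln(mean HCW) against instar number with the fitted regression line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = np.asarray(means, dtype=float)
    instars = np.arange(1, means.size + 1)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(instars, np.log(means), color="#2a5a8a", zorder=3)
    grid = np.linspace(0.8, means.size + 0.2, 50)
    ax.plot(grid, result.intercept + result.slope * grid, "k-", lw=1)
    ax.set_xticks(instars)
    ax.set_xlabel("instar")
    ax.set_ylabel("ln(mean head capsule width / μm)")
    ax.set_title(f"R² = {result.r_squared:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
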