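"""Scatter-plus-fit figures for the association analyses."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .association import RegressionResult


def scatter_fit(
    x, y, result: RegressionResult, path: str | Path, xlabel: str | None = None,
    ylabel: str | None = None,
) -> Path:
    """Scatter of the regime points with the fitted line/parabola, saved as SVG."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(x, y, color="tab:blue", zorder=3)
    grid = np.linspace(x.min(), x.max(), 200)
    coef = result.coefficients
    fit = coef[0] + coef[1] * grid + (coef[2] * grid**2 if len(coef) > 2 else 0.0)
    ax.plot(grid, fit, color="tab:red",
            label=f"{result.model} fit, $R^2$ = {result.r_squared:.2f}")
    ax.set_xlabel(xlabel or result.predictor)
    ax.set_ylabel(ylabel or result.response)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path
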