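"""Linear regression of working distance against maximum distortion ratio.

The wider the view (longer working distance at fixed optics), the
stronger the distortion at the image border, and the relationship over
the acquisition grid is well described by a simple straight line.
Following the reported analysis, the regression is run with the working
distance as the response and the per-distance maximum corresponding-line
distance as the predictor, even though predicting distortion from
geometry is the physically natural direction; both directions are
available, the response-on-ratio one is the default used by the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = ["RegressionFit", "fit_linear", "plot_fit"]


@dataclass
class RegressionFit:
    """Ordinary least squares fit y = slope*x + intercept.

    ``r_squared`` is the squared Pearson correlation and ``p_value`` the
    two-sided t-test of zero slope with n - 2 degrees of freedom.
    """

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    stderr: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def summary(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
            "stderr": self.stderr,
        }


def fit_linear(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """OLS straight-line fit with fit quality and slope significance.

    Requires at least three points and a non-constant predictor.  For
    the standard protocol, ``x`` is the maximum distortion ratio (mm)
    and ``y`` the working distance (mm).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be the same length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a meaningful line")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor; slope undefined")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
        stderr=float(res.stderr),
    )


def plot_fit(x: np.ndarray, y: np.ndarray, fit: RegressionFit, path: str | Path) -> None:
    """Scatter plus fitted line, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, color="tab:blue", zorder=3)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, fit.predict(grid), color="tab:red",
            label=f"y = {fit.slope:.2f}x + {fit.intercept:.2f}\nR² = {fit.r_squared:.4f}")
    ax.set_xlabel("maximum distortion ratio (mm)")
    ax.set_ylabel("working distance (mm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
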