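"""One-at-a-time perturbation analysis of a fitted PLS model.

Each predictor is stepped across an 8-level grid spanning from 20% of its
observed range below the minimum to 20% above the maximum,

    level_k = x_min + c_k * x_dif,   c_k in (-0.2, 0, 0.2, ..., 1.0, 1.2),

while every other predictor is held at its cohort mean; the fitted model
predicts the seven task times at each probe row. Because the model is
linear, each resulting curve is exactly affine in the varied predictor; its
slope sign classifies the (predictor, task) pair as increasing, decreasing
or negligible. The two outer levels deliberately extrapolate beyond the
observed range — a notice is logged rather than refusing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import PredictorSummary

__all__ = [
    "PERTURBATION_COEFFICIENTS",
    "PerturbationGrid",
    "SensitivityCurves",
    "build_grid",
    "perturb_predict",
    "classify_trends",
]

logger = logging.getLogger(__name__)

#: grid step multipliers applied to each predictor's range
PERTURBATION_COEFFICIENTS: tuple[float, ...] = (-0.2, 0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2)

#: default relative excursion below which a curve counts as "little change"
DEFAULT_FLAT_TOL = 0.02


@dataclass(frozen=True)
class PerturbationGrid:
    """8 levels per predictor: ``levels[k, j] = x_min_j + c_k * x_dif_j``."""

    coefficients: tuple[float, ...]
    levels: np.ndarray  # (8, m), predictor units
    x_names: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        idx = [f"Xmin{c:+.0%}Xdif" for c in self.coefficients]
        return pd.DataFrame(self.levels, index=idx, columns=list(self.x_names))


@dataclass(frozen=True)
class SensitivityCurves:
    """Predicted response curves, one 8 x p block per varied predictor."""

    grid: PerturbationGrid
    curves: np.ndarray  # (m, 8, p), response units (seconds)
    baseline: np.ndarray  # (p,) prediction with every predictor at its mean
    y_names: tuple[str, ...]

    def frame_for(self, predictor: str) -> pd.DataFrame:
        j = self.grid.x_names.index(predictor)
        df = pd.DataFrame(self.curves[j], columns=list(self.y_names))
        df.insert(0, "level", self.grid.levels[:, j])
        return df


def build_grid(summary: PredictorSummary) -> PerturbationGrid:
    """Construct the 8-level perturbation grid from a predictor summary."""
    c = np.asarray(PERTURBATION_COEFFICIENTS)
    levels = summary.x_min[None, :] + c[:, None] * summary.x_dif[None, :]
    return PerturbationGrid(
        coefficients=PERTURBATION_COEFFICIENTS,
        levels=levels,
        x_names=tuple(summary.x_names),
    )


def perturb_predict(results, summary: PredictorSummary, grid: PerturbationGrid | None = None) -> SensitivityCurves:
    """Predict task times while one predictor sweeps its grid.

    ``results`` is a fitted :class:`~firefit.pls.PLSResults` (or anything
    with ``predict`` and ``coefficients``). For predictor j, probe row k has
    ``levels[k, j]`` in coordinate j and the cohort mean elsewhere.
    """
    if grid is None:
        grid = build_grid(summary)
    m = len(summary.x_names)
    if results.coefficients.shape[0] != m:
        raise ValueError(
            f"model has {results.coefficients.shape[0]} predictors, summary has {m}"
        )
    if tuple(grid.x_names) != tuple(summary.x_names):
        raise ValueError("grid and summary predictor orderings disagree")
    logger.info(
        "perturbation grid extrapolates beyond the observed range at "
        "coefficients -0.2 and +1.2"
    )
    n_levels = grid.levels.shape[0]
    p = results.coefficients.shape[1]
    curves = np.empty((m, n_levels, p))
    for j in range(m):
        probe = np.tile(summary.x_ave, (n_levels, 1))
        probe[:, j] = grid.levels[:, j]
        curves[j] = results.predict(probe)
    baseline = results.predict(summary.x_ave)
    return SensitivityCurves(
        grid=grid,
        curves=curves,
        baseline=np.asarray(baseline, float),
        y_names=tuple(getattr(results.model, "y_names", [f"Y{k+1}" for k in range(p)]))
        if hasattr(results, "model")
        else tuple(f"Y{k+1}" for k in range(p)),
    )


def classify_trends(curves: SensitivityCurves, flat_tol: float = DEFAULT_FLAT_TOL) -> pd.DataFrame:
    """Classify each (predictor, task) curve as increasing/decreasing/negligible.

    A curve is *negligible* when its total excursion (max minus min across
    the 8 levels) is below ``flat_tol`` times the magnitude of the all-means
    baseline prediction for that task; otherwise the slope sign decides.
    The classification is invariant to a positive rescaling of the
    responses.
    """
    m, _, p = curves.curves.shape
    out = np.empty((m, p), dtype=object)
    for j in range(m):
        for k in range(p):
            col = curves.curves[j, :, k]
            excursion = col.max() - col.min()
            if excursion <= flat_tol * abs(curves.baseline[k]):
                out[j, k] = "negligible"
            else:
                out[j, k] = "increasing" if col[-1] > col[0] else "decreasing"
    return pd.DataFrame(out, index=list(curves.grid.x_names), columns=list(curves.y_names))


def plot_curves(curves: SensitivityCurves, path=None):
    """Render one panel per varied predictor (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = curves.curves.shape[0]
    fig, axes = plt.subplots(1, m, figsize=(3.2 * m, 3), sharey=False)
    for j, ax in enumerate(np.atleast_1d(axes)):
        for k, name in enumerate(curves.y_names):
            ax.plot(curves.grid.levels[:, j], curves.curves[j, :, k], label=name)
        ax.set_xlabel(curves.grid.x_names[j])
        ax.set_ylabel("predicted time (s)")
    axes = np.atleast_1d(axes)
    axes[-1].legend(fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
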