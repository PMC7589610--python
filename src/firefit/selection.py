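"""Leave-one-out PRESS, fitted SS and the Q² rule for choosing components.

For each candidate component count h the procedure compares

* ``PRESS(h)`` — the predicted residual sum of squares: each row is predicted
  by an h-component model fitted to the other n-1 rows (centering and scaling
  re-estimated inside every fold), and the squared errors are accumulated on
  the standardized-Y scale, summed over responses;
* ``SS(h)`` — the in-sample residual sum of squares of the h-component fit on
  all n rows, same scale; ``SS(0)`` is the total centered sum of squares of
  standardized Y, i.e. p·(n-1).

The cross-validity statistic ``Q²_h = 1 - PRESS(h)/SS(h-1)`` measures whether
component h predicts better than the (h-1)-component model explains.
Components are retained while ``Q²_h`` meets the threshold
``1 - 0.95² = 0.0975``; extraction stops at the first failure. If even the
first component fails, a one-component model is still returned, flagged as
non-significant, so downstream stages always have a model to work with.

The standardized scale for PRESS uses the full-sample y-scale (fold models
autoscale internally, but the left-out errors are divided by the full-sample
scale) so that PRESS(h) and SS(h-1) are commensurable. PRESS can optionally
be accumulated on the raw response scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import ExtractionError, PLSRegression, standardize

__all__ = [
    "DEFAULT_Q2_THRESHOLD",
    "CVTable",
    "compute_ss",
    "compute_press",
    "loo_predictions",
    "q_squared",
    "select_components",
]

#: Retention threshold for Q²: a component must beat the 0.95 "do-nothing"
#: prediction ratio, i.e. Q² >= 1 - 0.95².
DEFAULT_Q2_THRESHOLD = 1.0 - 0.95**2

# relative floor below which SS is treated as exactly zero (model exact)
_SS_FLOOR = 1e-12


def _as_matrices(X, Y):
    if hasattr(X, "X") and hasattr(X, "Y") and Y is None:
        return np.asarray(X.X, float), np.asarray(X.Y, float)
    return np.asarray(X, float), np.asarray(Y, float)


def loo_predictions(X, Y, n_components) -> np.ndarray:
    """Leave-one-out predictions (original units), one row per subject.

    Row i is predicted by an ``n_components`` model fitted on all rows except
    i; row i never influences its own prediction. A fold whose predictor or
    response block loses all variance in a column is an error naming the fold.
    """
    X, Y = _as_matrices(X, Y)
    n = X.shape[0]
    out = np.empty_like(Y, dtype=float)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            res = PLSRegression(X[mask], Y[mask]).fit(n_components)
        except (ValueError, ExtractionError) as exc:
            raise ValueError(f"leave-one-out fold {i} (row {i} held out) failed: {exc}") from exc
        out[i] = res.predict(X[i])
    return out


def compute_press(X, Y=None, n_components=1, scale="standardized"):
    """PRESS(h): leave-one-out squared prediction error, per response and total.

    Returns ``(press_j, press)`` where ``press_j`` has one entry per response
    and ``press = press_j.sum()``. With ``scale='standardized'`` (default)
    errors are divided by the full-sample response scale; ``scale='raw'``
    accumulates errors in original units.
    """
    X, Y = _as_matrices(X, Y)
    pred = loo_predictions(X, Y, n_components)
    err = Y - pred
    if scale == "standardized":
        _, _, y_scale = standardize(Y)
        err = err / y_scale
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    press_j = np.sum(err**2, axis=0)
    return press_j, float(press_j.sum())


def compute_ss(X, Y=None, n_components=0, scale="standardized"):
    """SS(h): in-sample residual sum of squares of the h-component fit.

    ``n_components=0`` gives the baseline: deviations of Y from its column
    means (on the standardized scale this is exactly p·(n-1)). Returns
    ``(ss_j, ss)``.
    """
    X, Y = _as_matrices(X, Y)
    if n_components == 0:
        resid = Y - Y.mean(axis=0)
    else:
        res = PLSRegression(X, Y).fit(n_components)
        resid = Y - res.predict(X)
    if scale == "standardized":
        _, _, y_scale = standardize(Y)
        resid = resid / y_scale
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    ss_j = np.sum(resid**2, axis=0)
    return ss_j, float(ss_j.sum())


def q_squared(press_h: float, ss_prev: float) -> float:
    """Cross-validity Q² = 1 - PRESS(h)/SS(h-1)."""
    if ss_prev <= 0:
        raise ValueError(f"SS(h-1) must be positive, got {ss_prev}")
    return 1.0 - press_h / ss_prev


@dataclass
class CVTable:
    """Per-component cross-validation table.

    One row per candidate component h = 1..h_max (possibly truncated when the
    residual sum of squares hits zero) with PRESS, SS, Q² and a retained
    flag. Retained flags always form a prefix: once a component fails the Q²
    rule no later one is retained.
    """

    h: np.ndarray
    press_j: np.ndarray
    press: np.ndarray
    ss_j: np.ndarray
    ss: np.ndarray
    q2: np.ndarray
    retained: np.ndarray
    ss0: float
    threshold: float
    significant: bool = True
    press_ge_ss_violations: list = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "h": self.h,
                "PRESS": self.press,
                "SS": self.ss,
                "Q2": self.q2,
                "retained": self.retained,
            }
        )


def select_components(X, Y=None, h_max=None, threshold: float = DEFAULT_Q2_THRESHOLD,
                      scale: str = "standardized"):
    """Choose the number of PLS components by the Q² retention rule.

    Components are examined in extraction order; component h is retained
    while ``Q²_h >= threshold`` and extraction stops at the first failure.
    The returned count is at least 1 even when the first component fails —
    the accompanying table then carries ``significant=False``.

    Returns
    -------
    (h, table) : (int, CVTable)
    """
    X, Y = _as_matrices(X, Y)
    n, m = X.shape
    cap = min(n - 1, m)
    if h_max is None:
        h_max = cap
    if not 1 <= h_max <= cap:
        raise ValueError(f"h_max must be in [1, {cap}], got {h_max}")

    rows = []
    violations = []
    _, ss_prev = compute_ss(X, Y, 0, scale=scale)
    ss0 = ss_prev
    stopped = False
    for h in range(1, h_max + 1):
        if ss_prev <= _SS_FLOOR * ss0:
            break  # (h-1)-component model already exact; Q² would be 0/0
        press_j, press = compute_press(X, Y, h, scale=scale)
        ss_j, ss = compute_ss(X, Y, h, scale=scale)
        q2 = q_squared(press, ss_prev)
        retained = (not stopped) and q2 >= threshold
        rows.append((h, press_j, press, ss_j, ss, q2, retained))
        if press < ss:
            violations.append(h)
        if not retained:
            stopped = True
            break
        ss_prev = ss

    hs = np.array([r[0] for r in rows])
    table = CVTable(
        h=hs,
        press_j=np.array([r[1] for r in rows]),
        press=np.array([r[2] for r in rows]),
        ss_j=np.array([r[3] for r in rows]),
        ss=np.array([r[4] for r in rows]),
        q2=np.array([r[5] for r in rows]),
        retained=np.array([r[6] for r in rows], dtype=bool),
        ss0=ss0,
        threshold=threshold,
        press_ge_ss_violations=violations,
    )
    n_retained = table.n_retained
    if n_retained == 0:
        table.significant = False
        n_retained = 1
    return n_retained, table
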