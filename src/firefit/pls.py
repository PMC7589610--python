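"""From-scratch partial least-squares regression (NIPALS family).

The model links an ``n x m`` predictor block X to an ``n x p`` response block
Y through a small number ``h`` of latent components. Both blocks are
autoscaled (centered, unit sample variance) before extraction: the variables
span incomparable units (kg, mL/kg/min, %, W, s), so correlation-scale PLS is
the defensible default. Each component is extracted from the current residual
blocks E, F:

* the weight vector ``w`` (unit norm) is the dominant left singular direction
  of ``E'F`` — the direction whose score ``t = E w`` has maximal covariance
  with a linear combination of the responses;
* loadings are least-squares regressions of each block on the score,
  ``alpha = E't / ||t||^2`` and ``beta = F't / ||t||^2``;
* both blocks are deflated by the rank-one score reconstruction,
  ``E <- E - t alpha'`` and ``F <- F - t beta'``, and the next component is
  extracted from the residuals.

Accumulating the per-component regressions gives the original-units
coefficient matrix ``B`` (m x p) and intercept ``b0`` so that
``Y_hat = X B + b0``; component-wise and coefficient-form predictions agree
to round-off.

Component count is capped at ``min(n - 1, m)``; with the study's shape
(n = 20, m = 5) that is 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExtractionError",
    "standardize",
    "extract_component",
    "deflate",
    "PLSRegression",
    "PLSResults",
    "fit_plsr",
]

#: convergence tolerance used when checking near-zero cross-covariance
_ZERO_TOL = 1e-12


class ExtractionError(RuntimeError):
    """No component is extractable (X and Y residuals are uncorrelated)."""


def standardize(M, means=None, scales=None, names=None):
    """Center columns and scale to unit sample variance (ddof=1).

    When ``means``/``scales`` are supplied (test-set use) they are applied as
    given, not re-estimated. Estimating scales from a zero-variance column is
    an error naming the column.

    Returns
    -------
    (Z, means, scales)
    """
    M = np.asarray(M, dtype=float)
    if means is None:
        means = M.mean(axis=0)
    else:
        means = np.asarray(means, dtype=float)
    if scales is None:
        scales = M.std(axis=0, ddof=1)
        zero = scales <= _ZERO_TOL * np.maximum(1.0, np.abs(means))
        if np.any(zero):
            j = int(np.flatnonzero(zero)[0])
            label = names[j] if names is not None else f"column {j}"
            raise ValueError(f"zero-variance column: {label}")
    else:
        scales = np.asarray(scales, dtype=float)
    return (M - means) / scales, means, scales


def extract_component(E, F):
    """Extract one PLS component from residual blocks E (n x m), F (n x p).

    Returns ``(w, t, u, alpha, beta)``: unit-norm predictor weights, predictor
    scores, response scores, and the least-squares loadings of each block on
    ``t``. The weight direction is the dominant left singular vector of
    ``E'F``, with the sign fixed so the largest-magnitude entry of ``w`` is
    positive (removes the inherent sign indeterminacy).
    """
    E = np.asarray(E, dtype=float)
    F = np.asarray(F, dtype=float)
    M = E.T @ F
    scale = np.linalg.norm(E) * np.linalg.norm(F)
    if np.linalg.norm(M) <= _ZERO_TOL * max(scale, 1.0):
        raise ExtractionError("no extractable component: X'Y residual cross-covariance is zero")
    U, _, _ = np.linalg.svd(M, full_matrices=False)
    w = U[:, 0]
    w = w * np.sign(w[np.argmax(np.abs(w))])
    t = E @ w
    tt = t @ t
    if tt <= _ZERO_TOL:
        raise ExtractionError("no extractable component: degenerate score vector")
    alpha = E.T @ t / tt
    beta = F.T @ t / tt
    beta_norm = np.linalg.norm(beta)
    u = F @ (beta / beta_norm) if beta_norm > 0 else np.zeros(E.shape[0])
    return w, t, u, alpha, beta


def deflate(E, F, t, alpha, beta):
    """Remove a component's rank-one reconstruction from both blocks.

    ``E_next = E - t alpha'`` and ``F_next = F - t beta'``; by construction
    the columns of ``E_next`` are orthogonal to ``t`` up to round-off.
    """
    return E - np.outer(t, alpha), F - np.outer(t, beta)


class PLSRegression:
    """Partial least-squares regression model of Y on X.

    Parameters
    ----------
    X : array-like, shape (n, m)
        Predictor block.
    Y : array-like, shape (n, p)
        Response block. A single response may be passed as a 1-D array.
    x_names, y_names : sequence of str, optional
        Variable labels used in error messages and ``summary()``.

    Examples
    --------
    >>> model = PLSRegression(X, Y)
    >>> res = model.fit(n_components=2)
    >>> res.coefficients.shape
    (5, 7)
    """

    def __init__(self, X, Y, x_names=None, y_names=None):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.ndim != 2 or Y.ndim != 2:
            raise ValueError("X and Y must be 2-D")
        if X.shape[0] != Y.shape[0]:
            raise ValueError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
        self.X = X
        self.Y = Y
        self.nobs, self.m = X.shape
        self.p = Y.shape[1]
        self.x_names = list(x_names) if x_names is not None else [f"X{j+1}" for j in range(self.m)]
        self.y_names = list(y_names) if y_names is not None else [f"Y{j+1}" for j in range(self.p)]

    @classmethod
    def from_dataset(cls, ds) -> "PLSRegression":
        """Build the model from a :class:`~firefit.dataset.FitnessDataset`."""
        return cls(ds.X, ds.Y, x_names=ds.x_names, y_names=ds.y_names)

    @property
    def max_components(self) -> int:
        return min(self.nobs - 1, self.m)

    def fit(self, n_components: int) -> "PLSResults":
        """Fit with a fixed number of components.

        Standardizes both blocks, runs ``n_components`` extract/deflate
        cycles, and accumulates the original-units coefficient matrix.
        """
        h = int(n_components)
        if not 1 <= h <= self.max_components:
            raise ValueError(
                f"n_components must be in [1, {self.max_components}] "
                f"for n={self.nobs}, m={self.m}; got {h}"
            )
        E, x_mean, x_scale = standardize(self.X, names=self.x_names)
        F, y_mean, y_scale = standardize(self.Y, names=self.y_names)

        W = np.empty((self.m, h))
        T = np.empty((self.nobs, h))
        U = np.empty((self.nobs, h))
        A = np.empty((self.m, h))  # x-loadings alpha
        C = np.empty((self.p, h))  # y-loadings beta
        for a in range(h):
            w, t, u, alpha, beta = extract_component(E, F)
            W[:, a], T[:, a], U[:, a], A[:, a], C[:, a] = w, t, u, alpha, beta
            E, F = deflate(E, F, t, alpha, beta)

        # T = Z_x @ R with R = W (A'W)^{-1}; standardized coefficients R C'.
        R = W @ np.linalg.inv(A.T @ W)
        coef_std = R @ C.T
        B = (coef_std / x_scale[:, None]) * y_scale[None, :]
        b0 = y_mean - x_mean @ B
        return PLSResults(
            model=self,
            n_components=h,
            weights=W,
            x_scores=T,
            y_scores=U,
            x_loadings=A,
            y_loadings=C,
            x_mean=x_mean,
            x_scale=x_scale,
            y_mean=y_mean,
            y_scale=y_scale,
            coefficients=B,
            intercept=b0,
        )


@dataclass
class PLSResults:
    """Fitted PLS regression.

    Attributes
    ----------
    weights : ndarray (m, h)
        Unit-norm predictor weight vectors, one column per component.
    x_scores, y_scores : ndarray (n, h)
        Training score vectors t_a and u_a.
    x_loadings, y_loadings : ndarray (m, h) / (p, h)
        Least-squares loadings alpha_a and beta_a on the scores.
    x_mean, x_scale, y_mean, y_scale : ndarray
        Autoscaling parameters estimated on the training data.
    coefficients : ndarray (m, p)
        Original-units coefficient matrix B.
    intercept : ndarray (p,)
        Original-units intercept b0 so that ``Y_hat = X B + b0``.
    """

    model: PLSRegression
    n_components: int
    weights: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    coefficients: np.ndarray
    intercept: np.ndarray

    @property
    def coefficients_standardized(self) -> np.ndarray:
        """Coefficient matrix between autoscaled X and autoscaled Y."""
        return (self.coefficients * self.x_scale[:, None]) / self.y_scale[None, :]

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)

    @property
    def resid(self) -> np.ndarray:
        return self.model.Y - self.fittedvalues

    def predict(self, X_new) -> np.ndarray:
        """Predict responses (original units) for new predictor rows."""
        X_new = np.asarray(X_new, dtype=float)
        one_row = X_new.ndim == 1
        if one_row:
            X_new = X_new[None, :]
        if X_new.shape[1] != self.model.m:
            raise ValueError(f"expected {self.model.m} predictor columns, got {X_new.shape[1]}")
        out = X_new @ self.coefficients + self.intercept
        return out[0] if one_row else out

    def explained_variance(self):
        """Fraction of autoscaled X- and Y-variance captured per component."""
        Zx, *_ = standardize(self.model.X, self.x_mean, self.x_scale)
        Zy, *_ = standardize(self.model.Y, self.y_mean, self.y_scale)
        ssx = np.linalg.norm(Zx) ** 2
        ssy = np.linalg.norm(Zy) ** 2
        tt = np.sum(self.x_scores**2, axis=0)
        var_x = tt * np.sum(self.x_loadings**2, axis=0) / ssx
        var_y = tt * np.sum(self.y_loadings**2, axis=0) / ssy
        return var_x, var_y

    def summary(self) -> str:
        """Plain-text fit summary (component variances and coefficients)."""
        var_x, var_y = self.explained_variance()
        lines = [
            "Partial Least-Squares Regression Results",
            "=" * 56,
            f"No. observations: {self.model.nobs:>6}    Components: {self.n_components}",
            f"No. predictors:   {self.model.m:>6}    No. responses: {self.model.p}",
            "",
            "Component   var(X) expl.   var(Y) expl.",
        ]
        for a in range(self.n_components):
            lines.append(f"{a + 1:>9}   {var_x[a]:>12.4f}   {var_y[a]:>12.4f}")
        lines += ["", "Coefficients (original units):"]
        header = "          " + "".join(f"{name:>12}" for name in self.model.y_names)
        lines.append(header)
        for j, name in enumerate(self.model.x_names):
            row = "".join(f"{self.coefficients[j, k]:>12.4g}" for k in range(self.model.p))
            lines.append(f"{name:<10}{row}")
        row = "".join(f"{self.intercept[k]:>12.4g}" for k in range(self.model.p))
        lines.append(f"{'intercept':<10}{row}")
        return "\n".join(lines)

    # -- plain-text serialization ------------------------------------------

    def to_text(self) -> str:
        """Serialize the fit to a diffable key-value text block."""

        def mat(name, M):
            M = np.atleast_2d(M)
            body = "\n".join(" ".join(repr(float(v)) for v in row) for row in M)
            return f"{name} {M.shape[0]} {M.shape[1]}\n{body}"

        parts = [
            f"n_components {self.n_components}",
            f"x_names {' '.join(self.model.x_names)}",
            f"y_names {' '.join(self.model.y_names)}",
            mat("weights", self.weights),
            mat("x_loadings", self.x_loadings),
            mat("y_loadings", self.y_loadings),
            mat("x_mean", self.x_mean),
            mat("x_scale", self.x_scale),
            mat("y_mean", self.y_mean),
            mat("y_scale", self.y_scale),
            mat("coefficients", self.coefficients),
            mat("intercept", self.intercept),
        ]
        return "\n".join(parts) + "\n"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())


class LoadedPLSResults:
    """Read-only fit loaded from :meth:`PLSResults.to_text` output.

    Carries the coefficient form only (enough for prediction and
    sensitivity analysis); training scores are not serialized.
    """

    def __init__(self, text: str):
        lines = [ln for ln in text.splitlines() if ln.strip()]
        i = 0
        fields: dict[str, np.ndarray] = {}
        while i < len(lines):
            head = lines[i].split()
            key = head[0]
            if key == "n_components":
                self.n_components = int(head[1])
                i += 1
            elif key in ("x_names", "y_names"):
                setattr(self, key, head[1:])
                i += 1
            else:
                nrow, ncol = int(head[1]), int(head[2])
                rows = [list(map(float, lines[i + 1 + r].split())) for r in range(nrow)]
                fields[key] = np.array(rows).reshape(nrow, ncol)
                i += 1 + nrow
        self.weights = fields["weights"]
        self.x_loadings = fields["x_loadings"]
        self.y_loadings = fields["y_loadings"]
        self.x_mean = fields["x_mean"][0]
        self.x_scale = fields["x_scale"][0]
        self.y_mean = fields["y_mean"][0]
        self.y_scale = fields["y_scale"][0]
        self.coefficients = fields["coefficients"]
        self.intercept = fields["intercept"][0]

    @classmethod
    def load(cls, path) -> "LoadedPLSResults":
        with open(path) as fh:
            return cls(fh.read())

    def predict(self, X_new) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        one_row = X_new.ndim == 1
        if one_row:
            X_new = X_new[None, :]
        if X_new.shape[1] != self.coefficients.shape[0]:
            raise ValueError(
                f"expected {self.coefficients.shape[0]} predictor columns, got {X_new.shape[1]}"
            )
        out = X_new @ self.coefficients + self.intercept
        return out[0] if one_row else out


def fit_plsr(X, Y, n_components, x_names=None, y_names=None) -> PLSResults:
    """Functional shorthand for ``PLSRegression(X, Y).fit(n_components)``.

    ``X`` may also be a :class:`~firefit.dataset.FitnessDataset`, in which
    case ``Y`` must be None.
    """
    if hasattr(X, "X") and hasattr(X, "Y"):
        if Y is not None:
            raise ValueError("pass either a dataset or two matrices, not both")
        return PLSRegression.from_dataset(X).fit(n_components)
    return PLSRegression(X, Y, x_names=x_names, y_names=y_names).fit(n_components)
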