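"""Synthetic cohort generator with a low-rank linear latent structure.

No raw measurements were ever published for the 20-firefighter cohort, so
every downstream stage is exercised on synthetic data built to have the
statistical structure the analysis assumes: a small number ``l`` of latent
fitness factors drive both the predictor and the response block linearly,
plus independent measurement noise.

For each subject a latent score vector ``s ~ N(0, I_l)`` is drawn; the
standardized blocks are

    X_std = S P' + noise_sd_x * N_x,     Y_std = S Q' + noise_sd_y * N_y

with loading matrices P (5 x l) and Q (7 x l). Each predictor column is then
mapped affinely onto its target (min, max) range — by default the published
cohort ranges — so that the empirical minimum and maximum match the targets
exactly, making summary tables deterministic. Each response column is mapped
affinely onto [0.8·base, 1.2·base] around a per-task baseline time, keeping
times strictly positive while preserving the linear latent structure.

The default loadings encode two factors: a general-fitness factor (raises
aerobic capacity and power, shortens all task times) and a body-size factor
(raises weight and body fat; slows climbing tasks, mildly speeds the loaded
carries). They are a modelling choice, not an estimate from the study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .dataset import FitnessDataset
from .reference import COHORT_X_MAX, COHORT_X_MIN, PREDICTOR_NAMES, RESPONSE_NAMES

__all__ = ["SyntheticConfig", "generate_dataset", "true_linear_map"]


def _unit_rows(rows) -> np.ndarray:
    M = np.asarray(rows, dtype=float)
    return M / np.linalg.norm(M, axis=1, keepdims=True)


def _default_P() -> np.ndarray:
    # rows: weight, VO2max, body fat, upper power, lower power
    # cols: (general fitness, body size); rows normalized to unit norm
    return _unit_rows(
        [
            [0.25, 0.97],
            [0.95, -0.31],
            [-0.55, 0.60],
            [0.80, 0.55],
            [0.85, 0.50],
        ]
    )


def _default_Q() -> np.ndarray:
    # rows: task times Y1..Y7; fitness shortens every task, size slows the
    # climbing tasks (Y1, Y4, Y6) and mildly speeds the loaded carries
    return _unit_rows(
        [
            [-0.75, 0.55],
            [-0.90, -0.30],
            [-0.85, -0.35],
            [-0.80, 0.50],
            [-0.90, -0.25],
            [-0.85, 0.45],
            [-0.90, -0.20],
        ]
    )


#: default per-task baseline completion times, seconds (plausible magnitudes
#: for the seven drills; the study published no response summaries)
_DEFAULT_RESPONSE_BASE = (25.0, 90.0, 15.0, 120.0, 180.0, 1500.0, 20.0)


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic cohort generator.

    Attributes
    ----------
    n : int
        Subjects to draw (default 20, the study's cohort size).
    latent_rank : int
        Number of latent factors l, 1..5 (default 2).
    P, Q : ndarray
        Predictor (5 x l) and response (7 x l) loading matrices.
    noise_sd_x, noise_sd_y : float or ndarray
        Per-column measurement-noise scales on the standardized blocks
        (default 0.3).
    predictor_ranges : ndarray (5, 2)
        Target (min, max) per predictor; defaults to the published cohort
        minima/maxima.
    response_base : ndarray (7,)
        Baseline task times in seconds; generated times span ±20% around
        them.
    seed : int
        Seed of the generator's random stream.
    """

    n: int = 20
    latent_rank: int = 2
    P: np.ndarray = field(default_factory=_default_P)
    Q: np.ndarray = field(default_factory=_default_Q)
    noise_sd_x: float = 0.3
    noise_sd_y: float = 0.3
    predictor_ranges: np.ndarray = field(
        default_factory=lambda: np.column_stack([COHORT_X_MIN, COHORT_X_MAX])
    )
    response_base: np.ndarray = field(
        default_factory=lambda: np.asarray(_DEFAULT_RESPONSE_BASE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.predictor_ranges = np.asarray(self.predictor_ranges, dtype=float)
        self.response_base = np.asarray(self.response_base, dtype=float)
        l = self.latent_rank
        if not 1 <= l <= 5:
            raise ValueError(f"latent_rank must be in 1..5, got {l}")
        if self.n < l + 2:
            raise ValueError(f"need n >= latent_rank + 2, got n={self.n}, l={l}")
        if self.P.shape != (5, l) or self.Q.shape != (7, l):
            raise ValueError(
                f"P must be 5x{l} and Q 7x{l}; got {self.P.shape} and {self.Q.shape}"
            )
        if np.linalg.matrix_rank(self.P) < l:
            raise ValueError("P is rank-deficient: latent factors are collinear in X")
        if np.any(np.atleast_1d(self.noise_sd_x) < 0) or np.any(np.atleast_1d(self.noise_sd_y) < 0):
            raise ValueError("noise scales must be non-negative")
        if self.predictor_ranges.shape != (5, 2):
            raise ValueError("predictor_ranges must be 5 x (min, max)")
        if np.any(self.predictor_ranges[:, 0] >= self.predictor_ranges[:, 1]):
            raise ValueError("every predictor range needs min < max")
        if self.response_base.shape != (7,) or np.any(self.response_base <= 0):
            raise ValueError("response_base must be 7 positive times")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        """Load a config from a YAML key-value file (missing keys default)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "n": int(self.n),
            "latent_rank": int(self.latent_rank),
            "P": self.P.tolist(),
            "Q": self.Q.tolist(),
            "noise_sd_x": float(np.atleast_1d(self.noise_sd_x)[0])
            if np.isscalar(self.noise_sd_x) or np.ndim(self.noise_sd_x) == 0
            else np.asarray(self.noise_sd_x).tolist(),
            "noise_sd_y": float(np.atleast_1d(self.noise_sd_y)[0])
            if np.isscalar(self.noise_sd_y) or np.ndim(self.noise_sd_y) == 0
            else np.asarray(self.noise_sd_y).tolist(),
            "predictor_ranges": self.predictor_ranges.tolist(),
            "response_base": self.response_base.tolist(),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _map_to_range(col: np.ndarray, lo: float, hi: float, what: str) -> np.ndarray:
    cmin, cmax = col.min(), col.max()
    if cmax - cmin <= 0:
        raise ValueError(
            f"cannot map constant {what} column onto ({lo}, {hi}); "
            "increase noise or check the loading matrix"
        )
    return lo + (col - cmin) * (hi - lo) / (cmax - cmin)


def generate_dataset(cfg: SyntheticConfig) -> FitnessDataset:
    """Draw a synthetic cohort; deterministic for a fixed config seed."""
    rng = np.random.default_rng(cfg.seed)
    S = rng.standard_normal((cfg.n, cfg.latent_rank))
    Xs = S @ cfg.P.T + np.atleast_1d(cfg.noise_sd_x) * rng.standard_normal((cfg.n, 5))
    Ys = S @ cfg.Q.T + np.atleast_1d(cfg.noise_sd_y) * rng.standard_normal((cfg.n, 7))

    X = np.empty_like(Xs)
    for j in range(5):
        lo, hi = cfg.predictor_ranges[j]
        X[:, j] = _map_to_range(Xs[:, j], lo, hi, PREDICTOR_NAMES[j])
    Y = np.empty_like(Ys)
    for j in range(7):
        base = cfg.response_base[j]
        Y[:, j] = _map_to_range(Ys[:, j], 0.8 * base, 1.2 * base, RESPONSE_NAMES[j])

    ids = tuple(f"S{i+1:02d}" for i in range(cfg.n))
    return FitnessDataset(subject_ids=ids, X=X, Y=Y)


def true_linear_map(cfg: SyntheticConfig) -> np.ndarray:
    """Implied 5x7 coefficient matrix on the generator's standardized scale.

    The least-squares map from noise-free standardized predictors to
    noise-free standardized responses: with ``x = P s`` and ``y = Q s``,
    the map is ``Q P⁺``, returned as the 5x7 matrix ``(Q P⁺)' = P⁺' Q'``
    for direct comparison with fitted coefficient matrices.
    """
    return (cfg.Q @ np.linalg.pinv(cfg.P)).T
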