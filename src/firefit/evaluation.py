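"""Train/test splitting, leave-one-out evaluation and accuracy reporting.

The study design holds out 20% of subjects (4 of 20) as a test set and
summarizes predictive quality with a leave-one-out "prediction accuracy"
percentage. The accuracy metric itself is a modelling choice here: the
default is 100·(1 − mean absolute relative error), i.e. the mean percentage
closeness of predicted to observed task times, floored at 0. Two
alternatives (normalized-RMSE-based and R²·100) are available behind the
``metric`` flag. Observed times must be strictly positive for the relative
metrics to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import FitnessDataset
from .pls import PLSRegression
from .selection import loo_predictions

__all__ = [
    "EvaluationReport",
    "split_dataset",
    "prediction_accuracy",
    "loo_report",
]

ACCURACY_METRICS = ("mare", "nrmse", "r2")


def split_dataset(ds: FitnessDataset, test_fraction: float = 0.2, seed: int | None = None):
    """Random train/test partition of subjects.

    The test-set size is ``round(n * test_fraction)`` with a minimum of one
    row. Returns ``(train, test, train_idx, test_idx)``; reproducible for a
    fixed seed.
    """
    if not 0 < test_fraction <= 0.5:
        raise ValueError(f"test_fraction must be in (0, 0.5], got {test_fraction}")
    n = ds.n
    if n < 5:
        raise ValueError(f"need at least 5 subjects to split, got {n}")
    n_test = max(1, int(round(n * test_fraction)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return ds.take(train_idx), ds.take(test_idx), train_idx, test_idx


def prediction_accuracy(Y, Y_hat, metric: str = "mare"):
    """Per-response and overall accuracy of predictions, in percent.

    ``mare`` (default): ``100 * (1 - mean_i |yhat - y| / y)`` per response.
    ``nrmse``: ``100 * (1 - RMSE / mean(y))`` per response.
    ``r2``: ``100 * R²`` per response.
    All floored at 0; overall is the mean over responses.
    """
    Y = np.asarray(Y, dtype=float)
    Y_hat = np.asarray(Y_hat, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
        Y_hat = np.asarray(Y_hat, float).reshape(Y.shape)
    if Y.shape != Y_hat.shape:
        raise ValueError(f"shape mismatch: observed {Y.shape}, predicted {Y_hat.shape}")
    if metric in ("mare", "nrmse") and np.any(Y <= 0):
        raise ValueError("observed values must be strictly positive for relative metrics")
    if metric == "mare":
        per = 100.0 * (1.0 - np.mean(np.abs(Y_hat - Y) / Y, axis=0))
    elif metric == "nrmse":
        rmse = np.sqrt(np.mean((Y_hat - Y) ** 2, axis=0))
        per = 100.0 * (1.0 - rmse / Y.mean(axis=0))
    elif metric == "r2":
        ss_res = np.sum((Y - Y_hat) ** 2, axis=0)
        ss_tot = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
        per = 100.0 * (1.0 - ss_res / ss_tot)
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {ACCURACY_METRICS}")
    per = np.maximum(per, 0.0)
    return per, float(per.mean())


@dataclass
class EvaluationReport:
    """Accuracy summary of a fitted pipeline.

    Leave-one-out accuracies cover the full dataset; the split accuracies
    (in-sample on the training rows, held-out on the test rows) are present
    only when an 80/20 split was requested.
    """

    metric: str
    n_components: int
    loo_per_response: np.ndarray
    loo_overall: float
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None
    train_per_response: np.ndarray | None = None
    train_overall: float | None = None
    test_per_response: np.ndarray | None = None
    test_overall: float | None = None
    y_names: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        cols = list(self.y_names) or [f"Y{k+1}" for k in range(len(self.loo_per_response))]
        rows = {"loo": self.loo_per_response}
        if self.train_per_response is not None:
            rows["train"] = self.train_per_response
        if self.test_per_response is not None:
            rows["test"] = self.test_per_response
        df = pd.DataFrame(rows, index=cols).T
        df["overall"] = [
            self.loo_overall,
            *([self.train_overall] if self.train_per_response is not None else []),
            *([self.test_overall] if self.test_per_response is not None else []),
        ]
        return df


def loo_report(
    ds: FitnessDataset,
    n_components: int,
    metric: str = "mare",
    test_fraction: float | None = None,
    seed: int | None = None,
) -> EvaluationReport:
    """Leave-one-out accuracy report, optionally with an 80/20 split.

    Every row's prediction comes from a model fitted without that row. When
    ``test_fraction`` is given, the model is additionally refitted on the
    training rows alone and scored in-sample (training accuracy) and on the
    held-out rows (test accuracy).
    """
    pred = loo_predictions(ds.X, ds.Y, n_components)
    per, overall = prediction_accuracy(ds.Y, pred, metric=metric)
    report = EvaluationReport(
        metric=metric,
        n_components=n_components,
        loo_per_response=per,
        loo_overall=overall,
        y_names=tuple(ds.y_names),
    )
    if test_fraction is not None:
        train, test, train_idx, test_idx = split_dataset(ds, test_fraction, seed)
        res = PLSRegression.from_dataset(train).fit(n_components)
        tr_per, tr_all = prediction_accuracy(train.Y, res.predict(train.X), metric=metric)
        te_per, te_all = prediction_accuracy(test.Y, res.predict(test.X), metric=metric)
        report.train_idx = train_idx
        report.test_idx = test_idx
        report.train_per_response = tr_per
        report.train_overall = tr_all
        report.test_per_response = te_per
        report.test_overall = te_all
    return report
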