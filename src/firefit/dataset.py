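"""Dataset container, CSV ingestion and per-predictor summary statistics.

The canonical table layout is one row per subject with a ``subject`` label
column, five predictor columns ``X1..X5`` (weight, VO2max, body-fat %,
upper- and lower-body peak power) and seven response columns ``Y1..Y7``
(task completion times, seconds). All values are physical measurements and
therefore strictly positive; zeros and negatives are data errors, not
warnings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import PREDICTOR_NAMES, PREDICTOR_UNITS, RESPONSE_NAMES, RESPONSE_UNITS


class DatasetError(ValueError):
    """Raised when a table fails the dataset contract."""


@dataclass(frozen=True)
class FitnessDataset:
    """A subjects-by-variables fitness/performance table.

    Parameters
    ----------
    subject_ids : tuple of str
        Opaque per-row labels, order preserved.
    X : ndarray, shape (n, m)
        Predictor block; units per column: kg, mL/kg/min, %, W, W.
    Y : ndarray, shape (n, p)
        Response block; task completion times in seconds.
    x_names, y_names : tuple of str
        Ordered variable labels (default X1..X5 / Y1..Y7).
    """

    subject_ids: tuple[str, ...]
    X: np.ndarray
    Y: np.ndarray
    x_names: tuple[str, ...] = PREDICTOR_NAMES
    y_names: tuple[str, ...] = RESPONSE_NAMES
    x_units: tuple[str, ...] = PREDICTOR_UNITS
    y_units: tuple[str, ...] = RESPONSE_UNITS

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "subject_ids", tuple(str(s) for s in self.subject_ids))
        if X.ndim != 2 or Y.ndim != 2:
            raise DatasetError("X and Y must be 2-D matrices")
        n = X.shape[0]
        if Y.shape[0] != n or len(self.subject_ids) != n:
            raise DatasetError(
                f"row counts disagree: {len(self.subject_ids)} subjects, "
                f"X has {n} rows, Y has {Y.shape[0]} rows"
            )
        if n < 2:
            raise DatasetError(f"need at least 2 subjects, got {n}")
        if X.shape[1] != len(self.x_names):
            raise DatasetError(
                f"X has {X.shape[1]} columns but {len(self.x_names)} predictor names"
            )
        if Y.shape[1] != len(self.y_names):
            raise DatasetError(
                f"Y has {Y.shape[1]} columns but {len(self.y_names)} response names"
            )
        for names, M, block in ((self.x_names, X, "predictor"), (self.y_names, Y, "response")):
            if not np.all(np.isfinite(M)):
                i, j = np.argwhere(~np.isfinite(M))[0]
                raise DatasetError(
                    f"non-finite {block} value at row {i} ({self.subject_ids[i]}), "
                    f"column {names[j]}"
                )
            if np.any(M <= 0):
                i, j = np.argwhere(M <= 0)[0]
                raise DatasetError(
                    f"non-positive {block} value {M[i, j]} at row {i} "
                    f"({self.subject_ids[i]}), column {names[j]}"
                )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def p(self) -> int:
        return self.Y.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a DataFrame with a leading ``subject`` column."""
        df = pd.DataFrame({"subject": list(self.subject_ids)})
        for j, name in enumerate(self.x_names):
            df[name] = self.X[:, j]
        for j, name in enumerate(self.y_names):
            df[name] = self.Y[:, j]
        return df

    def take(self, indices) -> "FitnessDataset":
        """Row subset (used by train/test splitting and leave-one-out folds)."""
        idx = np.asarray(indices, dtype=int)
        return FitnessDataset(
            subject_ids=tuple(self.subject_ids[i] for i in idx),
            X=self.X[idx],
            Y=self.Y[idx],
            x_names=self.x_names,
            y_names=self.y_names,
            x_units=self.x_units,
            y_units=self.y_units,
        )


@dataclass(frozen=True)
class PredictorSummary:
    """Per-predictor mean, max, min and range, in the predictor's units.

    ``x_dif`` is always recomputed as ``x_max - x_min``.
    """

    x_names: tuple[str, ...]
    x_ave: np.ndarray
    x_max: np.ndarray
    x_min: np.ndarray
    x_dif: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for name in ("x_ave", "x_max", "x_min"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "x_dif", self.x_max - self.x_min)
        if not (len(self.x_ave) == len(self.x_max) == len(self.x_min) == len(self.x_names)):
            raise DatasetError("summary fields must have one entry per predictor")
        bad = (self.x_min > self.x_ave) | (self.x_ave > self.x_max)
        if np.any(bad):
            j = int(np.flatnonzero(bad)[0])
            raise DatasetError(
                f"inconsistent summary for {self.x_names[j]}: "
                f"min {self.x_min[j]}, ave {self.x_ave[j]}, max {self.x_max[j]}"
            )

    def to_frame(self) -> pd.DataFrame:
        """Summary table with rows X_ave, X_max, X_min, X_dif."""
        return pd.DataFrame(
            [self.x_ave, self.x_max, self.x_min, self.x_dif],
            index=["X_ave", "X_max", "X_min", "X_dif"],
            columns=list(self.x_names),
        )


def compute_summary(ds: FitnessDataset) -> PredictorSummary:
    """Per-predictor mean, maximum, minimum and range of a dataset."""
    return PredictorSummary(
        x_names=ds.x_names,
        x_ave=ds.X.mean(axis=0),
        x_max=ds.X.max(axis=0),
        x_min=ds.X.min(axis=0),
    )


def read_dataset(path, delimiter: str = ",") -> FitnessDataset:
    """Read a fitness dataset from delimited text.

    The header must name a ``subject`` column plus all of X1..X5 and Y1..Y7.
    Lines starting with ``#`` are treated as comments (pipeline outputs carry
    a fingerprint comment line). Rejects missing columns, non-numeric cells,
    non-positive values and tables with fewer than two rows, naming the
    offending row/column.
    """
    df = pd.read_csv(path, sep=delimiter, comment="#", float_precision="round_trip")
    required = ["subject", *PREDICTOR_NAMES, *RESPONSE_NAMES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing required column(s): {', '.join(missing)}")
    subject_ids = tuple(str(s) for s in df["subject"])
    blocks = {}
    for key, names in (("X", PREDICTOR_NAMES), ("Y", RESPONSE_NAMES)):
        numeric = df[list(names)].apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & df[list(names)].notna()
        if bad.to_numpy().any():
            i = int(np.argwhere(bad.to_numpy())[0][0])
            j = int(np.argwhere(bad.to_numpy())[0][1])
            raise DatasetError(
                f"{path}: non-numeric value {df[list(names)].iloc[i, j]!r} "
                f"in row {i}, column {names[j]}"
            )
        if numeric.isna().to_numpy().any():
            i, j = np.argwhere(numeric.isna().to_numpy())[0]
            raise DatasetError(f"{path}: missing value in row {i}, column {names[j]}")
        blocks[key] = numeric.to_numpy(dtype=float)
    return FitnessDataset(subject_ids=subject_ids, X=blocks["X"], Y=blocks["Y"])


def write_dataset(ds: FitnessDataset, path, delimiter: str = ",", header: str | None = None) -> None:
    """Write a dataset as delimited text readable by :func:`read_dataset`.

    Values are written with 17 significant digits, enough to reproduce every
    float bit-for-bit on re-read. ``header`` adds a leading ``#`` comment
    line.
    """
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        ds.to_frame().to_csv(fh, sep=delimiter, index=False, float_format="%.17g")
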