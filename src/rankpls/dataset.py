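"""Tabular container for ranked regression problems and its CSV round trip.

A :class:`RankedDataset` holds an ``n x p`` predictor matrix ``Z`` (ordinal
integer codes or continuous values) together with an ordinal response ``y``
coded as consecutive integers ``1..K``. All modelling entry points in the
package consume this container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = ["RankedDataset", "read_dataset", "write_dataset"]


@dataclass
class RankedDataset:
    """Predictor matrix plus ordinal response.

    Parameters
    ----------
    Z : ndarray of shape (n, p)
        Predictor values; ordinal codes or continuous measurements.
    y : ndarray of shape (n,)
        Ordinal response codes. Conventionally consecutive integers ``1..K``.
    column_names : sequence of str, optional
        Predictor names; defaults to ``z1..zp``.
    level_labels : sequence of str, optional
        Human-readable name per response rank (lowest rank first).
    """

    Z: np.ndarray
    y: np.ndarray
    column_names: Sequence[str] | None = None
    level_labels: Sequence[str] | None = None
    response_name: str = "y"

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.y = np.asarray(self.y)
        if self.Z.ndim != 2:
            raise InvalidInputError("Z must be a 2-D matrix")
        if self.y.ndim != 1 or self.y.shape[0] != self.Z.shape[0]:
            raise InvalidInputError(
                f"y has shape {self.y.shape}, expected ({self.Z.shape[0]},)"
            )
        if self.column_names is None:
            self.column_names = [f"z{j + 1}" for j in range((self.Z.shape[1]))]
        else:
            self.column_names = [str(c) for c in self.column_names]
            if len(self.column_names) != self.Z.shape[1]:
                raise InvalidInputError("column_names length does not match p")

    # -- basic geometry ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    @property
    def n_levels(self) -> int:
        """Number of distinct response ranks K."""
        return int(np.unique(self.y).size)

    def validate(self) -> None:
        """Check the modelling invariants (no NaN, at least two response levels)."""
        if np.isnan(self.Z).any() or pd.isna(self.y).any():
            raise InvalidInputError("dataset contains missing values")
        if self.n_levels < 2:
            raise InvalidInputError("response takes fewer than 2 distinct levels")

    def restrict_columns(self, indices: Sequence[int]) -> "RankedDataset":
        """Return a copy keeping only the given predictor columns, order preserved."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            Z=self.Z[:, idx],
            column_names=[self.column_names[j] for j in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Z, columns=list(self.column_names))
        df[self.response_name] = self.y
        return df

    def __eq__(self, other: object) -> bool:  # field-for-field, used by round-trip tests
        if not isinstance(other, RankedDataset):
            return NotImplemented
        return (
            np.array_equal(self.Z, other.Z)
            and np.array_equal(np.asarray(self.y, float), np.asarray(other.y, float))
            and list(self.column_names) == list(other.column_names)
            and (self.level_labels is None) == (other.level_labels is None)
            and (
                self.level_labels is None
                or list(self.level_labels) == list(other.level_labels)
            )
        )


def write_dataset(data: RankedDataset, path: str | Path) -> Path:
    """Write the dataset as a headed CSV, response in column ``data.response_name``."""
    path = Path(path)
    data.to_frame().to_csv(path, index=False)
    return path


def read_dataset(
    path: str | Path,
    response: str = "y",
    level_labels: Sequence[str] | None = None,
) -> RankedDataset:
    """Read a headed CSV into a :class:`RankedDataset`.

    Rows containing missing cells are dropped (the count is logged). Non-numeric
    cells and a missing response column raise :class:`FormatError` naming the
    offending column.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if response not in df.columns:
        raise FormatError(f"{path}: response column {response!r} not found")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise FormatError(
                    f"{path}: non-numeric value in column {col!r}, row {row}"
                )
            df[col] = coerced
    n_before = len(df)
    df = df.dropna(axis=0)
    dropped = n_before - len(df)
    if dropped:
        logger.info("read_dataset(%s): dropped %d rows with missing values", path, dropped)
    y = df[response].to_numpy()
    if np.allclose(y, np.round(y)):
        y = y.astype(int)
    Z = df.drop(columns=[response]).to_numpy(dtype=float)
    return RankedDataset(
        Z=Z,
        y=y,
        column_names=[c for c in df.columns if c != response],
        level_labels=level_labels,
        response_name=response,
    )
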