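"""Filter-based variable importance and retention.

Three filters are provided, each producing a nonnegative per-variable
importance score and a retained set:

* **LW** — loading weights: per component the absolute weights are normalized
  by their maximum, then aggregated across components (max by default), so the
  strongest variable in some component scores 1.
* **RC** — regression coefficients: ``|beta_j|`` on the standardized predictor
  scale, with ``beta = W (P'W)^{-1} q``.
* **SMC** — significance multivariate correlation: an F-type ratio per
  variable. Each predictor column is decomposed into its projection on the
  normalized fitted-response direction ``u = Z beta / ||Z beta||`` and the
  orthogonal remainder; the importance is
  ``(z_j'u)^2 / (||z_j - (z_j'u) u||^2 / (n - 2))``, i.e. mean-square
  regression over mean-square residual with 1 and n-2 degrees of freedom.
  Under independence this is approximately F(1, n-2) distributed, which the
  default 95th-percentile threshold exploits.

Retention is threshold-based (``importance >= threshold``), with an optional
fixed top-k override.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import RankedDataset
from .exceptions import ConfigError, EmptySelectionError
from .pls_core import PLSModel

logger = logging.getLogger(__name__)

__all__ = [
    "SELECTION_METHODS",
    "SelectionScores",
    "lw_importance",
    "rc_importance",
    "smc_importance",
    "apply_selection",
    "importance_table",
]

#: Canonical selection-method names ("none" = no selection).
SELECTION_METHODS = ("none", "lw", "rc", "smc")

_SMC_CAP = 1e12  # sentinel for an exactly collinear column (MS_res = 0)


@dataclass
class SelectionScores:
    """Per-variable importance for one filter method plus the retained set."""

    method: str
    importance: np.ndarray
    retained: np.ndarray
    threshold: float
    column_names: list[str]

    @property
    def empty(self) -> bool:
        return self.retained.size == 0

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        self.retained = np.asarray(self.retained, dtype=int)
        if self.empty:
            logger.warning("%s selection retained no variables", self.method)


def _retain(importance: np.ndarray, threshold: float, top_k: int | None) -> tuple[np.ndarray, float]:
    if top_k is not None:
        if not 1 <= top_k <= importance.size:
            raise ConfigError(f"top_k={top_k} outside 1..p")
        order = np.argsort(-importance, kind="stable")
        kept = np.sort(order[:top_k])
        return kept, float(importance[order[top_k - 1]])
    return np.flatnonzero(importance >= threshold), float(threshold)


def lw_importance(
    model: PLSModel,
    threshold: float = 0.5,
    aggregate: str = "max",
    top_k: int | None = None,
) -> SelectionScores:
    """Loading-weight importance: |w_{a,j}| / max_k |w_{a,k}| aggregated over components."""
    A = np.abs(model.W)
    colmax = A.max(axis=0)
    colmax = np.where(colmax == 0, 1.0, colmax)
    per_comp = A / colmax
    if aggregate == "max":
        imp = per_comp.max(axis=1)
    elif aggregate == "mean":
        imp = per_comp.mean(axis=1)
    else:
        raise ConfigError(f"unknown LW aggregate {aggregate!r}")
    kept, thr = _retain(imp, threshold, top_k)
    return SelectionScores("lw", imp, kept, thr, list(model.column_names))


def rc_importance(
    model: PLSModel,
    threshold: float | None = None,
    top_k: int | None = None,
) -> SelectionScores:
    """Regression-coefficient importance: |beta_j| on standardized predictors.

    Default threshold: the median absolute coefficient.
    """
    imp = np.abs(model.beta_hat)
    if threshold is None:
        threshold = float(np.median(imp))
    kept, thr = _retain(imp, threshold, top_k)
    return SelectionScores("rc", imp, kept, thr, list(model.column_names))


def smc_importance(
    model: PLSModel,
    data: RankedDataset,
    threshold: float | None = None,
    top_k: int | None = None,
) -> SelectionScores:
    """Significance-multivariate-correlation importance (F-type ratio).

    Default threshold: the 0.95 quantile of F(1, n-2).
    """
    n = data.n
    if n <= 2:
        raise ConfigError("SMC needs n > 2")
    Zc = (np.asarray(data.Z, float) - model.centers) / model.scales
    fitted = Zc @ model.beta_hat
    norm = float(np.linalg.norm(fitted))
    names = list(model.column_names)
    if norm == 0.0:
        logger.warning("SMC: zero regression direction; empty selection")
        imp = np.zeros(data.p)
        return SelectionScores("smc", imp, np.array([], dtype=int),
                               np.inf if threshold is None else threshold, names)
    u = fitted / norm
    # standardize columns so the residual scale matches the F reference
    sd = Zc.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    Zs = (Zc - Zc.mean(axis=0)) / sd
    proj = Zs.T @ u
    ss_tot = (Zs**2).sum(axis=0)
    ss_reg = proj**2
    ss_res = np.maximum(ss_tot - ss_reg, 0.0)
    ms_res = ss_res / (n - 2)
    with np.errstate(divide="ignore"):
        imp = np.where(ms_res > 0, ss_reg / np.where(ms_res > 0, ms_res, 1.0), _SMC_CAP)
    if (ms_res <= 0).any():
        logger.warning("SMC: %d columns exactly collinear with the regression "
                       "direction; importance capped", int((ms_res <= 0).sum()))
    if threshold is None:
        threshold = float(stats.f.ppf(0.95, 1, n - 2))
    kept, thr = _retain(imp, threshold, top_k)
    return SelectionScores("smc", imp, kept, thr, names)


def apply_selection(data: RankedDataset, scores: SelectionScores) -> RankedDataset:
    """Restrict the dataset to the retained columns, preserving order and names."""
    if scores.empty:
        raise EmptySelectionError(
            f"{scores.method} selection retained no variables "
            f"(threshold={scores.threshold:g})"
        )
    logger.info("%s selection retained %d of %d variables",
                scores.method, scores.retained.size, data.p)
    return data.restrict_columns(scores.retained)


def importance_table(scores: SelectionScores) -> pd.DataFrame:
    """Importance values as a tidy table (variable, method, importance, retained)."""
    kept = np.zeros(scores.importance.size, dtype=bool)
    kept[scores.retained] = True
    return pd.DataFrame({
        "variable": scores.column_names,
        "method": scores.method,
        "importance": scores.importance,
        "retained": kept,
    })


def write_importance(scores: SelectionScores, path: str | Path) -> Path:
    path = Path(path)
    importance_table(scores).to_csv(path, index=False)
    return path
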