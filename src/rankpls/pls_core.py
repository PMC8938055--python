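"""Generalized NIPALS partial least squares with pluggable loading weights.

The algorithm follows the classical univariate-response NIPALS recursion. For
component ``c = 1..C`` on the deflated data ``(Z_{c-1}, y_{c-1})``:

    w_c = association(Z_{c-1}, y_{c-1})          (unit-norm loading weight)
    t_c = Z_{c-1} w_c                            (score)
    p_c = Z_{c-1}' t_c / (t_c' t_c)              (Z-loading)
    q_c = y_{c-1}' t_c / (t_c' t_c)              (Y-loading)
    Z_c = Z_{c-1} - t_c p_c',  y_c = y_{c-1} - t_c q_c

with regression coefficients recovered as ``beta = W (P'W)^{-1} q`` and
intercept ``alpha = mean(y) - mean(Z) . beta``. The association defining ``w_c``
is pluggable: the standard covariance weight ``Z'y`` or any of the eight
rank-correlation measures in :mod:`rankpls.rank_assoc`.

Rank measures are invariant to strictly monotone transformations, so for the
first component they see the original ordinal codes; from the second component
on, the deflated (continuous) variables enter the rank measures through their
midranks, which pair counting applies implicitly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import RankedDataset
from .exceptions import ConfigError, FitError, InvalidInputError
from .rank_assoc import WEIGHT_MEASURES, weight_vector

logger = logging.getLogger(__name__)

__all__ = ["PLSModel", "fit_pls"]

_TOL = 1e-12


@dataclass
class PLSModel:
    """A fitted PLS regression model.

    Attributes
    ----------
    W, T, P : ndarray
        Loading weights (p x C), training scores (n x C) and Z-loadings (p x C).
    q : ndarray
        Y-loadings (C,).
    beta_hat : ndarray
        Regression coefficients on the preprocessed (centered/scaled) predictor
        scale.
    alpha_hat : float
        Intercept on the original response scale.
    centers, scales : ndarray
        Column preprocessing constants applied before fitting and prediction.
    """

    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    q: np.ndarray
    beta_hat: np.ndarray
    alpha_hat: float
    n_components: int
    measure: str
    centers: np.ndarray
    scales: np.ndarray
    y_mean: float
    column_names: list[str] = field(default_factory=list)
    truncated: bool = False
    requested_components: int = 0

    @property
    def rotation(self) -> np.ndarray:
        """Projection matrix R = W (P'W)^{-1} mapping preprocessed Z to scores."""
        PtW = self.P.T @ self.W
        try:
            return self.W @ np.linalg.inv(PtW)
        except np.linalg.LinAlgError:
            logger.warning("P'W singular; using pseudo-inverse")
            return self.W @ np.linalg.pinv(PtW)

    def _preprocess(self, Z_new: np.ndarray) -> np.ndarray:
        Z_new = np.asarray(Z_new, dtype=float)
        if Z_new.ndim == 1:
            Z_new = Z_new[None, :]
        if Z_new.shape[1] != self.W.shape[0]:
            raise InvalidInputError(
                f"expected {self.W.shape[0]} columns, got {Z_new.shape[1]}"
            )
        return (Z_new - self.centers) / self.scales

    def predict(self, Z_new: np.ndarray) -> np.ndarray:
        """Continuous predictions ``alpha + Z_new . beta`` on the response scale."""
        return self.y_mean + self._preprocess(Z_new) @ self.beta_hat

    def transform(self, Z_new: np.ndarray) -> np.ndarray:
        """Project new samples into score space; training rows reproduce ``T``."""
        return self._preprocess(Z_new) @ self.rotation

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "W": self.W.tolist(),
            "T": self.T.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "beta_hat": self.beta_hat.tolist(),
            "alpha_hat": self.alpha_hat,
            "n_components": self.n_components,
            "measure": self.measure,
            "centers": self.centers.tolist(),
            "scales": self.scales.tolist(),
            "y_mean": self.y_mean,
            "column_names": list(self.column_names),
            "truncated": self.truncated,
            "requested_components": self.requested_components,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        arrays = {k: np.asarray(d[k], dtype=float) for k in
                  ("W", "T", "P", "q", "beta_hat", "centers", "scales")}
        return cls(
            alpha_hat=float(d["alpha_hat"]),
            n_components=int(d["n_components"]),
            measure=str(d["measure"]),
            y_mean=float(d["y_mean"]),
            column_names=list(d.get("column_names", [])),
            truncated=bool(d.get("truncated", False)),
            requested_components=int(d.get("requested_components", 0)),
            **arrays,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_pls(
    data: RankedDataset,
    measure: str = "standard",
    n_components: int = 2,
    scale: bool = False,
    gk_tau_mode: str = "printed",
) -> PLSModel:
    """Fit a PLS regression with the chosen loading-weight measure.

    Parameters
    ----------
    data : RankedDataset
        Predictors and ordinal response. The response codes are treated
        numerically (consecutive ranks) and centered internally.
    measure : str
        One of :data:`rankpls.rank_assoc.WEIGHT_MEASURES`.
    n_components : int
        Number of components C, ``1 <= C <= min(p, n - 1)``. Extraction stops
        early (with ``model.truncated`` set) if a weight vector or score
        collapses below tolerance.
    scale : bool
        Scale predictor columns to unit standard deviation. Off by default:
        the algorithm centers but does not standardize, so the covariance
        weight sees raw code variances while the rank measures are scale-free
        — the contrast the weight variants exist to exploit.
    """
    if measure not in WEIGHT_MEASURES:
        raise ConfigError(f"unknown measure {measure!r}")
    Z = np.asarray(data.Z, dtype=float)
    y = np.asarray(data.y, dtype=float)
    n, p = Z.shape
    if not 1 <= n_components <= min(p, n - 1):
        raise ConfigError(
            f"n_components={n_components} outside 1..min(p={p}, n-1={n - 1})"
        )
    data.validate()
    if np.unique(y).size < 2:
        raise FitError("response is constant; nothing to fit")

    centers = Z.mean(axis=0)
    if scale:
        scales = Z.std(axis=0, ddof=1)
        n_const = int((scales == 0).sum())
        if n_const:
            logger.warning("%d constant predictor columns left unscaled", n_const)
        scales = np.where(scales == 0, 1.0, scales)
    else:
        scales = np.ones(p)
    Zc = (Z - centers) / scales
    y_mean = float(y.mean())
    yc = y - y_mean

    Ws, Ts, Ps, qs = [], [], [], []
    Zd, yd = Zc.copy(), yc.copy()
    truncated = False
    for c in range(n_components):
        w = weight_vector(Zd, yd, measure, gk_tau_mode=gk_tau_mode)
        if np.linalg.norm(w) < _TOL:
            truncated = True
            break
        # sign convention: largest-magnitude entry positive
        if w[int(np.argmax(np.abs(w)))] < 0:
            w = -w
        t = Zd @ w
        tt = float(t @ t)
        if tt < _TOL:
            truncated = True
            break
        p_c = Zd.T @ t / tt
        q_c = float(yd @ t / tt)
        Ws.append(w)
        Ts.append(t)
        Ps.append(p_c)
        qs.append(q_c)
        Zd = Zd - np.outer(t, p_c)
        yd = yd - t * q_c

    if not Ws:
        raise FitError(f"no usable component for measure={measure!r} (degenerate weights)")
    if truncated:
        logger.info(
            "fit_pls(%s): extraction stopped at C=%d of requested %d",
            measure, len(Ws), n_components,
        )
    W = np.column_stack(Ws)
    T = np.column_stack(Ts)
    P = np.column_stack(Ps)
    q = np.asarray(qs)

    PtW = P.T @ W
    try:
        beta = W @ np.linalg.solve(PtW, q)
    except np.linalg.LinAlgError:
        logger.warning("P'W singular in coefficient recovery; using pseudo-inverse")
        beta = W @ (np.linalg.pinv(PtW) @ q)
    # intercept on the original predictor scale: alpha = ybar - mean(Z) . beta_orig
    alpha = float(y_mean - centers @ (beta / scales))

    return PLSModel(
        W=W, T=T, P=P, q=q,
        beta_hat=beta,
        alpha_hat=alpha,
        n_components=len(qs),
        measure=measure,
        centers=centers,
        scales=scales,
        y_mean=y_mean,
        column_names=list(data.column_names),
        truncated=truncated,
        requested_components=n_components,
    )
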