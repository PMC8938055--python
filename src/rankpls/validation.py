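"""Model comparison and Monte-Carlo validation.

Implements the validation workflow for ranked-response PLS: Gaussian
least-squares AIC, stratified 70:30 Monte-Carlo splitting, linear discriminant
analysis on PLS scores (with leave-one-out cross-validation), and the full
weight-variant x selection-method evaluation grid.

The classification protocol per Monte-Carlo iteration: fit PLS on the training
split, optionally select variables and refit on the retained set, project both
splits into score space, train an LDA on the training scores and classify the
projected test scores (headline accuracy). Leave-one-out LDA accuracy on the
training scores is recorded as a secondary metric.

Determinism: every grid cell and iteration derives its own child seed from the
master seed and the cell label, so adding or removing a cell never perturbs
the others and a rerun under the same master seed is bitwise identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import RankedDataset
from .exceptions import ConfigError, SplitError
from .pls_core import PLSModel, fit_pls
from .rank_assoc import WEIGHT_MEASURES
from .selection import (
    SELECTION_METHODS,
    apply_selection,
    lw_importance,
    rc_importance,
    smc_importance,
)

logger = logging.getLogger(__name__)

__all__ = [
    "aic",
    "split_70_30",
    "loocv_lda_accuracy",
    "monte_carlo_evaluate",
    "run_grid",
    "choose_components",
    "CellResult",
    "ValidationReport",
]


# ---------------------------------------------------------------------------
# AIC
# ---------------------------------------------------------------------------

def aic(model: PLSModel, data: RankedDataset) -> float:
    """Gaussian least-squares AIC: ``n ln(RSS/n) + 2 (C + 1)``.

    ``C + 1`` effective parameters (one per component plus the intercept).
    A perfect fit (RSS = 0) returns ``-inf``.
    """
    resid = np.asarray(data.y, float) - model.predict(data.Z)
    rss = float(resid @ resid)
    n = data.n
    if rss <= 0.0:
        logger.warning("aic: perfect fit (RSS = 0); returning -inf")
        return float("-inf")
    return n * float(np.log(rss / n)) + 2.0 * (model.n_components + 1)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_70_30(
    data: RankedDataset,
    seed: int,
    stratify: bool = True,
    max_redraws: int = 100,
) -> tuple[RankedDataset, RankedDataset]:
    """Random 70:30 partition; train size is ``floor(0.7 n)``.

    With ``stratify`` (default) the split is re-drawn until both parts contain
    every response level, keeping downstream LDA well-posed; after
    ``max_redraws`` failures a :class:`SplitError` is raised.
    """
    n = data.n
    if n < 10:
        raise SplitError(f"n={n} too small for a 70:30 split")
    n_train = int(np.floor(0.7 * n))
    levels = np.unique(data.y)
    rng = np.random.default_rng(seed)
    for _ in range(max_redraws):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if not stratify or (
            np.isin(levels, data.y[tr]).all() and np.isin(levels, data.y[te]).all()
        ):
            train = RankedDataset(
                Z=data.Z[tr], y=data.y[tr],
                column_names=list(data.column_names),
                level_labels=data.level_labels,
                response_name=data.response_name,
            )
            test = RankedDataset(
                Z=data.Z[te], y=data.y[te],
                column_names=list(data.column_names),
                level_labels=data.level_labels,
                response_name=data.response_name,
            )
            return train, test
    raise SplitError(
        f"could not draw a split containing all {levels.size} response levels "
        f"in both parts after {max_redraws} attempts"
    )


# ---------------------------------------------------------------------------
# linear discriminant analysis on scores
# ---------------------------------------------------------------------------

@dataclass
class _LDA:
    classes: np.ndarray
    means: np.ndarray        # k x d
    cov: np.ndarray          # pooled within-class, d x d
    log_priors: np.ndarray   # k


def _lda_fit(X: np.ndarray, labels: np.ndarray) -> _LDA:
    X = np.atleast_2d(np.asarray(X, float))
    classes, inv = np.unique(labels, return_inverse=True)
    n, d = X.shape
    k = classes.size
    if k < 2:
        raise ConfigError("LDA needs at least 2 classes")
    means = np.vstack([X[inv == g].mean(axis=0) for g in range(k)])
    resid = X - means[inv]
    cov = resid.T @ resid / max(n - k, 1)
    # ridge fallback for a singular pooled covariance
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        lam = 1e-6 * np.trace(cov) / d
        if lam <= 0:
            lam = 1e-6
        logger.warning("singular pooled covariance; adding ridge %.3g", lam)
        cov = cov + lam * np.eye(d)
    counts = np.bincount(inv, minlength=k)
    return _LDA(classes=classes, means=means, cov=cov,
                log_priors=np.log(counts / n))


def _lda_predict(model: _LDA, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    A = np.linalg.solve(model.cov, model.means.T)          # d x k
    scores = X @ A - 0.5 * np.einsum("kd,dk->k", model.means, A) + model.log_priors
    return model.classes[np.argmax(scores, axis=1)]


def lda_accuracy(
    T_train: np.ndarray, labels_train: np.ndarray,
    T_test: np.ndarray, labels_test: np.ndarray,
) -> float:
    """Train Fisher LDA on training scores, classify test scores."""
    model = _lda_fit(T_train, labels_train)
    pred = _lda_predict(model, T_test)
    return float(np.mean(pred == np.asarray(labels_test)))


def loocv_lda_accuracy(T: np.ndarray, labels: np.ndarray) -> float:
    """Leave-one-out LDA accuracy on a score matrix.

    For each row, an LDA (pooled within-class covariance, proportional priors)
    is fitted on the remaining rows and the held-out row is classified.
    """
    T = np.atleast_2d(np.asarray(T, float))
    if T.ndim == 2 and T.shape[0] == 1:
        T = T.T if T.shape[1] > 1 else T
    labels = np.asarray(labels)
    n = T.shape[0]
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ConfigError("LOOCV-LDA needs >= 2 classes with >= 2 members each")
    mask = np.ones(n, dtype=bool)
    correct = 0
    for i in range(n):
        mask[i] = False
        model = _lda_fit(T[mask], labels[mask])
        if _lda_predict(model, T[i])[0] == labels[i]:
            correct += 1
        mask[i] = True
    return correct / n


# ---------------------------------------------------------------------------
# Monte-Carlo evaluation
# ---------------------------------------------------------------------------

def _child_seed(master_seed: int, measure: str, selection: str, iteration: int) -> int:
    tag = f"{measure}|{selection}|{iteration}|{master_seed}".encode()
    return zlib.crc32(tag) % (2**31 - 1)


def _select(model, train, method: str):
    if method == "lw":
        return lw_importance(model)
    if method == "rc":
        return rc_importance(model)
    if method == "smc":
        return smc_importance(model, train)
    raise ConfigError(f"unknown selection method {method!r}")


@dataclass
class CellResult:
    """Per-iteration metrics for one (measure, selection) grid cell."""

    measure: str
    selection: str
    accuracies: list[float] = field(default_factory=list)
    loocv_accuracies: list[float] = field(default_factory=list)
    aics: list[float] = field(default_factory=list)
    n_retained: list[int] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)
    n_components: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies)) if self.accuracies else float("nan")

    @property
    def mean_loocv(self) -> float:
        return float(np.mean(self.loocv_accuracies)) if self.loocv_accuracies else float("nan")

    @property
    def mean_aic(self) -> float:
        return float(np.mean(self.aics)) if self.aics else float("nan")

    @property
    def mean_retained(self) -> float:
        return float(np.mean(self.n_retained)) if self.n_retained else float("nan")


def monte_carlo_evaluate(
    data: RankedDataset,
    measure: str,
    selection: str = "none",
    iterations: int = 10,
    seed: int = 0,
    n_components: int = 3,
    gk_tau_mode: str = "printed",
) -> CellResult:
    """Repeated 70:30 evaluation of one (measure, selection) pipeline.

    Per iteration: split, fit on train, optionally select-and-refit, project
    the test split and classify its scores with an LDA trained on the training
    scores. A failed iteration is recorded and excluded from the means.
    """
    if measure not in WEIGHT_MEASURES:
        raise ConfigError(f"unknown measure {measure!r}")
    if selection not in SELECTION_METHODS:
        raise ConfigError(f"unknown selection method {selection!r}")
    cell = CellResult(measure=measure, selection=selection, n_components=n_components)
    for it in range(iterations):
        child = _child_seed(seed, measure, selection, it)
        cell.seeds.append(child)
        try:
            train, test = split_70_30(data, seed=child)
            C = min(n_components, train.p, train.n - 1)
            model = fit_pls(train, measure=measure, n_components=C,
                            gk_tau_mode=gk_tau_mode)
            kept = train.p
            if selection != "none":
                scores = _select(model, train, selection)
                train_sel = apply_selection(train, scores)
                test_sel = test.restrict_columns(scores.retained)
                kept = train_sel.p
                C = min(n_components, train_sel.p, train_sel.n - 1)
                model = fit_pls(train_sel, measure=measure, n_components=C,
                                gk_tau_mode=gk_tau_mode)
                train_use, test_use = train_sel, test_sel
            else:
                train_use, test_use = train, test
            T_train = model.T
            T_test = model.transform(test_use.Z)
            cell.accuracies.append(
                lda_accuracy(T_train, train_use.y, T_test, test_use.y)
            )
            cell.loocv_accuracies.append(loocv_lda_accuracy(T_train, train_use.y))
            cell.aics.append(aic(model, train_use))
            cell.n_retained.append(kept)
        except Exception as exc:  # the grid must survive per-cell failures
            logger.warning("iteration %d of (%s, %s) failed: %s",
                           it, measure, selection, exc)
            cell.failures.append(f"iter {it}: {exc}")
    return cell


# ---------------------------------------------------------------------------
# the evaluation grid
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Results for every evaluated (measure, selection) cell plus the winner."""

    cells: list[CellResult]
    master_seed: int
    iterations: int
    n_components: int

    @property
    def winner(self) -> CellResult | None:
        """Best cell by mean accuracy; ties broken by fewer retained variables,
        then lower mean AIC."""
        ok = [c for c in self.cells if c.accuracies]
        if not ok:
            return None
        return min(ok, key=lambda c: (-c.mean_accuracy, c.mean_retained, c.mean_aic))

    @property
    def failures(self) -> list[str]:
        out = []
        for c in self.cells:
            out += [f"({c.measure}, {c.selection}) {msg}" for msg in c.failures]
        return out

    def to_frame(self) -> pd.DataFrame:
        """One row per cell per iteration, plus one summary row per cell."""
        rows = []
        for c in self.cells:
            for i, acc in enumerate(c.accuracies):
                rows.append({
                    "measure": c.measure, "selection": c.selection,
                    "row_type": "iteration", "iteration": i,
                    "seed": c.seeds[i] if i < len(c.seeds) else None,
                    "accuracy": acc,
                    "loocv_accuracy": c.loocv_accuracies[i],
                    "aic": c.aics[i],
                    "n_retained": c.n_retained[i],
                })
            rows.append({
                "measure": c.measure, "selection": c.selection,
                "row_type": "summary", "iteration": None, "seed": None,
                "accuracy": c.mean_accuracy,
                "loocv_accuracy": c.mean_loocv,
                "aic": c.mean_aic,
                "n_retained": c.mean_retained,
            })
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        win = self.winner
        return {
            "master_seed": self.master_seed,
            "iterations": self.iterations,
            "n_components": self.n_components,
            "n_cells": len(self.cells),
            "failures": self.failures,
            "winner": None if win is None else {
                "measure": win.measure,
                "selection": win.selection,
                "mean_accuracy": win.mean_accuracy,
                "mean_loocv_accuracy": win.mean_loocv,
                "mean_aic": win.mean_aic,
                "mean_retained": win.mean_retained,
            },
            "cells": [
                {
                    "measure": c.measure, "selection": c.selection,
                    "mean_accuracy": c.mean_accuracy,
                    "mean_loocv_accuracy": c.mean_loocv,
                    "mean_aic": c.mean_aic,
                    "mean_retained": c.mean_retained,
                    "n_failures": len(c.failures),
                }
                for c in self.cells
            ],
        }

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.summary(), indent=1))
        return path


def run_grid(
    data: RankedDataset,
    measures: list[str] | None = None,
    selection_methods: list[str] | None = None,
    iterations: int = 10,
    seed: int = 0,
    n_components: int = 3,
    gk_tau_mode: str = "printed",
) -> ValidationReport:
    """Evaluate every (measure x selection) cell with a shared seed schedule."""
    measures = list(WEIGHT_MEASURES) if measures is None else list(measures)
    selection_methods = (
        list(SELECTION_METHODS) if selection_methods is None else list(selection_methods)
    )
    if not measures or not selection_methods:
        raise ConfigError("measures and selection_methods must be non-empty")
    cells = []
    for m in measures:
        for s in selection_methods:
            logger.info("grid cell (%s, %s)", m, s)
            cells.append(monte_carlo_evaluate(
                data, m, s, iterations=iterations, seed=seed,
                n_components=n_components, gk_tau_mode=gk_tau_mode,
            ))
    return ValidationReport(cells=cells, master_seed=seed,
                            iterations=iterations, n_components=n_components)


def choose_components(
    data: RankedDataset,
    measure: str,
    c_max: int | None = None,
    iterations: int = 5,
    seed: int = 0,
) -> int:
    """Pick C maximizing Monte-Carlo LDA accuracy over ``1..min(p, 15)``."""
    c_max = min(data.p, 15) if c_max is None else min(c_max, data.p)
    best_c, best_acc = 1, -np.inf
    for c in range(1, c_max + 1):
        cell = monte_carlo_evaluate(data, measure, "none",
                                    iterations=iterations, seed=seed,
                                    n_components=c)
        if cell.accuracies and cell.mean_accuracy > best_acc:
            best_c, best_acc = c, cell.mean_accuracy
    logger.info("choose_components(%s): C=%d (accuracy %.3f)", measure, best_c, best_acc)
    return best_c
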