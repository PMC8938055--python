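"""Ordinal association measures used as PLS loading weights.

Nine weight variants are supported: the standard covariance weight plus eight
rank-association coefficients (Spearman's rho, Kendall's tau-A and tau-B,
Stuart-Kendall tau-C, Somers' D, Goodman-Kruskal tau and gamma, and Theil's
uncertainty coefficient U). The Kendall family shares a single pair-counting
core: for every observation pair (i, j), i < j, the pair is concordant when
``(x_i - x_j)(y_i - y_j) > 0``, discordant when ``< 0``, and otherwise tied in
x and/or y. Counting is done on the contingency table of the two variables via
double cumulative sums, which is exact and O(r*k) for r x k distinct levels.

Degenerate inputs (a constant vector, a fully tied variable, zero entropy)
return 0 with a :class:`~rankpls.exceptions.DegenerateInputWarning` rather than
raising, so a degenerate column can never abort a model fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ConfigError, DegenerateInputWarning, InvalidInputError

__all__ = [
    "PairCounts",
    "ContingencyTable",
    "WEIGHT_MEASURES",
    "count_pairs",
    "contingency_table",
    "spearman_rho",
    "kendall_tau_a",
    "kendall_tau_b",
    "stuart_tau_c",
    "somers_d",
    "gk_tau",
    "gk_gamma",
    "theil_u",
    "weight_vector",
]

#: Canonical weight-variant names, shared with the CLI ``--measure`` flag.
WEIGHT_MEASURES = (
    "standard",
    "rho_s",
    "tau_a",
    "tau_b",
    "tau_c",
    "somers_d",
    "gk_tau",
    "gk_gamma",
    "theil_u",
)

#: Measures that are intrinsically nonnegative; their magnitude is given the
#: sign of Spearman's rho when used as a loading weight.
_SIGN_FREE = frozenset({"theil_u"})

#: Contingency-table measures bin continuous inputs (> this many distinct
#: values) into quintiles; pair-based measures use raw values (rank-invariant).
_MAX_TABLE_LEVELS = 20


@dataclass(frozen=True)
class PairCounts:
    """Concordant/discordant/tie tallies over all n(n-1)/2 observation pairs.

    ``n_1``/``n_2`` are Kendall's tie terms ``sum t_i(t_i - 1)/2`` over tie
    groups of the first/second variable; a pair tied in both variables is
    counted in both.
    """

    n_c: int
    n_d: int
    n_0: int
    n_1: int
    n_2: int
    n: int


@dataclass(frozen=True)
class ContingencyTable:
    """Co-occurrence counts of two variables' levels (rows: x, cols: y)."""

    counts: np.ndarray

    @property
    def m(self) -> int:
        """min(rows, cols) — the table-shape term of Stuart-Kendall tau-C."""
        return int(min(self.counts.shape))

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _as_vectors(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise InvalidInputError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 2:
        raise InvalidInputError("need at least 2 observations")
    return x, y


def _quintile_bin(v: np.ndarray) -> np.ndarray:
    """Bin a continuous vector into (at most) 5 equal-probability levels."""
    edges = np.quantile(v, [0.2, 0.4, 0.6, 0.8])
    return np.searchsorted(edges, v, side="left").astype(float)


def _table_codes(v: np.ndarray) -> np.ndarray:
    """Level codes for contingency-table measures, quintile-binning continuous data."""
    if np.unique(v).size > _MAX_TABLE_LEVELS:
        v = _quintile_bin(v)
    return v


def contingency_table(x, y) -> ContingencyTable:
    x, y = _as_vectors(x, y)
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    r = int(xi.max()) + 1
    k = int(yi.max()) + 1
    counts = np.bincount(xi * k + yi, minlength=r * k).reshape(r, k)
    return ContingencyTable(counts=counts)


def _tie_term(codes: np.ndarray) -> int:
    counts = np.bincount(codes)
    return int((counts.astype(np.int64) * (counts - 1) // 2).sum())


def _pair_counts_sorted(x: np.ndarray, y: np.ndarray) -> PairCounts:
    """Exact pair counts in O(n log n): lexicographic sort plus strict
    inversion counting of y with a Fenwick tree. Used when the contingency
    table of distinct levels would be large (near-continuous inputs)."""
    n = x.shape[0]
    _, cx = np.unique(x, return_inverse=True)
    _, cy = np.unique(y, return_inverse=True)
    order = np.lexsort((cy, cx))
    ys = cy[order]
    k = int(ys.max()) + 1
    tree = [0] * (k + 1)
    n_d = 0
    for code in ys[::-1].tolist():
        j = code  # prefix sum over codes strictly below `code`
        while j > 0:
            n_d += tree[j]
            j -= j & -j
        j = code + 1
        while j <= k:
            tree[j] += 1
            j += j & -j
    n_0 = n * (n - 1) // 2
    n_1 = _tie_term(cx)
    n_2 = _tie_term(cy)
    n_12 = _tie_term(cx * np.int64(k) + cy)  # pairs tied in both variables
    n_c = n_0 - n_1 - n_2 + n_12 - n_d
    return PairCounts(n_c=int(n_c), n_d=int(n_d), n_0=n_0, n_1=n_1, n_2=n_2, n=n)


def _pair_counts_from_table(counts: np.ndarray) -> PairCounts:
    N = counts.astype(np.int64)
    r, k = N.shape
    n = int(N.sum())
    # P[i, j] = sum of N over rows < i and cols < j (exclusive prefix sums)
    P = np.zeros((r + 1, k + 1), dtype=np.int64)
    P[1:, 1:] = N.cumsum(axis=0).cumsum(axis=1)
    n_c = int((N * P[:-1, :-1]).sum())  # partner strictly below-left
    n_d = int((N * (P[:-1, -1:] - P[:-1, 1:])).sum())  # strictly below-right
    rows = N.sum(axis=1)
    cols = N.sum(axis=0)
    n_1 = int((rows * (rows - 1) // 2).sum())
    n_2 = int((cols * (cols - 1) // 2).sum())
    return PairCounts(n_c=n_c, n_d=n_d, n_0=n * (n - 1) // 2, n_1=n_1, n_2=n_2, n=n)


def count_pairs(x, y) -> PairCounts:
    """Tally concordant, discordant and tied pairs of ``(x, y)``."""
    x, y = _as_vectors(x, y)
    r = np.unique(x).size
    k = np.unique(y).size
    if r * k > 65536:
        return _pair_counts_sorted(x, y)
    return _pair_counts_from_table(contingency_table(x, y).counts)


def _degenerate(msg: str) -> float:
    warnings.warn(msg, DegenerateInputWarning, stacklevel=3)
    return 0.0


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation: Pearson correlation of midranks.

    For tie-free data this coincides with the classical
    ``1 - 6*sum(d_i^2) / (n(n^2-1))`` shortcut.
    """
    x, y = _as_vectors(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        return _degenerate("spearman_rho: zero variance in a rank vector")
    return float(((rx - rx.mean()) @ (ry - ry.mean())) / (len(rx) * sx * sy))


def kendall_tau_a(x, y) -> float:
    """Kendall's tau-A: (n_c - n_d) / n_0, no tie adjustment."""
    pc = count_pairs(x, y)
    return (pc.n_c - pc.n_d) / pc.n_0


def kendall_tau_b(x, y) -> float:
    """Kendall's tau-B: (n_c - n_d) / sqrt((n_0 - n_1)(n_0 - n_2))."""
    pc = count_pairs(x, y)
    denom = (pc.n_0 - pc.n_1) * (pc.n_0 - pc.n_2)
    if denom <= 0:
        return _degenerate("kendall_tau_b: a variable is fully tied")
    return (pc.n_c - pc.n_d) / float(np.sqrt(denom))


def stuart_tau_c(x, y) -> float:
    """Stuart-Kendall tau-C: 2m(n_c - n_d) / (n^2 (m - 1)), m = min(rows, cols)."""
    x, y = _as_vectors(x, y)
    table = contingency_table(_table_codes(x), _table_codes(y))
    m = table.m
    if m < 2:
        return _degenerate("stuart_tau_c: single-level variable (m = 1)")
    pc = _pair_counts_from_table(table.counts)
    return 2.0 * m * (pc.n_c - pc.n_d) / (pc.n**2 * (m - 1))


def somers_d(x, y) -> float:
    """Somers' D of y given x: (n_c - n_d) / (n_0 - n_1).

    Asymmetric — pairs tied in the first (predictor) variable are removed from
    the denominator. Equivalently tau_A(x, y) / tau_A(x, x).
    """
    pc = count_pairs(x, y)
    denom = pc.n_0 - pc.n_1
    if denom <= 0:
        return _degenerate("somers_d: predictor fully tied")
    return (pc.n_c - pc.n_d) / denom


def gk_tau(x, y, mode: str = "printed") -> float:
    """Goodman-Kruskal tau in two modes.

    ``printed`` (default): ``2 (n_c - n_d) / n_0`` — twice tau-A, which may
    exceed 1 in magnitude. ``classical``: the proportional-reduction-in-error
    statistic tau(y|x) in [0, 1], measuring how much knowing x reduces the
    Goodman-Kruskal prediction error of y.
    """
    if mode == "printed":
        pc = count_pairs(x, y)
        return 2.0 * (pc.n_c - pc.n_d) / pc.n_0
    if mode != "classical":
        raise ConfigError(f"unknown gk_tau mode {mode!r}")
    x, y = _as_vectors(x, y)
    N = contingency_table(_table_codes(x), _table_codes(y)).counts.astype(float)
    n = N.sum()
    col = N.sum(axis=0) / n
    v_y = 1.0 - (col**2).sum()
    if v_y <= 0:
        return _degenerate("gk_tau: response variable is constant")
    row = N.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        within = np.where(row[:, None] > 0, N**2 / row[:, None], 0.0)
    v_y_given_x = 1.0 - within.sum() / n
    return float((v_y - v_y_given_x) / v_y)


def gk_gamma(x, y) -> float:
    """Goodman-Kruskal gamma: (n_c - n_d) / (n_c + n_d); tied pairs dropped."""
    pc = count_pairs(x, y)
    if pc.n_c + pc.n_d == 0:
        return _degenerate("gk_gamma: no untied pairs")
    return (pc.n_c - pc.n_d) / (pc.n_c + pc.n_d)


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0*log 0 := 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def theil_u(x, y) -> float:
    """Theil's uncertainty coefficient U(x|y) = (H(x) - H(x|y)) / H(x).

    The fraction of x's entropy explained by conditioning on y; in [0, 1] and
    asymmetric. Base-invariant; natural log used.
    """
    x, y = _as_vectors(x, y)
    N = contingency_table(_table_codes(x), _table_codes(y)).counts.astype(float)
    n = N.sum()
    h_x = _entropy(N.sum(axis=1) / n)
    if h_x == 0.0:
        return _degenerate("theil_u: first variable is constant")
    p_y = N.sum(axis=0) / n
    h_x_given_y = 0.0
    for j in range(N.shape[1]):
        if p_y[j] > 0:
            h_x_given_y += p_y[j] * _entropy(N[:, j] / N[:, j].sum())
    return (h_x - h_x_given_y) / h_x


_MEASURE_FUNCS = {
    "rho_s": spearman_rho,
    "tau_a": kendall_tau_a,
    "tau_b": kendall_tau_b,
    "tau_c": stuart_tau_c,
    "somers_d": somers_d,
    "gk_gamma": gk_gamma,
    "theil_u": theil_u,
}


def _spearman_columns(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized Spearman rho of every column of Z with y (0 for constants)."""
    R = stats.rankdata(Z, axis=0)
    ry = stats.rankdata(y)
    Rc = R - R.mean(axis=0)
    ryc = ry - ry.mean()
    denom = np.sqrt((Rc**2).sum(axis=0) * (ryc**2).sum())
    num = Rc.T @ ryc
    out = np.zeros(Z.shape[1])
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def weight_vector(
    Z,
    y,
    measure: str,
    gk_tau_mode: str = "printed",
    normalize: bool = True,
) -> np.ndarray:
    """Loading-weight vector: association of each column of Z with y.

    ``standard`` gives the covariance weight ``Z'y`` (on centered data, the
    classical NIPALS weight); every other measure substitutes the corresponding
    rank-association coefficient. Sign-free measures (Theil's U, classical
    Goodman-Kruskal tau) are given the sign of Spearman's rho per column so the
    resulting PLS scores carry direction. The vector is scaled to unit
    Euclidean norm; an all-zero vector is returned un-normalized with a
    :class:`DegenerateInputWarning`.
    """
    if measure not in WEIGHT_MEASURES:
        raise ConfigError(
            f"unknown measure {measure!r}; choose one of {WEIGHT_MEASURES}"
        )
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise InvalidInputError("Z must be 2-D")
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != Z.shape[0]:
        raise InvalidInputError("Z and y row counts differ")

    if measure == "standard":
        zc = Z - Z.mean(axis=0)
        w = zc.T @ (y - y.mean())
    elif measure == "rho_s":
        w = _spearman_columns(Z, y)
    else:
        sign_free = measure in _SIGN_FREE or (
            measure == "gk_tau" and gk_tau_mode == "classical"
        )
        if measure == "gk_tau":
            func = lambda a, b: gk_tau(a, b, mode=gk_tau_mode)  # noqa: E731
        else:
            func = _MEASURE_FUNCS[measure]
        w = np.empty(Z.shape[1])
        signs = _spearman_columns(Z, y) if sign_free else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateInputWarning)
            for j in range(Z.shape[1]):
                w[j] = func(Z[:, j], y)
        if sign_free:
            w = np.abs(w) * np.sign(signs)

    norm = float(np.linalg.norm(w))
    if norm == 0.0:
        warnings.warn(
            f"weight_vector({measure}): all-zero weight vector",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return w
    return w / norm if normalize else w
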