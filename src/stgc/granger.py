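"""Spatio-temporal Granger causality (GC).

Directed influence between BOLD series is quantified by the classical
log residual-variance ratio (Geweke convention)::

    GC(x -> y) = ln( sigma2_restricted / sigma2_full )

where the restricted model regresses ``y`` on ``p`` of its own lags and
the full model adds ``p`` lags of ``x``.  Both models are fit by ordinary
least squares on the same effective sample, so the in-sample GC is
non-negative by nesting.

Time-varying coupling is handled by splitting the series into equal
windows (see :mod:`stgc.timeseries`), refitting per window with a
BIC-selected model order, and summarising each candidate window length by

* ``gc_avg``  — mean GC over windows,
* ``gc_err``  — sample-size-weighted mean of the full-model residual
  variances, and
* the objective ``J = gc_err + 1 / gc_avg``

which trades prediction error against detected causality.  Candidate
window lengths whose ``J`` values are statistically indistinguishable
from the minimiser are disambiguated by total windowed BIC (lower is
better), preferring fewer, better-estimated windows; any remaining tie
goes to the longer window.

At the spatial level, GC between two ROIs is the mean windowed GC over
all ordered voxel pairs (source voxel -> target voxel).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateSeriesError,
    LengthError,
    SingularDesignError,
)
from .timeseries import ROITimeSeries, WindowingScheme

__all__ = [
    "MVARModel",
    "GCWindowResult",
    "EdgeMatrix",
    "fit_mvar",
    "pairwise_gc",
    "windowed_gc",
    "select_window_length",
    "roi_gc",
    "build_edge_matrix",
    "gc_permutation_null",
]

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps


@dataclass
class MVARModel:
    """Least-squares multivariate autoregressive fit.

    ``coefficients[l][i, j]`` is the effect of channel ``j`` at lag
    ``l + 1`` on channel ``i``.  ``residual_covariance`` uses the
    maximum-likelihood denominator ``n_effective = T - order``.
    """

    order: int
    coefficients: np.ndarray  # (p, k, k)
    residual_covariance: np.ndarray  # (k, k)
    n_effective: int
    channel_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("MVAR coefficients must be finite")
        if np.any(np.diag(self.residual_covariance) < -1e-12):
            raise ValueError("residual variances must be non-negative")


@dataclass
class GCWindowResult:
    """Windowed GC summary for one (source, target) pair and window length."""

    per_window_gc: list[float]
    gc_avg: float
    gc_err: float
    objective_j: float
    bic: float
    window_length: int
    orders: list[int] = field(default_factory=list)
    n_effective: list[int] = field(default_factory=list)
    se_j: float = float("nan")
    degenerate_windows: int = 0


@dataclass
class EdgeMatrix:
    """Directed ROI-level GC matrix; entry (i, j) is influence i -> j."""

    roi_names: list[str]
    gc: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.roi_names)
        if self.gc.shape != (k, k):
            raise ValueError("gc matrix shape must match roi_names")

    def edge(self, source: str, target: str) -> float:
        i = self.roi_names.index(source)
        j = self.roi_names.index(target)
        return float(self.gc[i, j])


# ---------------------------------------------------------------------------
# low-level least squares helpers
# ---------------------------------------------------------------------------


def _lag_matrix(z: np.ndarray, order: int, start: int) -> np.ndarray:
    """Columns z[t-1] .. z[t-order] for t = start .. T-1."""
    T = z.shape[-1]
    return np.column_stack([z[start - k : T - k] for k in range(1, order + 1)])


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    """Residual sum of squares of the least-squares fit of y on X."""
    gram = X.T @ X
    try:
        beta = np.linalg.solve(gram, X.T @ y)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def fit_mvar(channels: np.ndarray, order: int) -> MVARModel:
    """Fit a VAR(p) model to a k x T matrix by equation-wise least squares.

    Channels are de-meaned over the fitted segment and the design carries
    an explicit intercept (so deterministic recursions are recovered
    exactly).  Raises
    :class:`SingularDesignError` naming the offending channels when the
    stacked lag design is rank deficient.
    """
    Z = np.atleast_2d(np.asarray(channels, dtype=float))
    k, T = Z.shape
    if order < 1:
        raise ConfigurationError("order must be >= 1")
    if T <= k * order + 1:
        raise LengthError(f"need T > k*p + 1 = {k * order + 1}, got T = {T}")
    means = Z.mean(axis=1, keepdims=True)
    Zc = Z - means
    n = T - order
    # lag-major design blocks plus intercept:
    # [all channels at lag 1 | lag 2 | ... | lag p | 1]
    design = np.empty((n, order * k + 1))
    for lag in range(order):
        for ch in range(k):
            design[:, lag * k + ch] = Zc[ch, order - 1 - lag : T - 1 - lag]
    design[:, -1] = 1.0
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _name_collinear_channels(Zc)
        raise SingularDesignError(
            f"rank-deficient lag design (rank {rank} < {design.shape[1]}); "
            f"suspect channels: {bad}"
        )
    Y = Zc[:, order:].T  # (n, k)
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    sigma = resid.T @ resid / n
    coeffs = np.empty((order, k, k))
    for lag in range(order):
        coeffs[lag] = beta[lag * k : (lag + 1) * k].T
    return MVARModel(
        order=order,
        coefficients=coeffs,
        residual_covariance=sigma,
        n_effective=n,
        channel_means=means.ravel(),
    )


def _name_collinear_channels(Zc: np.ndarray) -> list[int]:
    """Best-effort identification of channels causing rank deficiency."""
    bad = [i for i in range(Zc.shape[0]) if np.allclose(Zc[i], 0.0)]
    if bad:
        return bad
    # duplicated channels
    for i in range(Zc.shape[0]):
        for j in range(i + 1, Zc.shape[0]):
            if np.allclose(Zc[i], Zc[j]):
                bad.extend([i, j])
    return sorted(set(bad)) or list(range(Zc.shape[0]))


# ---------------------------------------------------------------------------
# pairwise GC
# ---------------------------------------------------------------------------


def _gc_core(y: np.ndarray, x: np.ndarray, order: int) -> tuple[float, float, int]:
    """Return (gc, full-model ML residual variance, n_effective).

    Series are de-meaned over the segment.  Degenerate cases: a constant
    input raises :class:`DegenerateSeriesError`; a zero full-model
    residual variance yields ``+inf`` GC with a warning.
    """
    T = y.size
    n = T - order
    y0 = y - y.mean()
    x0 = x - x.mean()
    if np.allclose(y0, 0.0) or np.allclose(x0, 0.0):
        raise DegenerateSeriesError("constant series supplied to GC estimator")
    yt = y0[order:]
    ones = np.ones((n, 1))
    ry = np.column_stack([_lag_matrix(y0, order, order), ones])
    rf = np.column_stack([_lag_matrix(y0, order, order), _lag_matrix(x0, order, order), ones])
    rss_r = _ols_rss(yt, ry)
    rss_f = _ols_rss(yt, rf)
    tss = float(yt @ yt)
    if rss_f <= _EPS * max(tss, 1.0):
        warnings.warn("zero full-model residual variance; GC degenerate (+inf)")
        return math.inf, 0.0, n
    gc = math.log(rss_r / rss_f)
    return max(gc, 0.0), rss_f / n, n


def pairwise_gc(x: np.ndarray, y: np.ndarray, order: int) -> float:
    """Unconditional GC from ``x`` to ``y`` at a fixed model order.

    Implements ``ln(sigma2_restricted / sigma2_full)`` with both models
    fit in-sample on the same effective sample, so the result is >= 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if x.size <= 2 * order + 2:
        raise LengthError(f"need length > 2p + 2 = {2 * order + 2}, got {x.size}")
    gc, _, _ = _gc_core(y, x, order)
    return gc


def _select_order(y: np.ndarray, x: np.ndarray, order_range: tuple[int, ...]) -> int:
    """BIC order selection for the full target-equation regression.

    All candidate orders are scored on the common sample starting at
    ``max(order_range)`` so their likelihoods are comparable.
    """
    pmax = max(order_range)
    T = y.size
    y0 = y - y.mean()
    x0 = x - x.mean()
    yt = y0[pmax:]
    n = yt.size
    best_bic, best_p = math.inf, min(order_range)
    ones = np.ones((n, 1))
    for p in sorted(order_range):
        design = np.column_stack(
            [_lag_matrix(y0, p, pmax), _lag_matrix(x0, p, pmax), ones]
        )
        rss = _ols_rss(yt, design)
        if rss <= 0:
            return p
        bic = n * math.log(rss / n) + (2 * p + 1) * math.log(n)
        if bic < best_bic:
            best_bic, best_p = bic, p
    return best_p


def _as_order_range(order_range) -> tuple[int, ...]:
    if isinstance(order_range, int):
        return (order_range,)
    orders = tuple(int(p) for p in order_range)
    if not orders or min(orders) < 1:
        raise ConfigurationError("order_range must contain positive integers")
    return orders


def windowed_gc(
    x: np.ndarray,
    y: np.ndarray,
    scheme: WindowingScheme,
    order_range=(1, 2, 3, 4, 5),
    on_degenerate: str = "raise",
) -> GCWindowResult:
    """Windowed GC from ``x`` to ``y`` under a windowing scheme.

    Each window is de-meaned and refit independently; its model order is
    chosen by BIC within ``order_range``.  ``gc_err`` weights the
    full-model residual variances by each window's effective sample size.
    ``bic`` is the total windowed BIC (summed over windows, counting
    2p + 1 parameters per window including the mean).

    Parameters
    ----------
    on_degenerate
        ``"raise"`` (default) fails loudly on a degenerate window;
        ``"exclude"`` drops the window from ``gc_avg``/``gc_err`` and
        counts it in ``degenerate_windows``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    orders = _as_order_range(order_range)
    if scheme.total_length > x.size:
        raise LengthError(
            f"scheme needs {scheme.total_length} points, series has {x.size}"
        )
    if scheme.window_length <= 2 * max(orders) + 2:
        raise ConfigurationError(
            f"window length {scheme.window_length} too short for max order {max(orders)}"
        )
    if on_degenerate not in ("raise", "exclude"):
        raise ConfigurationError("on_degenerate must be 'raise' or 'exclude'")

    gcs: list[float] = []
    errs: list[float] = []
    ns: list[int] = []
    ps: list[int] = []
    total_bic = 0.0
    n_degenerate = 0
    for sl in scheme.slices():
        xw, yw = x[sl], y[sl]
        try:
            p = _select_order(yw, xw, orders)
            gc, s2f, n = _gc_core(yw, xw, p)
        except DegenerateSeriesError:
            if on_degenerate == "raise":
                raise
            n_degenerate += 1
            continue
        if not math.isfinite(gc):
            if on_degenerate == "raise":
                raise DegenerateSeriesError("degenerate window: zero residual variance")
            n_degenerate += 1
            continue
        gcs.append(gc)
        errs.append(s2f)
        ns.append(n)
        ps.append(p)
        total_bic += n * math.log(max(s2f, _EPS)) + (2 * p + 1) * math.log(n)
    if not gcs:
        raise DegenerateSeriesError("all windows degenerate")

    gc_arr = np.array(gcs)
    err_arr = np.array(errs)
    n_arr = np.array(ns, dtype=float)
    gc_avg = float(gc_arr.mean())
    gc_err = float(np.average(err_arr, weights=n_arr))
    if gc_avg <= _EPS:
        logger.warning("gc_avg <= machine epsilon; objective set to +inf")
        objective = math.inf
    else:
        objective = gc_err + 1.0 / gc_avg
    m = len(gcs)
    if m > 1 and gc_avg > _EPS:
        se_avg = float(gc_arr.std(ddof=1)) / math.sqrt(m)
        se_err = float(err_arr.std(ddof=1)) / math.sqrt(m)
        se_j = math.sqrt(se_err**2 + (se_avg / gc_avg**2) ** 2)
    else:
        se_j = math.inf
    return GCWindowResult(
        per_window_gc=gcs,
        gc_avg=gc_avg,
        gc_err=gc_err,
        objective_j=objective,
        bic=total_bic,
        window_length=scheme.window_length,
        orders=ps,
        n_effective=ns,
        se_j=se_j,
        degenerate_windows=n_degenerate,
    )


def select_window_length(
    x: np.ndarray,
    y: np.ndarray,
    candidate_lengths,
    order_range=(1, 2, 3, 4, 5),
    se_band: float = 1.0,
) -> tuple[int, dict[int, GCWindowResult]]:
    """Choose the optimal window length among candidates.

    For each candidate ``L`` the retained series is truncated from the
    start to the largest multiple of ``L`` (non-divisor candidates are
    admitted this way) and the windowed objective ``J`` is computed.
    Candidates whose ``J`` lies within ``se_band`` delta-method standard
    errors of the minimiser (interval overlap, both sides) are treated as
    statistically tied; ties are resolved by the lowest total windowed
    BIC, then toward the longer window.

    Returns ``(optimal_length, {length: GCWindowResult})``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cands = [int(c) for c in candidate_lengths]
    if not cands:
        raise ConfigurationError("candidate_lengths must be non-empty")
    results: dict[int, GCWindowResult] = {}
    for L in cands:
        m = x.size // L
        if m < 1:
            raise ConfigurationError(f"candidate window {L} exceeds series length")
        if x.size % L != 0:
            logger.info("candidate %d does not divide %d; truncating from start", L, x.size)
        xs, ys = x[x.size - m * L :], y[y.size - m * L :]
        scheme = WindowingScheme(window_length=L, n_windows=m)
        results[L] = windowed_gc(xs, ys, scheme, order_range)
    finite = {L: r for L, r in results.items() if math.isfinite(r.objective_j)}
    if not finite:
        raise DegenerateSeriesError("objective +inf for every candidate window length")
    l_min = min(finite, key=lambda L: finite[L].objective_j)
    j_min = finite[l_min].objective_j
    band_min = se_band * finite[l_min].se_j
    tied = [
        L
        for L, r in finite.items()
        if r.objective_j - se_band * r.se_j <= j_min + band_min
    ]
    tied.sort(key=lambda L: (results[L].bic, -L))
    return tied[0], results


def gc_permutation_null(
    x: np.ndarray,
    y: np.ndarray,
    scheme: WindowingScheme,
    order_range=(1, 2, 3, 4, 5),
    n_permutations: int = 99,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Permutation null sample of ``gc_avg`` for the edge x -> y.

    The source series is permuted in time (destroying any lagged
    dependence on the target while preserving its marginal distribution)
    and windowed GC recomputed.  Returns the array of permuted
    ``gc_avg`` values; compare the observed statistic against e.g. its
    95th percentile.
    """
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(x, dtype=float)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        xp = rng.permutation(x)
        null[i] = windowed_gc(xp, y, scheme, order_range).gc_avg
    return null


# ---------------------------------------------------------------------------
# ROI level
# ---------------------------------------------------------------------------


def roi_gc(
    source: ROITimeSeries,
    target: ROITimeSeries,
    scheme: WindowingScheme,
    order_range=(1, 2, 3, 4, 5),
) -> float:
    """ROI-level GC: mean windowed ``gc_avg`` over all ordered voxel pairs."""
    if source.n_voxels == 0:
        raise ValueError(f"empty source ROI {source.roi_name!r}")
    if target.n_voxels == 0:
        raise ValueError(f"empty target ROI {target.roi_name!r}")
    if source.n_timepoints != target.n_timepoints:
        raise LengthError(
            f"ROIs {source.roi_name!r} and {target.roi_name!r} differ in length"
        )
    total = 0.0
    for xi in source.data:
        for yj in target.data:
            total += windowed_gc(xi, yj, scheme, order_range).gc_avg
    return total / (source.n_voxels * target.n_voxels)


def build_edge_matrix(
    rois: list[ROITimeSeries],
    scheme: WindowingScheme,
    order_range=(1, 2, 3, 4, 5),
) -> EdgeMatrix:
    """All-pairs directed ROI GC matrix; diagonal fixed at zero."""
    if len(rois) < 2:
        raise ConfigurationError("need at least two ROIs")
    names = [r.roi_name for r in rois]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicated ROI names in {names}")
    k = len(rois)
    gc = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                gc[i, j] = roi_gc(rois[i], rois[j], scheme, order_range)
    return EdgeMatrix(roi_names=names, gc=gc)
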