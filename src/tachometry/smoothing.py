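"""Local polynomial regression (LOESS) with tricube weights.

At each query point x0 the ``ceil(span * n)`` training points nearest to x0
(contiguous in sorted x; distance ties resolved toward the smaller x) are
fit with a weighted polynomial of the given degree, weights

    w_j = (1 - (|x_j - x0| / d_max)^3)^3,

where d_max is the largest distance within the window; the local prediction
is the fitted value at x0. Every query point gets its own exact weighted
least-squares solve — there is no interpolation between anchor points.

The solver centers and rescales each window (u = (x - x0) / d_max), builds
the normal equations for all query points at once and solves them as a
batched linear system, so smoothing a curve of a thousand bins costs a few
milliseconds. Rank-deficient windows (possible when the window barely
exceeds the polynomial degree and the boundary weight vanishes) fall back
to a minimum-norm least-squares solve.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


def tricube(u: np.ndarray) -> np.ndarray:
    """Tricube kernel on |u| <= 1 (0 outside)."""
    a = np.clip(np.abs(u), 0.0, 1.0)
    return (1.0 - a**3) ** 3


def _window_starts(x: np.ndarray, queries: np.ndarray, k: int) -> np.ndarray:
    """Start index of the k-nearest contiguous window for each query.

    ``x`` must be sorted and strictly increasing. Among windows of k
    consecutive points the one with the smallest maximum distance to the
    query is chosen; on a tie the left (smaller-x) window wins, matching
    k-nearest-neighbour selection with ties broken toward smaller x.
    """
    n = len(x)
    if k >= n:
        return np.zeros(len(queries), dtype=np.intp)
    # midpoints of (left edge of window s, right edge) are strictly
    # increasing, so the optimal start brackets the query's position
    mid = (x[: n - k + 1] + x[k - 1 :]) / 2.0
    s = np.searchsorted(mid, queries, side="left")
    s = np.clip(s, 0, n - k)
    s_prev = np.maximum(s - 1, 0)
    r = np.maximum(queries - x[s], x[s + k - 1] - queries)
    r_prev = np.maximum(queries - x[s_prev], x[s_prev + k - 1] - queries)
    return np.where(r_prev <= r, s_prev, s)


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    queries: np.ndarray | None = None,
    span: float = 0.2,
    degree: int = 2,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate the LOESS fit of (x, y) at ``queries`` (default: at x).

    ``x`` must be sorted strictly increasing. ``weights`` optionally
    multiplies the tricube weights (e.g. per-bin trial counts).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if n <= degree + 1:
        raise ValueError(
            f"need more than degree + 1 = {degree + 1} points, got {n}"
        )
    k = int(np.ceil(span * n))
    if k <= degree:
        raise ValueError(
            f"window of ceil(span*n) = {k} points is too small for a degree-"
            f"{degree} fit; increase the span"
        )
    k = min(k, n)
    q = x if queries is None else np.asarray(queries, dtype=float)
    starts = _window_starts(x, q, k)
    if weights is None and _moment_kernel is not None:
        fitted = _moment_kernel(x, y, q, starts, k, degree)
        bad = ~np.isfinite(fitted)
    else:
        fitted, bad = _moments_numpy(x, y, q, starts, k, degree, weights)
    for i in np.flatnonzero(bad):
        fitted[i] = _lstsq_point(x, y, q[i], int(starts[i]), k, degree, weights)
    return fitted


def _moments_numpy(x, y, q, starts, k, degree, weights):
    """Batched normal equations in centered/scaled window coordinates.

    The local prediction is the intercept beta_0 of the weighted polynomial
    fit; the (degree+1)^2 normal matrix is a Hankel matrix of the weighted
    moments of u^0..u^(2*degree).
    """
    idx = starts[:, None] + np.arange(k)[None, :]  # (m, k)
    xw = x[idx]
    yw = y[idx]
    dmax = np.maximum(q - x[starts], x[starts + k - 1] - q)
    dmax = np.where(dmax <= 0, 1.0, dmax)
    u = (xw - q[:, None]) / dmax[:, None]
    w = tricube(u)
    if weights is not None:
        w = w * np.asarray(weights, dtype=float)[idx]
    p = degree + 1
    m = len(q)
    S = np.empty((m, 2 * degree + 1))
    T = np.empty((m, p))
    wy = w * yw
    S[:, 0] = w.sum(axis=1)
    T[:, 0] = wy.sum(axis=1)
    upow = w.copy()
    for j in range(1, 2 * degree + 1):
        upow *= u
        S[:, j] = upow.sum(axis=1)
    wypow = wy
    for j in range(1, p):
        wypow = wypow * u
        T[:, j] = wypow.sum(axis=1)
    jj = np.arange(p)
    A = S[:, jj[:, None] + jj[None, :]]  # Hankel: A[i,j] = S[i+j]
    fitted = np.empty(m)
    try:
        fitted[:] = np.linalg.solve(A, T[..., None])[:, 0, 0]
        bad = ~np.isfinite(fitted)
    except np.linalg.LinAlgError:
        bad = np.ones(m, dtype=bool)
    return fitted, bad


def _lstsq_point(x, y, x0, start, k, degree, weights):
    """Minimum-norm weighted least squares for one (rank-deficient) window."""
    sl = slice(start, start + k)
    d = np.abs(x[sl] - x0)
    dmax = d.max() or 1.0
    u = (x[sl] - x0) / dmax
    w = tricube(u)
    if weights is not None:
        w = w * np.asarray(weights, dtype=float)[sl]
    sw = np.sqrt(w)
    Xd = np.vander(u, degree + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(Xd * sw[:, None], y[sl] * sw, rcond=None)
    return beta[0]


def _build_moment_kernel():
    """JIT the per-query moment accumulation (order-of-magnitude speedup
    for resampling loops); identical math to :func:`_moments_numpy` with a
    tiny Gaussian-elimination solve per query. Returns None without numba.
    """
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is an optional accelerator
        return None

    @njit(cache=True)
    def kernel(x, y, q, starts, k, degree):  # pragma: no cover - jitted
        p = degree + 1
        m = len(q)
        out = np.empty(m)
        S = np.empty(2 * p - 1)
        T = np.empty(p)
        A = np.empty((p, p + 1))
        for i in range(m):
            s = starts[i]
            x0 = q[i]
            dmax = max(x0 - x[s], x[s + k - 1] - x0)
            if dmax <= 0:
                dmax = 1.0
            for j in range(2 * p - 1):
                S[j] = 0.0
            for j in range(p):
                T[j] = 0.0
            for t in range(s, s + k):
                u = (x[t] - x0) / dmax
                au = abs(u)
                w = 1.0 - au * au * au
                w = w * w * w
                wy = w * y[t]
                S[0] += w
                T[0] += wy
                up = w
                for j in range(1, 2 * p - 1):
                    up *= u
                    S[j] += up
                wyp = wy
                for j in range(1, p):
                    wyp *= u
                    T[j] += wyp
            # augmented normal matrix, Gaussian elimination w/ partial pivot
            for r in range(p):
                for c in range(p):
                    A[r, c] = S[r + c]
                A[r, p] = T[r]
            singular = False
            for col in range(p):
                piv = col
                big = abs(A[col, col])
                for r in range(col + 1, p):
                    if abs(A[r, col]) > big:
                        big = abs(A[r, col])
                        piv = r
                if big == 0.0:
                    singular = True
                    break
                if piv != col:
                    for c in range(col, p + 1):
                        tmp = A[col, c]
                        A[col, c] = A[piv, c]
                        A[piv, c] = tmp
                for r in range(col + 1, p):
                    f = A[r, col] / A[col, col]
                    for c in range(col, p + 1):
                        A[r, c] -= f * A[col, c]
            if singular:
                out[i] = np.nan
                continue
            # back-substitution; only beta_0 is needed
            beta = np.empty(p)
            for r in range(p - 1, -1, -1):
                acc = A[r, p]
                for c in range(r + 1, p):
                    acc -= A[r, c] * beta[c]
                beta[r] = acc / A[r, r]
            out[i] = beta[0]
        return out

    return kernel


_moment_kernel = _build_moment_kernel()


class LoessRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style LOESS regressor (tricube, local polynomial).

    Parameters
    ----------
    span:
        Fraction of training points in each local window, in (0, 1].
    degree:
        Degree of the local polynomial (2 reproduces local curvature and
        is the conventional default for conditional-accuracy curves).

    Attributes
    ----------
    x_, y_ : ndarray
        Training data, sorted by x (x must be strictly increasing after
        sorting, i.e. duplicate x values are not allowed — pre-bin them).
    window_ : int
        Number of points in each local window, ``ceil(span * n)``.

    Examples
    --------
    >>> reg = LoessRegressor(span=0.5).fit([[0], [1], [2], [3]], [0, 1, 4, 9])
    >>> reg.predict([[2]]).shape
    (1,)
    """

    def __init__(self, span: float = 0.2, degree: int = 2):
        self.span = span
        self.degree = degree

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(len(X), -1)
        if x.shape[1] != 1:
            raise ValueError("LoessRegressor expects a single feature")
        x = x[:, 0]
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError("X and y length mismatch")
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        if np.any(np.diff(x) == 0):
            raise ValueError("duplicate x values; aggregate them before fitting")
        # validate span/degree/window eagerly (raises on bad parameters)
        loess_fit(x, y, queries=x[:1], span=self.span, degree=self.degree)
        self.x_ = x
        self.y_ = y
        self.window_ = int(np.ceil(self.span * len(x)))
        return self

    def predict(self, X):
        check_is_fitted(self, "x_")
        q = np.asarray(X, dtype=float).reshape(len(X), -1)[:, 0]
        return loess_fit(self.x_, self.y_, queries=q, span=self.span,
                         degree=self.degree)
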