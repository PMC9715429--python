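"""Locally estimated scatterplot smoothing (LOESS).

Local polynomial regression with tricube weights and a span-nearest-
neighbour bandwidth, the conventional defaults of the original
implementation: span 0.75, local quadratic.  Pointwise standard errors
come from the equivalent kernel (the fit at x0 is a linear combination
l(x0)·y of the responses, so var = sigma^2 * ||l(x0)||^2 with sigma^2
estimated from the smoother's residual sum of squares and its
approximate residual degrees of freedom).

Implemented in-package because the trend stack needs degree-2 fits with
pointwise uncertainty on arbitrary evaluation grids.
"""

from __future__ import annotations

import numpy as np

from .errors import InsufficientDataError


def _equivalent_kernel(x: np.ndarray, x0: float, span: float, degree: int) -> np.ndarray:
    """Weight vector l with fit(x0) = l @ y."""
    n = len(x)
    d = np.abs(x - x0)
    q = min(n, max(degree + 2, int(np.floor(span * n))))
    h = np.partition(d, q - 1)[q - 1]
    if h <= 0:
        # duplicated x values at x0: average them
        l = (d == 0).astype(float)
        return l / l.sum()
    w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
    # local polynomial basis in (x - x0); fit value at x0 is the intercept
    X = np.vander(x - x0, N=degree + 1, increasing=True)
    XtW = X.T * w
    beta_map = np.linalg.pinv(XtW @ X) @ XtW  # (degree+1, n)
    return beta_map[0]


def loess(
    x,
    y,
    x_eval=None,
    *,
    span: float = 0.75,
    degree: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """LOESS fit and pointwise standard error at ``x_eval``.

    Returns ``(fit, se)`` arrays over ``x_eval`` (default: the data ``x``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < degree + 2:
        raise InsufficientDataError(
            f"need at least {degree + 2} points for degree-{degree} LOESS, got {n}"
        )
    if not 0 < span <= 1:
        raise InsufficientDataError(f"span must be in (0, 1], got {span}")
    x_eval = x if x_eval is None else np.asarray(x_eval, dtype=float)

    # residual variance from the fit at the data points
    trace_l = 0.0
    fitted = np.empty(n)
    for i, xi in enumerate(x):
        li = _equivalent_kernel(x, xi, span, degree)
        fitted[i] = li @ y
        trace_l += li[i]
    dof = max(n - trace_l, 1.0)
    sigma2 = float(((y - fitted) ** 2).sum() / dof)

    fit = np.empty(len(x_eval))
    se = np.empty(len(x_eval))
    for j, x0 in enumerate(x_eval):
        l = _equivalent_kernel(x, x0, span, degree)
        fit[j] = l @ y
        se[j] = np.sqrt(sigma2 * (l @ l))
    return fit, se
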