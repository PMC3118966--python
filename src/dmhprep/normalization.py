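"""M/A computation and within-array LOESS-family normalization.

For corrected intensities R (test, Cy5) and G (reference, Cy3),

    M = log2(R) - log2(G)        observed methylation signal
    A = (log2(R) + log2(G)) / 2  average log intensity

Cells with R <= 0 or G <= 0 are missing.  Four within-array
normalizations are supported:

``none``
    M unchanged.
``global``
    M_new = M - f_all(A), LOESS trend fitted on all biological probes.
``control``
    M_new = M - f_control(A), trend fitted on the internal control probes
    only (probes whose theoretical M is 0 under the DMH protocol).
``composite``
    M_new = M - g(A) with g(A) = a(A) f_control(A) + (1 - a(A)) f_all(A),
    where a(A) is the proportion of biological-probe A values strictly
    below A (empirical CDF).

The composite curve follows the control curve at low intensities — where
few probes but many controls inform the trend — and the global curve at
high intensities.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import FitError, InputError
from .background import CorrectedIntensities
from .restriction import ControlProbeSet

#: LOESS defaults (common two-color practice; see docs/methods.md).
DEFAULT_SPAN = 0.3
DEFAULT_DEGREE = 1
DEFAULT_ROBUST_ITERS = 3
MIN_CONTROL_PROBES = 30

NORMALIZATION_ALIASES = {
    "none": "none",
    "global": "global",
    "loess": "global",
    "control": "control",
    "composite": "composite",
}

NORMALIZATION_METHODS = ("none", "global", "control", "composite")


@dataclasses.dataclass
class MAArray:
    """M and A values for one array.  NaN marks missing cells (and is
    always simultaneous between M and A)."""

    array_id: str
    probe_ids: np.ndarray
    M: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.probe_ids) == len(self.M) == len(self.A)):
            raise InputError("probe_ids, M and A must have equal length")
        if np.any(np.isnan(self.M) != np.isnan(self.A)):
            raise InputError("M and A must be missing at the same cells")

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.M)


def stack_m_values(mas: list[MAArray]) -> pd.DataFrame:
    """Probes x arrays matrix of M values (NaN = missing)."""
    cols = {}
    index = mas[0].probe_ids
    for ma in mas:
        if not np.array_equal(ma.probe_ids, index):
            s = pd.Series(ma.M, index=ma.probe_ids).reindex(index)
            cols[ma.array_id] = s.to_numpy()
        else:
            cols[ma.array_id] = ma.M
    return pd.DataFrame(cols, index=index)


def compute_ma(corrected: CorrectedIntensities) -> MAArray:
    """M/A values from corrected intensities; non-positive R or G gives a
    missing cell."""
    R = np.asarray(corrected.R, dtype=float)
    G = np.asarray(corrected.G, dtype=float)
    ok = (R > 0) & (G > 0)
    M = np.full(R.shape, np.nan)
    A = np.full(R.shape, np.nan)
    lr = np.log2(R[ok])
    lg = np.log2(G[ok])
    M[ok] = lr - lg
    A[ok] = (lr + lg) / 2.0
    return MAArray(
        array_id=corrected.array_id,
        probe_ids=np.asarray(corrected.probe_ids),
        M=M,
        A=A,
    )


@dataclasses.dataclass
class LoessCurve:
    """Fitted M-on-A trend: linear interpolation between LOESS-fitted
    points, extended by its boundary values outside the training domain."""

    x_fit: np.ndarray
    y_fit: np.ndarray
    span: float
    degree: int

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.x_fit[0]), float(self.x_fit[-1])

    def __call__(self, A):
        A = np.asarray(A, dtype=float)
        out = np.full(A.shape, np.nan)
        ok = np.isfinite(A)
        out[ok] = np.interp(A[ok], self.x_fit, self.y_fit)
        return out if out.ndim else float(out)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w**3


def local_polynomial_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float,
    degree: int,
    robust_iters: int = DEFAULT_ROBUST_ITERS,
) -> np.ndarray:
    """Plain numpy LOESS: local polynomial of the given degree with
    tricube weights over the span-nearest neighbours of each point, with
    bisquare robustness iterations.  Quadratic in n; used for degrees the
    fast path does not cover and as an independent check of it.
    """
    n = len(x)
    k = max(int(np.ceil(span * n)), degree + 2)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    robust_w = np.ones(n)
    fitted_s = np.empty(n)
    for iteration in range(robust_iters + 1):
        for i in range(n):
            lo = np.searchsorted(xs, xs[i], side="left")
            # symmetric nearest-neighbour window around point i
            left, right = i, i
            while right - left + 1 < k:
                if left == 0:
                    right += 1
                elif right == n - 1:
                    left -= 1
                elif xs[i] - xs[left - 1] <= xs[right + 1] - xs[i]:
                    left -= 1
                else:
                    right += 1
            xi = xs[left : right + 1]
            yi = ys[left : right + 1]
            h = max(np.max(np.abs(xi - xs[i])), 1e-12)
            w = _tricube((xi - xs[i]) / h) * robust_w[left : right + 1]
            if w.sum() <= 0:
                w = np.ones_like(w)
            coeffs = np.polynomial.polynomial.polyfit(xi - xs[i], yi, degree, w=np.sqrt(w))
            fitted_s[i] = coeffs[0]
        resid = ys - fitted_s
        if iteration < robust_iters:
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            robust_w = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    fitted = np.empty(n)
    fitted[order] = fitted_s
    return fitted


def fit_loess(
    A,
    M,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    robust_iters: int = DEFAULT_ROBUST_ITERS,
) -> LoessCurve:
    """Fit a LOESS trend of M on A and return an evaluator.

    Non-finite pairs are dropped.  Requires >= 10 points and
    span * n >= degree + 2.  Degree 1 uses the compiled statsmodels
    lowess; other degrees use :func:`local_polynomial_fit`.
    """
    A = np.asarray(A, dtype=float)
    M = np.asarray(M, dtype=float)
    ok = np.isfinite(A) & np.isfinite(M)
    A, M = A[ok], M[ok]
    n = len(A)
    if n < 10:
        raise FitError(f"loess fit needs >= 10 finite points, got {n}")
    if span <= 0 or span > 1:
        raise FitError(f"span must be in (0, 1], got {span}")
    if span * n < degree + 2:
        raise FitError(f"span * n = {span * n:.1f} < degree + 2 = {degree + 2}")
    if degree == 1:
        delta = 0.005 * float(np.ptp(A))
        out = sm.nonparametric.lowess(
            M, A, frac=span, it=robust_iters, delta=delta, return_sorted=True
        )
        x_fit, y_fit = out[:, 0], out[:, 1]
    else:
        fitted = local_polynomial_fit(A, M, span=span, degree=degree, robust_iters=robust_iters)
        order = np.argsort(A, kind="stable")
        x_fit, y_fit = A[order], fitted[order]
        # collapse duplicate x for a well-defined interpolant
        x_fit, idx = np.unique(x_fit, return_index=True)
        y_fit = y_fit[idx]
    return LoessCurve(x_fit=x_fit, y_fit=y_fit, span=span, degree=degree)


def composite_weight(A, A_all) -> np.ndarray:
    """Empirical-CDF weight a(A): proportion of ``A_all`` strictly below
    each query value (ties count toward the smaller weight)."""
    A_all = np.asarray(A_all, dtype=float)
    A_all = A_all[np.isfinite(A_all)]
    if A_all.size == 0:
        raise InputError("A_all must be non-empty")
    sorted_all = np.sort(A_all)
    A = np.asarray(A, dtype=float)
    ranks = np.searchsorted(sorted_all, A, side="left")
    out = ranks / sorted_all.size
    return out if out.ndim else float(out)


def normalize(
    ma: MAArray,
    method: str,
    controls: ControlProbeSet | None = None,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    robust_iters: int = DEFAULT_ROBUST_ITERS,
) -> MAArray:
    """Within-array normalization of one array's M values.

    ``controls`` is required for the control and composite methods and
    must supply at least 30 control probes with non-missing M on this
    array.  A values pass through unchanged; missing cells stay missing.
    """
    if method not in NORMALIZATION_ALIASES:
        raise InputError(
            f"unknown normalization method {method!r}; choose from {sorted(set(NORMALIZATION_ALIASES))}"
        )
    method = NORMALIZATION_ALIASES[method]
    if method == "none":
        return MAArray(ma.array_id, ma.probe_ids, ma.M.copy(), ma.A.copy())

    present = ma.present
    f_all = None
    f_control = None
    if method in ("global", "composite"):
        f_all = fit_loess(ma.A[present], ma.M[present], span, degree, robust_iters)
    if method in ("control", "composite"):
        if controls is None:
            raise InputError(f"method {method!r} requires a control probe set")
        is_control = np.isin(ma.probe_ids, list(controls.probe_ids))
        usable = is_control & present
        n_usable = int(usable.sum())
        if n_usable < MIN_CONTROL_PROBES:
            raise FitError(
                f"array {ma.array_id!r}: only {n_usable} control probes with "
                f"non-missing M (need >= {MIN_CONTROL_PROBES})"
            )
        f_control = fit_loess(ma.A[usable], ma.M[usable], span, degree, robust_iters)

    M_new = ma.M.copy()
    if method == "global":
        trend = f_all(ma.A[present])
    elif method == "control":
        trend = f_control(ma.A[present])
    else:  # composite
        a = composite_weight(ma.A[present], ma.A[present])
        trend = a * f_control(ma.A[present]) + (1.0 - a) * f_all(ma.A[present])
    M_new[present] = ma.M[present] - trend
    return MAArray(ma.array_id, ma.probe_ids, M_new, ma.A.copy())
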