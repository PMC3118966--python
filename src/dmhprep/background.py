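"""Background correction for two-color DMH arrays.

Five methods are provided, matching the standard two-color expression
repertoire:

``none``
    R = Rf, G = Gf (foreground only).
``subtract``
    R = Rf - Rb, G = Gf - Gb.  May produce non-positive intensities,
    which yield missing M values downstream.
``edwards``
    Background subtraction replaced by a smooth, monotone, strictly
    positive function when the difference falls below a threshold d:
    f - b for f - b > d, else d * exp(1 - (b + d) / f).
``normexp``
    Normal + exponential convolution model fitted per channel per array
    to x = f - b by maximum likelihood; each intensity is replaced by the
    conditional expectation E(S | X = x) of the exponential true signal.
``normexp_offset``
    normexp plus a small positive offset k (default 50) on both channels,
    damping the variance of low-intensity log-ratios.

Model for normexp: X = S + B with S ~ Exponential(mean alpha) independent
of B ~ Normal(mu, sigma^2).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, special, stats

from .exceptions import FitError, InputError
from .io import TwoColorArray

#: Default offset for the ``normexp_offset`` method.
DEFAULT_OFFSET = 50.0

#: Canonical method ids and their CLI/table aliases.
METHOD_ALIASES = {
    "none": "none",
    "subtract": "subtract",
    "sub": "subtract",
    "edwards": "edwards",
    "normexp": "normexp",
    "normexp_offset": "normexp_offset",
    "normexp50": "normexp_offset",
}

BACKGROUND_METHODS = ("none", "subtract", "edwards", "normexp", "normexp_offset")


@dataclasses.dataclass(frozen=True)
class NormexpParams:
    """Parameters of the normal + exponential convolution.

    alpha: mean of the exponential signal component (> 0, a.u.)
    mu: mean of the normal noise component (a.u.)
    sigma: standard deviation of the normal noise (> 0, a.u.)
    """

    alpha: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.sigma > 0):
            raise InputError(f"require alpha > 0 and sigma > 0, got {self}")


@dataclasses.dataclass
class CorrectedIntensities:
    """Per-probe corrected red/green intensities for one array."""

    array_id: str
    probe_ids: np.ndarray
    R: np.ndarray
    G: np.ndarray
    method_id: str
    offset_k: float = 0.0
    normexp_params: dict | None = None  # channel -> NormexpParams


def edwards_correct_channel(f, b, d: float):
    """Edwards' smooth background adjustment for one channel.

    Returns ``f - b`` where that difference exceeds the threshold ``d``
    and the smooth positive completion ``d * exp(1 - (b + d) / f)``
    otherwise; the two branches agree at ``f - b = d``, and the result is
    strictly positive and increasing in ``f``.
    """
    if d <= 0:
        raise InputError(f"edwards threshold d must be > 0, got {d}")
    f = np.asarray(f, dtype=float)
    b = np.asarray(b, dtype=float)
    if (f <= 0).any():
        raise InputError("edwards correction requires foreground > 0")
    diff = f - b
    smooth = d * np.exp(1.0 - (b + d) / f)
    # the exponential underflows to 0 for b >> f; keep the result positive
    smooth = np.maximum(smooth, np.finfo(float).tiny)
    return np.where(diff > d, diff, smooth)


def default_edwards_threshold(f, b) -> float:
    """Data-adaptive Edwards threshold: the 10th percentile of the
    positive foreground-minus-background differences of the channel."""
    diff = np.asarray(f, dtype=float) - np.asarray(b, dtype=float)
    pos = diff[diff > 0]
    if pos.size == 0:
        raise FitError("no positive foreground-minus-background differences")
    return float(np.percentile(pos, 10))


def _normexp_negloglik(theta: np.ndarray, x: np.ndarray) -> float:
    mu, log_sigma, log_alpha = theta
    sigma = np.exp(log_sigma)
    alpha = np.exp(log_alpha)
    m = x - mu - sigma**2 / alpha
    ll = (
        -np.log(alpha)
        + (mu - x) / alpha
        + sigma**2 / (2 * alpha**2)
        + special.log_ndtr(m / sigma)
    )
    return -float(np.sum(ll))


def normexp_loglik(x, params: NormexpParams) -> float:
    """Log-likelihood of data ``x`` under the convolution model."""
    theta = np.array([params.mu, np.log(params.sigma), np.log(params.alpha)])
    return -_normexp_negloglik(theta, np.asarray(x, dtype=float))


def _moments_init(x: np.ndarray) -> np.ndarray:
    """Method-of-moments initializer: mean = mu + alpha,
    var = sigma^2 + alpha^2, third central moment = 2 alpha^3."""
    m1 = x.mean()
    var = x.var()
    m3 = np.mean((x - m1) ** 3)
    alpha = (max(m3, 1e-6) / 2.0) ** (1.0 / 3.0)
    alpha = max(alpha, 1e-3 * max(np.sqrt(var), 1.0))
    sigma2 = max(var - alpha**2, 0.01 * var)
    mu = m1 - alpha
    return np.array([mu, 0.5 * np.log(sigma2), np.log(alpha)])


def normexp_fit(x, min_points: int = 50) -> NormexpParams:
    """Maximum-likelihood fit of the normexp convolution to one channel.

    ``x`` are background-subtracted intensities of one channel of one
    array.  Requires at least ``min_points`` finite, non-constant values.
    The returned parameters attain a log-likelihood at least as high as
    the method-of-moments initializer.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_points:
        raise FitError(f"normexp fit needs >= {min_points} finite values, got {x.size}")
    if np.ptp(x) == 0:
        raise FitError("normexp fit is degenerate on constant input")
    theta0 = _moments_init(x)
    res = optimize.minimize(
        _normexp_negloglik,
        theta0,
        args=(x,),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    theta = res.x if res.fun <= _normexp_negloglik(theta0, x) else theta0
    mu, log_sigma, log_alpha = theta
    return NormexpParams(alpha=float(np.exp(log_alpha)), mu=float(mu), sigma=float(np.exp(log_sigma)))


def normexp_conditional_mean(x, params: NormexpParams):
    """E(S | X = x) under the normexp model, evaluated stably.

    Equals ``m + sigma * phi(m/sigma) / Phi(m/sigma)`` with
    ``m = x - mu - sigma^2 / alpha``; the Mills-type ratio is evaluated
    in the log domain so the result stays finite and positive even for
    strongly negative ``m / sigma``.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise InputError("non-finite intensity passed to normexp_conditional_mean")
    sigma, alpha, mu = params.sigma, params.alpha, params.mu
    m = x - mu - sigma**2 / alpha
    z = m / sigma
    ratio = np.exp(stats.norm.logpdf(z) - special.log_ndtr(z))
    out = m + sigma * ratio
    # guard against catastrophic cancellation far in the left tail, where
    # the exact value approaches 0 from above
    tiny = np.finfo(float).tiny
    out = np.maximum(out, tiny)
    return out if out.ndim else float(out)


def correct_background(
    array: TwoColorArray,
    method: str,
    d: float | None = None,
    k: float = DEFAULT_OFFSET,
) -> CorrectedIntensities:
    """Apply one background-correction method to a whole array.

    Parameters
    ----------
    method:
        One of ``none, subtract (sub), edwards, normexp,
        normexp_offset (normexp50)``.
    d:
        Edwards threshold; defaults to the 10th percentile of the
        channel's positive (foreground - background) differences.
    k:
        Offset added to both channels by ``normexp_offset``.
    """
    if method not in METHOD_ALIASES:
        raise InputError(f"unknown background method {method!r}; choose from {sorted(set(METHOD_ALIASES))}")
    method = METHOD_ALIASES[method]
    if k < 0:
        raise InputError(f"offset k must be >= 0, got {k}")
    data = array.data
    Rf = data["Rf"].to_numpy(dtype=float)
    Gf = data["Gf"].to_numpy(dtype=float)
    Rb = data["Rb"].to_numpy(dtype=float)
    Gb = data["Gb"].to_numpy(dtype=float)
    params = None
    offset = 0.0

    if method == "none":
        R, G = Rf.copy(), Gf.copy()
    elif method == "subtract":
        R, G = Rf - Rb, Gf - Gb
    elif method == "edwards":
        d_r = default_edwards_threshold(Rf, Rb) if d is None else d
        d_g = default_edwards_threshold(Gf, Gb) if d is None else d
        R = edwards_correct_channel(Rf, Rb, d_r)
        G = edwards_correct_channel(Gf, Gb, d_g)
    else:  # normexp or normexp_offset
        params = {}
        corrected = {}
        for channel, (fg, bg) in {"R": (Rf, Rb), "G": (Gf, Gb)}.items():
            p = normexp_fit(fg - bg)
            params[channel] = p
            corrected[channel] = normexp_conditional_mean(fg - bg, p)
        R, G = corrected["R"], corrected["G"]
        if method == "normexp_offset":
            offset = float(k)
            R, G = R + offset, G + offset

    return CorrectedIntensities(
        array_id=array.array_id,
        probe_ids=data["probe_id"].to_numpy(),
        R=R,
        G=G,
        method_id=method,
        offset_k=offset,
        normexp_params=params,
    )
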