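"""Windowed FIR channel fitting by standardized nonnegative least squares.

The directed interaction from a sender region to a receiver region is
modelled, within one analysis window, as a finite-impulse-response (FIR)
linear time-invariant channel with additive white Gaussian noise:

    y_t = a_0 x_t + a_1 x_{t-1} + ... + a_{k-1} x_{t-k+1} + w_t,  a_j >= 0

where ``x`` is the sender signal, ``y`` the receiver signal and ``w`` iid
Gaussian noise independent of ``x``.  Coefficients are constrained to be
nonnegative: negative couplings are hard to interpret in global-signal
regressed data, so the model class is restricted to positive interactions
and the all-zero fit is the meaningful "no channel" answer.

Both the receiver vector and each lagged sender column are standardized to
zero mean and unit root-mean-square (population convention, divisor n).
This enforces the unit sender-power constraint under which channel capacity
is later evaluated, and makes the order-1 fit available in closed form:
``a0 = max(r, 0)`` with residual power ``1 - a0 * (2 r - a0)``, where ``r``
is the sample correlation of the standardized signals.

Under the Gaussian likelihood the constrained maximum-likelihood estimate
is the nonnegative least squares (NNLS) solution, a deterministic convex
program; the noise power MLE is the mean squared residual.  The channel
memory ``k`` is selected per window by an information criterion (AIC, BIC
or AICc) computed from the Gaussian log-likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "DegenerateSignalError",
    "InsufficientHistoryError",
    "WindowSegment",
    "ChannelFit",
    "OrderSelectionConfig",
    "standardize",
    "build_convolution_matrix",
    "fit_channel",
    "select_order",
    "default_k_max",
]


class DegenerateSignalError(ValueError):
    """A window contains a constant (zero-variance) signal."""


class InsufficientHistoryError(ValueError):
    """Not enough pre-window samples to build a full-lag design matrix."""


def standardize(values) -> np.ndarray:
    """Remove the mean and divide by the root mean square (divisor n).

    The output has exactly zero mean and unit RMS.  Raises
    :class:`DegenerateSignalError` for constant input, where the
    transformation is undefined; callers decide whether to skip the window
    or report the measure as missing.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("standardize expects a 1-D sequence")
    if x.size < 2:
        raise ValueError("standardize needs at least 2 samples")
    centered = x - x.mean()
    rms = math.sqrt(float(centered @ centered) / x.size)
    if rms == 0.0 or not math.isfinite(rms):
        raise DegenerateSignalError("constant or non-finite signal in window")
    return centered / rms


@dataclass(frozen=True)
class WindowSegment:
    """One analysis window of a directed pair.

    ``lookback`` holds up to ``k_max - 1`` sender samples immediately
    preceding the window, used to fill the early rows of the lagged design
    matrix.  It may be empty, in which case rows with unobserved lags are
    truncated.
    """

    sender: np.ndarray
    receiver: np.ndarray
    lookback: np.ndarray = field(default_factory=lambda: np.empty(0))
    tr_seconds: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "sender", np.asarray(self.sender, dtype=float))
        object.__setattr__(self, "receiver", np.asarray(self.receiver, dtype=float))
        object.__setattr__(self, "lookback", np.asarray(self.lookback, dtype=float))
        if self.sender.shape != self.receiver.shape or self.sender.ndim != 1:
            raise ValueError("sender and receiver must be 1-D with equal length")
        if self.n < 2:
            raise ValueError("window needs at least 2 samples")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n(self) -> int:
        return self.sender.size


@dataclass
class ChannelFit:
    """Fitted FIR channel for one window: taps, noise power, memory."""

    order: int
    coefficients: np.ndarray
    noise_variance: float
    residuals: np.ndarray
    prediction: np.ndarray
    n_used: int
    criterion_value: float = math.nan

    def prediction_correlation(self) -> float:
        """Pearson correlation of observed and model-predicted receiver.

        Returns 0.0 for the all-zero fit (constant prediction), matching
        the convention that a vanished channel carries no predictive
        connectivity.
        """
        if not np.any(self.coefficients > 0):
            return 0.0
        y = self.prediction + self.residuals
        yhat = self.prediction
        sy = y.std()
        syh = yhat.std()
        if sy == 0.0 or syh == 0.0:
            return 0.0
        return float(np.mean((y - y.mean()) * (yhat - yhat.mean())) / (sy * syh))


@dataclass(frozen=True)
class OrderSelectionConfig:
    """Information-criterion order search over FIR memories 1..k_max."""

    criterion: str = "BIC"
    k_max: int | None = None

    def __post_init__(self):
        if self.criterion not in ("AIC", "BIC", "AICc"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.k_max is not None and self.k_max < 1:
            raise ValueError("k_max must be >= 1")

    def resolve_k_max(self, n: int) -> int:
        k = default_k_max(n) if self.k_max is None else self.k_max
        if k >= n - 2:
            raise ValueError(
                f"k_max={k} too large for window length n={n}; need k_max < n - 2"
            )
        return k


def default_k_max(n: int) -> int:
    """Default memory cap: min(8, n // 10), at least 1.

    Keeps the per-window regression strongly overdetermined.
    """
    return max(1, min(8, n // 10))


def build_convolution_matrix(
    segment: WindowSegment, order: int, allow_truncation: bool = True
) -> tuple[np.ndarray, int]:
    """Lagged, per-column standardized sender design matrix.

    Row ``t``, column ``j`` holds the sender value at time ``t - j`` for
    lags 0..order-1.  Missing history at the window start is drawn from
    ``segment.lookback``; any remaining unobserved rows are truncated when
    ``allow_truncation`` (the default), otherwise
    :class:`InsufficientHistoryError` is raised.

    Returns ``(X, offset)`` where ``offset`` is the number of truncated
    leading rows; the receiver must be trimmed by the same offset.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    s = segment.sender
    lb = segment.lookback
    n = s.size
    need = order - 1
    use_lb = min(lb.size, need)
    missing = need - use_lb
    if missing > 0 and not allow_truncation:
        raise InsufficientHistoryError(
            f"order {order} needs {need} lookback samples, have {lb.size}"
        )
    offset = missing
    rows = n - offset
    if rows < 2:
        raise ValueError(f"window too short for order {order} with truncation")
    ext = np.concatenate([lb[lb.size - use_lb:], s]) if use_lb else s
    X = np.empty((rows, order))
    base = use_lb + offset
    for j in range(order):
        X[:, j] = standardize(ext[base - j : base - j + rows])
    return X, offset


def fit_channel(
    segment: WindowSegment, order: int, allow_truncation: bool = True
) -> ChannelFit:
    """Constrained MLE of the FIR channel at a fixed order.

    Solves ``min ||X a - y||^2 subject to a >= 0`` on the standardized
    system by NNLS and reports the noise power as the mean squared
    residual.  Deterministic given its inputs.
    """
    X, offset = build_convolution_matrix(segment, order, allow_truncation)
    y = standardize(segment.receiver[offset:])
    coef, _ = nnls(X, y)
    pred = X @ coef
    resid = y - pred
    noise_variance = float(resid @ resid) / resid.size
    return ChannelFit(
        order=order,
        coefficients=coef,
        noise_variance=noise_variance,
        residuals=resid,
        prediction=pred,
        n_used=resid.size,
    )


def _criterion_score(noise_variance: float, n: int, k: int, criterion: str) -> float:
    # Gaussian-likelihood information criteria; the tap count k is the
    # parameter count (noise variance omitted identically across candidates,
    # leaving rankings unchanged).
    sigma2 = max(noise_variance, 1e-300)
    base = n * math.log(sigma2)
    if criterion == "AIC":
        return base + 2 * k
    if criterion == "BIC":
        return base + k * math.log(n)
    if criterion == "AICc":
        if n - k - 1 <= 0:
            return math.inf
        return base + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    raise ValueError(f"unknown criterion {criterion!r}")


def select_order(
    segment: WindowSegment,
    config: OrderSelectionConfig | None = None,
    allow_truncation: bool = True,
) -> ChannelFit:
    """Fit orders 1..k_max and return the criterion-minimizing fit.

    Ties break toward the smaller order (parsimony).  The search starts at
    order 1; the all-zero NNLS solution at order 1 represents "no channel".
    """
    config = config or OrderSelectionConfig()
    k_max = config.resolve_k_max(segment.n)
    best: ChannelFit | None = None
    last_error: Exception | None = None
    for k in range(1, k_max + 1):
        try:
            fit = fit_channel(segment, k, allow_truncation)
        except (DegenerateSignalError, ValueError) as err:
            last_error = err
            continue
        fit.criterion_value = _criterion_score(
            fit.noise_variance, fit.n_used, k, config.criterion
        )
        if best is None or fit.criterion_value < best.criterion_value:
            best = fit
    if best is None:
        raise DegenerateSignalError(
            f"no candidate order could be fitted: {last_error}"
        )
    return best
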