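"""Water-filling channel capacity of a fitted FIR/AWGN channel.

For a linear channel with frequency response H(f) and white noise power
sigma^2, the noise referred to the channel input has power spectral density
S_EIN(f) = sigma^2 / |H(f)|^2 (the equivalent input noise, EIN).  With the
sender constrained to unit power, the capacity is the classic water-filling
solution: input power fills the valleys of S_EIN up to a water level
lambda fixed by the power budget, and

    C = integral over [0, 1/2] of [log(lambda / S_EIN(f))]_+ df .

Numerically the DTFT is approximated on an N-point DFT grid
f_l = l / (N * TR): the EIN values are sorted ascending, the candidate
water level for the m smallest bins is

    lambda_m = (N + sum_{l<m} S_inc(l)) / m ,

m grows while the level stays above the next bin, and the capacity is
(2N)^{-1} sum_{l<m} log(lambda_m / S_inc(l)).  The discrete power budget
(1/N) sum_active (lambda - S) = 1 holds exactly by construction and is
asserted.  Bins where |H| = 0 carry infinite EIN and are never active; a
channel with all-zero taps has capacity 0.

Capacities are returned in nats by default (``units="bits"`` divides by
ln 2), so the closed-form identities used in testing read without
conversion factors, e.g. a one-tap channel has C = 1/2 log(1 + SNR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ChannelFit

__all__ = [
    "CapacityResult",
    "EinSpectrum",
    "ein_spectrum",
    "water_fill",
    "channel_capacity",
    "capacity_closed_form_one_tap",
]

_LN2 = math.log(2.0)


def _convert(value_nats: float, units: str) -> float:
    if units == "nats":
        return value_nats
    if units == "bits":
        return value_nats / _LN2
    raise ValueError(f"unknown capacity units {units!r}")


@dataclass(frozen=True)
class CapacityResult:
    """Capacity estimate with its water level and active-bin count."""

    capacity: float
    water_level: float
    active_bins: int
    grid_size: int
    units: str = "nats"


@dataclass(frozen=True)
class EinSpectrum:
    """Equivalent-input-noise PSD sampled on the DFT grid.

    ``values[l] = sigma^2 / |H(f_l)|^2`` with ``+inf`` exactly where the
    frequency response vanishes; ``frequencies[l] = l / (N * TR)`` in Hz.
    Conjugate symmetry of H for real taps implies
    ``values[l] == values[N - l]``.
    """

    values: np.ndarray
    frequencies: np.ndarray

    @property
    def grid_size(self) -> int:
        return self.values.size


def ein_spectrum(
    fit: ChannelFit, grid_size: int, tr_seconds: float = 1.0
) -> EinSpectrum:
    """EIN PSD of a fitted channel on an N-point DFT grid.

    The frequency response is the FFT of the tap vector zero-padded to
    length ``grid_size``.  All-zero taps yield an all-infinite spectrum,
    which signals zero capacity downstream rather than an error.
    """
    return _ein_from_taps(fit.coefficients, fit.noise_variance, grid_size, tr_seconds)


def _ein_from_taps(
    coefficients: np.ndarray,
    noise_variance: float,
    grid_size: int,
    tr_seconds: float = 1.0,
) -> EinSpectrum:
    a = np.asarray(coefficients, dtype=float)
    if grid_size < 2 or grid_size < a.size:
        raise ValueError("grid_size must be >= 2 and >= the channel order")
    if noise_variance < 0:
        raise ValueError("noise_variance must be nonnegative")
    mag2 = np.abs(np.fft.fft(a, n=grid_size)) ** 2
    # Bins where the response vanishes up to FFT rounding (e.g. the exact
    # zeros of [a, a] at f = 1/2) are treated as zero response: their EIN
    # is infinite and they can never be active.
    dead = mag2 <= mag2.max() * 1e-15
    with np.errstate(divide="ignore", invalid="ignore"):
        values = noise_variance / mag2
    values[dead | ~np.isfinite(mag2)] = np.inf
    frequencies = np.arange(grid_size) / (grid_size * tr_seconds)
    return EinSpectrum(values=values, frequencies=frequencies)


def water_fill(spectrum: EinSpectrum | np.ndarray, units: str = "nats") -> CapacityResult:
    """Discrete water-filling over a sorted EIN spectrum.

    Selects the largest active-bin count m (over the finite bins) for
    which the candidate water level exceeds the m-th smallest EIN value —
    the standard water-filling active set.  Returns zero capacity when no
    finite bin exists.
    """
    values = spectrum.values if isinstance(spectrum, EinSpectrum) else np.asarray(spectrum, float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("spectrum must be a nonempty 1-D array")
    if np.any(values < 0):
        raise ValueError("EIN values must be nonnegative")
    N = values.size
    # EIN bins beyond ~1e12 would contribute less capacity than machine
    # precision resolves (log(1 + N/S)/(2N) < 1e-12 nats) while breaking
    # float arithmetic in the water level; treat them as unusable.
    s = np.sort(values[np.isfinite(values) & (values <= 1e12)])
    if s.size == 0:
        return CapacityResult(0.0, math.nan, 0, N, units)
    m_grid = np.arange(1, s.size + 1, dtype=float)
    levels = (N + np.cumsum(s)) / m_grid
    # The admissible set {m : lambda_m > S^(m)} is a prefix; the optimal
    # active count is the last admissible m (= index of the first failure).
    # lambda_1 = N + S^(1) > S^(1) always, so the prefix is nonempty.
    failures = levels <= s
    m = int(np.argmax(failures)) if failures.any() else s.size
    assert m >= 1, "water level below the smallest EIN bin"
    level = float(levels[m - 1])
    # Discrete power budget: (1/N) * (m * level - sum of active bins) == 1
    # exactly, because level is defined from that sum (tolerance scaled to
    # the magnitude of the summands).
    budget = (m * level - float(np.sum(s[:m]))) / N
    assert abs(budget - 1.0) <= 1e-9 * max(1.0, float(s[m - 1])), "power budget violated"
    with np.errstate(divide="ignore"):
        cap_nats = float(np.sum(np.log(level / s[:m]))) / (2 * N)
    return CapacityResult(_convert(max(cap_nats, 0.0), units), level, m, N, units)


def channel_capacity(
    fit: ChannelFit,
    grid_size: int = 4096,
    tr_seconds: float = 1.0,
    units: str = "nats",
) -> CapacityResult:
    """Capacity of a fitted channel: EIN spectrum then water-filling."""
    return water_fill(ein_spectrum(fit, grid_size, tr_seconds), units=units)


def capacity_closed_form_one_tap(correlation: float, units: str = "nats") -> float:
    """Closed-form capacity of the order-1 standardized regression fit.

    For a one-tap channel fitted to standardized signals with sample
    correlation ``r`` in [0, 1), the EIN spectrum is flat and the capacity
    reduces to ``-1/2 log(1 - r^2)``.  Used as an analytic reference.
    """
    if not 0.0 <= correlation < 1.0:
        raise ValueError("correlation must lie in [0, 1)")
    return _convert(-0.5 * math.log1p(-correlation * correlation), units)
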