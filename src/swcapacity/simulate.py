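"""Ground-truth synthetic data generators.

Every generator is a pure function of its spec and seed (bit-identical
reruns) and produces data satisfying the model class the estimator
assumes — nonnegative FIR taps, additive white Gaussian noise independent
of the sender — so parameter-recovery experiments are well posed.  Four
designs are covered:

- a sender/receiver pair coupled by known taps (:func:`simulate_pair`),
- bilateral null scans with exchangeable directions
  (:func:`simulate_bilateral_null`) and a directed alternative
  (:func:`simulate_directed_scans`),
- task/rest block designs where coupling exists only in task trials
  (:func:`generate_task_rest_trials` / :func:`simulate_task_rest`),
- multi-ROI sessions switching among planted coupling states
  (:func:`simulate_state_sessions`, :func:`simulate_session`).

Sender model default is white Gaussian, matching the channel analysis
assumptions; AR(1) and band-limited options probe robustness to colored
senders, which real recordings certainly have.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .model import OrderSelectionConfig
from .sliding import RoiTimeSeriesSet, trial_measures_batch

__all__ = [
    "ChannelSimSpec",
    "SessionSimSpec",
    "simulate_pair",
    "simulate_bilateral_null",
    "simulate_directed_scans",
    "generate_task_rest_trials",
    "task_rest_capacity_samples",
    "simulate_task_rest",
    "simulate_state_sessions",
    "simulate_session",
    "correlated_pair",
    "simulate_capacity_pcorr_samples",
    "TaskRestTrials",
]


@dataclass(frozen=True)
class ChannelSimSpec:
    """Forward model of one coupled pair: y = taps * x + noise."""

    taps: tuple[float, ...]
    noise_sd: float = 1.0
    length: int = 1000
    sender_model: str = "white"  # white | ar1 | bandlimited
    ar_coef: float = 0.5
    passband: tuple[float, float] = (0.01, 0.2)  # cycles/sample, for bandlimited
    seed: int = 0
    tr_seconds: float = 1.0

    def __post_init__(self):
        if any(t < 0 for t in self.taps):
            raise ValueError("taps must be nonnegative (positive-coupling model class)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.length <= 10 * len(self.taps):
            raise ValueError("length must exceed 10x the tap count")
        if self.sender_model not in ("white", "ar1", "bandlimited"):
            raise ValueError(f"unknown sender_model {self.sender_model!r}")


def _sender_signal(spec: ChannelSimSpec, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal(spec.length)
    if spec.sender_model == "white":
        return z
    if spec.sender_model == "ar1":
        phi = spec.ar_coef
        x = lfilter([1.0], [1.0, -phi], z)
        return x * np.sqrt(1.0 - phi * phi)  # unit stationary variance
    lo, hi = spec.passband
    spec_fft = np.fft.rfft(z)
    freqs = np.fft.rfftfreq(spec.length)
    mask = (freqs >= lo) & (freqs <= hi)
    spec_fft[~mask] = 0.0
    x = np.fft.irfft(spec_fft, n=spec.length)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_pair(spec: ChannelSimSpec) -> RoiTimeSeriesSet:
    """One sender/receiver pair generated exactly from the FIR/AWGN model."""
    rng = np.random.default_rng(spec.seed)
    x = _sender_signal(spec, rng)
    y = lfilter(list(spec.taps), [1.0], x)
    if spec.noise_sd > 0:
        y = y + spec.noise_sd * rng.standard_normal(spec.length)
    return RoiTimeSeriesSet(
        values=np.vstack([x, y]),
        roi_labels=["sender", "receiver"],
        tr_seconds=spec.tr_seconds,
        scan_id=f"pair-seed{spec.seed}",
    )


def simulate_bilateral_null(
    n_scans: int = 22,
    T: int = 600,
    drive_taps: tuple[float, ...] = (0.7, 0.7),
    noise_sd: float = 1.0,
    gain_range: tuple[float, float] = (0.7, 1.3),
    tr_seconds: float = 1.0,
    seed: int = 0,
) -> list[RoiTimeSeriesSet]:
    """Bilateral scans with statistically exchangeable directions.

    Each scan shares a latent drive filtered by identical taps into both
    ROIs, plus independent per-ROI noise; a per-scan gain drawn from
    ``gain_range`` creates scan-to-scan variability of the coupling
    strength.  By construction no directed asymmetry exists.
    """
    if n_scans < 6:
        raise ValueError("need >= 6 scans")
    rng = np.random.default_rng(seed)
    scans = []
    for s in range(n_scans):
        z = rng.standard_normal(T)
        c = lfilter(list(drive_taps), [1.0], z)
        g = rng.uniform(*gain_range)
        left = g * c + noise_sd * rng.standard_normal(T)
        right = g * c + noise_sd * rng.standard_normal(T)
        scans.append(
            RoiTimeSeriesSet(
                values=np.vstack([left, right]),
                roi_labels=["S1L", "S1R"],
                tr_seconds=tr_seconds,
                scan_id=f"null-{s:02d}",
            )
        )
    return scans


def simulate_directed_scans(
    n_scans: int = 22,
    T: int = 600,
    taps: tuple[float, ...] = (0.5, 0.5),
    noise_sd: float = 1.0,
    gain_range: tuple[float, float] = (0.7, 1.3),
    tr_seconds: float = 1.0,
    seed: int = 0,
) -> list[RoiTimeSeriesSet]:
    """Directed alternative: coupling from the first ROI to the second
    only, with the same per-scan gain jitter as the bilateral null.

    Note that genuine directional asymmetry of the estimated capacity
    requires channel memory >= 2 taps: at order 1 the standardized fit is
    symmetric in its arguments.
    """
    if n_scans < 6:
        raise ValueError("need >= 6 scans")
    rng = np.random.default_rng(seed)
    scans = []
    for s in range(n_scans):
        g = rng.uniform(*gain_range)
        x = rng.standard_normal(T)
        y = g * lfilter(list(taps), [1.0], x) + noise_sd * rng.standard_normal(T)
        scans.append(
            RoiTimeSeriesSet(
                values=np.vstack([x, y]),
                roi_labels=["S1L", "S1R"],
                tr_seconds=tr_seconds,
                scan_id=f"directed-{s:02d}",
            )
        )
    return scans


@dataclass
class TaskRestTrials:
    """Raw trial time series of a task/rest block design.

    Arrays are shaped (subjects, pairs, trials, trial_length); coupling is
    planted only in task trials of the pairs flagged in ``planted``.
    """

    task_x: np.ndarray
    task_y: np.ndarray
    rest_x: np.ndarray
    rest_y: np.ndarray
    planted: np.ndarray
    pair_names: list[str] = field(default_factory=list)


def generate_task_rest_trials(
    n_subjects: int = 30,
    n_pairs: int = 20,
    n_planted: int = 4,
    effect_size: float = 1.0,
    n_trials: int = 4,
    trial_len: int = 16,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> TaskRestTrials:
    """Task/rest trial generator.

    Rest trials are uncoupled noise; task trials of the first
    ``n_planted`` pairs receive an order-1 coupling with tap
    ``effect_size`` (task SNR = effect_size^2 / noise_sd^2).  Trials are
    short blocks (16 samples by default) analyzed with a single window.
    """
    if n_planted > n_pairs:
        raise ValueError("planted pairs must be a subset of the pair set")
    rng = np.random.default_rng(seed)
    shape = (n_subjects, n_pairs, n_trials, trial_len)
    task_x = rng.standard_normal(shape)
    rest_x = rng.standard_normal(shape)
    task_y = noise_sd * rng.standard_normal(shape)
    rest_y = noise_sd * rng.standard_normal(shape)
    planted = np.zeros(n_pairs, dtype=bool)
    planted[:n_planted] = True
    task_y[:, planted] += effect_size * task_x[:, planted]
    pair_names = [f"pair{p:02d}" for p in range(n_pairs)]
    return TaskRestTrials(task_x, task_y, rest_x, rest_y, planted, pair_names)


def task_rest_capacity_samples(
    trials: TaskRestTrials,
    order_config: OrderSelectionConfig | None = None,
    grid_size: int = 256,
    units: str = "nats",
) -> pd.DataFrame:
    """Trial-wise single-window capacity, averaged to subject-level
    paired samples (one row per unit x pair, columns task/rest value)."""
    order_config = order_config or OrderSelectionConfig(criterion="AICc")
    S, P, T, n = trials.task_x.shape
    task = trial_measures_batch(
        trials.task_x.reshape(-1, n), trials.task_y.reshape(-1, n),
        order_config, grid_size, units,
    ).reshape(S, P, T).mean(axis=2)
    rest = trial_measures_batch(
        trials.rest_x.reshape(-1, n), trials.rest_y.reshape(-1, n),
        order_config, grid_size, units,
    ).reshape(S, P, T).mean(axis=2)
    rows = []
    for s in range(S):
        for p in range(P):
            rows.append(
                {
                    "unit_id": f"sub{s:02d}",
                    "pair": trials.pair_names[p],
                    "task_value": task[s, p],
                    "rest_value": rest[s, p],
                    "planted": bool(trials.planted[p]),
                }
            )
    return pd.DataFrame(rows)


def simulate_task_rest(
    n_subjects: int = 30,
    n_pairs: int = 20,
    n_planted: int = 4,
    effect_size: float = 1.0,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """End-to-end task/rest design: generate trials and reduce them to
    subject-level paired capacity samples."""
    trials = generate_task_rest_trials(
        n_subjects, n_pairs, n_planted, effect_size, seed=seed, **kwargs
    )
    return task_rest_capacity_samples(trials)


def simulate_state_sessions(
    n_states: int = 4,
    n_rois: int = 8,
    windows_per_state: int = 500,
    spread: float = 1.0,
    separation: float = 10.0,
    centroids: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window features sampled around planted state centroids.

    Returns ``(features, labels, centroids)``.  Auto-generated centroids
    are rescaled so the minimum pairwise centroid distance equals
    ``separation`` times the expected within-state deviation norm
    (``spread * sqrt(D)``), with D = n_rois * (n_rois - 1) directed pairs.
    ``spread == 0`` reproduces each centroid exactly.
    """
    if n_states < 2:
        raise ValueError("need >= 2 states")
    rng = np.random.default_rng(seed)
    D = n_rois * (n_rois - 1)
    if centroids is None:
        centroids = rng.uniform(0.0, 1.0, size=(n_states, D))
        dists = [
            np.linalg.norm(centroids[i] - centroids[j])
            for i in range(n_states)
            for j in range(i + 1, n_states)
        ]
        d_min = min(dists)
        if d_min > 0 and spread > 0:
            centroids = centroids * (separation * spread * np.sqrt(D) / d_min)
    else:
        centroids = np.asarray(centroids, float)
        if centroids.shape != (n_states, D):
            raise ValueError("centroids must be (n_states, n_rois*(n_rois-1))")
    labels = np.repeat(np.arange(n_states), windows_per_state)
    rng.shuffle(labels)
    features = centroids[labels]
    if spread > 0:
        features = features + rng.normal(0.0, spread, size=features.shape)
    return features, labels, centroids


def correlated_pair(r: float, n: int = 200, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Standardized pair with *exact* sample correlation ``r``.

    Built from an orthogonalized Gaussian basis, so the sample Pearson
    correlation equals ``r`` to machine precision — useful for checking
    closed-form capacity identities at order 1.
    """
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    from .model import standardize

    x = standardize(rng.standard_normal(n))
    z = rng.standard_normal(n)
    z = z - (z @ x) / (x @ x) * x  # orthogonal to x
    z = standardize(z)
    z = z - (z @ x) / (x @ x) * x  # second pass for exact orthogonality
    z = standardize(z)
    y = r * x + np.sqrt(1.0 - r * r) * z
    return x, y


def simulate_capacity_pcorr_samples(
    order: int,
    n_windows: int = 800,
    n: int = 200,
    snr_range: tuple[float, float] = (0.25, 4.0),
    grid_size: int = 512,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (capacity, prediction-correlation) samples at a known
    channel memory.

    Each window is generated from the FIR/AWGN forward model with the
    given tap count, random tap shape, unit noise and total SNR drawn
    log-uniformly from ``snr_range``, then fitted at the true order.
    Used to study how the capacity–p-corr relationship disperses as the
    connection duration grows (at memory 1 it is deterministic).
    """
    from .capacity import channel_capacity
    from .model import WindowSegment, fit_channel

    rng = np.random.default_rng(seed)
    caps = np.empty(n_windows)
    pcs = np.empty(n_windows)
    lo, hi = np.log(snr_range[0]), np.log(snr_range[1])
    for w in range(n_windows):
        snr = np.exp(rng.uniform(lo, hi))
        taps = rng.uniform(0.2, 1.0, order)
        taps *= np.sqrt(snr / np.sum(taps * taps))
        x = rng.standard_normal(n + order)
        y = lfilter(taps, [1.0], x) + rng.standard_normal(n + order)
        seg = WindowSegment(sender=x[order:], receiver=y[order:], lookback=x[:order])
        fit = fit_channel(seg, order)
        caps[w] = channel_capacity(fit, grid_size).capacity
        pcs[w] = fit.prediction_correlation()
    return caps, pcs


@dataclass(frozen=True)
class SessionSimSpec:
    """Multi-ROI session whose directed coupling switches over time.

    ``coupling_schedule`` is a list of ``(span_samples, couplings)``
    entries partitioning the session; ``couplings`` maps directed index
    pairs (sender, receiver) to tap tuples (empty diagonal implied).
    """

    n_rois: int
    coupling_schedule: tuple
    noise_sd: float = 1.0
    tr_seconds: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for _, couplings in self.coupling_schedule:
            for (i, j) in couplings:
                if i == j:
                    raise ValueError("coupling matrices have empty diagonal")
                if not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                    raise ValueError("coupling indices out of range")


def simulate_session(spec: SessionSimSpec) -> RoiTimeSeriesSet:
    """Generate a state-switching multi-ROI session.

    Each ROI carries independent unit-variance innovations; within each
    schedule span, receiver ROIs additionally accumulate the FIR-filtered
    innovations of their senders (feed-forward coupling from innovations,
    avoiding recursive loops).
    """
    rng = np.random.default_rng(spec.seed)
    segments = []
    for span, couplings in spec.coupling_schedule:
        e = rng.standard_normal((spec.n_rois, span))
        s = spec.noise_sd * rng.standard_normal((spec.n_rois, span))
        s += e
        for (i, j), taps in couplings.items():
            s[j] += lfilter(list(taps), [1.0], e[i])
        segments.append(s)
    values = np.concatenate(segments, axis=1)
    return RoiTimeSeriesSet(
        values=values,
        roi_labels=[f"roi{r:02d}" for r in range(spec.n_rois)],
        tr_seconds=spec.tr_seconds,
        scan_id=f"session-seed{spec.seed}",
    )
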