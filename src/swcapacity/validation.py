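"""Statistical validation of directed connectivity estimates.

Three procedures, mirroring how a new directed measure is vetted:

1. **Sensitivity** — does the measure increase when a real directed
   interaction is switched on?  Per directed pair, task vs rest values are
   compared across units (subjects) with right-tailed paired t-tests after
   a coefficient-of-variation (CV) filter, and the surviving p-values are
   FDR-corrected (Benjamini-Hochberg).
2. **Specificity** — does the measure stay symmetric when no directionality
   exists?  In resting data with no expected hemispheric bias, the per-scan
   absolute directional asymmetry is tested against the scan-to-scan
   variability of the measure with a left-tailed Wilcoxon signed-rank test;
   rejecting H0 (median asymmetry >= variability) supports a low
   false-positive tendency in inferred directionality.
3. **Cross-modal correspondence** — do concurrent modalities agree?
   Pearson correlations of paired windowed series (bootstrap over windows
   within scan) or of time-averaged directed matrices (bootstrap over
   scans) with percentile intervals and a one-sided p-value for a positive
   correlation.

All bootstrap resampling is driven by a NumPy Generator seeded by the
caller, so results are reproducible bit-exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "InsufficientDataError",
    "TestReport",
    "BootstrapSummary",
    "sensitivity_test",
    "specificity_test",
    "bootstrap_window_correlation",
    "bootstrap_matrix_correlation",
]

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few units/scans for the requested test."""


@dataclass
class TestReport:
    """Outcome of one validation test."""

    statistic: float
    p_value: float
    alpha: float
    significant_set: list = field(default_factory=list)
    q_values: np.ndarray | None = None
    rejected: bool | None = None
    table: pd.DataFrame | None = None


def sensitivity_test(
    samples: pd.DataFrame,
    cv_threshold: float = 0.30,
    q_threshold: float = 0.02,
) -> TestReport:
    """Task-evoked sensitivity with CV filtering and BH-FDR.

    ``samples`` has one row per (unit, directed pair) with columns
    ``unit_id``, ``pair``, ``task_value``, ``rest_value`` (unit = subject;
    values are that unit's mean connectivity per condition).  Per pair:
    CV = std/mean of the task values across units; pairs with CV >=
    ``cv_threshold`` (or nonpositive mean, where CV is undefined) are
    excluded before testing.  Remaining pairs get right-tailed paired
    t-tests (task > rest), BH correction across tested pairs, and the
    significant set is ``q < q_threshold``.
    """
    if not 0 < cv_threshold < 1 or not 0 < q_threshold < 1:
        raise ValueError("cv_threshold and q_threshold must lie in (0, 1)")
    required = {"unit_id", "pair", "task_value", "rest_value"}
    if not required.issubset(samples.columns):
        raise ValueError(f"samples must have columns {sorted(required)}")
    rows = []
    for pair, grp in samples.groupby("pair", sort=True):
        task = grp["task_value"].to_numpy(float)
        rest = grp["rest_value"].to_numpy(float)
        if task.size < 3:
            raise InsufficientDataError(f"pair {pair}: need >= 3 units")
        mean = task.mean()
        if mean <= 0:
            logger.info("pair %s: nonpositive mean task value, CV undefined; excluded", pair)
            cv, tested = math.nan, False
        else:
            cv = task.std(ddof=1) / mean
            tested = cv < cv_threshold
        t_stat = p = math.nan
        if tested:
            diffs = task - rest
            if np.all(diffs == 0):
                t_stat, p = 0.0, 1.0  # no task effect at all
            else:
                t_stat, p = stats.ttest_rel(task, rest, alternative="greater")
        rows.append(
            {"pair": pair, "n_units": task.size, "cv": cv, "tested": tested,
             "t": float(t_stat), "p": float(p)}
        )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    table["significant"] = False
    tested_mask = table["tested"].to_numpy()
    if tested_mask.any():
        ps = table.loc[tested_mask, "p"].to_numpy()
        _, qs, _, _ = multipletests(ps, alpha=q_threshold, method="fdr_bh")
        table.loc[tested_mask, "q"] = qs
        table.loc[tested_mask, "significant"] = qs < q_threshold
    significant = table.loc[table["significant"], "pair"].tolist()
    return TestReport(
        statistic=math.nan,
        p_value=math.nan,
        alpha=q_threshold,
        significant_set=significant,
        q_values=table["q"].to_numpy(),
        rejected=len(significant) > 0,
        table=table,
    )


def specificity_test(
    samples: pd.DataFrame,
    variability: float | None = None,
    alpha: float = 0.02,
) -> TestReport:
    """Directional-asymmetry specificity via left-tailed signed-rank test.

    ``samples`` has one row per scan with columns ``scan_id``,
    ``forward_mean``, ``backward_mean`` (time-averaged connectivity of the
    two directions of the same pair).  Per scan the asymmetry is
    ``|forward - backward|``; the reference scan-to-scan ``variability``
    defaults to the standard deviation across scans of the mean of the two
    directions.  H0: median(asymmetry) >= variability; a small p-value
    (p < alpha) rejects H0, i.e. directional asymmetry is insignificant
    relative to baseline scan-to-scan fluctuation.

    Zero differences are dropped (Wilcoxon's original treatment); the
    exact null distribution is used for small samples without ties.
    """
    required = {"scan_id", "forward_mean", "backward_mean"}
    if not required.issubset(samples.columns):
        raise ValueError(f"samples must have columns {sorted(required)}")
    fwd = samples["forward_mean"].to_numpy(float)
    bwd = samples["backward_mean"].to_numpy(float)
    if fwd.size < 6:
        raise InsufficientDataError("need >= 6 scans for the signed-rank test")
    asym = np.abs(fwd - bwd)
    if variability is None:
        variability = float(np.std((fwd + bwd) / 2.0, ddof=1))
    d = asym - variability
    nonzero = d[d != 0]
    if nonzero.size == 0:
        stat_val, p = math.nan, 1.0
    else:
        stat_val, p = stats.wilcoxon(
            nonzero, alternative="less", zero_method="wilcox", method="auto"
        )
    return TestReport(
        statistic=float(stat_val),
        p_value=float(p),
        alpha=alpha,
        rejected=bool(p < alpha),
        table=pd.DataFrame(
            {"scan_id": samples["scan_id"], "asymmetry": asym,
             "variability": variability, "difference": d}
        ),
    )


@dataclass
class BootstrapSummary:
    """Replicate distribution of a bootstrap correlation."""

    replicates: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    p_positive: float  # one-sided p for correlation > 0: fraction of replicates <= 0
    n_scans: int

    @classmethod
    def from_replicates(cls, reps: np.ndarray, n_scans: int, ci: float = 95.0):
        lo, hi = np.percentile(reps, [(100 - ci) / 2, 100 - (100 - ci) / 2])
        return cls(
            replicates=reps,
            mean=float(np.mean(reps)),
            ci_low=float(lo),
            ci_high=float(hi),
            p_positive=float(np.mean(reps <= 0)),
            n_scans=n_scans,
        )


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(ac * ac, axis=1) * np.sum(bc * bc, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sum(ac * bc, axis=1) / denom


def bootstrap_window_correlation(
    series_a: dict[str, np.ndarray],
    series_b: dict[str, np.ndarray],
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
) -> BootstrapSummary:
    """Bootstrap Pearson correlation of paired windowed series.

    Each replicate resamples window indices with replacement *within each
    scan* (the same indices for both modalities, preserving the pairing),
    concatenates the paired values across scans, and computes the Pearson
    correlation.  Scans with fewer than 2 valid paired windows are
    excluded with a warning; NaN windows are dropped pairwise per scan.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if set(series_a) != set(series_b):
        raise ValueError("series_a and series_b must cover the same scans")
    rng = np.random.default_rng(seed)
    pairs = []
    for scan in sorted(series_a):
        a = np.asarray(series_a[scan], float)
        b = np.asarray(series_b[scan], float)
        if a.shape != b.shape:
            raise ValueError(f"scan {scan}: unpaired window counts")
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2:
            logger.warning("scan %s: fewer than 2 valid windows, excluded", scan)
            continue
        pairs.append((a[ok], b[ok]))
    if not pairs:
        raise InsufficientDataError("no scan with >= 2 valid windows")
    boot_a, boot_b = [], []
    for a, b in pairs:
        idx = rng.integers(0, a.size, size=(n_boot, a.size))
        boot_a.append(a[idx])
        boot_b.append(b[idx])
    reps = _pearson_rows(np.concatenate(boot_a, axis=1), np.concatenate(boot_b, axis=1))
    return BootstrapSummary.from_replicates(reps, n_scans=len(pairs), ci=ci)


def bootstrap_matrix_correlation(
    matrices_a: list[np.ndarray],
    matrices_b: list[np.ndarray],
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
) -> BootstrapSummary:
    """Bootstrap Pearson correlation of time-averaged directed matrices.

    Each replicate resamples scans with replacement, averages the per-scan
    matrices within each modality, vectorizes the off-diagonal directed
    entries and correlates the two modalities.
    """
    if len(matrices_a) != len(matrices_b):
        raise ValueError("matched scan lists required")
    S = len(matrices_a)
    if S < 2:
        raise InsufficientDataError("bootstrap over scans needs >= 2 scans")
    A = np.stack([np.asarray(m, float) for m in matrices_a])
    B = np.stack([np.asarray(m, float) for m in matrices_b])
    if A.shape != B.shape or A.shape[1] != A.shape[2]:
        raise ValueError("matrices must be square and share ROI sets")
    off = ~np.eye(A.shape[1], dtype=bool)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, S, size=(n_boot, S))
    reps = np.empty(n_boot)
    for i in range(n_boot):
        va = A[idx[i]].mean(axis=0)[off]
        vb = B[idx[i]].mean(axis=0)[off]
        ok = np.isfinite(va) & np.isfinite(vb)
        reps[i] = _pearson_rows(va[ok][None, :], vb[ok][None, :])[0]
    return BootstrapSummary.from_replicates(reps, n_scans=S, ci=ci)
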