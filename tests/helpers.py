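"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: water-filling is
cross-validated against scalar root-finding on the KKT condition and
against direct constrained maximization of the mutual information; the
signed-rank test against exhaustive sign enumeration; BH q-values against
the brute-force definition.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import brentq, minimize


def oracle_capacity_root(values: np.ndarray, N: int) -> float:
    """Water-filling capacity via root-finding on the power budget.

    Solves sum_l (lambda - S_l)_+ = N for the water level by bracketing
    and Brent's method, then evaluates the capacity sum — no sorting or
    iterative active-set logic shared with the implementation under test.
    """
    s = np.sort(values[np.isfinite(values) & (values <= 1e12)])
    if s.size == 0:
        return 0.0

    def excess(lam):
        return np.sum(np.clip(lam - s, 0.0, None)) - N

    lo = float(s[0])
    hi = float(s[0]) + N + 1.0
    while excess(hi) < 0:
        hi *= 2.0
    lam = brentq(excess, lo, hi, xtol=1e-14 * max(1.0, lo), rtol=1e-15)
    active = s < lam
    return float(np.sum(np.log(lam / s[active]))) / (2 * N)


def oracle_capacity_convex(values: np.ndarray, N: int) -> float:
    """Capacity by direct convex maximization of the mutual information.

    Maximizes sum_l log(1 + P_l / S_l) over P >= 0, sum P = N with SLSQP.
    Only intended for small grids (N <= ~16).
    """
    s = np.asarray(values, float)
    finite = np.isfinite(s)
    sf = s[finite]
    n = sf.size
    if n == 0:
        return 0.0

    def neg_mi(P):
        return -np.sum(np.log1p(P / sf))

    def grad(P):
        return -1.0 / (sf + P)

    cons = [{"type": "eq", "fun": lambda P: np.sum(P) - N,
             "jac": lambda P: np.ones_like(P)}]
    res = minimize(
        neg_mi, np.full(n, N / n), jac=grad, method="SLSQP",
        bounds=[(0.0, None)] * n, constraints=cons,
        options={"maxiter": 500, "ftol": 1e-14},
    )
    assert res.success, res.message
    return float(-res.fun) / (2 * N)


def water_fill_folded(values: np.ndarray) -> float:
    """Capacity summing only bins 0..N/2 with symmetry weights.

    For conjugate-symmetric EIN spectra, integrating over [0, 1/2] with
    weight 2 on interior bins must equal the full-grid sum.
    """
    N = values.size
    half = N // 2
    idx = np.arange(half + 1)
    weights = np.where((idx == 0) | ((N % 2 == 0) & (idx == half)), 1.0, 2.0)
    s = values[idx]
    keep = np.isfinite(s) & (s <= 1e12)
    s, w = s[keep], weights[keep]
    order = np.argsort(s, kind="stable")
    s, w = s[order], w[order]
    cw = np.cumsum(w)
    levels = (N + np.cumsum(w * s)) / cw
    failures = levels <= s
    m = int(np.argmax(failures)) if failures.any() else s.size
    if m == 0:
        return 0.0
    lam = levels[m - 1]
    return float(np.sum(w[:m] * np.log(lam / s[:m]))) / (2 * N)


def wilcoxon_left_p_enumeration(d: np.ndarray) -> float:
    """Exact left-tailed signed-rank p-value by enumerating all 2^n signs.

    Zeros dropped; ranks of |d| with midranks for ties.  The p-value is
    the null probability that W+ is <= the observed W+.
    """
    from scipy.stats import rankdata

    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    assert 1 <= n <= 12
    ranks = rankdata(np.abs(d))
    w_obs = float(np.sum(ranks[d > 0]))
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = float(np.sum(ranks[np.array(signs, bool)]))
        if w <= w_obs:
            count += 1
    return count / 2.0**n


def bh_qvalues_bruteforce(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values from the definition:
    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
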