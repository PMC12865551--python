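"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle follows the textbook definition directly (loops, explicit
sums, grid searches) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def bh_stepup_brute(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up by the literal definition.

    Sort ascending; q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; map
    back to input order.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


def permanova_f_brute(dist: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from explicit within-group sums of squared distances."""
    n = len(labels)
    groups = sorted(set(labels.tolist()))
    k = len(groups)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += dist[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        acc = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += dist[idx[a], idx[b]] ** 2
        ss_within += acc / len(idx)
    ss_between = ss_total - ss_within
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, ss_between / ss_total


def euclidean_distance_brute(columns: np.ndarray) -> np.ndarray:
    """Double-loop Euclidean distance between matrix columns."""
    n = columns.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(np.sum((columns[:, i] - columns[:, j]) ** 2))
    return out


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients by explicitly solving the normal equations."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def cosine_peak_grid(
    mesor: float,
    beta_sin: float,
    beta_cos: float,
    period_h: float,
    step_h: float = 0.01,
) -> float:
    """Grid-search maximiser of M + bs*sin(wt) + bc*cos(wt) on [0, P)."""
    t = np.arange(0.0, period_h, step_h)
    omega = 2.0 * np.pi / period_h
    curve = mesor + beta_sin * np.sin(omega * t) + beta_cos * np.cos(omega * t)
    return float(t[int(np.argmax(curve))])


def circular_gap_h(a: float, b: float, period_h: float = 24.0) -> float:
    """Absolute circular distance between two clock times, in [0, P/2]."""
    d = abs(a - b) % period_h
    return min(d, period_h - d)
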