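"""Storey q-values: pi0 estimation by the lambda smoother plus scaled step-up.

q_i = pi0 * min_{j >= i} m * p_(j) / j  over the sorted p-values; with pi0
forced to 1 this is exactly Benjamini-Hochberg.  pi0 is estimated from the
tail counts pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over the grid
lambda = 0.05, 0.10, ..., 0.95, smoothed by a cubic fit whose fitted values
are averaged over the upper half of the grid, clipped to (0, 1].
"""

from __future__ import annotations

import numpy as np

__all__ = ["estimate_pi0", "qvalues"]

LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def _check_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def estimate_pi0(p, lambdas: np.ndarray = LAMBDA_GRID) -> float:
    """Estimate the proportion of true nulls from a p-value collection."""
    p = _check_p(p)
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if m < 20:
        # too few tests for the smoother; conservative default
        return 1.0
    coef = np.polyfit(lambdas, pi0_l, 3)
    # average the smoothed curve over the upper half of the grid: much more
    # stable than the fitted endpoint, which extrapolates tail-count noise
    upper = lambdas[lambdas >= 0.5]
    pi0 = float(np.mean(np.polyval(coef, upper)))
    return float(min(max(pi0, 1.0 / m), 1.0))


def qvalues(p, pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Return (q-values, pi0); monotone non-decreasing with p."""
    p = _check_p(p)
    m = p.size
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1] * pi0
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, float(pi0)
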