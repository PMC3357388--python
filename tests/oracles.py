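"""Independent brute-force oracles used to cross-check the implementations.

Everything here deliberately avoids the code paths under test: grid
search instead of least squares, subset enumeration instead of closed
forms, classical balanced sums-of-squares formulas instead of model
comparison.
"""

from itertools import combinations

import numpy as np


def cosinor_grid_search(
    times,
    values,
    period: float = 24.0,
    phi_step: float = 0.01,
    amp_step: float = 0.001,
    amp_max: float = 4.0,
):
    """Minimize RSS of m + A*cos(2*pi*(t-phi)/T) over an (A, phi) grid.

    The mesor is profiled out analytically (mean of residuals), which is
    independent of the OLS normal-equations path. Returns
    (amplitude, phi, mesor, rss).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    phis = np.arange(0.0, period, phi_step)
    basis = np.cos(2 * np.pi * (t[None, :] - phis[:, None]) / period)
    yc = y - y.mean()
    bc = basis - basis.mean(axis=1, keepdims=True)
    s0 = float(np.sum(yc**2))
    s1 = bc @ yc
    s2 = np.sum(bc * bc, axis=1)
    amps = np.arange(0.0, amp_max, amp_step)
    rss = s0 - 2.0 * s1[:, None] * amps[None, :] + s2[:, None] * amps[None, :] ** 2
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    amp, phi = amps[j], phis[i]
    mesor = y.mean() - amp * basis[i].mean()
    return float(amp), float(phi), float(mesor), float(rss[i, j])


def hypergeom_tail_by_enumeration(k: int, set_size: int, list_size: int, universe: int):
    """P(overlap >= k) by enumerating every possible drawn list."""
    target = set(range(set_size))
    total = 0
    hits = 0
    for draw in combinations(range(universe), list_size):
        total += 1
        if len(target.intersection(draw)) >= k:
            hits += 1
    return hits, total


def balanced_anova_ss(cells: np.ndarray):
    """Classical sums of squares for a balanced a x b x r layout."""
    a, b, r = cells.shape
    grand = cells.mean()
    row = cells.mean(axis=(1, 2))
    col = cells.mean(axis=(0, 2))
    cell = cells.mean(axis=2)
    ss_a = b * r * np.sum((row - grand) ** 2)
    ss_b = a * r * np.sum((col - grand) ** 2)
    ss_ab = r * np.sum(
        (cell - row[:, None] - col[None, :] + grand) ** 2
    )
    ss_err = np.sum((cells - cell[:, :, None]) ** 2)
    ss_total = np.sum((cells - grand) ** 2)
    return ss_a, ss_b, ss_ab, ss_err, ss_total


def welch_t(x1, x2):
    """Welch two-sample t-test via scipy (independent of the hand-rolled path)."""
    from scipy import stats

    res = stats.ttest_ind(x2, x1, equal_var=False)
    return float(res.statistic), float(res.pvalue)
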