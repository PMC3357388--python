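"""Cosinor/harmonic regression rhythm detection and damped-oscillation fits.

The workhorse is ordinary least squares on the harmonic basis

    y(t) = m + sum_{k=1..K} [ a_k cos(2*pi*k*t/T) + b_k sin(2*pi*k*t/T) ]

with an F-test of the full model against the intercept-only null.
For K=1 the amplitude is A = sqrt(a1^2 + b1^2) and the acrophase
phi = (T/2pi) * atan2(b1, a1) mod T, i.e. the peak time of the fitted
sinusoid in ZT hours. Per-condition q-values use Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import AnalysisConfig
from .errors import ValidationError

_SATURATION_RTOL = 1e-12


@dataclass
class HarmonicFit:
    """A per-series cosinor fit with its rhythmicity F-test."""

    mesor: float
    coefficients: np.ndarray  # shape (K, 2): (a_k, b_k)
    amplitude: float
    acrophase: float  # hours in [0, T)
    rss_full: float
    rss_null: float
    df_model: int
    df_resid: int
    f_stat: float
    p_value: float
    saturated: bool = False


def harmonic_design(times: np.ndarray, n_harmonics: int, period: float) -> np.ndarray:
    omega = 2.0 * np.pi / period
    cols = [np.ones_like(times)]
    for k in range(1, n_harmonics + 1):
        cols.append(np.cos(omega * k * times))
        cols.append(np.sin(omega * k * times))
    return np.column_stack(cols)


def fit_cosinor(
    times, values, n_harmonics: int = 1, period: float = 24.0
) -> HarmonicFit:
    """Fit the harmonic regression and F-test rhythmicity for one series.

    Requires ``2K + 1 < number of distinct timepoints (mod T)`` for
    identifiability and at least one residual degree of freedom. A flat
    series yields F=0, p=1; an exactly-fitting series is flagged
    ``saturated`` with p=0.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("times and values must be 1-D arrays of equal length")
    n = t.size
    k = int(n_harmonics)
    if k < 1:
        raise ValidationError("n_harmonics must be >= 1")
    n_params = 2 * k + 1
    distinct = np.unique(np.round(np.mod(t, period), 9)).size
    if n_params >= distinct:
        raise ValidationError(
            f"K={k} harmonics need more than {n_params} distinct timepoints; "
            f"only {distinct} present"
        )
    df_resid = n - n_params
    if df_resid < 1:
        raise ValidationError(
            f"zero residual degrees of freedom: n={n}, parameters={n_params}"
        )

    design = harmonic_design(t, k, period)
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    rss_full = float(np.sum((y - fitted) ** 2))
    rss_null = float(np.sum((y - y.mean()) ** 2))
    rss_full = min(rss_full, rss_null)  # guard float noise on flat input

    mesor = float(beta[0])
    coeffs = beta[1:].reshape(k, 2)
    if k == 1:
        a1, b1 = coeffs[0]
        amplitude = float(np.hypot(a1, b1))
        acrophase = float(np.mod(np.arctan2(b1, a1) * period / (2 * np.pi), period))
    else:
        grid = np.arange(0.0, period, 0.01)
        curve = harmonic_design(grid, k, period) @ beta
        amplitude = float((curve.max() - curve.min()) / 2.0)
        acrophase = float(grid[np.argmax(curve)])

    saturated = False
    if rss_null <= _SATURATION_RTOL * max(1.0, float(np.abs(y).max()) ** 2):
        f_stat, p_value = 0.0, 1.0  # flat profile: null and full coincide
    elif rss_full <= _SATURATION_RTOL * rss_null:
        f_stat, p_value, saturated = np.inf, 0.0, True
    else:
        f_stat = ((rss_null - rss_full) / (2 * k)) / (rss_full / df_resid)
        p_value = float(stats.f.sf(f_stat, 2 * k, df_resid))
    return HarmonicFit(
        mesor=mesor,
        coefficients=coeffs,
        amplitude=amplitude,
        acrophase=acrophase,
        rss_full=rss_full,
        rss_null=rss_null,
        df_model=2 * k,
        df_resid=df_resid,
        f_stat=float(f_stat),
        p_value=float(p_value),
        saturated=saturated,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def detect_rhythms(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    condition: str,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-gene cosinor fits for one condition with BH-corrected calls.

    Returns a DataFrame with one row per gene (matrix order) carrying the
    fit parameters, F, p, BH q across all genes of the condition, and the
    boolean ``rhythmic`` call (q < alpha).
    """
    config = config or AnalysisConfig()
    mask = samples["condition"] == condition
    if not mask.any():
        present = sorted(samples["condition"].unique())
        raise ValidationError(f"condition {condition!r} not present; have {present}")
    sub = samples.loc[mask]
    cols = sub["sample_id"].tolist()
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise ValidationError(f"samples absent from matrix columns: {missing}")
    times = sub["zt"].to_numpy(dtype=float)
    values = matrix.loc[:, cols].to_numpy(dtype=float)

    rows = []
    for gene, y in zip(matrix.index, values):
        fit = fit_cosinor(times, y, config.max_harmonics_K, config.period_T)
        rows.append(
            (
                gene,
                condition,
                fit.mesor,
                fit.amplitude,
                fit.acrophase,
                fit.f_stat,
                fit.p_value,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["gene", "condition", "mesor", "amplitude", "acrophase", "f_stat", "p_value"],
    )
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["rhythmic"] = table["q_value"] < config.alpha
    return table


# ---------------------------------------------------------------------------
# damped oscillations (tissue-explant luminescence traces)


@dataclass
class DampedOscFit:
    """Exponentially damped cosine fit of a detrended luminescence trace."""

    mesor: float
    amplitude: float
    period_tau: float
    phase: float  # hours in [0, period_tau)
    damping_lambda: float  # per hour, >= 0
    rss: float
    converged: bool


def _running_mean_detrend(t: np.ndarray, y: np.ndarray, window: float):
    """Centered running mean over ``window`` hours; only the fully covered
    interior region is returned, so same-frequency structure is preserved
    exactly and edge bias is avoided."""
    half = window / 2.0
    lo, hi = t[0] + half, t[-1] - half
    keep = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    trend = np.empty(keep.sum())
    for i, ti in enumerate(t[keep]):
        in_win = (t >= ti - half - 1e-9) & (t <= ti + half + 1e-9)
        trend[i] = y[in_win].mean()
    return t[keep], y[keep] - trend


def fit_damped_oscillation(
    times,
    values,
    period_bounds: tuple[float, float] = (16.0, 32.0),
    n_phase_starts: int = 8,
) -> DampedOscFit:
    """Fit ``m + A*exp(-lambda*t)*cos(2*pi*(t - phi)/tau)`` to a trace.

    The trace is first detrended with a centered running mean whose window
    equals the lower period bound, then fit by bounded nonlinear least
    squares from a grid of phase and period starts. ``converged`` is False
    when the trace carries no oscillation or no start converges.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    lower, upper = period_bounds
    if not 0 < lower < upper:
        raise ValidationError(f"invalid period bounds {period_bounds}")
    span = t[-1] - t[0]
    if span < 2 * lower:
        raise ValidationError(
            f"trace spans {span:.1f} h; need >= {2 * lower:.1f} h (twice the lower period bound)"
        )
    td, yd = _running_mean_detrend(t, y, window=lower)
    scale = max(np.abs(y).max(), 1.0)
    if yd.std() <= 1e-9 * scale:
        return DampedOscFit(
            mesor=float(y.mean()),
            amplitude=np.nan,
            period_tau=np.nan,
            phase=np.nan,
            damping_lambda=np.nan,
            rss=np.nan,
            converged=False,
        )

    t0 = td[0]

    def residuals(params):
        m, amp, lam, tau, phi = params
        return m + amp * np.exp(-lam * (td - t0)) * np.cos(
            2 * np.pi * (td - phi) / tau
        ) - yd

    amp0 = float(yd.std() * np.sqrt(2.0))
    best = None
    mid = 0.5 * (lower + upper)
    for tau0 in (lower * 1.05, mid, upper * 0.95):
        for phi0 in np.arange(n_phase_starts) * tau0 / n_phase_starts:
            try:
                sol = optimize.least_squares(
                    residuals,
                    x0=[0.0, amp0, 0.01, tau0, phi0],
                    bounds=(
                        [-np.inf, 0.0, 0.0, lower, -np.inf],
                        [np.inf, np.inf, 1.0, upper, np.inf],
                    ),
                    method="trf",
                )
            except Exception:
                continue
            if not sol.success:
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    if best is None:
        return DampedOscFit(
            mesor=np.nan,
            amplitude=np.nan,
            period_tau=np.nan,
            phase=np.nan,
            damping_lambda=np.nan,
            rss=np.nan,
            converged=False,
        )
    rss, (m, amp, lam, tau, phi) = best
    # undo the time-origin shift of the damping envelope
    amp_at_zero = amp * np.exp(lam * t0)
    return DampedOscFit(
        mesor=float(y.mean()),
        amplitude=float(amp_at_zero),
        period_tau=float(tau),
        phase=float(np.mod(phi, tau)),
        damping_lambda=float(lam),
        rss=float(rss),
        converged=True,
    )
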