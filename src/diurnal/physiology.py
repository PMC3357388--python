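"""Statistics for diurnal physiology profiles and metabolic tests.

Two-way fixed-effects ANOVA (condition x time) with Bonferroni per-time
post-hoc contrasts, cosinor peak-phase estimation of a profile, trapezoid
area under tolerance-test curves, and relative qPCR quantitation by the
delta-delta-Ct method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .rhythms import fit_cosinor

PROFILE_COLUMNS = ("condition", "zt", "replicate", "value")


@dataclass
class AnovaResult:
    """Type-II two-way ANOVA table plus per-timepoint condition contrasts."""

    effects: pd.DataFrame  # effect, sum_sq, df, f_stat, p_value
    posthoc: pd.DataFrame  # zt, diff, t_stat, p_value, p_bonferroni
    residual_ss: float
    residual_df: int


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    return float(np.sum((y - design @ beta) ** 2))


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    # treatment coding, first level dropped
    out = np.zeros((codes.size, n_levels - 1))
    for lvl in range(1, n_levels):
        out[codes == lvl, lvl - 1] = 1.0
    return out


def two_way_anova(profile: pd.DataFrame) -> AnovaResult:
    """Condition x time fixed-effects ANOVA of a physiology profile.

    ``profile`` needs columns ``condition``, ``zt`` and ``value``.
    Effects use type-II sums of squares (equal to the classical
    decomposition for balanced designs). Post-hoc condition contrasts are
    computed per timepoint with the pooled residual variance and
    Bonferroni-multiplied by the number of timepoints; they require
    exactly two conditions.
    """
    for col in ("condition", "zt", "value"):
        if col not in profile.columns:
            raise ValidationError(f"profile missing column {col!r}")
    y = profile["value"].to_numpy(dtype=float)
    cond_codes, cond_levels = pd.factorize(profile["condition"], sort=True)
    zt_codes, zt_levels = pd.factorize(profile["zt"], sort=True)
    a, b = len(cond_levels), len(zt_levels)
    if a < 2 or b < 2:
        raise ValidationError("two-way ANOVA needs >= 2 conditions and >= 2 timepoints")
    cells = pd.crosstab(cond_codes, zt_codes)
    cells = cells.reindex(index=range(a), columns=range(b), fill_value=0)
    empty = np.argwhere(cells.to_numpy() == 0)
    if len(empty):
        i, j = empty[0]
        raise ValidationError(
            f"empty design cell: condition {cond_levels[i]!r} at ZT {zt_levels[j]}"
        )

    n = y.size
    intercept = np.ones((n, 1))
    x_a = _dummies(cond_codes, a)
    x_b = _dummies(zt_codes, b)
    x_ab = np.column_stack(
        [x_a[:, i] * x_b[:, j] for i in range(a - 1) for j in range(b - 1)]
    )
    full = np.column_stack([intercept, x_a, x_b, x_ab])
    rss_full = _rss(full, y)
    df_resid = n - a * b
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom (need >= 2 replicates/cell)")

    # type-II: each main effect adjusted for the other, interaction last
    rss_ab = _rss(np.column_stack([intercept, x_a, x_b]), y)
    ss_a = _rss(np.column_stack([intercept, x_b]), y) - rss_ab
    ss_b = _rss(np.column_stack([intercept, x_a]), y) - rss_ab
    ss_ab = rss_ab - rss_full
    scale = max(float(np.sum((y - y.mean()) ** 2)), 1.0)

    def f_and_p(ss: float, df: int) -> tuple[float, float]:
        ss = max(ss, 0.0)
        mse = rss_full / df_resid
        if rss_full <= 1e-12 * scale:  # saturated: no residual noise
            if ss <= 1e-12 * scale:
                return 0.0, 1.0
            return np.inf, 0.0
        f = (ss / df) / mse
        return float(f), float(stats.f.sf(f, df, df_resid))

    effect_rows = []
    for name, ss, df in (
        ("condition", ss_a, a - 1),
        ("time", ss_b, b - 1),
        ("interaction", ss_ab, (a - 1) * (b - 1)),
    ):
        f, p = f_and_p(ss, df)
        effect_rows.append((name, max(ss, 0.0), df, f, p))
    effects = pd.DataFrame(
        effect_rows, columns=["effect", "sum_sq", "df", "f_stat", "p_value"]
    )

    posthoc_rows = []
    if a == 2:
        mse = rss_full / df_resid
        for j, zt in enumerate(zt_levels):
            sel = zt_codes == j
            g1 = y[sel & (cond_codes == 0)]
            g2 = y[sel & (cond_codes == 1)]
            diff = g2.mean() - g1.mean()
            se = np.sqrt(mse * (1.0 / g1.size + 1.0 / g2.size))
            if se <= 1e-12 * np.sqrt(scale):
                t_stat = np.inf if abs(diff) > 0 else 0.0
                p = 0.0 if abs(diff) > 0 else 1.0
            else:
                t_stat = diff / se
                p = float(2.0 * stats.t.sf(abs(t_stat), df_resid))
            posthoc_rows.append((zt, diff, t_stat, p, min(1.0, p * b)))
    posthoc = pd.DataFrame(
        posthoc_rows, columns=["zt", "diff", "t_stat", "p_value", "p_bonferroni"]
    )
    return AnovaResult(
        effects=effects, posthoc=posthoc, residual_ss=rss_full, residual_df=df_resid
    )


def profile_peak_phase(
    profile: pd.DataFrame, condition: str, period: float = 24.0
) -> float:
    """Acrophase (hours) of a condition's profile from a K=1 cosinor fit
    on replicate means; requires >= 4 distinct timepoints."""
    sub = profile.loc[profile["condition"] == condition]
    if sub.empty:
        raise ValidationError(f"condition {condition!r} not in profile")
    means = sub.groupby("zt")["value"].mean()
    if means.size < 4:
        raise ValidationError(
            f"need >= 4 distinct timepoints for phase estimation, got {means.size}"
        )
    fit = fit_cosinor(means.index.to_numpy(float), means.to_numpy(float), 1, period)
    return fit.acrophase


@dataclass
class AucResult:
    total_auc: float
    baseline_corrected_auc: float  # baseline = value at t=0; may be negative


def tolerance_auc(minutes, values) -> AucResult:
    """Trapezoidal AUC of a tolerance-test curve starting at t=0.

    The baseline-corrected variant subtracts value-at-0 times the duration
    and is not floored at zero.
    """
    t = np.asarray(minutes, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2 or t.size != v.size:
        raise ValidationError("need >= 2 (time, value) pairs of equal length")
    if t[0] != 0:
        raise ValidationError(f"time grid must start at 0, starts at {t[0]}")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("time grid must be strictly increasing")
    total = float(np.trapezoid(v, t))
    corrected = total - float(v[0]) * float(t[-1] - t[0])
    return AucResult(total_auc=total, baseline_corrected_auc=corrected)


def ddct_fold_change(
    ct_table: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """Relative quantitation of qPCR Ct values by the delta-delta-Ct method.

    ``ct_table`` is long-format with columns ``sample``, ``gene``, ``ct``;
    replicate Ct values are averaged on the Ct scale first. For each
    target gene and sample: delta_ct = Ct(target) - Ct(reference),
    delta_delta_ct = delta_ct - delta_ct(calibrator), fold change
    2**(-delta_delta_ct). The calibrator's own fold change is 1.
    """
    for col in ("sample", "gene", "ct"):
        if col not in ct_table.columns:
            raise ValidationError(f"Ct table missing column {col!r}")
    means = ct_table.groupby(["sample", "gene"])["ct"].mean()
    samples = ct_table["sample"].unique()
    genes = [g for g in ct_table["gene"].unique() if g != reference_gene]
    if calibrator_sample not in samples:
        raise ValidationError(f"calibrator sample {calibrator_sample!r} absent")
    rows = []
    for gene in genes:
        for sample in samples:
            for need_gene, who in ((reference_gene, sample), (gene, sample),
                                   (reference_gene, calibrator_sample),
                                   (gene, calibrator_sample)):
                if (who, need_gene) not in means.index:
                    raise ValidationError(
                        f"missing Ct value for sample {who!r}, gene {need_gene!r}"
                    )
            delta = means[(sample, gene)] - means[(sample, reference_gene)]
            delta_cal = means[(calibrator_sample, gene)] - means[
                (calibrator_sample, reference_gene)
            ]
            ddct = delta - delta_cal
            rows.append((sample, gene, delta, ddct, 2.0 ** (-ddct)))
    return pd.DataFrame(
        rows, columns=["sample", "gene", "delta_ct", "delta_delta_ct", "fold_change"]
    )
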