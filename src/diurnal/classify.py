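"""Six-class taxonomy of between-condition rhythm changes.

Classes, applied in order over the joined per-condition rhythm tables:

    I   rhythmic in both conditions, |delta phase| <  threshold
    II  rhythmic in both conditions, |delta phase| >= threshold
    III rhythmic in condition 1 only ("rhythmic to arrhythmic")
    VI  rhythmic in condition 2 only (de-novo rhythm)
    IV  rhythmic in neither, baseline significantly up in condition 2
    V   rhythmic in neither, baseline significantly down in condition 2
    NC  no change

Baseline changes are Welch t-tests on all samples pooled across
timepoints, BH-corrected within the non-rhythmic stratum only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circular import signed_phase_difference
from .config import AnalysisConfig
from .errors import ValidationError
from .rhythms import bh_adjust

CLASS_LABELS = ("I", "II", "III", "IV", "V", "VI", "NC")


@dataclass
class BaselineTest:
    lfc: float  # mean(condition2) - mean(condition1), log2 units
    p_value: float
    degenerate: bool  # True when both within-condition variances are ~0


def baseline_change_test(values_cond1, values_cond2) -> BaselineTest:
    """Welch two-sample t-test of pooled expression between conditions.

    With zero variance in both groups the test is degenerate: p is 0 when
    the means differ and 1 otherwise, and the result is flagged.
    """
    x1 = np.asarray(values_cond1, dtype=float)
    x2 = np.asarray(values_cond2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValidationError(
            f"baseline test needs >= 2 samples per condition, got {x1.size} and {x2.size}"
        )
    m1, m2 = x1.mean(), x2.mean()
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    lfc = float(m2 - m1)
    se2 = v1 / x1.size + v2 / x2.size
    scale = max(abs(m1), abs(m2), 1.0)
    if se2 <= (1e-12 * scale) ** 2:
        return BaselineTest(lfc=lfc, p_value=0.0 if abs(lfc) > 0 else 1.0, degenerate=True)
    t_stat = lfc / np.sqrt(se2)
    df = se2**2 / (
        (v1 / x1.size) ** 2 / (x1.size - 1) + (v2 / x2.size) ** 2 / (x2.size - 1)
    )
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return BaselineTest(lfc=lfc, p_value=p, degenerate=False)


def baseline_tests(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    condition1: str,
    condition2: str,
) -> pd.DataFrame:
    """Per-gene Welch baseline tests (condition2 vs condition1), all genes."""
    cols1 = samples.loc[samples["condition"] == condition1, "sample_id"].tolist()
    cols2 = samples.loc[samples["condition"] == condition2, "sample_id"].tolist()
    if not cols1 or not cols2:
        raise ValidationError(f"conditions {condition1!r}/{condition2!r} not both present")
    rows = [
        (gene, *_astuple(baseline_change_test(matrix.loc[gene, cols1], matrix.loc[gene, cols2])))
        for gene in matrix.index
    ]
    return pd.DataFrame(rows, columns=["gene", "baseline_lfc", "baseline_p", "degenerate"])


def _astuple(bt: BaselineTest):
    return bt.lfc, bt.p_value, bt.degenerate


def classify_genes(
    rhythms_cond1: pd.DataFrame,
    rhythms_cond2: pd.DataFrame,
    baseline: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Assign every gene to exactly one change class.

    ``rhythms_cond1``/``rhythms_cond2`` are :func:`detect_rhythms` outputs
    over the same gene universe; ``baseline`` is the :func:`baseline_tests`
    output. Returns a DataFrame (gene order of condition 1) with columns
    gene, class_label, delta_phase, baseline_lfc, baseline_p, baseline_q.
    """
    config = config or AnalysisConfig()
    r1 = rhythms_cond1.set_index("gene")
    r2 = rhythms_cond2.set_index("gene")
    if set(r1.index) != set(r2.index) or len(r1) != len(r2):
        raise ValidationError("rhythm tables cover different gene universes")
    r2 = r2.loc[r1.index]
    base = baseline.set_index("gene")
    if set(base.index) != set(r1.index):
        raise ValidationError("baseline table covers a different gene universe")
    base = base.loc[r1.index]

    rhythmic1 = r1["rhythmic"].to_numpy(dtype=bool)
    rhythmic2 = r2["rhythmic"].to_numpy(dtype=bool)
    lfc = base["baseline_lfc"].to_numpy(dtype=float)
    p_base = base["baseline_p"].to_numpy(dtype=float)

    # BH across the non-rhythmic stratum only
    neither = ~rhythmic1 & ~rhythmic2
    q_base = np.full(len(r1), np.nan)
    if neither.any():
        q_base[neither] = bh_adjust(p_base[neither])

    delta = np.full(len(r1), np.nan)
    both = rhythmic1 & rhythmic2
    phi1 = r1["acrophase"].to_numpy(dtype=float)
    phi2 = r2["acrophase"].to_numpy(dtype=float)
    for i in np.flatnonzero(both):
        delta[i] = signed_phase_difference(phi1[i], phi2[i], config.period_T)

    labels = np.full(len(r1), "NC", dtype=object)
    labels[both & (np.abs(delta) < config.phase_shift_threshold)] = "I"
    labels[both & (np.abs(delta) >= config.phase_shift_threshold)] = "II"
    labels[rhythmic1 & ~rhythmic2] = "III"
    labels[~rhythmic1 & rhythmic2] = "VI"
    sig_base = neither & (q_base < config.alpha)
    labels[sig_base & (lfc > config.baseline_lfc_threshold)] = "IV"
    labels[sig_base & (lfc < -config.baseline_lfc_threshold)] = "V"

    return pd.DataFrame(
        {
            "gene": r1.index,
            "class_label": labels,
            "delta_phase": delta,
            "baseline_lfc": lfc,
            "baseline_p": p_base,
            "baseline_q": q_base,
        }
    ).reset_index(drop=True)


def peak_time_histogram(
    rhythm_table: pd.DataFrame,
    bin_centers,
    period: float = 24.0,
) -> pd.DataFrame:
    """Histogram of acrophases of rhythmic genes over circular bin centers.

    Each acrophase goes to the nearest bin center on the circle; exact
    ties go to the earlier (smaller) center. Returns a DataFrame with
    ``bin_center`` and ``count`` rows in center order.
    """
    centers = np.asarray(sorted(bin_centers), dtype=float)
    if centers.size == 0:
        raise ValidationError("at least one bin center required")
    phases = rhythm_table.loc[rhythm_table["rhythmic"], "acrophase"].to_numpy(dtype=float)
    counts = np.zeros(centers.size, dtype=int)
    for phi in phases:
        d = np.abs(phi - centers)
        circ = np.minimum(d, period - d)
        counts[int(np.argmin(circ))] += 1  # argmin keeps first (earlier) on ties
    return pd.DataFrame({"bin_center": centers, "count": counts})


def filter_by_gene_sets(
    assignments: pd.DataFrame,
    collection: dict[str, list[str]],
    set_names,
) -> pd.DataFrame:
    """Restrict a class table to genes in the union of the named sets."""
    unknown = [s for s in set_names if s not in collection]
    if unknown:
        raise ValidationError(
            f"unknown gene sets {unknown}; available: {sorted(collection)}"
        )
    members: set[str] = set()
    for name in set_names:
        members.update(collection[name])
    return assignments.loc[assignments["gene"].isin(members)].reset_index(drop=True)
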