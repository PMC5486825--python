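"""Prognostic subgroup comparisons with multiple-testing control.

For each binary outcome (e.g. clinical nodal stage, mesorectal fascia
involvement) every selected histogram metric is compared between the two
arms: an independent-samples Welch t-test when both arms pass a
Shapiro-Wilk normality check (alpha = 0.05), otherwise a two-sided
Mann-Whitney U test.  Raw p-values are then adjusted per outcome family
with the Holm-Bonferroni step-down procedure, which controls the
family-wise error rate at the nominal level without any independence
assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: The metric subset tested per outcome (the most commonly reported
#: percentile ranges plus the basic summary statistics), 13 metrics.
DEFAULT_METRIC_SUBSET: tuple[str, ...] = (
    "volume_cm3",
    "min",
    "max",
    "mean",
    "median",
    "sd",
    "skew",
    "kurt",
    "p5",
    "p30",
    "p45",
    "p70",
    "p95",
)

OUTCOME_COLUMNS: tuple[str, ...] = (
    "cN",
    "cMRF",
    "differentiation",
    "response",
    "metastasis",
)

__all__ = [
    "GroupComparison",
    "choose_and_run_test",
    "holm_bonferroni",
    "outcome_table",
    "DEFAULT_METRIC_SUBSET",
    "OUTCOME_COLUMNS",
]


@dataclass
class GroupComparison:
    """One metric-vs-outcome comparison row."""

    metric: str
    outcome: str
    mean_neg: float
    sd_neg: float
    n_neg: int
    mean_pos: float
    sd_pos: float
    n_pos: int
    test_used: str
    p_raw: float
    p_holm: float = float("nan")

    @property
    def significant(self) -> bool:
        return bool(self.p_holm <= 0.05)


def _arm_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    # Shapiro-Wilk needs n >= 3 and non-constant data; anything smaller
    # or degenerate routes to the rank test.
    if x.size < 3 or np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > alpha


def choose_and_run_test(a, b, force: str | None = None):
    """Compare two independent samples, choosing the test from normality.

    Both arms normal by Shapiro-Wilk (alpha = 0.05) -> two-sided Welch
    t-test; otherwise two-sided Mann-Whitney U.  ``force`` = ``"t"`` or
    ``"mann_whitney"`` overrides the gate.

    Returns
    -------
    (test_used, p_raw, summary)
        ``summary`` holds per-arm n, mean and n-1 SD.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each arm needs at least two observations")
    summary = {
        "n_a": int(a.size),
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "n_b": int(b.size),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
    }
    if force is None:
        use_t = _arm_normal(a) and _arm_normal(b)
    elif force in ("t", "mann_whitney"):
        use_t = force == "t"
    else:
        raise ValueError(f"unknown forced test {force!r}")
    if use_t:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        return "t", p, summary
    if np.ptp(np.concatenate([a, b])) == 0:
        # identical constant arms: no evidence against the null
        return "mann_whitney", 1.0, summary
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return "mann_whitney", min(p, 1.0), summary


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in the input order.

    Sort the m raw p-values ascending; the i-th (1-based) sorted value is
    adjusted to ``min(1, max_{j<=i} (m - j + 1) * p_(j))``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = (m - np.arange(m)) * p[order]
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def outcome_table(
    case_metrics: pd.DataFrame,
    labels: pd.DataFrame,
    metric_subset=DEFAULT_METRIC_SUBSET,
    outcomes=OUTCOME_COLUMNS,
    force_test: str | None = None,
) -> pd.DataFrame:
    """Metric-by-outcome comparison table for one delineation method.

    Parameters
    ----------
    case_metrics
        DataFrame indexed by ``case_id`` (one row per case, typically
        reader-averaged) containing the metric columns.
    labels
        DataFrame indexed by ``case_id`` with binary outcome columns.
    metric_subset
        Metrics to test within each outcome family (the Holm correction
        is applied per outcome across these metrics).

    Outcomes with an arm of fewer than two cases are skipped with a
    logged reason.
    """
    labels = labels.loc[case_metrics.index]
    rows: list[GroupComparison] = []
    for outcome in outcomes:
        y = labels[outcome].astype(int)
        neg = case_metrics.loc[y == 0]
        pos = case_metrics.loc[y == 1]
        if len(neg) < 2 or len(pos) < 2:
            log.warning(
                "outcome %s skipped: arm sizes %d/%d too small",
                outcome, len(neg), len(pos),
            )
            continue
        family: list[GroupComparison] = []
        for metric in metric_subset:
            test_used, p_raw, s = choose_and_run_test(
                neg[metric], pos[metric], force=force_test
            )
            family.append(
                GroupComparison(
                    metric=metric,
                    outcome=outcome,
                    mean_neg=s["mean_a"],
                    sd_neg=s["sd_a"],
                    n_neg=s["n_a"],
                    mean_pos=s["mean_b"],
                    sd_pos=s["sd_b"],
                    n_pos=s["n_b"],
                    test_used=test_used,
                    p_raw=p_raw,
                )
            )
        adj = holm_bonferroni([c.p_raw for c in family])
        for c, pa in zip(family, adj):
            c.p_holm = float(pa)
        rows.extend(family)
    if not rows:
        raise ValueError("no outcome had two populated arms")
    df = pd.DataFrame(
        [
            {
                "outcome": c.outcome,
                "metric": c.metric,
                "mean_neg": c.mean_neg,
                "sd_neg": c.sd_neg,
                "n_neg": c.n_neg,
                "mean_pos": c.mean_pos,
                "sd_pos": c.sd_pos,
                "n_pos": c.n_pos,
                "test_used": c.test_used,
                "p_raw": c.p_raw,
                "p_holm": c.p_holm,
                "significant": c.significant,
            }
            for c in rows
        ]
    )
    return df
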