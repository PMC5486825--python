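"""Inter-reader and inter-method agreement statistics.

Implements the intraclass correlation coefficient for absolute agreement
of single measures under a two-way model -- ICC(A,1) in McGraw & Wong's
nomenclature, the "two-way mixed, absolute agreement, single measures"
setting of SPSS.  With subjects as rows and raters as columns the
two-way ANOVA mean squares (rows MSR, columns MSC, error MSE) give::

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

The point estimate is identical under the mixed and random two-way
models, so a single computation serves both.

Also provided: Bland-Altman bias and 95% limits of agreement, and the
percentile sweep that searches the non-precise histogram metrics for the
best surrogate of the precise-delineation mean ADC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .voimetrics import PERCENTILES

#: Candidate metrics scanned by the surrogate sweep (the rows of the
#: corresponding results table: mean, min, every 5th percentile, max,
#: median).
SWEEP_CANDIDATES: tuple[str, ...] = (
    "mean",
    "min",
    *[f"p{p}" for p in PERCENTILES],
    "max",
    "median",
)

__all__ = [
    "RatingsMatrix",
    "ICCResult",
    "BlandAltmanResult",
    "SweepTable",
    "icc_absolute_single",
    "bland_altman",
    "bland_altman_plot",
    "percentile_sweep",
    "interreader_table",
    "SWEEP_CANDIDATES",
]


@dataclass
class RatingsMatrix:
    """An n_subjects x k_raters matrix of measurements, no missing cells."""

    values: np.ndarray
    subject_ids: list | None = None
    rater_labels: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2-D (subjects x raters) matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratings contain non-finite cells")


@dataclass
class ICCResult:
    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int


@dataclass
class BlandAltmanResult:
    """Bias = mean(x - y); limits of agreement = bias -/+ 1.96 sd(x - y)."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float


def icc_absolute_single(ratings) -> ICCResult:
    """ICC(A,1): two-way model, absolute agreement, single measures.

    Parameters
    ----------
    ratings
        An ``n x k`` array-like or :class:`RatingsMatrix` (subjects x
        raters, complete).

    Raises
    ------
    ValueError
        If the matrix is degenerate (all cells equal) or malformed.
    """
    if not isinstance(ratings, RatingsMatrix):
        ratings = RatingsMatrix(np.asarray(ratings))
    y = ratings.values
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((y - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)  # guard round-off
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or not np.isfinite(denom):
        if sst <= 1e-30:
            raise ValueError("ICC undefined: all ratings identical")
        raise ValueError("ICC undefined: zero denominator")
    return ICCResult(
        icc=float((msr - mse) / denom),
        ms_rows=msr,
        ms_cols=msc,
        ms_error=mse,
        n=n,
        k=k,
    )


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman agreement between two paired measurement series.

    The sign convention is ``d = x - y``.  The limits of agreement are
    ``bias -/+ 1.96 * sd(d)`` with the n-1 standard deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, sd_diff=sd
    )


def bland_altman_plot(x, y, ax=None, xlabel="mean of methods", ylabel="difference"):
    """Scatter the pairwise means against differences with bias/LoA lines."""
    import matplotlib.pyplot as plt

    res = bland_altman(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((x + y) / 2.0, x - y, s=18, color="k")
    for v, style in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(v, linestyle=style, color="gray")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    return ax, res


# ---------------------------------------------------------------------------
# surrogate sweep


@dataclass
class SweepTable:
    """Result of the surrogate percentile sweep.

    ``table`` has one row per candidate non-precise metric and one column
    per (reference reader, test reader) pair plus their average;
    ``best_metric`` maximises the pair-averaged ICC against the
    precise-delineation mean ADC.
    """

    table: pd.DataFrame
    best_metric: str
    best_icc_range: tuple[float, float]

    @property
    def best_icc_avg(self) -> float:
        return float(self.table.loc[self.best_metric, "avg"])


def _tie_key(metric: str, candidates=SWEEP_CANDIDATES):
    """Deterministic tie-break: percentiles first, nearest the 50th, then
    the lower percentile; named metrics fall back to candidate order."""
    if metric.startswith("p") and metric[1:].isdigit():
        p = int(metric[1:])
        return (0, abs(p - 50), p)
    return (1, candidates.index(metric), 0)


def percentile_sweep(
    precise_metrics: pd.DataFrame,
    nonprecise_metrics: pd.DataFrame,
    candidates=SWEEP_CANDIDATES,
    reference_metric: str = "mean",
) -> SweepTable:
    """Find the non-precise metric that best reproduces the precise mean ADC.

    Parameters
    ----------
    precise_metrics, nonprecise_metrics
        Long DataFrames with columns ``case_id``, ``reader`` and the
        metric columns, one row per (case, reader), two readers each.

    For every candidate metric ``m`` and every pair (precise reader
    reference mean, non-precise reader ``m``) an ICC(A,1) is computed on
    the per-case two-column matrix; the best metric maximises the
    pair-averaged ICC, ties broken toward the percentile closest to the
    50th, then the lower.
    """
    p_readers = sorted(precise_metrics["reader"].unique())
    n_readers = sorted(nonprecise_metrics["reader"].unique())
    ref = precise_metrics.pivot(index="case_id", columns="reader", values=reference_metric)
    cases = ref.dropna().index
    if len(cases) < 2:
        raise ValueError("need at least two complete cases for the sweep")
    cols: dict[str, dict[str, float]] = {}
    for m in candidates:
        test = nonprecise_metrics.pivot(index="case_id", columns="reader", values=m)
        test = test.loc[cases]
        row = {}
        for pr in p_readers:
            for nr in n_readers:
                mat = np.column_stack([ref.loc[cases, pr], test[nr]])
                row[f"{pr}:{nr}"] = icc_absolute_single(mat).icc
        cols[m] = row
    table = pd.DataFrame.from_dict(cols, orient="index")
    table["avg"] = table.mean(axis=1)
    best = min(table.index, key=lambda m: (-table.loc[m, "avg"], _tie_key(m)))
    pair_cols = [c for c in table.columns if c != "avg"]
    rng = (float(table.loc[best, pair_cols].min()), float(table.loc[best, pair_cols].max()))
    return SweepTable(table=table, best_metric=best, best_icc_range=rng)


def interreader_table(
    metrics: pd.DataFrame, metric_names=None, reader_averaged_between: bool = True
) -> pd.DataFrame:
    """Per-metric agreement table: within each method and between methods.

    Returns a DataFrame indexed by metric with columns
    ``icc_precise`` (reader 1 vs reader 2), ``icc_nonprecise`` and
    ``icc_between`` (methods compared after averaging the two readers
    within each method; set ``reader_averaged_between=False`` to average
    the four single-reader cross-method ICCs instead).
    """
    if metric_names is None:
        metric_names = [
            "volume_cm3", "mean", "min", "max", "sd", "skew", "kurt", "median",
            *[f"p{p}" for p in PERCENTILES],
        ]
    def _icc_or_nan(mat) -> float:
        # a metric can be degenerate (e.g. minimum ADC clipped to 0 in
        # every contaminated VOI); report NaN rather than fail the table
        try:
            return icc_absolute_single(mat).icc
        except ValueError:
            return float("nan")

    out = {}
    for m in metric_names:
        wide = metrics.pivot_table(
            index="case_id", columns=["method", "reader"], values=m, sort=True
        )
        prec = wide["precise"]
        nonp = wide["nonprecise"]
        row = {
            "icc_precise": _icc_or_nan(prec.to_numpy()),
            "icc_nonprecise": _icc_or_nan(nonp.to_numpy()),
        }
        if reader_averaged_between:
            mat = np.column_stack([prec.mean(axis=1), nonp.mean(axis=1)])
            row["icc_between"] = _icc_or_nan(mat)
        else:
            iccs = [
                _icc_or_nan(np.column_stack([prec[pr], nonp[nr]]))
                for pr in prec.columns
                for nr in nonp.columns
            ]
            row["icc_between"] = float(np.mean(iccs))
        out[m] = row
    return pd.DataFrame.from_dict(out, orient="index")
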