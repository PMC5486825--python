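"""ICC(A,1), Bland-Altman, and the surrogate percentile sweep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adchist.agreement import (
    SWEEP_CANDIDATES,
    bland_altman,
    icc_absolute_single,
    interreader_table,
    percentile_sweep,
)


def icc_a1_bruteforce(y):
    """Independent ANOVA oracle: sums of squares by explicit double loops."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = sum(y[i, j] for i in range(n) for j in range(k)) / (n * k)
    ssr = sum(k * (sum(y[i, :]) / k - grand) ** 2 for i in range(n))
    ssc = sum(n * (sum(y[:, j]) / n - grand) ** 2 for j in range(k))
    sst = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def test_perfect_copies_give_icc_one():
    y = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
    assert icc_absolute_single(y).icc == pytest.approx(1.0)


def test_all_identical_cells_is_an_error():
    with pytest.raises(ValueError, match="identical|denominator"):
        icc_absolute_single(np.full((4, 2), 3.0))


def test_pure_noise_icc_near_zero(rng):
    y = rng.standard_normal((2000, 2))
    assert abs(icc_absolute_single(y).icc) < 0.1


def test_fixed_matrix_matches_bruteforce_oracle():
    y = np.array([[9.0, 2.0], [1.0, 5.0], [8.0, 7.0], [6.0, 3.0], [4.0, 4.0], [7.0, 8.0]])
    res = icc_absolute_single(y)
    assert res.icc == pytest.approx(icc_a1_bruteforce(y), abs=1e-12)
    # the reported mean squares reproduce the reported ICC
    recon = (res.ms_rows - res.ms_error) / (
        res.ms_rows
        + (res.k - 1) * res.ms_error
        + (res.k / res.n) * (res.ms_cols - res.ms_error)
    )
    assert res.icc == pytest.approx(recon, abs=1e-14)


@settings(derandomize=True, max_examples=120, deadline=None)
@given(
    n=st.integers(2, 12),
    k=st.integers(2, 4),
    seed=st.integers(0, 10_000),
)
def test_random_matrices_match_bruteforce_oracle(n, k, seed):
    r = np.random.default_rng(seed)
    y = r.normal(size=(n, 1)) + 0.3 * r.normal(size=(1, k)) + 0.5 * r.normal(size=(n, k))
    assert icc_absolute_single(y).icc == pytest.approx(icc_a1_bruteforce(y), abs=1e-10)


def test_matches_pingouin_icc2(rng):
    pg = pytest.importorskip("pingouin")
    y = rng.normal(size=(10, 1)) + rng.normal(size=(10, 3)) * 0.4
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(10), 3),
            "rater": np.tile(np.arange(3), 10),
            "score": y.ravel(),
        }
    )
    ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    icc2 = float(ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0])
    assert icc_absolute_single(y).icc == pytest.approx(icc2, abs=1e-8)


def test_icc_shift_and_scale_invariance(rng):
    y = rng.normal(size=(15, 2))
    base = icc_absolute_single(y).icc
    assert icc_absolute_single(y + 7.3).icc == pytest.approx(base, abs=1e-10)
    assert icc_absolute_single(y * 42.0).icc == pytest.approx(base, abs=1e-10)


def test_malformed_ratings_rejected():
    with pytest.raises(ValueError):
        icc_absolute_single(np.ones((1, 2)))
    with pytest.raises(ValueError):
        icc_absolute_single(np.array([[1.0, np.nan], [2.0, 3.0]]))


# ---------------------------------------------------------------------------
# Bland-Altman


def test_identical_methods_have_zero_bias_and_limits():
    r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (r.bias, r.loa_low, r.loa_high, r.sd_diff) == (0.0, 0.0, 0.0, 0.0)


def test_constant_offset_sign_convention():
    x = np.array([1.0, 2.0, 3.0])
    r = bland_altman(x, x + 0.07)
    assert r.bias == pytest.approx(-0.07)
    assert r.sd_diff == pytest.approx(0.0, abs=1e-15)


def test_hand_computed_limits():
    r = bland_altman([-0.1, 0.0, 0.1], [0.0, 0.0, 0.0])
    assert r.bias == pytest.approx(0.0, abs=1e-15)
    assert r.sd_diff == pytest.approx(0.1)
    assert r.loa_high == pytest.approx(1.96 * 0.1)
    assert r.loa_low == pytest.approx(-1.96 * 0.1)


def test_limits_cover_95_percent_of_normal_differences(rng):
    x = rng.normal(size=20_000)
    y = rng.normal(size=20_000)
    r = bland_altman(x, y)
    inside = ((x - y) >= r.loa_low) & ((x - y) <= r.loa_high)
    assert inside.mean() == pytest.approx(0.95, abs=0.01)


def test_length_mismatch_raises():
    with pytest.raises(ValueError):
        bland_altman([1.0, 2.0], [1.0])


# ---------------------------------------------------------------------------
# sweep


def _metrics_frame(readers, columns):
    rows = []
    for reader, per_case in readers.items():
        for cid, vals in per_case.items():
            rows.append({"case_id": cid, "reader": reader, **dict(zip(columns, vals))})
    return pd.DataFrame(rows)


def test_degenerate_perfect_surrogate_prefers_central_percentile(rng):
    """If every non-precise metric equals the precise mean, all pair ICCs
    are 1 and the tie rule picks the percentile closest to the 50th."""
    cases = [f"{i:02d}" for i in range(8)]
    means = rng.uniform(1.0, 2.0, 8)
    prec = _metrics_frame(
        {"R1": dict(zip(cases, means[:, None])), "R2": dict(zip(cases, means[:, None]))},
        ["mean"],
    )
    nonp = _metrics_frame(
        {
            "R3": {c: [m] * len(SWEEP_CANDIDATES) for c, m in zip(cases, means)},
            "R4": {c: [m] * len(SWEEP_CANDIDATES) for c, m in zip(cases, means)},
        },
        list(SWEEP_CANDIDATES),
    )
    sw = percentile_sweep(prec, nonp)
    assert sw.best_metric == "p50"
    assert np.allclose(sw.table["avg"], 1.0)
    assert sw.best_icc_range == (pytest.approx(1.0), pytest.approx(1.0))


def test_sweep_requires_two_complete_cases():
    prec = _metrics_frame({"R1": {"a": [1.0]}, "R2": {"a": [1.0]}}, ["mean"])
    nonp = _metrics_frame(
        {"R3": {"a": [1.0] * len(SWEEP_CANDIDATES)}, "R4": {"a": [1.0] * len(SWEEP_CANDIDATES)}},
        list(SWEEP_CANDIDATES),
    )
    with pytest.raises(ValueError, match="two complete cases"):
        percentile_sweep(prec, nonp)


def test_self_agreement_limit_zero_margin_zero_jitter():
    """With margin 0 and jitter 0 both methods see nearly the same voxels,
    so a central metric agrees almost perfectly with the precise mean."""
    from adchist import RunConfig, cohort_metrics

    cfg = RunConfig(master_seed=5, n_cases=6)
    cfg.phantom.grid_shape = (48, 48, 14)
    cfg.phantom.margin_mm = 0.0
    cfg.phantom.reader_jitter = 0.0
    cfg.phantom.lumen_radius_mm = (0.1, 0.2)  # no hole: masks coincide
    m, _ = cohort_metrics(cfg)
    sw = percentile_sweep(m[m.method == "precise"], m[m.method == "nonprecise"])
    assert sw.best_metric in ("mean", "median", "p45", "p50", "p55")
    assert sw.best_icc_avg > 0.95
    tab = interreader_table(m)
    assert tab.loc["mean", "icc_precise"] == pytest.approx(1.0)
    assert tab.loc["mean", "icc_nonprecise"] == pytest.approx(1.0)


def test_interreader_table_between_uses_reader_averages(small_cohort):
    m, _ = small_cohort
    tab = interreader_table(m, metric_names=["mean", "volume_cm3"])
    assert {"icc_precise", "icc_nonprecise", "icc_between"} == set(tab.columns)
    assert np.isfinite(tab.loc["mean"]).all()
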