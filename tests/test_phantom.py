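"""Phantom construction: geometry, determinism, masks, labels."""

import numpy as np
import pytest

from adchist.adcfit import compute_adc_map
from adchist.phantom import (
    LABELS,
    PhantomConfig,
    PhantomConfigError,
    build_phantom_case,
    case_seed_for,
    draw_cohort_labels,
    draw_nonprecise_mask,
    draw_precise_mask,
    generate_cohort,
    write_case,
)
from adchist.io import read_dwi, read_mask
from adchist.voimetrics import average_readers

GRID = (48, 48, 14)


def _dice(a, b):
    return 2 * (a & b).sum() / (a.sum() + b.sum())


def test_signal_follows_monoexponential_decay_exactly():
    cfg = PhantomConfig(grid_shape=GRID, noise_sigma=0.0)
    case = build_phantom_case(cfg, 42)
    b = case.dwi.b_values
    truth = case.truth_adc.adc
    s0 = case.dwi.signal[..., 0]  # b=0 plane is S0 when noiseless
    expected = s0[..., None] * np.exp(-truth[..., None] * b)
    np.testing.assert_allclose(case.dwi.signal, expected, rtol=1e-12)
    # spot value: a tumor voxel at b=1000 keeps exp(-b*ADC) of its S0
    ix = tuple(np.argwhere(case.tumor_mask)[0])
    assert case.dwi.signal[ix][5] == pytest.approx(
        1000.0 * np.exp(-1000.0 * truth[ix]), rel=1e-12
    )


def test_same_seed_reproduces_case_bit_for_bit():
    cfg = PhantomConfig(grid_shape=GRID)
    a = build_phantom_case(cfg, 7)
    b = build_phantom_case(cfg, 7)
    np.testing.assert_array_equal(a.dwi.signal, b.dwi.signal)
    np.testing.assert_array_equal(a.label_map, b.label_map)
    for rid in a.precise_masks:
        np.testing.assert_array_equal(a.precise_masks[rid].mask, b.precise_masks[rid].mask)
    c = build_phantom_case(cfg, 8)
    assert not np.array_equal(a.dwi.signal, c.dwi.signal)


def test_tumor_truth_adc_centered_on_configured_mean():
    cfg = PhantomConfig(grid_shape=GRID, case_adc_shift_sd=0.0)
    vals = []
    for s in range(6):
        case = build_phantom_case(cfg, 100 + s)
        vals.append(case.truth_adc.adc[case.tumor_mask])
    vals = np.concatenate(vals)
    se = 0.40e-3 / np.sqrt(vals.size)
    assert abs(vals.mean() - 1.44e-3) < 3 * se


def test_signals_are_nonnegative(small_case):
    assert np.all(small_case.dwi.signal >= 0)


def test_noiseless_phantom_fit_recovers_truth():
    cfg = PhantomConfig(grid_shape=GRID, noise_sigma=0.0)
    case = build_phantom_case(cfg, 3)
    amap = compute_adc_map(case.dwi)
    assert amap.fit_valid.all()
    rel = np.abs(amap.adc - case.truth_adc.adc) / case.truth_adc.adc
    assert rel.max() < 1e-10


# ---------------------------------------------------------------------------
# masks


def test_zero_jitter_precise_mask_is_exact_tumor(small_case):
    voi = draw_precise_mask(small_case, 0.0, reader_seed=1)
    np.testing.assert_array_equal(voi.mask, small_case.tumor_mask)
    assert voi.n_voxels * voi.voxel_volume_mm3 / 1000.0 == pytest.approx(
        small_case.true_tumor_volume_cm3
    )


def test_jittered_masks_differ_but_keep_the_core(small_case):
    from scipy import ndimage

    jitter = 0.8
    m1 = draw_precise_mask(small_case, jitter, reader_seed=1).mask
    m2 = draw_precise_mask(small_case, jitter, reader_seed=2).mask
    tumor = small_case.tumor_mask
    assert not np.array_equal(m1, m2)
    assert (m1 & ~tumor).sum() == 0 and (m2 & ~tumor).sum() == 0
    sp = np.asarray(small_case.dwi.voxel_spacing)
    dist = ndimage.distance_transform_edt(tumor, sampling=sp / sp.min())
    core = tumor & (dist > 2 * jitter)
    assert (core & ~m1).sum() == 0 and (core & ~m2).sum() == 0


def test_two_readers_overlap_strongly(small_case):
    d = _dice(
        small_case.precise_masks["R1"].mask, small_case.precise_masks["R2"].mask
    )
    assert d > 0.8


def test_precise_masks_nest_inside_nonprecise(small_case):
    for p in small_case.precise_masks.values():
        for n in small_case.nonprecise_masks.values():
            assert not (p.mask & ~n.mask).any()


def test_every_precise_voxel_is_tumor_and_voi_mixes_tissues(small_case):
    tumor_code = LABELS["tumor"]
    for p in small_case.precise_masks.values():
        assert set(np.unique(small_case.label_map[p.mask])) == {tumor_code}
    for n in small_case.nonprecise_masks.values():
        assert len(np.unique(small_case.label_map[n.mask])) >= 2


def test_zero_margin_mask_still_covers_tumor_slices(small_case):
    voi = draw_nonprecise_mask(small_case, 0.0, reader_seed=9)
    assert not (small_case.tumor_mask & ~voi.mask).any()
    # and only slices that contain tumor are delineated
    tumor_z = small_case.tumor_mask.any(axis=(0, 1))
    assert (voi.mask.any(axis=(0, 1)) == tumor_z).all()


def test_oversized_tumor_names_the_offending_axis():
    cfg = PhantomConfig(
        grid_shape=(24, 48, 14), tumor_axes_mm=((40.0, 41.0), (7.0, 8.0), (6.0, 7.0))
    )
    with pytest.raises(PhantomConfigError, match="semi-axis x"):
        build_phantom_case(cfg, 1)


# ---------------------------------------------------------------------------
# cohorts


def test_cohort_requires_two_cases(small_config):
    with pytest.raises(ValueError, match="n_cases"):
        generate_cohort(small_config, 1)


def test_cohort_ids_unique_and_labels_aligned(small_config):
    cases, labels = generate_cohort(small_config, 4, outcome_effect=2.0)
    ids = [c.case_id for c in cases]
    assert len(set(ids)) == 4
    assert list(labels.index) == ids
    assert set(labels.columns) == {"cN", "cMRF", "differentiation", "response", "metastasis"}
    assert labels.isin([0, 1]).all().all()


def test_case_seeds_stable_under_cohort_extension(small_config):
    a, _ = generate_cohort(small_config, 2)
    b, _ = generate_cohort(small_config, 3)
    np.testing.assert_array_equal(a[0].dwi.signal, b[0].dwi.signal)
    assert case_seed_for(0, "001") != case_seed_for(1, "001")


def test_outcome_effect_links_labels_to_volume_only_when_nonzero(rng):
    vols = rng.lognormal(1.0, 0.6, 3000)
    ids = [str(i) for i in range(vols.size)]
    linked = draw_cohort_labels(ids, vols, outcome_effect=2.0, seed=4)
    null = draw_cohort_labels(ids, vols, outcome_effect=0.0, seed=4)
    z = (np.log(vols) - np.log(vols).mean()) / np.log(vols).std()
    assert np.corrcoef(z, linked["cN"])[0, 1] > 0.3
    assert abs(np.corrcoef(z, null["cN"])[0, 1]) < 0.05
    # with zero effect the draw ignores the volumes entirely
    other = draw_cohort_labels(ids, rng.permutation(vols), 0.0, seed=4)
    assert (null["metastasis"].values == other["metastasis"].values).all()


def test_cohort_volume_ratio_and_mean_elevation(small_cohort):
    m, _ = small_cohort
    avg = average_readers(m)
    pm = avg.xs("precise", level="method")
    nm = avg.xs("nonprecise", level="method")
    ratio = nm["volume_cm3"].mean() / pm["volume_cm3"].mean()
    assert 2.2 < ratio < 3.8
    assert nm["mean"].mean() > pm["mean"].mean()
    assert nm["sd"].mean() > pm["sd"].mean()


def test_case_roundtrips_through_nifti(small_case, tmp_path):
    write_case(small_case, tmp_path)
    cid = small_case.case_id
    dwi = read_dwi(tmp_path / f"case_{cid}_dwi.nii.gz", tmp_path / f"case_{cid}.bval")
    assert dwi.signal.shape == small_case.dwi.signal.shape
    np.testing.assert_allclose(dwi.signal, small_case.dwi.signal, rtol=1e-6)
    np.testing.assert_array_equal(dwi.b_values, small_case.dwi.b_values)
    assert dwi.voxel_spacing == pytest.approx(small_case.dwi.voxel_spacing, rel=1e-5)
    mask, _ = read_mask(tmp_path / f"case_{cid}_mask_precise_R1.nii.gz")
    np.testing.assert_array_equal(mask, small_case.precise_masks["R1"].mask)
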