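"""Brain age workflows, bias correction identities, reliability metrics."""

import numpy as np
import pandas as pd
import pytest

from bagpipe import brainage as ba
from bagpipe.grids import FWHM_TO_SIGMA, FeatureGrid, GridGeometry, smooth_and_resample


def _grid_from_array(data, spacing=(1.0, 1.0, 1.0), index=None):
    geom = GridGeometry(dims=data.shape[1:], spacing=spacing)
    return FeatureGrid(data=data, geometry=geom,
                       index=index if index is not None else pd.DataFrame())


# ---------------------------------------------------------------------------
# smoothing / resampling


def test_smooth_resample_identity():
    rng = np.random.default_rng(0)
    grid = _grid_from_array(rng.normal(size=(2, 8, 8, 8)))
    out = smooth_and_resample(grid, fwhm=0.0, factor=1)
    assert np.array_equal(out.data, grid.data)


def test_smooth_resample_constant_preserved():
    grid = _grid_from_array(np.full((1, 12, 12, 12), 7.0))
    out = smooth_and_resample(grid, fwhm=4.0, factor=4)
    assert np.allclose(out.data, 7.0)
    assert out.geometry.dims == (3, 3, 3)
    assert out.geometry.spacing == (4.0, 4.0, 4.0)


def test_smooth_impulse_matches_direct_convolution():
    """Separable Gaussian smoothing of a central impulse vs a brute-force kernel."""
    n = 33
    data = np.zeros((1, n, n, n))
    data[0, n // 2, n // 2, n // 2] = 1.0
    grid = _grid_from_array(data)
    out = smooth_and_resample(grid, fwhm=4.0, factor=1)

    sigma = 4.0 / FWHM_TO_SIGMA
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    expected = np.zeros(n)
    expected[n // 2 - radius : n // 2 + radius + 1] = k
    full = expected[:, None, None] * expected[None, :, None] * expected[None, None, :]
    assert np.allclose(out.data[0], full, atol=1e-10)


def test_smooth_resample_rejects_bad_args():
    grid = _grid_from_array(np.zeros((1, 8, 8, 8)))
    with pytest.raises(ValueError):
        smooth_and_resample(grid, fwhm=-1.0, factor=1)
    with pytest.raises(ValueError):
        smooth_and_resample(grid, fwhm=0.0, factor=0)


def test_interior_mass_preserved_within_one_percent():
    # interior-supported signal, smoothed enough that the coarse grid samples
    # it adequately; downsampling by f shrinks the voxel count by f^3
    rng = np.random.default_rng(1)
    data = np.zeros((1, 32, 32, 32))
    data[0, 8:24, 8:24, 8:24] = rng.uniform(1, 2, size=(16, 16, 16))
    grid = _grid_from_array(data)
    out = smooth_and_resample(grid, fwhm=6.0, factor=4)
    assert out.data.sum() * 4**3 == pytest.approx(data.sum(), rel=0.01)


# ---------------------------------------------------------------------------
# workflows / training


def test_named_workflows_reproduce_reference_combinations():
    assert ba.Workflow.s4_r4_gpr().name == "S4_R4+GPR"
    assert ba.Workflow.s4_r4_pca_gpr().name == "S4_R4+PCA+GPR"
    assert ba.Workflow.s0_r4_lr().name == "S0_R4+LR"
    assert ba.Workflow.s0_r4_lr().smoothing_fwhm == 0.0
    assert ba.Workflow.s0_r4_lr().resample_factor == 4


def test_constant_training_labels_yield_constant_predictor():
    rng = np.random.default_rng(2)
    grid = _grid_from_array(rng.normal(size=(12, 8, 8, 8)))
    with pytest.warns(UserWarning):
        model = ba.train_brain_age(grid, np.full(12, 63.0), ba.Workflow.s0_r4_lr(), 0)
    other = _grid_from_array(rng.normal(size=(5, 8, 8, 8)))
    assert np.allclose(model.predict(other), 63.0)


def test_holdout_mae_below_six_years(hc_baseline):
    hc, ages = hc_baseline
    rng = np.random.default_rng(0)
    order = rng.permutation(len(ages))
    train, test = order[:100], order[100:]
    model = ba.train_brain_age(hc.take(train), ages[train], ba.Workflow.s0_r4_lr(), 0)
    pred = model.predict(hc.take(test))
    assert np.mean(np.abs(pred - ages[test])) < 6.0


def test_permuted_labels_give_null_mae(hc_baseline):
    hc, ages = hc_baseline
    rng = np.random.default_rng(1)
    shuffled = rng.permutation(ages)
    order = rng.permutation(len(ages))
    train, test = order[:100], order[100:]
    model = ba.train_brain_age(hc.take(train), shuffled[train], ba.Workflow.s0_r4_lr(), 0)
    pred = model.predict(hc.take(test))
    mae = np.mean(np.abs(pred - ages[test]))
    null_mae = np.mean(np.abs(ages[test] - ages[train].mean()))
    assert mae > 0.6 * null_mae  # no better than predicting the mean, roughly


# ---------------------------------------------------------------------------
# bias corrections


def test_identity_when_predictions_unbiased():
    chron = np.linspace(50, 80, 20)
    for method in ("cole", "beheshti"):
        corr = ba.fit_bias_correction(chron, chron, method)
        assert np.allclose(corr.corrected_prediction(chron, chron), chron, atol=1e-9)
        assert np.allclose(corr.corrected_bag(chron, chron), 0.0, atol=1e-9)


def test_beheshti_hand_ols():
    ages = np.array([50.0, 60.0, 70.0] * 4)
    bag = np.array([2.0, 0.0, -2.0] * 4)
    corr = ba.fit_bias_correction(ages + bag, ages, "beheshti")
    assert corr.intercept == pytest.approx(12.0, abs=1e-9)
    assert corr.slope == pytest.approx(-0.2, abs=1e-12)
    assert np.allclose(corr.corrected_bag(ages + bag, ages), 0.0, atol=1e-9)


def test_cole_hand_ols():
    ages = np.array([50.0, 60.0, 70.0] * 4)
    pred = np.array([55.0, 60.0, 65.0] * 4)
    corr = ba.fit_bias_correction(pred, ages, "cole")
    assert corr.intercept == pytest.approx(30.0, abs=1e-9)
    assert corr.slope == pytest.approx(0.5, abs=1e-12)
    assert np.allclose(corr.corrected_prediction(pred, ages), ages, atol=1e-9)


def test_bias_correction_input_validation():
    with pytest.raises(ValueError):
        ba.fit_bias_correction([1.0] * 5, [1.0] * 5, "cole")  # too few
    ages = np.full(12, 60.0)
    with pytest.raises(ValueError):
        ba.fit_bias_correction(ages + 1, ages, "beheshti")  # zero age variance
    chron = np.linspace(50, 80, 12)
    with pytest.raises(ValueError):
        ba.fit_bias_correction(np.full(12, 55.0), chron, "cole")  # slope ~ 0


def test_beheshti_invariant_to_constant_prediction_shift():
    rng = np.random.default_rng(3)
    chron = rng.uniform(45, 85, 40)
    pred = chron + rng.normal(0, 3, 40) + 0.2 * (chron - 65)
    c1 = ba.fit_bias_correction(pred, chron, "beheshti")
    c2 = ba.fit_bias_correction(pred + 7.5, chron, "beheshti")
    assert np.allclose(c1.corrected_bag(pred, chron),
                       c2.corrected_bag(pred + 7.5, chron), atol=1e-9)


def test_cole_invariant_to_affine_recalibration():
    rng = np.random.default_rng(4)
    chron = rng.uniform(45, 85, 40)
    pred = 0.8 * chron + 10 + rng.normal(0, 2, 40)
    c1 = ba.fit_bias_correction(pred, chron, "cole")
    recal = 1.7 * pred - 12.0
    c2 = ba.fit_bias_correction(recal, chron, "cole")
    assert np.allclose(c1.corrected_prediction(pred, chron),
                       c2.corrected_prediction(recal, chron), atol=1e-8)


# ---------------------------------------------------------------------------
# apply_bag on the training HC: the algebraic fingerprint


def test_apply_bag_training_set_identities(bag_table, hc_baseline):
    model, correction, _ = bag_table
    hc, ages = hc_baseline
    table = ba.apply_bag(model, correction, hc)
    bag = table.bag_corrected.to_numpy()
    assert abs(bag.mean()) < 1e-8
    assert abs(np.corrcoef(bag, ages)[0, 1]) < 1e-8


def test_apply_bag_group_ordering(bag_table):
    _, _, table = bag_table
    base = table.sort_values("scan_time").groupby("subject_id").first()
    means = base.groupby("glabel").bag_corrected.mean()
    assert means["fast"] > 0.5
    assert means["fast"] > means["slow"]


def test_apply_bag_length_mismatch(bag_table, hc_baseline):
    model, correction, _ = bag_table
    hc, ages = hc_baseline
    with pytest.raises(ValueError):
        ba.apply_bag(model, correction, hc, chron=ages[:-1])


# ---------------------------------------------------------------------------
# workflow selection


def test_select_single_candidate_trivial(hc_baseline):
    hc, ages = hc_baseline
    sub = hc.take(np.arange(60))
    report = ba.select_workflow(sub, ages[:60], [ba.Workflow.s0_r4_lr()],
                                ["beheshti"], k=3, seed=0)
    assert len(report.table) == 1
    assert report.best_workflow.name == "S0_R4+LR"
    assert report.best_mae == report.table.mae.iloc[0]


def test_select_duplicate_candidate_identical_mae(hc_baseline):
    hc, ages = hc_baseline
    sub = hc.take(np.arange(60))
    wf = ba.Workflow.s0_r4_lr()
    report = ba.select_workflow(sub, ages[:60], [wf, ba.Workflow(0.0, 4, "none", "sparse_linear")],
                                ["beheshti"], k=3, seed=0)
    maes = report.table.mae.to_numpy()
    assert abs(maes[0] - maes[1]) < 1e-10


def test_select_full_grid_reports_all_pairs(hc_baseline):
    hc, ages = hc_baseline
    sub = hc.take(np.arange(90))
    workflows = [ba.Workflow.s4_r4_gpr(), ba.Workflow.s4_r4_pca_gpr(), ba.Workflow.s0_r4_lr()]
    report = ba.select_workflow(sub, ages[:90], workflows, ["cole", "beheshti"],
                                k=3, seed=0)
    assert len(report.table) == 6
    assert report.best_mae <= report.table.mae.min() + 1e-12


def test_select_empty_list_rejected(hc_baseline):
    hc, ages = hc_baseline
    with pytest.raises(ValueError):
        ba.select_workflow(hc, ages, [], ["cole"], k=2, seed=0)


# ---------------------------------------------------------------------------
# longitudinal consistency


def _bag_frame(rows):
    return pd.DataFrame(rows, columns=[
        "subject_id", "scan_time", "chronological_age",
        "brain_age_corrected", "bag_corrected",
    ])


def test_consistency_perfect_aging_gives_rho_one():
    rows = []
    rng = np.random.default_rng(0)
    for i in range(10):
        gap = 1.5 + 3.0 * rng.random()
        base_age = 60 + i
        rows.append((f"s{i}", 0.0, base_age, base_age, 0.0))
        rows.append((f"s{i}", gap, base_age + gap, base_age + gap, 0.0))
    report = ba.longitudinal_consistency(_bag_frame(rows))
    assert report.consistency_rho == pytest.approx(1.0)
    assert report.retest_ccc is None  # no short-interval pairs


def test_consistency_uses_first_and_last_scan():
    rows = []
    for i in range(3):
        for t in (0.0, 1.0, 4.0):
            rows.append((f"s{i}", t, 60.0 + t, 60.0 + t + 0.1 * i, 0.1 * i))
    report = ba.longitudinal_consistency(_bag_frame(rows))
    # pair used is (0, 4): all subjects land in the consistency set
    assert report.consistency_n == 3
    assert report.retest_n == 0


def test_consistency_shuffled_null():
    rng = np.random.default_rng(7)
    rows = []
    for i in range(200):
        gap = rng.uniform(1.6, 6.0)
        jump = rng.normal(0, 2.0)  # brain age change unrelated to time
        rows.append((f"s{i}", 0.0, 60.0, 60.0, 0.0))
        rows.append((f"s{i}", gap, 60.0 + gap, 60.0 + jump, jump - gap))
    report = ba.longitudinal_consistency(_bag_frame(rows))
    assert abs(report.consistency_rho) < 0.15


def test_consistency_threshold_is_half_open():
    rows = []
    for i in range(6):
        rows.append((f"s{i}", 0.0, 60.0, 60.0, 0.0))
        rows.append((f"s{i}", 1.5 if i < 3 else 0.5, 61.0, 61.0, 0.2 * i))
    report = ba.longitudinal_consistency(_bag_frame(rows), threshold=1.5)
    assert report.consistency_n == 3  # exactly-1.5y pairs go to consistency
    assert report.retest_n == 3


def test_consistency_requires_multiscan_subjects():
    rows = [("a", 0.0, 60.0, 60.0, 0.0), ("b", 0.0, 61.0, 61.0, 0.0)]
    with pytest.raises(ValueError):
        ba.longitudinal_consistency(_bag_frame(rows))


def test_reliability_in_target_window(bag_table):
    _, _, table = bag_table
    hc = table[table.group == "HC"]
    report = ba.longitudinal_consistency(hc)
    assert 0.75 <= report.retest_ccc <= 0.97
    assert report.consistency_rho > 0.2
    assert report.consistency_p < 0.05
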