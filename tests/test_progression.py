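"""BAG group comparisons, trajectories, slope extraction and correlations."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bagpipe import progression as pg
from bagpipe.cohort import LongCohort
from bagpipe.simulate import SimConfig, default_outcome_specs, simulate_cohort
from bagpipe.latent import normalize_outcomes


def _bag_rows(rng, group_sizes, offsets, label_col="subtype"):
    rows = []
    i = 0
    for label, n in group_sizes.items():
        for _ in range(n):
            rows.append({
                "subject_id": f"s{i}",
                "scan_time": 0.0,
                label_col: label,
                "chronological_age": rng.uniform(50, 80),
                "sex": rng.choice(["M", "F"]),
                "bag_corrected": rng.normal(offsets[label], 1.0),
            })
            i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparisons


def test_compare_null_groups_coefficient_near_zero():
    rng = np.random.default_rng(0)
    ps = []
    for rep in range(40):
        bag = _bag_rows(rng, {"a": 30, "b": 30}, {"a": 0.0, "b": 0.0})
        rep_ = pg.compare_bag_groups(bag, ("a", "b"), group_column="subtype",
                                     covariates=("chronological_age", "sex"))
        ps.append(rep_.p_value)
    # p-values roughly uniform: mean near 0.5, few small ones
    assert 0.3 < np.mean(ps) < 0.7
    assert np.mean(np.array(ps) < 0.05) < 0.2


def test_compare_recovers_constructed_offset():
    rng = np.random.default_rng(1)
    bag = _bag_rows(rng, {"HC": 200, "fast": 200}, {"HC": 0.0, "fast": 3.0})
    rep = pg.compare_bag_groups(bag, ("HC", "fast"), group_column="subtype",
                                covariates=("chronological_age", "sex"))
    assert rep.delta_bag == pytest.approx(3.0, abs=0.35)
    assert rep.p_value < 1e-6


def test_compare_fast_slow_auto_includes_latent_time():
    rng = np.random.default_rng(2)
    bag = _bag_rows(rng, {"fast": 30, "slow": 30}, {"fast": 2.0, "slow": 0.0})
    bag["latent_time"] = rng.normal(0, 1, len(bag))
    rep = pg.compare_bag_groups(bag, ("slow", "fast"),
                                covariates=("chronological_age", "sex"))
    assert "latent_time" in rep.covariates
    rep_hc = pg.compare_bag_groups(
        _bag_rows(rng, {"HC": 30, "fast": 30}, {"HC": 0.0, "fast": 2.0}),
        ("HC", "fast"), covariates=("chronological_age", "sex"))
    assert "latent_time" not in rep_hc.covariates


def test_compare_collinear_covariate_rejected():
    rng = np.random.default_rng(3)
    bag = _bag_rows(rng, {"a": 10, "b": 10}, {"a": 0.0, "b": 0.0})
    bag["dup"] = (bag.subtype == "b").astype(float)
    with pytest.raises(ValueError, match="rank"):
        pg.compare_bag_groups(bag, ("a", "b"),
                              covariates=("chronological_age", "dup"))


def test_compare_small_group_rejected():
    rng = np.random.default_rng(4)
    bag = _bag_rows(rng, {"a": 2, "b": 10}, {"a": 0.0, "b": 0.0})
    with pytest.raises(ValueError, match="fewer than 3"):
        pg.compare_bag_groups(bag, ("a", "b"), covariates=())


# ---------------------------------------------------------------------------
# trajectories


def _trajectory_frame(rng, n_subj, slope, noise=0.3, n_scans=4, singles=0):
    rows = []
    for i in range(n_subj):
        intercept = rng.normal(0, 1)
        for t in np.linspace(0, 4, n_scans):
            rows.append({"subject_id": f"s{i}", "scan_time": t, "subtype": "fast",
                         "bag_corrected": intercept + slope * t + rng.normal(0, noise)})
    for j in range(singles):
        rows.append({"subject_id": f"single{j}", "scan_time": 0.0, "subtype": "fast",
                     "bag_corrected": rng.normal()})
    return pd.DataFrame(rows)


def test_trajectory_constant_bag_gives_zero_slope():
    rng = np.random.default_rng(5)
    frame = _trajectory_frame(rng, 20, slope=0.0, noise=0.05)
    rep = pg.bag_trajectory(frame, "fast")
    assert abs(rep.slope) < 0.05


def test_trajectory_recovers_generative_slope():
    rng = np.random.default_rng(6)
    frame = _trajectory_frame(rng, 60, slope=0.4)
    rep = pg.bag_trajectory(frame, "fast")
    lo, hi = rep.slope_ci
    assert lo <= 0.4 <= hi
    assert rep.slope == pytest.approx(0.4, abs=0.1)
    assert rep.slope_p < 1e-4


def test_trajectory_single_scan_subjects_logged():
    rng = np.random.default_rng(7)
    frame = _trajectory_frame(rng, 10, slope=0.2, singles=4)
    rep = pg.bag_trajectory(frame, "fast")
    assert rep.n_excluded_single_scan == 4
    assert rep.n_subjects == 10


def test_trajectory_needs_multiscan_subjects():
    rng = np.random.default_rng(8)
    frame = _trajectory_frame(rng, 2, slope=0.2, singles=10)
    with pytest.raises(ValueError):
        pg.bag_trajectory(frame, "fast")


# ---------------------------------------------------------------------------
# outcome slopes on the latent timescale


def _slope_cohort(noise=0.0, n=30, seed=9):
    specs = [dataclasses.replace(s, noise_sd=noise, accel_loading=0.0)
             for s in default_outcome_specs()[:3]]
    config = SimConfig(n_hc=0, n_pd=n, outcomes=specs, delta_sd=0.5,
                       alpha0_sd=0.02 if noise else 0.0,
                       alpha1_sd=0.02 if noise else 0.0,
                       slope_multiplier={"fast": 1.0, "slow": 1.0}, accel_sd=0.0,
                       dropout_prob=0.05)
    cohort, truth = simulate_cohort(config, seed)
    norm = normalize_outcomes(cohort, specs, on_out_of_range="clamp")
    visits = norm.observations[["subject_id", "time"]].drop_duplicates().copy()
    delta = truth.subjects.set_index("subject_id").delta
    visits["latent_time"] = visits.time + delta.reindex(visits.subject_id).to_numpy()
    return config, norm, truth, visits


def test_noise_free_slopes_recovered_exactly():
    config, norm, truth, visits = _slope_cohort(noise=0.0)
    slopes = pg.outcome_slopes(norm, visits, min_subjects=10)
    expected = {s.name: s.mean_slope for s in config.outcomes}
    for name, g in slopes.groupby("outcome"):
        assert np.allclose(g.slope, expected[name], atol=1e-4)


def test_shrinkage_toward_fixed_slope():
    """Subjects with 2 visits shrink harder toward the fixed slope than 8-visit ones."""
    rng = np.random.default_rng(10)
    rows = []
    fixed = 0.5
    true_dev = {}
    for i in range(120):
        # 2-visit subjects have a short, uninformative window; 8-visit a long one
        times = np.array([0.0, 1.0]) if i % 2 == 0 else np.linspace(0, 3.5, 8)
        dev = rng.normal(0, 0.15)
        true_dev[f"s{i}"] = dev
        for t in times:
            rows.append({"subject_id": f"s{i}", "time": t, "outcome": "y",
                         "value": (fixed + dev) * t + rng.normal(0, 0.5)})
    obs = pd.DataFrame(rows)
    subjects = pd.DataFrame({
        "subject_id": obs.subject_id.unique(), "group": "PD", "subtype": "slow",
        "sex": "M", "age_at_baseline": 60.0, "age_at_diagnosis": 60.0,
    })
    cohort = LongCohort(subjects=subjects, observations=obs, normalized=True)
    visits = obs[["subject_id", "time"]].drop_duplicates().copy()
    visits["latent_time"] = visits.time
    slopes = pg.outcome_slopes(cohort, visits, min_subjects=10)
    slopes["true"] = slopes.subject_id.map(true_dev) + fixed
    slopes["nv"] = np.where(slopes.subject_id.str[1:].astype(int) % 2 == 0, 2, 8)
    # attenuation of EB deviations onto true deviations, per visit count:
    # sparse subjects should be pulled toward the fixed slope much harder
    atten = {}
    for nv, g in slopes.groupby("nv"):
        atten[nv] = np.polyfit(g["true"] - g.fixed_slope, g.slope - g.fixed_slope, 1)[0]
    assert atten[2] < atten[8]
    assert atten[2] < 0.75  # visibly shrunk


def test_slopes_correlate_with_truth(mid_cohort):
    config, cohort, truth, _ = mid_cohort
    norm = normalize_outcomes(cohort, config.outcomes, on_out_of_range="clamp")
    pd_ids = set(cohort.pd_subjects().subject_id)
    obs = norm.observations[norm.observations.subject_id.isin(pd_ids)]
    sub = LongCohort(subjects=cohort.subjects, observations=obs, normalized=True)
    visits = obs[["subject_id", "time"]].drop_duplicates().copy()
    delta = truth.subjects.set_index("subject_id").delta
    visits["latent_time"] = visits.time + delta.reindex(visits.subject_id).to_numpy()
    slopes = pg.outcome_slopes(sub, visits, outcomes=["sdm"], min_subjects=20)
    # generative slope: gamma * multiplier + alpha1 + loading * u, per year
    t = truth.subjects.set_index("subject_id")
    re = truth.random_effects.query("outcome == 'sdm'").set_index("subject_id")
    spec = {s.name: s for s in config.outcomes}["sdm"]
    sids = slopes.subject_id
    true_slope = (spec.mean_slope * t.slope_multiplier.reindex(sids).to_numpy()
                  + re.alpha1.reindex(sids).to_numpy()
                  + spec.accel_loading * t.accel_factor.reindex(sids).to_numpy())
    r = np.corrcoef(slopes.slope, true_slope)[0, 1]
    assert r >= 0.7


def test_missing_longitudinal_coverage_rejected():
    _, norm, _, visits = _slope_cohort(n=12)
    with pytest.raises(ValueError, match="fewer than"):
        pg.outcome_slopes(norm, visits, min_subjects=20)


# ---------------------------------------------------------------------------
# correlations


def test_correlations_null_target():
    rng = np.random.default_rng(11)
    n = 200
    bag = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "bag_corrected": rng.normal(size=n),
        "chronological_age": rng.uniform(50, 80, n),
    })
    targets = pd.DataFrame({
        "subject_id": bag.subject_id,
        "noise": rng.normal(size=n),
    })
    table = pg.bag_correlations(bag, targets)
    assert abs(table.partial_r.iloc[0]) < 0.2


def test_correlations_cognitive_load_motor_null():
    """Cognitive slopes load on the aging factor; motor slopes do not."""
    rng = np.random.default_rng(12)
    n = 250
    u = rng.normal(0, 5, n)
    bag = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "bag_corrected": u + rng.normal(0, 2, n),
        "chronological_age": rng.uniform(50, 80, n),
    })
    targets = pd.DataFrame({
        "subject_id": bag.subject_id,
        "cog_slope": 0.004 * u + rng.normal(0, 0.01, n),
        "motor_slope": rng.normal(0, 0.02, n),
    })
    table = pg.bag_correlations(
        bag, targets, bh_groups={"cog_slope": "cognitive", "motor_slope": "motor"},
    ).set_index("target")
    assert table.loc["cog_slope", "p_adjusted"] < 0.01
    assert table.loc["motor_slope", "p_adjusted"] > 0.05
    assert set(table.family) == {"cognitive", "motor"}
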