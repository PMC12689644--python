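"""Synthetic longitudinal cohort generator with known ground truth.

The simulator draws multi-outcome clinical trajectories from a latent
time joint mixed-effects structure (shared per-subject time shift, fixed
outcome slopes, per-subject random intercepts/slopes, normal noise),
voxel feature grids with age- and disease-dependent atrophy, ordinal
staging, and time-to-event outcomes under a proportional-hazards model.
Every generative parameter is returned in a :class:`GroundTruth` object
so that downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import LongCohort, OutcomeSpec, harmonized_value, specs_by_name
from .grids import FeatureGrid, GridGeometry, shell_core_mask

AGE_CENTER = 62.5  # years; covariate centering constant shared with fitters
DX_LEAD_YEARS = 2.0  # assumed head start of brain aging before latent time 0


def default_outcome_specs() -> list[OutcomeSpec]:
    """Ten outcomes echoing a motor/non-motor/cognitive PD battery.

    The first seven form the default multi-outcome progression model
    battery; the last three are extra cognitive tests used by the
    composite endpoint. Slopes/noise are on the normalized scale.
    """
    return [
        OutcomeSpec("updrs1", 0, 52, "higher_worse", 0.030, 0.030, "clinical"),
        OutcomeSpec("updrs2", 0, 52, "higher_worse", 0.040, 0.030, "motor"),
        OutcomeSpec("updrs3", 0, 132, "higher_worse", 0.045, 0.035, "motor"),
        OutcomeSpec("updrs4", 0, 24, "higher_worse", 0.020, 0.030, "motor"),
        OutcomeSpec("pigd", 0, 4, "higher_worse", 0.035, 0.035, "motor"),
        OutcomeSpec("moca", 0, 30, "higher_better", 0.025, 0.030, "cognitive", 0.002),
        OutcomeSpec("scopa", 0, 69, "higher_worse", 0.030, 0.030, "clinical"),
        OutcomeSpec("hvlt_ir", 0, 36, "higher_better", 0.025, 0.035, "cognitive", 0.004),
        OutcomeSpec("lns", 0, 21, "higher_better", 0.020, 0.035, "cognitive", 0.004),
        OutcomeSpec("sdm", 0, 110, "higher_better", 0.030, 0.035, "cognitive", 0.004),
    ]


LTJMM_OUTCOMES = ["updrs1", "updrs2", "updrs3", "updrs4", "pigd", "moca", "scopa"]
COMPOSITE_TESTS = ["hvlt_ir", "lns", "moca", "sdm"]


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort generator.

    Variances refer to the normalized [0, 1] outcome scale. Subtype
    probabilities are over (fast, slow, unknown) within PD; "unknown"
    subjects carry a hidden fast/slow class drawn with the renormalized
    fast/slow odds.
    """

    n_hc: int = 172
    n_pd: int = 451
    outcomes: list[OutcomeSpec] = field(default_factory=default_outcome_specs)
    subtype_probs: tuple[float, float, float] = (0.146, 0.654, 0.200)
    age_min: float = 40.0
    age_max: float = 85.0
    male_frac: float = 0.63
    baseline_level: float = 0.22
    beta_age: float = 0.02  # normalized units per decade of age at diagnosis
    beta_sex: float = 0.02  # female-vs-male offset, normalized units
    delta_sd: float = 1.0  # years
    alpha0_sd: float = 0.04
    alpha1_sd: float = 0.015
    slope_multiplier: dict = field(default_factory=lambda: {"fast": 1.5, "slow": 0.9})
    brain_aging_rate: dict = field(default_factory=lambda: {"fast": 0.7, "slow": 0.08})
    accel_sd: float = 5.0  # years; stable per-subject brain-age offset
    scan_jitter_sd: float = 1.9  # years; per-scan brain-age measurement noise
    feature_noise_sd: float = 0.5  # feature units; smooth voxel noise
    tiv_scale_sd: float = 0.03
    baseline_window: tuple[float, float] = (0.0, 2.0)
    visit_interval: float = 0.5
    dropout_prob: float = 0.10
    max_followup: float = 11.0
    clamp: bool = True

    def __post_init__(self):
        for name, v in [("delta_sd", self.delta_sd), ("alpha0_sd", self.alpha0_sd),
                        ("alpha1_sd", self.alpha1_sd)]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        for spec in self.outcomes:
            if spec.noise_sd < 0:
                raise ValueError(f"{spec.name}: noise_sd must be >= 0")
        if abs(sum(self.subtype_probs) - 1.0) > 1e-9:
            raise ValueError("subtype probabilities over (fast, slow, unknown) must sum to 1")
        if any(p < 0 for p in self.subtype_probs):
            raise ValueError("subtype probabilities must be nonnegative")


@dataclass
class GroundTruth:
    """Every generative parameter of a simulated cohort."""

    subjects: pd.DataFrame  # subject_id, delta, hidden_subtype, slope_multiplier, ...
    outcomes: pd.DataFrame  # outcome, beta0, beta_age, beta_sex, gamma, sigma_eps, loading
    random_effects: pd.DataFrame  # subject_id, outcome, alpha0, alpha1
    config: SimConfig
    seed: int
    clamped_fraction: float = 0.0

    def delta_for(self, subject_ids) -> np.ndarray:
        m = self.subjects.set_index("subject_id")["delta"]
        return m.reindex(subject_ids).to_numpy()

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(directory / "truth_subjects.tsv", sep="\t", index=False)
        self.outcomes.to_csv(directory / "truth_outcomes.tsv", sep="\t", index=False)
        self.random_effects.to_csv(directory / "truth_random_effects.tsv", sep="\t", index=False)
        meta = {"seed": self.seed, "clamped_fraction": self.clamped_fraction,
                "config": _config_to_jsonable(self.config)}
        (directory / "truth_meta.json").write_text(json.dumps(meta, indent=1))


def _config_to_jsonable(config: SimConfig) -> dict:
    d = asdict(config)
    d["outcomes"] = [asdict(s) for s in config.outcomes]
    return d


def _visit_times(rng, t0: float, config: SimConfig) -> np.ndarray:
    times = [t0]
    t = t0
    while True:
        if rng.random() < config.dropout_prob:
            break
        t += config.visit_interval
        if t - t0 > config.max_followup + 1e-9:
            break
        times.append(t)
    return np.asarray(times)


def simulate_cohort(config: SimConfig, seed: int) -> tuple[LongCohort, GroundTruth]:
    """Draw a cohort from the latent-time joint mixed-effects structure.

    PD outcome values on the normalized scale follow

        v = beta0 + beta_age * (age_dx - c)/10 + beta_sex * female
            + gamma_k * m_i * (t + delta_i) + alpha0_ik
            + (alpha1_ik + loading_k * u_i) * t + eps

    with m_i the subtype slope multiplier and u_i the accelerated-aging
    factor. HC lack the disease terms (m = 0, delta = 0). Values are
    mapped to raw scales, de-harmonized and (optionally) clamped.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    specs = list(config.outcomes)
    K = len(specs)

    n = config.n_hc + config.n_pd
    subject_id = np.array(
        [f"HC{i:04d}" for i in range(config.n_hc)]
        + [f"PD{i:04d}" for i in range(config.n_pd)]
    )
    group = np.array(["HC"] * config.n_hc + ["PD"] * config.n_pd)
    sex = np.where(rng.random(n) < config.male_frac, "M", "F")
    age_baseline = rng.uniform(config.age_min, config.age_max, n)

    # subtype assignment (PD only); "unknown" carries a hidden class
    p_fast, p_slow, p_unknown = config.subtype_probs
    subtype = np.array(["none"] * n, dtype=object)
    hidden = np.array(["none"] * n, dtype=object)
    is_pd = group == "PD"
    u = rng.random(config.n_pd)
    lab = np.where(u < p_fast, "fast", np.where(u < p_fast + p_slow, "slow", "unknown"))
    subtype[is_pd] = lab
    odds_fast = p_fast / (p_fast + p_slow) if (p_fast + p_slow) > 0 else 0.5
    hidden_lab = lab.copy()
    unknown = hidden_lab == "unknown"
    hidden_lab[unknown] = np.where(rng.random(unknown.sum()) < odds_fast, "fast", "slow")
    hidden[is_pd] = hidden_lab

    delta = np.zeros(n)
    delta[is_pd] = rng.normal(0.0, config.delta_sd, config.n_pd)
    slope_mult = np.ones(n)
    aging_rate = np.zeros(n)
    for cls in ("fast", "slow"):
        sel = hidden == cls
        slope_mult[sel] = config.slope_multiplier[cls]
        aging_rate[sel] = config.brain_aging_rate[cls]
    accel = rng.normal(0.0, config.accel_sd, n)
    tiv_scale = rng.normal(1.0, config.tiv_scale_sd, n)

    t0 = np.zeros(n)
    t0[is_pd] = rng.uniform(*config.baseline_window, config.n_pd)
    age_dx = age_baseline - t0

    alpha0 = rng.normal(0.0, config.alpha0_sd, (n, K))
    alpha1 = rng.normal(0.0, config.alpha1_sd, (n, K))

    female = (sex == "F").astype(float)
    rows = []
    n_clamped = 0
    n_values = 0
    for i in range(n):
        times = _visit_times(rng, t0[i], config)
        covar = (config.baseline_level
                 + config.beta_age * (age_dx[i] - AGE_CENTER) / 10.0
                 + config.beta_sex * female[i])
        for k, spec in enumerate(specs):
            disease = 0.0
            if is_pd[i]:
                disease = spec.mean_slope * slope_mult[i] * (times + delta[i])
            slope_extra = (alpha1[i, k] + spec.accel_loading * accel[i]) * times
            eps = rng.normal(0.0, spec.noise_sd, times.size)
            v = covar + disease + alpha0[i, k] + slope_extra + eps
            raw = harmonized_value(spec, v)
            n_values += raw.size
            if config.clamp:
                clipped = np.clip(raw, spec.theoretical_min, spec.theoretical_max)
                n_clamped += int(np.sum(clipped != raw))
                raw = clipped
            for t, val in zip(times, raw):
                rows.append((subject_id[i], float(t), spec.name, float(val)))

    observations = pd.DataFrame(rows, columns=["subject_id", "time", "outcome", "value"])
    subjects = pd.DataFrame({
        "subject_id": subject_id,
        "group": group,
        "subtype": subtype,
        "sex": sex,
        "age_at_baseline": age_baseline,
        "age_at_diagnosis": age_dx,
    })
    truth_subjects = pd.DataFrame({
        "subject_id": subject_id,
        "group": group,
        "subtype": subtype,
        "hidden_subtype": hidden,
        "delta": delta,
        "slope_multiplier": np.where(is_pd, slope_mult, 0.0),
        "brain_aging_rate": aging_rate,
        "accel_factor": accel,
        "tiv_scale": tiv_scale,
        "baseline_time": t0,
        "age_at_diagnosis": age_dx,
    })
    truth_outcomes = pd.DataFrame({
        "outcome": [s.name for s in specs],
        "beta0": config.baseline_level,
        "beta_age": config.beta_age,
        "beta_sex": config.beta_sex,
        "gamma": [s.mean_slope for s in specs],
        "sigma_eps": [s.noise_sd for s in specs],
        "accel_loading": [s.accel_loading for s in specs],
    })
    re_rows = pd.DataFrame({
        "subject_id": np.repeat(subject_id, K),
        "outcome": np.tile([s.name for s in specs], n),
        "alpha0": alpha0.ravel(),
        "alpha1": alpha1.ravel(),
    })
    cohort = LongCohort(subjects=subjects, observations=observations)
    truth = GroundTruth(
        subjects=truth_subjects,
        outcomes=truth_outcomes,
        random_effects=re_rows,
        config=config,
        seed=int(seed),
        clamped_fraction=n_clamped / max(n_values, 1),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# feature grids


def true_brain_age_offset(truth: GroundTruth, subject_ids, times) -> np.ndarray:
    """Ground-truth brain-age-gap at given times since diagnosis/enrollment.

    offset = u_i + rate_i * (t + delta_i + lead) for PD, u_i for HC.
    """
    sub = truth.subjects.set_index("subject_id")
    u = sub["accel_factor"].reindex(subject_ids).to_numpy()
    rate = sub["brain_aging_rate"].reindex(subject_ids).to_numpy()
    delta = sub["delta"].reindex(subject_ids).to_numpy()
    t = np.asarray(times, dtype=float)
    return u + rate * np.clip(t + delta + DX_LEAD_YEARS, 0.0, None)


def default_grid(dims=(16, 16, 16), spacing=(1.0, 1.0, 1.0)) -> GridGeometry:
    brain, _, _ = shell_core_mask(dims)
    return GridGeometry(dims=dims, spacing=spacing, brain_mask=brain)


def _spatial_fields(geometry: GridGeometry):
    """Template, aging coefficient, and subtype atrophy weights on the grid."""
    dims = geometry.dims
    brain, shell, core = shell_core_mask(dims)
    coords = np.meshgrid(*[np.linspace(-1, 1, d) for d in dims], indexing="ij")
    r2 = sum(c**2 for c in coords)
    template = 140.0 * np.exp(-1.2 * r2) * brain
    aging = (0.6 + 0.8 * np.exp(-r2)) * brain  # units per year, positive in brain
    w = {}
    for name, shell_gain, core_gain in [("fast", 1.3, 0.7), ("slow", 0.7, 1.5)]:
        raw = np.where(shell, shell_gain, np.where(core, core_gain, 0.0))
        a2 = aging[brain] ** 2
        norm = np.sum(a2 * raw[brain]) / np.sum(a2)
        w[name] = raw / norm  # aging-weighted mean of w over the brain is 1
    w["none"] = np.zeros(dims)
    return brain, template, aging, w


def _scan_schedule(cohort: LongCohort, rng, retest_frac: float, long_frac: float):
    """Per subject: baseline scan, plus a <1.5 y retest or a multi-year series.

    Inter-scan intervals are jittered so that elapsed time varies across
    subjects (needed for a meaningful longitudinal consistency check).
    """
    rows = []
    obs = cohort.observations
    first = obs.groupby("subject_id")["time"].min()
    for _, subj in cohort.subjects.iterrows():
        t0 = float(first.get(subj.subject_id, 0.0))
        times = [t0]
        u = rng.random()
        if u < retest_frac:
            times.append(t0 + rng.uniform(0.4, 1.4))
        elif u < retest_frac + long_frac:
            times.append(t0 + rng.uniform(1.5, 3.0))
            times.append(t0 + rng.uniform(3.5, 6.5))
        for t in times:
            rows.append((subj.subject_id, t))
    return rows


def simulate_features(
    cohort: LongCohort,
    truth: GroundTruth,
    grid: GridGeometry,
    seed: int,
    retest_frac: float = 0.20,
    long_frac: float = 0.25,
    noise_sd: float | None = None,
    scan_times: pd.DataFrame | None = None,
) -> FeatureGrid:
    """Voxel feature maps per scan: template minus age- and disease-driven atrophy.

    value(v) = s_i * template(v) - aging(v) * (age + u_i + eta_scan)
               - aging(v) * w_subtype(v) * rate_i * (t + delta_i + lead)
               + smooth noise

    Monotone nonincreasing in age at every voxel when all noise is off.
    ``scan_times`` (subject_id, scan_time) overrides the random schedule.
    """
    if any(d < 4 for d in grid.dims):
        raise ValueError("grid dimensions must be >= 4 per axis")
    known = set(cohort.subjects.subject_id)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFEA7]))
    config = truth.config
    if noise_sd is None:
        noise_sd = config.feature_noise_sd

    brain, template, aging, w = _spatial_fields(grid)
    brain &= grid.brain_mask

    if scan_times is None:
        schedule = _scan_schedule(cohort, rng, retest_frac, long_frac)
    else:
        schedule = list(scan_times[["subject_id", "scan_time"]].itertuples(index=False))
    if any(s not in known for s, _ in schedule):
        raise ValueError("scan schedule references subjects absent from the cohort")

    sub = truth.subjects.set_index("subject_id")
    meta = cohort.subjects.set_index("subject_id")
    first = cohort.observations.groupby("subject_id")["time"].min()

    data = np.empty((len(schedule), *grid.dims))
    index_rows = []
    jitter_sd = config.scan_jitter_sd if noise_sd > 0 else 0.0
    for s, (sid, t) in enumerate(schedule):
        t0 = float(first.get(sid, 0.0))
        age = float(meta.loc[sid, "age_at_baseline"]) + (t - t0)
        u_i = float(sub.loc[sid, "accel_factor"])
        rate = float(sub.loc[sid, "brain_aging_rate"])
        delta = float(sub.loc[sid, "delta"])
        hidden = str(sub.loc[sid, "hidden_subtype"])
        s_i = float(sub.loc[sid, "tiv_scale"])
        eta = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
        disease = rate * max(t + delta + DX_LEAD_YEARS, 0.0)
        vol = s_i * template - aging * (age + u_i + eta) - aging * w[hidden] * disease
        if noise_sd > 0:
            white = rng.normal(0.0, 1.0, grid.dims)
            smooth = ndimage.gaussian_filter(white, sigma=1.5, mode="nearest")
            smooth *= noise_sd / max(smooth.std(), 1e-12)
            vol = vol + smooth
        data[s] = vol * brain
        index_rows.append({
            "subject_id": sid,
            "scan_time": float(t),
            "age": age,
            "group": str(meta.loc[sid, "group"]),
            "subtype": str(meta.loc[sid, "subtype"]),
            "sex": str(meta.loc[sid, "sex"]),
            "tiv": float(s_i * template[brain].sum() * grid.voxel_volume),
        })
    geom = GridGeometry(dims=grid.dims, spacing=grid.spacing, brain_mask=brain)
    return FeatureGrid(data=data, geometry=geom, index=pd.DataFrame(index_rows))


# ---------------------------------------------------------------------------
# staging and events


def simulate_staging(cohort: LongCohort, truth: GroundTruth, seed: int,
                     noise_sd: float = 1.5,
                     thresholds=(-0.5, 2.0, 5.0, 8.0)) -> pd.DataFrame:
    """Ordinal disease stage per PD visit, generated from true latent time.

    Stage is the bin index of (t + delta + noise) over ``thresholds``
    plus one, emulating a coarse clinical staging scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x57A6]))
    obs = cohort.observations
    visits = obs[["subject_id", "time"]].drop_duplicates().reset_index(drop=True)
    visits = visits.merge(cohort.subjects[["subject_id", "group"]], on="subject_id")
    visits = visits[visits.group == "PD"].reset_index(drop=True)
    delta = truth.delta_for(visits.subject_id)
    latent = visits.time.to_numpy() + delta
    noisy = latent + rng.normal(0.0, noise_sd, latent.size)
    stage = np.digitize(noisy, thresholds) + 1
    return pd.DataFrame({
        "subject_id": visits.subject_id,
        "time": visits.time,
        "stage": stage,
        "true_latent_time": latent,
    })


def simulate_events(
    cohort: LongCohort,
    truth: GroundTruth,
    beta_bag: float,
    seed: int,
    baseline_hazard: float = 0.25,
    beta_age: float = 0.01,
    beta_sex: float = -0.1,
) -> pd.DataFrame:
    """Time-to-event outcomes from a proportional-hazards model (PD subjects).

    hazard_i = baseline_hazard * exp(beta_age (age - c) + beta_sex female
               + beta_bag * score_i), with score_i the true accelerated-
    aging offset at baseline. Entry is the baseline latent time; censoring
    at the subject's observed follow-up duration.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE4E7]))
    subjects = cohort.pd_subjects()
    obs = cohort.observations
    tmin = obs.groupby("subject_id")["time"].min()
    tmax = obs.groupby("subject_id")["time"].max()
    sub = truth.subjects.set_index("subject_id")

    rows = []
    for _, rec in subjects.iterrows():
        sid = rec.subject_id
        t0 = float(tmin.get(sid, 0.0))
        followup = float(tmax.get(sid, t0)) - t0
        delta = float(sub.loc[sid, "delta"])
        score = float(true_brain_age_offset(truth, [sid], [t0])[0])
        female = 1.0 if rec.sex == "F" else 0.0
        loghaz = (np.log(baseline_hazard)
                  + beta_age * (rec.age_at_baseline - AGE_CENTER)
                  + beta_sex * female
                  + beta_bag * score)
        event_after = rng.exponential(1.0 / np.exp(loghaz))
        duration = min(event_after, followup)
        rows.append({
            "subject_id": sid,
            "entry_time": t0 + delta,
            "exit_time": t0 + delta + duration,
            "event": int(event_after <= followup),
            "age_at_baseline": float(rec.age_at_baseline),
            "sex": rec.sex,
            "baseline_bag": score,
        })
    return pd.DataFrame(rows)
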