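"""Composite endpoints and sample size for slope-difference trials.

Closed-form sizing follows the random-slope mixed-model formula for a
two-arm comparison of mean slopes under a fixed visit schedule,

    n_per_arm = 2 (z_{1-a/2} + z_{pow})^2 (sig_b^2 + sig_e^2 / Sxx)
                / (effect * mean_slope)^2,   Sxx = sum_j (t_j - tbar)^2,

with Monte Carlo trial simulation as an independent check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .cohort import LongCohort, OutcomeSpec, specs_by_name

__all__ = [
    "TrialDesign",
    "SlopeComponents",
    "PowerResult",
    "composite_score",
    "estimate_slope_components",
    "edland_n",
    "stratified_power",
    "validate_power_mc",
]


@dataclass(frozen=True)
class TrialDesign:
    visit_times: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    alpha: float = 0.1
    power_target: float = 0.8
    effect_fraction: float = 0.3
    two_sided: bool = True

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power_target < 1:
            raise ValueError("power_target must be in (0, 1)")
        if len(self.visit_times) < 2:
            raise ValueError("need at least 2 visits")

    @property
    def sxx(self) -> float:
        t = np.asarray(self.visit_times, dtype=float)
        return float(np.sum((t - t.mean()) ** 2))

    @property
    def z_alpha(self) -> float:
        a = self.alpha / 2 if self.two_sided else self.alpha
        return float(sps.norm.ppf(1 - a))

    @property
    def z_power(self) -> float:
        return float(sps.norm.ppf(self.power_target))


@dataclass(frozen=True)
class SlopeComponents:
    mean_slope: float  # composite units / year (positive = worsening)
    slope_var: float  # between-subject variance of slopes
    resid_var: float  # within-subject residual variance

    def __post_init__(self):
        if self.slope_var < 0 or self.resid_var < 0:
            raise ValueError("variance components must be >= 0")


@dataclass
class PowerResult:
    n_per_arm: int
    n_total: int
    power_curve: pd.DataFrame  # columns n_total, power
    stratification_percentile: float | None
    relative_reduction: float
    components: SlopeComponents
    design: TrialDesign
    n_subgroup: int | None = None


def composite_score(cohort: LongCohort, tests, specs: list[OutcomeSpec] | None = None
                    ) -> pd.DataFrame:
    """Cognitive composite: baseline-anchored z-scores averaged over tests.

    Uses each subject's earliest visit per test as baseline; z-scores are
    computed against the baseline mean/sd across included subjects,
    inverted for ``higher_better`` outcomes so that a larger composite is
    worse, and averaged. Only subjects with all tests at baseline are
    included. Returns (subject_id, time, composite).
    """
    tests = list(tests)
    by_name = specs_by_name(specs) if specs is not None else {}
    obs = cohort.observations[cohort.observations.outcome.isin(tests)]
    if obs.empty:
        raise ValueError("no observations for the requested tests")
    first = obs.sort_values("time").groupby(["subject_id", "outcome"]).first().reset_index()
    have_all = first.groupby("subject_id")["outcome"].nunique() == len(tests)
    keep = have_all[have_all].index
    if keep.empty:
        raise ValueError("no subject has all composite tests at baseline")
    obs = obs[obs.subject_id.isin(keep)]
    base = first[first.subject_id.isin(keep)]

    stats = base.groupby("outcome")["value"].agg(["mean", "std"])
    if (stats["std"].fillna(0.0) == 0).any():
        bad = stats.index[stats["std"].fillna(0.0) == 0].tolist()
        raise ValueError(f"zero baseline standard deviation for: {bad}")

    z = obs.copy()
    z["z"] = (z["value"] - z["outcome"].map(stats["mean"])) / z["outcome"].map(stats["std"])
    flip = {
        name: -1.0 if (name in by_name and by_name[name].direction == "higher_better") else 1.0
        for name in tests
    }
    if cohort.normalized:  # already harmonized: nothing to invert
        flip = {name: 1.0 for name in tests}
    z["z"] *= z["outcome"].map(flip)
    out = z.groupby(["subject_id", "time"])["z"].mean().rename("composite").reset_index()
    return out


def estimate_slope_components(composite: pd.DataFrame,
                              max_time: float | None = None) -> SlopeComponents:
    """Random-intercept/random-slope mixed model on the composite.

    Time is measured since each subject's first composite visit,
    optionally truncated at ``max_time`` (e.g. the trial horizon).
    Falls back to a moments estimator on per-subject least-squares
    slopes if the mixed model does not converge usably.
    """
    t = composite.copy()
    t["tt"] = t["time"] - t.groupby("subject_id")["time"].transform("min")
    if max_time is not None:
        t = t[t["tt"] <= max_time + 1e-9]
    counts = t.groupby("subject_id")["tt"].transform("size")
    t = t[counts >= 2]
    if t.subject_id.nunique() < 10:
        raise ValueError("too few subjects with longitudinal composites")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("composite ~ tt", data=t, groups=t["subject_id"],
                                re_formula="~tt").fit(method="lbfgs", maxiter=500)
        mean_slope = float(model.params["tt"])
        slope_var = float(model.cov_re.loc["tt", "tt"])
        resid_var = float(model.scale)
        if not np.isfinite(slope_var) or slope_var < 0 or not model.converged:
            raise RuntimeError("unusable mixed-model fit")
    except Exception:
        mean_slope, slope_var, resid_var = _moment_components(t)
    return SlopeComponents(mean_slope=mean_slope, slope_var=max(slope_var, 0.0),
                           resid_var=max(resid_var, 0.0))


def _moment_components(t: pd.DataFrame):
    """Per-subject OLS slopes; decompose their variance via E[resid/Sxx]."""
    slopes, resid_vars, inv_sxx = [], [], []
    for _, g in t.groupby("subject_id"):
        x = g["tt"].to_numpy(dtype=float)
        y = g["composite"].to_numpy(dtype=float)
        sxx = np.sum((x - x.mean()) ** 2)
        if sxx <= 0:
            continue
        b = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        slopes.append(b)
        inv_sxx.append(1.0 / sxx)
        if x.size > 2:
            a = y.mean() - b * x.mean()
            r = y - a - b * x
            resid_vars.append(np.sum(r**2) / (x.size - 2))
    resid_var = float(np.mean(resid_vars)) if resid_vars else 0.0
    slopes = np.asarray(slopes)
    slope_var = float(np.var(slopes, ddof=1) - resid_var * np.mean(inv_sxx))
    return float(np.mean(slopes)), slope_var, resid_var


def edland_n(components: SlopeComponents, design: TrialDesign,
             curve_max_factor: float = 3.0) -> PowerResult:
    """Closed-form per-arm sample size and power curve for a slope trial."""
    if components.mean_slope <= 0:
        raise ValueError("mean_slope must be > 0 (harmonize directions first)")
    delta = design.effect_fraction * components.mean_slope
    if delta == 0:
        raise ValueError("zero treatment effect: required n is infinite")
    sig_eff2 = components.slope_var + components.resid_var / design.sxx
    n_exact = 2.0 * (design.z_alpha + design.z_power) ** 2 * sig_eff2 / delta**2
    n_per_arm = int(np.ceil(n_exact))

    ns = np.unique(np.maximum(
        np.round(np.linspace(2, max(n_per_arm * curve_max_factor, 10), 60)), 2
    ).astype(int))
    ncp = delta / np.sqrt(2.0 * sig_eff2 / ns)
    powers = sps.norm.cdf(ncp - design.z_alpha)
    curve = pd.DataFrame({"n_total": 2 * ns, "power": powers})
    return PowerResult(
        n_per_arm=n_per_arm,
        n_total=2 * n_per_arm,
        power_curve=curve,
        stratification_percentile=None,
        relative_reduction=0.0,
        components=components,
        design=design,
    )


def stratified_power(composite: pd.DataFrame, bag_baseline: pd.DataFrame,
                     percentiles, design: TrialDesign,
                     min_subjects: int = 20,
                     bag_column: str = "bag_corrected") -> list[PowerResult]:
    """Required n with and without BAG-percentile prognostic enrichment.

    The first result is the unstratified scenario; each further result
    restricts to subjects whose baseline BAG is strictly above the given
    empirical percentile, re-estimates the slope components on that
    subgroup, and reports the relative sample-size reduction.
    """
    merged_ids = set(composite.subject_id) & set(bag_baseline.subject_id)
    comp = composite[composite.subject_id.isin(merged_ids)]
    bag = bag_baseline.set_index("subject_id")[bag_column]
    horizon = max(design.visit_times)

    results = []
    base_components = estimate_slope_components(comp, max_time=horizon)
    base = edland_n(base_components, design)
    base.n_subgroup = len(merged_ids)
    results.append(base)

    for pct in percentiles:
        if not 0 <= pct < 100:
            raise ValueError("percentile must be in [0, 100)")
        if pct == 0:
            results.append(PowerResult(
                n_per_arm=base.n_per_arm, n_total=base.n_total,
                power_curve=base.power_curve, stratification_percentile=0.0,
                relative_reduction=0.0, components=base_components, design=design,
                n_subgroup=len(merged_ids),
            ))
            continue
        thr = float(np.percentile(bag.reindex(sorted(merged_ids)).dropna(), pct))
        chosen = set(bag[bag > thr].index) & merged_ids
        if len(chosen) < min_subjects:
            raise ValueError(
                f"subgroup above percentile {pct} has {len(chosen)} subjects "
                f"(< {min_subjects})"
            )
        comp_sub = comp[comp.subject_id.isin(chosen)]
        comps = estimate_slope_components(comp_sub, max_time=horizon)
        res = edland_n(comps, design)
        res.stratification_percentile = float(pct)
        res.relative_reduction = 1.0 - res.n_total / base.n_total
        res.n_subgroup = len(chosen)
        results.append(res)
    return results


def validate_power_mc(components: SlopeComponents, design: TrialDesign,
                      n: int, reps: int, seed: int) -> float:
    """Empirical power by simulating trials from the random-slope model.

    Each arm gets ``n`` subjects with latent slopes N(mu, slope_var)
    (treatment mu reduced by the design's effect fraction) and noisy
    visits at the design schedule; the analysis is a pooled two-sample
    t-test on per-subject least-squares slopes, which is the exact
    matched test for this design. Returns the rejection fraction.
    """
    if reps < 200:
        raise ValueError("need at least 200 replications")
    rng = np.random.default_rng(seed)
    t = np.asarray(design.visit_times, dtype=float)
    w = (t - t.mean()) / design.sxx  # LS slope weights
    sd_b = np.sqrt(components.slope_var)
    sd_e = np.sqrt(components.resid_var)
    mu_c = components.mean_slope
    mu_t = components.mean_slope * (1.0 - design.effect_fraction)

    def arm_slopes(mu):
        b = rng.normal(mu, sd_b, size=(reps, n))
        y = b[:, :, None] * t[None, None, :] + rng.normal(0.0, sd_e, size=(reps, n, t.size))
        return y @ w

    sc = arm_slopes(mu_c)
    st = arm_slopes(mu_t)
    mdiff = sc.mean(axis=1) - st.mean(axis=1)
    var_pool = (sc.var(axis=1, ddof=1) + st.var(axis=1, ddof=1)) / 2.0
    tstat = mdiff / np.sqrt(var_pool * 2.0 / n)
    dof = 2 * n - 2
    if design.two_sided:
        crit = sps.t.ppf(1 - design.alpha / 2, dof)
        reject = np.abs(tstat) > crit
    else:
        crit = sps.t.ppf(1 - design.alpha, dof)
        reject = tstat > crit
    return float(np.mean(reject))


def select_composite_tests(cohort: LongCohort, candidates, design: TrialDesign,
                           specs: list[OutcomeSpec], n_tests: int = 4) -> list[str]:
    """Optional selection pass: the candidates with the lowest single-test n."""
    sizes = []
    for name in candidates:
        comp = composite_score(cohort, [name], specs)
        try:
            comps = estimate_slope_components(comp, max_time=max(design.visit_times))
            n = edland_n(comps, design).n_total
        except ValueError:
            n = np.inf
        sizes.append((n, name))
    sizes.sort()
    return [name for _, name in sizes[:n_tests]]
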