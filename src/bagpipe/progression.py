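"""Group comparisons, trajectories, slope extraction and correlations for BAG."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .cohort import LongCohort
from .stats import bh_adjust, partial_correlation

__all__ = [
    "baseline_bag",
    "compare_bag_groups",
    "ComparisonReport",
    "bag_trajectory",
    "TrajectoryReport",
    "outcome_slopes",
    "bag_correlations",
]


def baseline_bag(bag_table: pd.DataFrame) -> pd.DataFrame:
    """First scan per subject."""
    t = bag_table.sort_values("scan_time")
    return t.groupby("subject_id", sort=False).first().reset_index()


@dataclass
class ComparisonReport:
    group_a: str
    group_b: str
    delta_bag: float  # adjusted coefficient: mean(b) - mean(a)
    p_value: float
    covariates: tuple[str, ...]
    n_a: int
    n_b: int


def compare_bag_groups(bag_table: pd.DataFrame, groups: tuple[str, str],
                       group_column: str = "subtype",
                       covariates=("age", "sex"),
                       latent_time_column: str = "latent_time") -> ComparisonReport:
    """Covariate-adjusted pairwise BAG difference between two groups.

    BAG at the first scan is regressed on a group indicator plus the
    covariates; the latent-time covariate is added automatically for the
    fast-vs-slow subtype contrast (both groups then have a disease
    stage). The reported delta is the group coefficient for ``groups[1]``
    relative to ``groups[0]``.
    """
    base = baseline_bag(bag_table)
    a, b = groups
    sel = base[base[group_column].isin([a, b])].copy()
    n_a = int((sel[group_column] == a).sum())
    n_b = int((sel[group_column] == b).sum())
    if min(n_a, n_b) < 3:
        raise ValueError(f"group with fewer than 3 subjects in contrast {groups}")

    covs = list(covariates)
    if {a, b} == {"fast", "slow"} and latent_time_column in sel.columns:
        covs.append(latent_time_column)

    columns = [np.ones(len(sel)), (sel[group_column] == b).to_numpy(dtype=float)]
    for c in covs:
        v = sel[c]
        if v.dtype == object:
            v = (v.astype(str) == "F").astype(float)
        columns.append(np.asarray(v, dtype=float))
    X = np.column_stack(columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates?)")
    model = sm.OLS(sel["bag_corrected"].to_numpy(dtype=float), X).fit()
    return ComparisonReport(
        group_a=a, group_b=b,
        delta_bag=float(model.params[1]),
        p_value=float(model.pvalues[1]),
        covariates=tuple(covs),
        n_a=n_a, n_b=n_b,
    )


@dataclass
class TrajectoryReport:
    group: str
    slope: float  # BAG years per year
    slope_p: float
    slope_ci: tuple[float, float]
    intercept: float
    n_subjects: int
    n_excluded_single_scan: int


def bag_trajectory(bag_table: pd.DataFrame, group: str,
                   group_column: str = "subtype") -> TrajectoryReport:
    """Fixed BAG slope over time since first scan, via a linear mixed model.

    Random intercepts and slopes per subject; subjects with a single scan
    are excluded from estimation (their count is reported).
    """
    t = bag_table[bag_table[group_column] == group].copy()
    counts = t.groupby("subject_id")["scan_time"].transform("size")
    n_single = int((counts == 1).groupby(t["subject_id"]).first().sum())
    t = t[counts >= 2].copy()
    n_subj = t["subject_id"].nunique()
    if n_subj < 5:
        raise ValueError(f"need >= 5 subjects with >= 2 scans in group {group!r}")
    first = t.groupby("subject_id")["scan_time"].transform("min")
    t["time_since_first"] = t["scan_time"] - first

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "bag_corrected ~ time_since_first", data=t,
            groups=t["subject_id"], re_formula="~time_since_first",
        ).fit(method="lbfgs", maxiter=500)
    slope = float(model.params["time_since_first"])
    p = float(model.pvalues["time_since_first"])
    se = float(model.bse["time_since_first"])
    return TrajectoryReport(
        group=group,
        slope=slope,
        slope_p=p,
        slope_ci=(slope - 1.959963984540054 * se, slope + 1.959963984540054 * se),
        intercept=float(model.params["Intercept"]),
        n_subjects=n_subj,
        n_excluded_single_scan=n_single,
    )


def outcome_slopes(cohort: LongCohort, latent: pd.DataFrame,
                   outcomes=None, min_subjects: int = 20) -> pd.DataFrame:
    """Per-subject progression slopes on the latent disease timescale.

    One linear mixed model per outcome (fixed + random intercept/slope on
    latent time); returns conditional (empirical-Bayes) slopes per
    subject x outcome: slope = fixed slope + BLUP. The cohort should be
    normalized/harmonized so positive slopes mean worsening.
    """
    obs = cohort.observations.merge(latent, on=["subject_id", "time"], how="inner")
    names = outcomes if outcomes is not None else sorted(obs.outcome.unique())
    rows = []
    for name in names:
        sub = obs[obs.outcome == name].copy()
        counts = sub.groupby("subject_id").size()
        longitudinal = counts[counts >= 2].index
        sub = sub[sub.subject_id.isin(longitudinal)]
        if sub.subject_id.nunique() < min_subjects:
            raise ValueError(
                f"outcome {name!r}: fewer than {min_subjects} subjects with >= 2 visits"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "value ~ latent_time", data=sub,
                groups=sub["subject_id"], re_formula="~latent_time",
            ).fit(method="lbfgs", maxiter=500)
        fixed = float(model.params["latent_time"])
        for sid, re in model.random_effects.items():
            rows.append({
                "subject_id": sid,
                "outcome": name,
                "slope": fixed + float(re.get("latent_time", 0.0)),
                "fixed_slope": fixed,
            })
    return pd.DataFrame(rows)


def bag_correlations(bag_baseline: pd.DataFrame, targets: pd.DataFrame,
                     covariates=("chronological_age",),
                     bh_groups: dict | None = None,
                     bag_column: str = "bag_corrected") -> pd.DataFrame:
    """Partial correlations of baseline BAG with per-subject targets.

    ``targets`` is wide: subject_id plus one column per target (baseline
    values or progression slopes, already harmonized so higher = worse /
    faster). ``bh_groups`` maps target name -> multiplicity family; BH
    adjustment runs within each family.
    """
    merged = bag_baseline.merge(targets, on="subject_id", how="inner")
    target_cols = [c for c in targets.columns if c != "subject_id"]
    rows = []
    for c in target_cols:
        cols = [bag_column, c, *covariates]
        sub = merged[cols].dropna()
        covs = np.column_stack([
            (sub[k].astype(str) == "F").astype(float) if sub[k].dtype == object
            else sub[k].to_numpy(dtype=float)
            for k in covariates
        ]) if covariates else None
        r, p = partial_correlation(
            sub[bag_column].to_numpy(dtype=float),
            sub[c].to_numpy(dtype=float),
            covs,
        )
        rows.append({
            "target": c,
            "family": (bh_groups or {}).get(c, "all"),
            "partial_r": r,
            "p_raw": p,
            "n": len(sub),
        })
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.nan
    for fam, sel in table.groupby("family").groups.items():
        table.loc[sel, "p_adjusted"] = bh_adjust(table.loc[sel, "p_raw"].to_numpy())
    table.attrs["covariates"] = tuple(covariates)
    return table
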