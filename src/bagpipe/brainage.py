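"""Brain age estimation workflows, bias correction, and reliability checks."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import LassoCV, RidgeCV
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .grids import FeatureGrid, smooth_and_resample
from .stats import concordance_ccc

__all__ = [
    "Workflow",
    "BrainAgeModel",
    "BiasCorrection",
    "train_brain_age",
    "fit_bias_correction",
    "apply_bag",
    "select_workflow",
    "SelectionReport",
    "concordance",
    "longitudinal_consistency",
    "ConsistencyReport",
]

concordance = concordance_ccc


@dataclass(frozen=True)
class Workflow:
    """A brain age estimation workflow: feature pipeline + regressor.

    The three named combinations reproduce the reference workflows:
    smoothing+resampling with a Gaussian-process regressor, the same
    with a principal-components reduction, and resampling-only with an
    L1-penalized ("lasso") linear regressor.
    """

    smoothing_fwhm: float = 0.0
    resample_factor: int = 4
    reducer: str = "none"  # none | principal_components
    regressor: str = "sparse_linear"  # sparse_linear | kernel_gp | ridge

    def __post_init__(self):
        if self.smoothing_fwhm < 0:
            raise ValueError("smoothing_fwhm must be >= 0")
        if self.resample_factor < 1:
            raise ValueError("resample_factor must be >= 1")
        if self.reducer not in ("none", "principal_components"):
            raise ValueError(f"unknown reducer {self.reducer!r}")
        if self.regressor not in ("sparse_linear", "kernel_gp", "ridge"):
            raise ValueError(f"unknown regressor {self.regressor!r}")

    @property
    def name(self) -> str:
        tag = f"S{self.smoothing_fwhm:g}_R{self.resample_factor}"
        if self.reducer == "principal_components":
            tag += "+PCA"
        tag += {"sparse_linear": "+LR", "kernel_gp": "+GPR", "ridge": "+Ridge"}[self.regressor]
        return tag

    @property
    def n_stages(self) -> int:
        """Pipeline stage count, used for deterministic tie-breaking."""
        return (
            int(self.smoothing_fwhm > 0)
            + int(self.resample_factor > 1)
            + int(self.reducer != "none")
            + 1
        )

    @classmethod
    def s4_r4_gpr(cls):
        return cls(4.0, 4, "none", "kernel_gp")

    @classmethod
    def s4_r4_pca_gpr(cls):
        return cls(4.0, 4, "principal_components", "kernel_gp")

    @classmethod
    def s0_r4_lr(cls):
        return cls(0.0, 4, "none", "sparse_linear")


@dataclass
class BrainAgeModel:
    """Fitted workflow artifact; ``predict`` maps a FeatureGrid to years."""

    workflow: Workflow
    scaler: StandardScaler | None
    pca: PCA | None
    regressor: object
    constant: float | None  # degenerate constant-age fallback
    seed: int
    version: str = "bagpipe-brainage-1"

    def _features(self, grid: FeatureGrid) -> np.ndarray:
        wf = self.workflow
        if wf.smoothing_fwhm > 0 or wf.resample_factor > 1:
            grid = smooth_and_resample(grid, wf.smoothing_fwhm, wf.resample_factor)
        mat = grid.masked_matrix()
        if self.scaler is not None:
            mat = self.scaler.transform(mat)
        if self.pca is not None:
            mat = self.pca.transform(mat)
        return mat

    def predict(self, grid: FeatureGrid) -> np.ndarray:
        if self.constant is not None:
            return np.full(grid.n_scans, self.constant)
        return np.asarray(self.regressor.predict(self._features(grid)), dtype=float)


def train_brain_age(train_features: FeatureGrid, train_ages, wf: Workflow,
                    seed: int) -> BrainAgeModel:
    """Train one workflow on HC scans. Deterministic given seed."""
    ages = np.asarray(train_ages, dtype=float)
    if ages.size != train_features.n_scans:
        raise ValueError("ages do not match number of training scans")
    if ages.size < 50 or np.ptp(ages) < 20:
        warnings.warn(
            "small or narrow training set (< 50 subjects or < 20 y span); "
            "brain age estimates may be unstable", UserWarning,
        )
    if np.ptp(ages) == 0:
        # constant-label degenerate case: constant predictor
        return BrainAgeModel(wf, None, None, None, constant=float(ages[0]), seed=int(seed))

    model = BrainAgeModel(wf, None, None, None, constant=None, seed=int(seed))
    grid = train_features
    if wf.smoothing_fwhm > 0 or wf.resample_factor > 1:
        grid = smooth_and_resample(grid, wf.smoothing_fwhm, wf.resample_factor)
    mat = grid.masked_matrix()
    model.scaler = StandardScaler().fit(mat)
    mat = model.scaler.transform(mat)
    if wf.reducer == "principal_components":
        n_comp = int(min(mat.shape[0] - 1, mat.shape[1], 50))
        model.pca = PCA(n_components=n_comp, random_state=seed).fit(mat)
        mat = model.pca.transform(mat)

    inner_cv = KFold(n_splits=min(5, ages.size), shuffle=True, random_state=seed)
    if wf.regressor == "sparse_linear":
        reg = LassoCV(cv=inner_cv, alphas=40, max_iter=50_000, random_state=seed)
    elif wf.regressor == "ridge":
        reg = RidgeCV(alphas=np.logspace(-3, 4, 30))
    else:
        kernel = (
            ConstantKernel(1.0, (1e-3, 1e4)) * RBF(10.0, (1e-2, 1e5))
            + WhiteKernel(1.0, (1e-6, 1e4))
        )
        reg = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=seed, n_restarts_optimizer=1
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reg.fit(mat, ages)
    model.regressor = reg
    return model


@dataclass
class BiasCorrection:
    """Linear age-bias recalibration fitted on HC.

    ``cole``: OLS of predicted age on chronological age (pred = a + b*age);
    corrected prediction = (pred - a) / b.
    ``beheshti``: OLS of BAG on chronological age (bag = a + b*age);
    corrected BAG = bag - (a + b*age).
    """

    method: str
    intercept: float
    slope: float
    training_n: int

    def corrected_prediction(self, pred, chron) -> np.ndarray:
        pred = np.asarray(pred, dtype=float)
        chron = np.asarray(chron, dtype=float)
        if self.method == "cole":
            return (pred - self.intercept) / self.slope
        return pred - (self.intercept + self.slope * chron)

    def corrected_bag(self, pred, chron) -> np.ndarray:
        return self.corrected_prediction(pred, chron) - np.asarray(chron, dtype=float)


def fit_bias_correction(pred, chron, method: str) -> BiasCorrection:
    """Fit the linear bias correction on HC (prediction, age) pairs."""
    pred = np.asarray(pred, dtype=float)
    chron = np.asarray(chron, dtype=float)
    if pred.size != chron.size:
        raise ValueError("pred and chron must have equal length")
    if pred.size < 10:
        raise ValueError("need at least 10 HC pairs to fit a bias correction")
    if np.var(chron) == 0:
        raise ValueError("chronological age has zero variance")
    if method not in ("cole", "beheshti"):
        raise ValueError(f"unknown bias correction method {method!r}")
    target = pred if method == "cole" else pred - chron
    slope, intercept = np.polyfit(chron, target, deg=1)
    if method == "cole" and abs(slope) < 1e-8:
        raise ValueError("cole correction undefined: fitted slope is ~0")
    return BiasCorrection(method=method, intercept=float(intercept),
                          slope=float(slope), training_n=int(pred.size))


def apply_bag(model: BrainAgeModel, correction: BiasCorrection,
              features: FeatureGrid, chron=None) -> pd.DataFrame:
    """Corrected brain age gap per scan.

    Returns a BagTable: subject_id, scan_time, chronological_age,
    brain_age_raw, brain_age_corrected, bag_corrected.
    """
    if chron is None:
        if "age" not in features.index.columns:
            raise ValueError("no chronological ages: pass chron or an index with 'age'")
        chron = features.index["age"].to_numpy(dtype=float)
    chron = np.asarray(chron, dtype=float)
    if chron.size != features.n_scans:
        raise ValueError("chronological ages do not match number of scans")
    raw = model.predict(features)
    corrected = correction.corrected_prediction(raw, chron)
    table = pd.DataFrame({
        "chronological_age": chron,
        "brain_age_raw": raw,
        "brain_age_corrected": corrected,
        "bag_corrected": corrected - chron,
    })
    if len(features.index):
        keep = [c for c in features.index.columns if c not in table.columns]
        table = pd.concat([features.index[keep].reset_index(drop=True), table], axis=1)
    else:
        table.insert(0, "subject_id", [f"scan{i}" for i in range(features.n_scans)])
        table.insert(1, "scan_time", 0.0)
    return table


def _age_stratified_folds(ages: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold assignment cycling through age-sorted scans (quantile balance)."""
    rng = np.random.default_rng(seed)
    order = np.argsort(ages, kind="mergesort")
    folds = np.empty(ages.size, dtype=int)
    assign = np.tile(np.arange(k), ages.size // k + 1)[: ages.size]
    # shuffle fold labels within consecutive blocks of k to decorrelate
    for start in range(0, ages.size, k):
        block = assign[start : start + k]
        rng.shuffle(block)
    folds[order] = assign
    return folds


@dataclass
class SelectionReport:
    table: pd.DataFrame  # workflow, correction, mae
    best_workflow: Workflow
    best_correction: str
    best_mae: float
    k: int


def select_workflow(hc_features: FeatureGrid, hc_ages, workflows, corrections,
                    k: int = 5, seed: int = 0,
                    stratify_by_age: bool = True) -> SelectionReport:
    """Cross-validated MAE of corrected predictions per (workflow, correction).

    The regressor and the bias correction are fitted on the train folds
    and evaluated on the held-out fold; the pair with the lowest mean
    absolute error wins. Ties break toward the workflow with fewer
    pipeline stages, then lexicographic name.
    """
    workflows = list(workflows)
    corrections = list(corrections)
    if not workflows:
        raise ValueError("empty workflow list")
    if k < 2:
        raise ValueError("need k >= 2 folds")
    ages = np.asarray(hc_ages, dtype=float)
    if stratify_by_age:
        folds = _age_stratified_folds(ages, k, seed)
    else:
        folds = np.random.default_rng(seed).permutation(ages.size) % k

    abs_err = {(i, c): [] for i in range(len(workflows)) for c in corrections}
    for i, wf in enumerate(workflows):
        for fold in range(k):
            test = folds == fold
            train = ~test
            model = train_brain_age(hc_features.take(np.flatnonzero(train)),
                                    ages[train], wf, seed=seed)
            pred_train = model.predict(hc_features.take(np.flatnonzero(train)))
            pred_test = model.predict(hc_features.take(np.flatnonzero(test)))
            for cname in corrections:
                corr = fit_bias_correction(pred_train, ages[train], cname)
                est = corr.corrected_prediction(pred_test, ages[test])
                abs_err[(i, cname)].extend(np.abs(est - ages[test]))

    rows = [
        {"workflow": workflows[i].name, "correction": cname,
         "mae": float(np.mean(errs)), "_i": i}
        for (i, cname), errs in abs_err.items()
    ]
    ranked = sorted(
        rows,
        key=lambda r: (r["mae"], workflows[r["_i"]].n_stages, r["workflow"], r["correction"]),
    )
    best = ranked[0]
    table = pd.DataFrame(rows).drop(columns="_i")
    return SelectionReport(
        table=table,
        best_workflow=workflows[best["_i"]],
        best_correction=best["correction"],
        best_mae=best["mae"],
        k=k,
    )


@dataclass
class ConsistencyReport:
    retest_ccc: float | None
    retest_n: int
    consistency_rho: float | None
    consistency_p: float | None
    consistency_n: int
    threshold: float


def longitudinal_consistency(bag_table: pd.DataFrame,
                             threshold: float = 1.5) -> ConsistencyReport:
    """Retest reliability and longitudinal consistency of brain age.

    Subjects with >= 2 scans contribute their first and last scans.
    Pairs with inter-scan interval < ``threshold`` years form the retest
    set (CCC of corrected BAG); pairs with interval >= threshold form the
    consistency set (Pearson correlation of the brain-age increase with
    the elapsed time). Statistics with no qualifying pairs are None.
    """
    t = bag_table.sort_values("scan_time")
    firsts = t.groupby("subject_id").first()
    lasts = t.groupby("subject_id").last()
    multi = t.groupby("subject_id").size() >= 2
    if multi.sum() < 3:
        raise ValueError("need at least 3 subjects with >= 2 scans")
    firsts = firsts[multi]
    lasts = lasts[multi]
    interval = (lasts.scan_time - firsts.scan_time).to_numpy(dtype=float)

    retest = interval < threshold
    cons = ~retest
    retest_ccc = None
    if retest.sum() >= 2:
        retest_ccc = concordance_ccc(
            firsts.bag_corrected.to_numpy()[retest],
            lasts.bag_corrected.to_numpy()[retest],
        )
    rho = p = None
    if cons.sum() >= 3:
        dba = (lasts.brain_age_corrected - firsts.brain_age_corrected).to_numpy()[cons]
        dt = interval[cons]
        if np.std(dt) > 0 and np.std(dba) > 0:
            rho, p = sps.pearsonr(dba, dt)
            rho, p = float(rho), float(p)
    return ConsistencyReport(
        retest_ccc=retest_ccc,
        retest_n=int(retest.sum()),
        consistency_rho=rho,
        consistency_p=p,
        consistency_n=int(cons.sum()),
        threshold=threshold,
    )
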