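import warnings

import numpy as np
import pytest

from bagpipe import brainage as ba
from bagpipe.simulate import SimConfig, default_grid, simulate_cohort, simulate_features

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap cohort for plumbing tests."""
    config = SimConfig(n_hc=20, n_pd=40)
    cohort, truth = simulate_cohort(config, seed=11)
    return config, cohort, truth


@pytest.fixture(scope="session")
def mid_cohort():
    """Mid-size cohort with feature grids and a trained brain-age model."""
    config = SimConfig(n_hc=150, n_pd=300, dropout_prob=0.08)
    cohort, truth = simulate_cohort(config, seed=21)
    grid = simulate_features(cohort, truth, default_grid(), seed=21)
    return config, cohort, truth, grid


@pytest.fixture(scope="session")
def hc_baseline(mid_cohort):
    """Baseline HC scans + ages from the mid cohort."""
    _, _, _, grid = mid_cohort
    idx = grid.index.reset_index()
    rows = (idx[idx.group == "HC"].sort_values("scan_time")
            .groupby("subject_id").head(1)["index"].to_numpy())
    hc = grid.take(rows)
    return hc, hc.index.age.to_numpy()


@pytest.fixture(scope="session")
def bag_table(mid_cohort, hc_baseline):
    """BAG table for every scan of the mid cohort (lasso workflow + Beheshti)."""
    _, _, _, grid = mid_cohort
    hc, ages = hc_baseline
    model = ba.train_brain_age(hc, ages, ba.Workflow.s0_r4_lr(), seed=0)
    correction = ba.fit_bias_correction(model.predict(hc), ages, "beheshti")
    table = ba.apply_bag(model, correction, grid)
    table["glabel"] = np.where(table.group == "HC", "HC", table.subtype)
    return model, correction, table
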