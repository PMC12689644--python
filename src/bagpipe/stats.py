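"""Statistical primitives shared across the pipeline.

These are deliberately written from their definitions (pair counting,
step-up rule, population moments, residual-on-residual correlation) so
that downstream modules do not depend on any particular library's
conventions for ties, degrees of freedom, or adjustment ordering.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "kendall_tau_b",
    "bh_adjust",
    "concordance_ccc",
    "partial_correlation",
]


def kendall_tau_b(x, y) -> float:
    """Kendall rank correlation with tie correction (tau-b).

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) where C/D are concordant /
    discordant pair counts, n0 = n(n-1)/2 and n1, n2 are the tied-pair
    counts in x and y respectively.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    prod = sx[iu] * sy[iu]
    concordant = np.sum(prod > 0)
    discordant = np.sum(prod < 0)
    ties_x = np.sum(sx[iu] == 0)
    ties_y = np.sum(sy[iu] == 0)
    n0 = n * (n - 1) // 2
    denom = np.sqrt(float(n0 - ties_x) * float(n0 - ties_y))
    if denom == 0:
        raise ValueError("tau-b undefined: a variable is constant")
    return float((concordant - discordant) / denom)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Returns adjusted values q_i = min_{j >= rank(i)} p_(j) * m / j,
    capped at 1, in the original input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-d")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def concordance_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    ccc = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    mx, my = x.mean(), y.mean()
    vx = np.mean((x - mx) ** 2)
    vy = np.mean((y - my) ** 2)
    cxy = np.mean((x - mx) * (y - my))
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("ccc undefined: both variables are constant and equal")
    return float(2.0 * cxy / denom)


def partial_correlation(x, y, covars=None, method: str = "residuals"):
    """Partial Pearson correlation of ``x`` and ``y`` given ``covars``.

    Parameters
    ----------
    x, y : array-like, shape (n,)
    covars : array-like, shape (n, k) or (n,), optional
        Covariates to partial out (an intercept is always included).
    method : {"residuals", "precision"}
        ``residuals`` correlates the OLS residuals of x and y on the
        covariates; ``precision`` uses the inverse correlation matrix of
        (x, y, covars). The two agree to numerical precision and the
        second route is kept as an independent cross-check.

    Returns
    -------
    (r, p) : partial correlation and two-sided p-value with
        df = n - 2 - k.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covars is None:
        z = np.empty((n, 0))
    else:
        z = np.asarray(covars, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
    k = z.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete cases, got {n}")

    if method == "residuals":
        design = np.column_stack([np.ones(n), z])
        bx, *_ = np.linalg.lstsq(design, x, rcond=None)
        by, *_ = np.linalg.lstsq(design, y, rcond=None)
        rx = x - design @ bx
        ry = y - design @ by
        sr = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
        if sr == 0:
            raise ValueError("partial correlation undefined: zero residual variance")
        r = float(np.sum(rx * ry) / sr)
    elif method == "precision":
        mat = np.column_stack([x, y, z])
        corr = np.corrcoef(mat, rowvar=False)
        prec = np.linalg.pinv(corr)
        r = float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))
    else:
        raise ValueError(f"unknown method {method!r}")

    r = max(-1.0, min(1.0, r))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p
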