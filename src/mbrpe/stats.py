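"""Behavioural effect-size statistics and the model-vs-experiment comparison.

A conditioning batch yields a performance index PI = (n+ - n-)/(n+ + n-),
converted to the fraction choosing the CS+, f = (PI + 1)/2.  The effect of an
intervention relative to its control is the binomial-scaled statistic

    Delta_f = (f_i - f_c) / sqrt[(1/N_fly) (f_i + f_c) (1 - (f_i + f_c)/2)],

whose denominator is the null s.d. of a difference of two binomial fractions
with N_fly samples each.  Model and experimental Delta_f vectors are compared
with an iteratively reweighted least-squares (bisquare) linear fit; the
reported correlation is the Pearson R of the weight-scaled vectors, with a
pairing-permutation p value and a case-resampling bootstrap CI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "DeltaFRecord",
    "performance_index",
    "pi_to_fraction",
    "delta_f",
    "weighted_robust_fit",
    "weighted_pearson",
    "permutation_pvalue",
    "bootstrap_ci",
    "compare_deltaf",
]

logger = logging.getLogger(__name__)

N_FLY_DEFAULT = 50
BISQUARE_TUNING = 4.685
IRLS_MAX_ITER = 50
IRLS_TOL = 1e-8


@dataclass
class DeltaFRecord:
    """One intervention-vs-control comparison."""

    study_id: str
    us_valence: str
    target: str
    kind: str
    schedule: str
    f_i: float
    f_c: float
    n_fly: int = N_FLY_DEFAULT
    delta_f: Optional[float] = None
    weight: Optional[float] = None

    def __post_init__(self):
        if not (0.0 <= self.f_i <= 1.0 and 0.0 <= self.f_c <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.delta_f is None:
            self.delta_f = delta_f(self.f_i, self.f_c, self.n_fly)


def performance_index(n_plus: int, n_minus: int) -> float:
    """PI = (n+ - n-) / (n+ + n-), in [-1, 1]."""
    total = n_plus + n_minus
    if total <= 0:
        raise ValueError("n_plus + n_minus must be > 0")
    return (n_plus - n_minus) / total


def pi_to_fraction(pi: float) -> float:
    """Fraction choosing the CS+: f = (PI + 1) / 2."""
    if not -1.0 <= pi <= 1.0:
        raise ValueError("PI must lie in [-1, 1]")
    return (pi + 1.0) / 2.0


def delta_f(f_i: float, f_c: float, n_fly: int = N_FLY_DEFAULT) -> float:
    """Binomial-scaled effect size of an intervention on the CS+ fraction.

    Undefined (NaN) when f_i = f_c = 0 or f_i = f_c = 1, where the null
    variance vanishes.
    """
    if not (0.0 <= f_i <= 1.0 and 0.0 <= f_c <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    if n_fly <= 0:
        raise ValueError("n_fly must be > 0")
    s = f_i + f_c
    var = s * (1.0 - 0.5 * s) / n_fly
    if var <= 0:
        return float("nan")
    return (f_i - f_c) / np.sqrt(var)


def weighted_robust_fit(x, y):
    """IRLS linear fit of y on x with Tukey bisquare weights.

    Uses the standard tuning constant 4.685 with a median-absolute-deviation
    scale estimate.  Returns ``(slope, intercept, weights, converged)``; the
    weights are the converged per-point bisquare weights in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a robust fit")
    import statsmodels.api as sm

    exog = sm.add_constant(x)
    # An (almost) exact linear relationship drives the robust scale to zero,
    # where IRLS is undefined; every point then carries full weight.
    ols = np.linalg.lstsq(exog, y, rcond=None)[0]
    resid = y - exog @ ols
    if np.median(np.abs(resid - np.median(resid))) < 1e-10 * max(
            1.0, float(np.max(np.abs(y)))):
        return float(ols[1]), float(ols[0]), np.ones_like(x), True
    model = sm.RLM(y, exog, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_TUNING))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=IRLS_MAX_ITER, tol=IRLS_TOL,
                        scale_est="mad", conv="coefs")
    converged = bool(getattr(res, "converged", True))
    if not converged:
        logger.warning("IRLS did not converge in %d iterations; "
                       "returning last iterate", IRLS_MAX_ITER)
    intercept, slope = res.params
    try:
        weights = np.asarray(res.weights, dtype=float)
    except AttributeError:  # scale collapsed to 0 on the final iteration
        weights = np.ones_like(x)
    return float(slope), float(intercept), weights, converged


def weighted_pearson(x, y, w) -> float:
    """Pearson correlation of the elementwise weight-scaled vectors.

    Computes corr(w*x, w*y) literally — the covariance of the scaled vectors
    over the product of their standard deviations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.shape == y.shape == w.shape):
        raise ValueError("x, y and w must have equal length")
    wx, wy = w * x, w * y
    sx, sy = wx.std(), wy.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in weighted data")
    return float(np.cov(wx, wy, bias=True)[0, 1] / (sx * sy))


def permutation_pvalue(x, y, w, n_perm: int = 10000,
                       rng: Optional[np.random.Generator] = None) -> float:
    """Two-sided permutation p value for the weighted correlation.

    The pairing of the weighted y values against the weighted x values is
    reshuffled; p = (1 + #{|R_perm| >= |R_obs|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    wx, wy = w * x, w * y
    r_obs = abs(np.corrcoef(wx, wy)[0, 1])
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(wy.size)
        if abs(np.corrcoef(wx, wy[perm])[0, 1]) >= r_obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def bootstrap_ci(x, y, n_boot: int = 1000, level: float = 0.95,
                 rng: Optional[np.random.Generator] = None):
    """Percentile bootstrap CI for the weighted correlation R.

    Cases are resampled with replacement and the robust-fit weights are
    re-estimated on every resample.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        try:
            _, _, wb, _ = weighted_robust_fit(xb, yb)
            rs.append(weighted_pearson(xb, yb, wb))
        except (ValueError, np.linalg.LinAlgError):
            continue  # degenerate resample (e.g. all-identical x)
    rs = np.sort(rs)
    alpha = (1.0 - level) / 2.0
    lo = float(np.quantile(rs, alpha))
    hi = float(np.quantile(rs, 1.0 - alpha))
    return lo, hi


def compare_deltaf(model_deltaf, exp_deltaf, n_perm: int = 10000,
                   n_boot: int = 1000,
                   rng: Optional[np.random.Generator] = None) -> dict:
    """Full comparison pipeline between model and experimental Delta_f.

    Non-finite pairs (degenerate Delta_f) are dropped with a logged warning.
    Returns a dict with the robust-fit slope/intercept, per-point weights,
    weighted Pearson R, permutation p and bootstrap CI.
    """
    x = np.asarray(model_deltaf, dtype=float)
    y = np.asarray(exp_deltaf, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if not keep.all():
        logger.warning("dropping %d degenerate Delta_f pairs", (~keep).sum())
    x, y = x[keep], y[keep]
    if rng is None:
        rng = np.random.default_rng()
    slope, intercept, w, converged = weighted_robust_fit(x, y)
    r = weighted_pearson(x, y, w)
    p = permutation_pvalue(x, y, w, n_perm=n_perm, rng=rng)
    lo, hi = bootstrap_ci(x, y, n_boot=n_boot, rng=rng)
    return {
        "n": int(x.size),
        "slope": slope,
        "intercept": intercept,
        "weights": w.tolist(),
        "R": r,
        "p_permutation": p,
        "ci_low": lo,
        "ci_high": hi,
        "irls_converged": converged,
    }
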