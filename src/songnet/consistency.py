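"""Variable inter-correlations, size correction, and repeatability.

Repeatability (intraclass correlation) is the between-individual share of
variance, ``R = V_between / (V_between + V_within)``, from a Gaussian
random-intercept mixed model fitted by REML with male age as a fixed
covariate ("adjusted" repeatability).  Confidence intervals come from a
fully parametric bootstrap: responses are re-simulated from the fitted
variance components and fixed effects, the model is refitted, and percentile
bounds are taken over the bootstrap repeatabilities.

The REML fit is computed by profiling the likelihood over the variance ratio
gamma = V_between / V_within, which reduces the random-intercept model to a
one-dimensional optimisation with closed-form GLS pieces; this makes the
thousands of refits required by the bootstrap essentially free.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "RepeatabilityResult",
    "correlation_matrix",
    "residualize",
    "repeatability",
]


def correlation_matrix(
    metrics_table: pd.DataFrame, n_tests: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with Bonferroni-adjusted P values.

    Returns ``(rho, p_adjusted)`` square frames over the numeric columns.
    Adjusted P = min(1, P * n_tests); by default ``n_tests`` is the number of
    pairs.  Zero-variance columns yield NaN for all their pairs.
    """
    df = metrics_table.select_dtypes(include=[np.number])
    if len(df) < 3:
        raise ValueError("need at least 3 recordings")
    cols = list(df.columns)
    if n_tests is None:
        n_tests = len(cols) * (len(cols) - 1) // 2
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    padj = pd.DataFrame(np.nan, index=cols, columns=cols)
    for a, b in combinations(cols, 2):
        x, y = df[a].to_numpy(float), df[b].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            r = p = float("nan")
            if ok.sum() >= 3:
                warnings.warn(f"correlation_matrix: zero-variance column in ({a},{b})")
        else:
            r, p = stats.pearsonr(x[ok], y[ok])
            p = min(1.0, p * n_tests)
        rho.loc[a, b] = rho.loc[b, a] = r
        padj.loc[a, b] = padj.loc[b, a] = p
    return rho, padj


def residualize(
    values: np.ndarray, repertoire_sizes: np.ndarray, n_syllables: np.ndarray
) -> np.ndarray:
    """Residuals of a network variable on repertoire size and syllable count.

    Ordinary least squares with intercept; the residuals are by construction
    mean-zero and uncorrelated with both covariates, and are used downstream
    as the size-independent network variables.  Collinear covariates are
    handled by the minimum-norm solution with a warning.
    """
    y = np.asarray(values, dtype=float)
    X = np.column_stack(
        [np.ones_like(y), np.asarray(repertoire_sizes, float), np.asarray(n_syllables, float)]
    )
    if len(y) < 4:
        raise ValueError("need at least 4 observations")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn("residualize: collinear covariates; minimum-norm fit used")
    return y - X @ beta


@dataclass(frozen=True)
class RepeatabilityResult:
    """Variance components and bootstrap CI for one variable at one scale."""

    variable_name: str
    time_scale: str
    v_between: float
    v_within: float
    r: float
    ci_low: float
    ci_high: float
    n_individuals: int
    n_boot: int
    significant: bool


_LOG_GAMMA_BOUNDS = (-16.0, 16.0)


def _reml_random_intercept(
    y: np.ndarray, X: np.ndarray, codes: np.ndarray, n_groups: int
) -> tuple[float, float, np.ndarray]:
    """REML fit of y = X b + u[group] + e; returns (v_between, v_within, beta).

    Profiles the REML criterion over gamma = v_between/v_within.  For the
    single random-intercept model, V = v_within * (I + gamma Z Z'), whose
    inverse and determinant are closed-form per group, so each criterion
    evaluation is O(n).
    """
    n, p = X.shape
    m = np.bincount(codes, minlength=n_groups).astype(float)
    ysum = np.zeros(n_groups)
    np.add.at(ysum, codes, y)
    Xsum = np.zeros((n_groups, p))
    np.add.at(Xsum, codes, X)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def pieces(log_gamma: float):
        g = np.exp(log_gamma)
        a = g / (1.0 + m * g)  # shrinkage per group
        XtViX = XtX - (Xsum * a[:, None]).T @ Xsum
        XtViy = Xty - Xsum.T @ (a * ysum)
        ytViy = yty - float(a @ ysum**2)
        beta = np.linalg.solve(XtViX, XtViy)
        rss = max(ytViy - float(beta @ XtViy), 1e-300)
        s2 = rss / (n - p)
        logdet_v = float(np.sum(np.log1p(m * g)))
        sign, logdet_x = np.linalg.slogdet(XtViX)
        crit = (n - p) * np.log(s2) + logdet_v + logdet_x
        return crit, beta, s2, g

    res = minimize_scalar(
        lambda t: pieces(t)[0], bounds=_LOG_GAMMA_BOUNDS, method="bounded",
        options={"xatol": 1e-8},
    )
    # the optimiser can miss a boundary optimum; compare with the edges
    best_t = res.x
    best = pieces(best_t)[0]
    for t_edge in _LOG_GAMMA_BOUNDS:
        c_edge = pieces(t_edge)[0]
        if c_edge < best:
            best, best_t = c_edge, t_edge
    _, beta, s2, g = pieces(best_t)
    if best_t <= _LOG_GAMMA_BOUNDS[0] + 1e-9:
        g = 0.0  # boundary: no detectable between-individual variance
    return g * s2, s2, beta


def repeatability(
    values: np.ndarray,
    individual_ids: np.ndarray,
    ages: np.ndarray | None = None,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    variable_name: str = "",
    time_scale: str = "",
    ci_method: str = "percentile",
) -> RepeatabilityResult:
    """Adjusted repeatability of one variable from paired recordings.

    Requires the balanced design used for consistency estimation: every
    individual contributes exactly two records.  ``ages`` (one value per
    record) enters as a fixed covariate when given.  ``ci_method`` is
    ``"percentile"`` (default) or ``"basic"``.
    """
    rng = np.random.default_rng() if rng is None else rng
    y = np.asarray(values, dtype=float)
    ids = np.asarray(individual_ids)
    uniq, codes = np.unique(ids, return_inverse=True)
    counts = np.bincount(codes)
    if len(uniq) < 2:
        raise ValueError("need at least 2 individuals")
    if not np.all(counts == 2):
        raise ValueError("balanced design required: exactly 2 records per individual")

    X = np.ones((len(y), 1))
    if ages is not None:
        age = np.asarray(ages, dtype=float)
        if np.std(age) > 0:
            X = np.column_stack([X, age])

    vb, vw, beta = _reml_random_intercept(y, X, codes, len(uniq))
    r = vb / (vb + vw) if (vb + vw) > 0 else 0.0

    sb, sw = np.sqrt(vb), np.sqrt(vw)
    boots = np.empty(n_boot)
    n_failed = 0
    for b in range(n_boot):
        u = rng.normal(0.0, sb, size=len(uniq))
        e = rng.normal(0.0, sw, size=len(y))
        yb = X @ beta + u[codes] + e
        try:
            vb_b, vw_b, _ = _reml_random_intercept(yb, X, codes, len(uniq))
            boots[b] = vb_b / (vb_b + vw_b) if (vb_b + vw_b) > 0 else 0.0
        except np.linalg.LinAlgError:
            boots[b] = np.nan
            n_failed += 1
    if n_failed:
        logger.warning("repeatability bootstrap: %d replicates dropped", n_failed)
    ok = boots[np.isfinite(boots)]
    if ok.size:
        lo, hi = np.percentile(ok, [2.5, 97.5])
        if ci_method == "basic":
            lo, hi = 2 * r - hi, 2 * r - lo
        lo, hi = float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))
    else:
        lo = hi = float("nan")
    return RepeatabilityResult(
        variable_name=variable_name,
        time_scale=time_scale,
        v_between=float(vb),
        v_within=float(vw),
        r=float(r),
        ci_low=lo,
        ci_high=hi,
        n_individuals=len(uniq),
        n_boot=n_boot,
        significant=bool(np.isfinite(lo) and lo > 1e-6),
    )
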