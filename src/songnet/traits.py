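"""Linear and binomial models linking network variables to male phenotype.

Quality models: one Gaussian LM per (size-corrected) network variable with
body condition, age and arrival date as continuous fixed effects and year as
a discrete fixed effect.  Fitness models: one binomial GLM (logit link) per
fitness component (pairing success, survival to the next year) with both
network variables entered together alongside the quality covariates and
year.  Every term is tested by a likelihood-ratio test of the model with vs
without it; Bonferroni correction spans the number of responses examined.

By default only network variables whose repeatability was significant at at
least one time scale are treated as candidate signals; a variable that is
not repeatable cannot function as an individual signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .consistency import RepeatabilityResult

__all__ = [
    "TermResult",
    "ModelReport",
    "fit_quality_model",
    "fit_fitness_model",
    "paired_within_individual_test",
    "select_repeatable_responses",
    "model_report_frame",
]


@dataclass(frozen=True)
class TermResult:
    estimate: float          # coefficient (NaN for multi-df factor terms)
    stat: float              # t (Gaussian) or z (binomial) of the coefficient
    lrt_chi2: float
    df: int
    p_raw: float
    p_bonferroni: float


@dataclass(frozen=True)
class ModelReport:
    response_name: str
    family: str              # "gaussian" or "binomial"
    n: int
    r2: float                # R^2 (Gaussian) or McFadden pseudo-R^2 (binomial)
    terms: Mapping[str, TermResult]
    separation: bool = False


def _term_columns(df: pd.DataFrame, terms: Sequence[str]) -> dict[str, pd.DataFrame]:
    """Expand each term into its design columns; 'year' becomes dummies."""
    out: dict[str, pd.DataFrame] = {}
    for term in terms:
        if term == "year":
            dummies = pd.get_dummies(df["year"].astype("category"), prefix="year",
                                     drop_first=True, dtype=float)
            out[term] = dummies
        else:
            out[term] = df[[term]].astype(float)
    return out


def _assemble(blocks: dict[str, pd.DataFrame], skip: str | None = None) -> np.ndarray:
    cols = [b.to_numpy() for t, b in blocks.items() if t != skip]
    X = np.hstack([np.ones((len(next(iter(blocks.values()))), 1))] + cols)
    return X


def _lrt_report(
    y, blocks, family, bonferroni_m
) -> tuple[dict[str, TermResult], float, bool]:
    """Fit full and per-term reduced models; return term table, r2, separation."""

    def fit(X):
        if family == "gaussian":
            return sm.OLS(y, X).fit()
        return sm.GLM(y, X, family=sm.families.Binomial()).fit()

    X_full = _assemble(blocks)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = fit(X_full)
    separation = False
    if family == "binomial":
        mu = np.asarray(full.fittedvalues)
        if np.all((mu < 1e-8) | (mu > 1 - 1e-8)):
            separation = True

    terms: dict[str, TermResult] = {}
    col = 1  # skip intercept
    for term, block in blocks.items():
        k = block.shape[1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            red = fit(_assemble(blocks, skip=term))
        chi2 = max(0.0, 2.0 * (full.llf - red.llf))
        p = float(stats.chi2.sf(chi2, k))
        est = float(full.params[col]) if k == 1 else float("nan")
        tval = float(full.params[col] / full.bse[col]) if k == 1 else float("nan")
        terms[term] = TermResult(
            estimate=est, stat=tval, lrt_chi2=float(chi2), df=k, p_raw=p,
            p_bonferroni=min(1.0, p * bonferroni_m),
        )
        col += k

    if family == "gaussian":
        r2 = float(full.rsquared)
    else:
        r2 = float(1.0 - full.deviance / full.null_deviance)
    return terms, r2, separation


def fit_quality_model(
    response: pd.Series | np.ndarray,
    traits: pd.DataFrame,
    response_name: str = "network_variable",
    covariates: Sequence[str] = ("condition", "age", "arrival_std"),
    bonferroni_m: int = 2,
) -> ModelReport:
    """Gaussian LM of one network variable on quality traits and year.

    ``traits`` must align row-wise with ``response`` and contain the
    covariate columns plus ``year``.  Rows with missing values are dropped.
    ``bonferroni_m`` is the number of network variables examined in the
    family of tests (default 2: average degree and small-worldness).
    """
    df = traits.copy()
    df["_y"] = np.asarray(response, dtype=float)
    df = df.dropna(subset=["_y", "year", *covariates])
    if len(df) < len(covariates) + 3:
        raise ValueError("too few complete cases")
    terms = list(covariates)
    if df["year"].nunique() > 1:
        terms.append("year")
    else:
        warnings.warn("fit_quality_model: single year present; year term dropped")
    blocks = _term_columns(df, terms)
    y = df["_y"].to_numpy()
    table, r2, _ = _lrt_report(y, blocks, "gaussian", bonferroni_m)
    return ModelReport(response_name, "gaussian", len(df), r2, table)


def fit_fitness_model(
    fitness: pd.Series | np.ndarray,
    network_vars: pd.DataFrame,
    traits: pd.DataFrame,
    response_name: str = "fitness",
    covariates: Sequence[str] = ("age", "condition", "arrival_std"),
    bonferroni_m: int = 2,
) -> ModelReport:
    """Binomial GLM of a binary fitness component on network variables.

    Both network variables enter together, with the quality covariates and
    year.  Complete separation is flagged on the report (statistics are
    still returned but should not be interpreted).
    """
    y = np.asarray(fitness, dtype=float)
    if not np.isin(y[np.isfinite(y)], [0, 1]).all():
        raise ValueError("fitness response must be binary 0/1")
    df = pd.concat(
        [traits.reset_index(drop=True), network_vars.reset_index(drop=True)], axis=1
    )
    df = df.loc[:, ~df.columns.duplicated()]  # network vars may repeat traits cols
    df["_y"] = y
    netcols = list(network_vars.columns)
    df = df.dropna(subset=["_y", "year", *covariates, *netcols])
    yv = df["_y"].to_numpy()
    if yv.min() == yv.max():
        raise ValueError("degenerate response: all outcomes identical")
    terms = netcols + list(covariates)
    if df["year"].nunique() > 1:
        terms.append("year")
    else:
        warnings.warn("fit_fitness_model: single year present; year term dropped")
    blocks = _term_columns(df, terms)
    table, r2, separation = _lrt_report(yv, blocks, "binomial", bonferroni_m)
    if separation:
        warnings.warn("fit_fitness_model: complete separation detected")
    return ModelReport(response_name, "binomial", len(df), r2, table, separation)


def paired_within_individual_test(
    values_year1: Sequence[float],
    values_year2: Sequence[float],
    tail: str = "two-sided",
) -> tuple[float, int, float]:
    """Paired t-test of within-individual change (year2 - year1).

    Returns ``(t, df, p)`` with ``df = n - 1``.  ``tail`` is "two-sided",
    "less" (change < 0) or "greater".  Identical pairs give t = 0, p = 1;
    constant nonzero differences have zero SD and yield NaN statistics.
    """
    x1 = np.asarray(values_year1, dtype=float)
    x2 = np.asarray(values_year2, dtype=float)
    if x1.shape != x2.shape or x1.size < 2:
        raise ValueError("need >= 2 matched pairs")
    diff = x2 - x1
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0:
        if diff.mean() == 0:
            return 0.0, n - 1, 1.0
        return float("nan"), n - 1, float("nan")
    t = diff.mean() / (sd / np.sqrt(n))
    if tail == "two-sided":
        p = 2 * stats.t.sf(abs(t), n - 1)
    elif tail == "less":
        p = stats.t.cdf(t, n - 1)
    elif tail == "greater":
        p = stats.t.sf(t, n - 1)
    else:
        raise ValueError(f"unknown tail: {tail!r}")
    return float(t), n - 1, float(p)


def select_repeatable_responses(
    results: Iterable[RepeatabilityResult],
) -> list[str]:
    """Variables significantly repeatable at >= 1 time scale (default filter)."""
    ok = sorted({r.variable_name for r in results if r.significant})
    return ok


def model_report_frame(reports: Iterable[ModelReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for term, tr in rep.terms.items():
            rows.append(
                {
                    "response": rep.response_name,
                    "family": rep.family,
                    "n": rep.n,
                    "r2": rep.r2,
                    "term": term,
                    "estimate": tr.estimate,
                    "stat": tr.stat,
                    "lrt_chi2": tr.lrt_chi2,
                    "df": tr.df,
                    "p_raw": tr.p_raw,
                    "p_bonferroni": tr.p_bonferroni,
                }
            )
    return pd.DataFrame(rows)
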