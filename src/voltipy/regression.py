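"""Which generation drives next spring's abundance?

If the whole first (early-summer) generation reproduced, spring abundance
should track the first generation of the previous year; if the autumn
(second) generation is the overwintering stock, spring should track it
instead. The module aligns per-year generation AUC indices into a lag-1
table and fits ordinary least squares models of next-spring abundance:

* the multiple model  spring(t+1) ~ gen1(t) + gen2(t)
* the two simple models with each generation alone
* the within-year pairs  gen1(t) ~ spring(t)  and  gen2(t) ~ gen1(t)

Each fit reports coefficients, standard errors, per-fit R² and p-values
(t-tests on slopes for the simple fits, the F-test for the multiple fit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import InsufficientDataError

logger = logging.getLogger(__name__)

MIN_YEAR_PAIRS = 4
CONDITION_NUMBER_CAP = 1e8


def build_generation_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Lag-1 table: spring/gen1/gen2 AUC of year t plus spring AUC of year t+1.

    Rows exist only for consecutive-year pairs where all four values are
    defined; dropped years are logged. Needs at least 4 pairs.
    """
    wide = (summaries.pivot_table(index="year", columns="generation",
                                  values="auc_index", aggfunc="first")
            .reindex(columns=["spring", "gen1", "gen2"]))
    wide["spring_next"] = wide["spring"].reindex(wide.index + 1).to_numpy()
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if dropped:
        logger.info("generation table: dropped year pairs starting %s", dropped)
    if len(complete) < MIN_YEAR_PAIRS:
        raise InsufficientDataError(
            f"need >= {MIN_YEAR_PAIRS} consecutive-year pairs, got {len(complete)}")
    return complete.reset_index()


@dataclass
class FitResult:
    """One OLS fit: slope(s), uncertainty, fit quality."""

    name: str
    predictors: list[str]
    response: str
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    p_value: float          # overall: slope t-test (simple) / F-test (multiple)
    n: int
    condition_number: float
    degenerate: bool = False

    def summary_row(self) -> dict:
        return {"fit": self.name, "response": self.response,
                "predictors": "+".join(self.predictors),
                "r_squared": self.r_squared, "p_value": self.p_value, "n": self.n}


@dataclass
class RegressionResultSet:
    """All fits of the spring-coupling analysis, keyed by name."""

    fits: dict[str, FitResult] = field(default_factory=dict)

    def __getitem__(self, key: str) -> FitResult:
        return self.fits[key]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([f.summary_row() for f in self.fits.values()])

    def to_dict(self) -> dict:
        return {name: {"predictors": f.predictors, "response": f.response,
                       "params": f.params, "bse": f.bse, "pvalues": f.pvalues,
                       "r_squared": f.r_squared, "p_value": f.p_value, "n": f.n}
                for name, f in self.fits.items()}


def _ols(name: str, table: pd.DataFrame, response: str,
         predictors: list[str]) -> FitResult:
    y = table[response].to_numpy(float)
    X = np.column_stack([np.ones(len(table)), table[predictors].to_numpy(float)])
    degenerate = any(np.isclose(table[p].std(ddof=0), 0.0) for p in predictors)
    if degenerate:
        logger.warning("fit %s: predictor with zero variance", name)
    res = sm.OLS(y, X).fit()
    names = ["const"] + predictors
    overall_p = float(res.f_pvalue) if len(predictors) > 1 else float(res.pvalues[1])
    cond = float(np.linalg.cond(X))
    if cond > CONDITION_NUMBER_CAP:
        logger.warning("fit %s: condition number %.3g above cap", name, cond)
    return FitResult(
        name=name, predictors=predictors, response=response,
        params=dict(zip(names, map(float, res.params))),
        bse=dict(zip(names, map(float, res.bse))),
        pvalues=dict(zip(names, map(float, res.pvalues))),
        r_squared=float(res.rsquared), p_value=overall_p,
        n=int(res.nobs), condition_number=cond, degenerate=degenerate)


def fit_spring_models(table: pd.DataFrame) -> RegressionResultSet:
    """Fit the multiple, simple and within-year OLS models on a lag-1 table."""
    out = RegressionResultSet()
    out.fits["multiple"] = _ols("multiple", table, "spring_next", ["gen1", "gen2"])
    out.fits["simple_gen1"] = _ols("simple_gen1", table, "spring_next", ["gen1"])
    out.fits["simple_gen2"] = _ols("simple_gen2", table, "spring_next", ["gen2"])
    out.fits["within_spring_gen1"] = _ols("within_spring_gen1", table, "gen1", ["spring"])
    out.fits["within_gen1_gen2"] = _ols("within_gen1_gen2", table, "gen2", ["gen1"])
    return out
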