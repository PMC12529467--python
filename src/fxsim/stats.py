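"""Statistical attribution of Fx-zone effects on postfire regeneration.

Responses are log10(density + 1)-transformed seedling densities. A two-way
ANOVA (amount x configuration, excluding the reference scenario) attributes
variance across climates pooled; per-climate ordinary least squares with Fx
scenario (amount + configuration) as predictor quantifies effects within
each climate and period. Interpretation relies on F / t magnitudes and
adjusted R^2 rather than p-value thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


def transform_density(x):
    """log10(x + 1) transform of a seedling density (scalar or array)."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("densities must be non-negative")
    out = np.log10(arr + 1.0)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


@dataclass
class AnovaResult:
    """Two-way ANOVA decomposition for one species x period response."""

    response: str
    table: pd.DataFrame  # term, sum_sq, df, F
    adj_r2: float
    n: int
    f_values: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.f_values = {
            term: float(row["F"]) for term, row in self.table.iterrows() if term != "Residual"
        }


@dataclass
class RegressionResult:
    """OLS of transformed regeneration on Fx amount + configuration."""

    response: str
    params: pd.Series
    tvalues: pd.Series
    adj_r2: float
    n: int
    direction: str = field(init=False)  # sign of the Fx-amount effect

    def __post_init__(self) -> None:
        coef = float(self.params.get("amount", 0.0))
        self.direction = "increase" if coef > 0 else ("decrease" if coef < 0 else "flat")


def _prepare(table: pd.DataFrame, response: str = "mean_density") -> pd.DataFrame:
    df = table.copy()
    df["y"] = transform_density(df[response].to_numpy())
    return df


def two_way_anova(
    table: pd.DataFrame,
    response_label: str = "",
    *,
    block_climate: bool = False,
) -> AnovaResult:
    """Two-way ANOVA of transformed density on amount x configuration.

    The input is a tidy table of Fx-scenario runs only (no reference rows;
    raise otherwise) with ``amount``, ``configuration`` and ``mean_density``
    columns. Type II sums of squares are used (identical to Type I/III on
    balanced designs). Climates are pooled by default; ``block_climate``
    adds climate as an additive blocking factor.
    """
    if (table["amount"] <= 0).any():
        raise ValueError("ANOVA table must exclude the reference scenario (amount 0)")
    for col in ("amount", "configuration"):
        if table[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs at least 2 levels")
    df = _prepare(table)
    formula = "y ~ C(amount) * C(configuration)"
    if block_climate:
        formula += " + C(climate)"
    fit = smf.ols(formula, data=df).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        aov = anova_lm(fit, typ=2)
    aov = aov.rename(
        index=lambda s: s.replace("C(amount)", "amount").replace("C(configuration)", "configuration").replace(":", " x ").replace("C(climate)", "climate")
    )
    return AnovaResult(
        response=response_label,
        table=aov,
        adj_r2=float(fit.rsquared_adj),
        n=int(fit.nobs),
    )


def scenario_regression(
    table: pd.DataFrame,
    response_label: str = "",
    *,
    categorical_amount: bool = False,
) -> RegressionResult:
    """OLS of transformed density on Fx amount (ordinal) + configuration.

    Reference rows (amount 0) are included and coded dispersed = 0. Amount
    is numeric 0 / 0.1 / 0.3 / 0.5 by default; ``categorical_amount`` swaps
    in factor coding. Aliased terms (e.g. a single-level configuration) are
    dropped automatically by the pseudo-inverse fit and reported with t = 0.
    """
    df = _prepare(table)
    df["dispersed"] = (df["configuration"] == "dispersed").astype(float)
    if categorical_amount:
        X = pd.get_dummies(df[["dispersed"]].assign(amount=df["amount"].astype(str)), columns=["amount"], drop_first=True, dtype=float)
    else:
        X = df[["amount", "dispersed"]].astype(float)
    X = sm.add_constant(X, has_constant="add")
    if float(np.ptp(df["y"].to_numpy())) == 0.0:
        # Constant response: nothing to explain; avoid 0/0 t statistics.
        params = pd.Series(0.0, index=X.columns)
        params["const"] = float(df["y"].iloc[0])
        return RegressionResult(
            response=response_label,
            params=params,
            tvalues=pd.Series(0.0, index=X.columns),
            adj_r2=0.0,
            n=len(df),
        )
    fit = sm.OLS(df["y"], X).fit()
    return RegressionResult(
        response=response_label,
        params=fit.params,
        tvalues=fit.tvalues.fillna(0.0),
        adj_r2=float(fit.rsquared_adj),
        n=int(fit.nobs),
    )


def anova_summary_frame(results: dict[str, AnovaResult]) -> pd.DataFrame:
    """Tidy frame (response, term, F, df, adj_R2) across ANOVA results."""
    rows = []
    for key, res in results.items():
        for term, f in res.f_values.items():
            rows.append(
                {
                    "response": key,
                    "term": term,
                    "F": f,
                    "df": float(res.table.loc[term, "df"]),
                    "adj_r2": res.adj_r2,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def regression_summary_frame(results: dict[str, RegressionResult]) -> pd.DataFrame:
    """Tidy frame (response, coefficient, t, adj_R2, direction)."""
    rows = []
    for key, res in results.items():
        for name, coef in res.params.items():
            rows.append(
                {
                    "response": key,
                    "coef": name,
                    "estimate": float(coef),
                    "t": float(res.tvalues.get(name, 0.0)),
                    "adj_r2": res.adj_r2,
                    "direction": res.direction,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)
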