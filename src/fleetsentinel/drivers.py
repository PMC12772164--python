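"""Driver attribution: how much of the fleet's movement is ecology vs economics.

Fleet indicator anomalies (Y centroid, distance to shore) are regressed on
five standardized candidate drivers — the same-axis habitat shift, SSTa,
fuel price, weather-alert area, and ex-vessel price per pound — with
ordinary least squares on z-scored variables, so coefficients are
standardized effect sizes (beta) directly comparable across drivers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class RegressionResult:
    response: str
    beta: dict[str, float]
    p_value: dict[str, float]
    n_obs: int
    r_squared: float
    ranking: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "response": self.response,
            "predictor": list(self.beta),
            "beta": list(self.beta.values()),
            "p_value": [self.p_value[k] for k in self.beta],
            "n_obs": self.n_obs,
            "r_squared": self.r_squared,
        })


def standardize(series: pd.Series) -> pd.Series:
    """z-score over complete cases (sample sd, n-1); errors on zero variance."""
    s = series.dropna()
    if len(s) < 3:
        raise ValueError(f"series '{series.name}': need >= 3 non-missing values")
    sd = s.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"series '{series.name}': zero variance, cannot standardize")
    out = (series - s.mean()) / sd
    out.name = series.name
    return out


def interpolate_gaps(series: pd.Series) -> pd.Series:
    """Linearly fill interior gaps; leading/trailing gaps stay missing."""
    if series.dropna().empty:
        raise ValueError("all-missing series cannot be interpolated")
    if len(series.dropna()) < 2:
        raise ValueError("need >= 2 anchor points to interpolate")
    return series.interpolate(method="linear", limit_area="inside")


def fit_driver_model(
    response: pd.Series,
    predictors: dict[str, pd.Series],
    robust: bool = False,
    hac_maxlags: int = 30,
) -> RegressionResult:
    """OLS of the standardized response on standardized predictors.

    Complete-case join across all series.  ``robust=True`` switches to
    Newey-West (HAC) standard errors for autocorrelation-aware p-values;
    the default reports plain OLS p-values.
    """
    df = pd.concat({"response": response, **predictors}, axis=1).dropna()
    if len(df) < len(predictors) + 2:
        raise ValueError("not enough complete-case observations for the model")
    z = df.apply(standardize)
    X = z.drop(columns="response")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = corr.stack().sort_values(ascending=False).head(3)
        raise ValueError(f"rank-deficient design; most collinear pairs: {pairs.index.tolist()}")
    model = sm.OLS(z["response"], sm.add_constant(X))
    if robust:
        fit = model.fit(cov_type="HAC", cov_kwds={"maxlags": hac_maxlags})
    else:
        fit = model.fit()
    beta = fit.params.drop("const").to_dict()
    pvals = fit.pvalues.drop("const").to_dict()
    ranking = sorted(beta, key=lambda k: abs(beta[k]), reverse=True)
    return RegressionResult(
        response=str(response.name or "response"),
        beta=beta,
        p_value=pvals,
        n_obs=int(fit.nobs),
        r_squared=float(fit.rsquared),
        ranking=ranking,
    )
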