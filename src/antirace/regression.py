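"""Downstream statistics: OLS of fitted parameters against disease stage and
clinical scores, and a single-predictor piecewise-linear (hinge) regression
for locating breakpoints in a parameter's decline.

The hinge regression is a pared-down MARS: a linear term plus up to
``max_terms`` hinge basis functions max(0, x - knot) with knots chosen from
observed-x quantiles by greedy forward selection, then the model size is
picked by generalized cross-validation (GCV).  One predictor and a handful
of hinges is all that is needed to ask *where* a parameter starts to
decline across disease stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

PARAM_COLUMNS = ("v_pre", "v_inhib", "v_exec", "a_mean", "t", "t_exec")


@dataclass
class OlsResult:
    """Slim view of an ordinary-least-squares fit."""

    coefficients: pd.Series
    pvalues: pd.Series
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: float
    df_resid: float
    aic: float
    bic: float
    n_obs: int


def ols_fit(design: pd.DataFrame, response) -> OlsResult:
    """OLS of ``response`` on the columns of ``design`` (intercept added).

    Rows with missing values are dropped listwise.  A rank-deficient design
    raises with the offending shape rather than returning silent garbage.
    """
    X = pd.DataFrame(design).astype(float)
    y = pd.Series(np.asarray(response, dtype=float), index=X.index, name="y")
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X.loc[keep], y.loc[keep]
    if len(X) < X.shape[1] + 2:
        raise ValueError(f"too few rows ({len(X)}) for {X.shape[1]} predictors")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient ({Xc.shape[1]} columns, "
            f"rank {np.linalg.matrix_rank(Xc.to_numpy())})"
        )
    res = sm.OLS(y, Xc).fit()
    return OlsResult(
        coefficients=res.params,
        pvalues=res.pvalues,
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        df_model=float(res.df_model),
        df_resid=float(res.df_resid),
        aic=float(res.aic),
        bic=float(res.bic),
        n_obs=int(res.nobs),
    )


class HingeRegression(RegressorMixin, BaseEstimator):
    """Piecewise-linear regression y ~ 1 + x + sum_j c_j * max(0, x - k_j).

    Forward selection adds the SSE-best hinge from candidate knots at
    observed-x quantiles, up to ``max_terms`` hinges; the retained model
    size (0..max_terms hinges) minimizes the GCV score

        GCV(M) = (SSE_M / n) / (1 - C(M)/n)^2,   C(M) = p_M + penalty * knots_M,

    with ``penalty`` defaulting to the conventional 3 per knot.  Ties go to
    the smaller model, so an exactly linear response retains no hinge.
    """

    def __init__(self, max_terms: int = 2, penalty: float = 3.0, knot_percentiles=None):
        self.max_terms = max_terms
        self.penalty = penalty
        self.knot_percentiles = knot_percentiles

    def _candidates(self, x: np.ndarray) -> np.ndarray:
        if self.knot_percentiles is not None:
            knots = np.unique(np.percentile(x, self.knot_percentiles))
        else:
            # knots at observed values, as in standard MARS; thin to a
            # quantile grid when the predictor has many distinct values
            knots = np.unique(x)
            if knots.size > 50:
                knots = np.unique(np.percentile(x, np.linspace(2, 98, 50)))
        return knots[(knots > x.min()) & (knots < x.max())]

    @staticmethod
    def _design(x: np.ndarray, knots) -> np.ndarray:
        cols = [np.ones_like(x), x] + [np.maximum(0.0, x - k) for k in knots]
        return np.column_stack(cols)

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("x and y must be the same length")
        if np.ptp(x) == 0:
            raise ValueError("constant predictor: breakpoints are undefined")
        n = x.size

        def sse(knots):
            D = self._design(x, knots)
            beta, *_ = np.linalg.lstsq(D, y, rcond=None)
            resid = y - D @ beta
            return float(resid @ resid), beta

        # forward pass: greedy hinge additions
        path = [([], *sse([]))]  # (knots, sse, beta)
        candidates = list(self._candidates(x))
        knots: list[float] = []
        for _ in range(self.max_terms):
            remaining = [k for k in candidates if k not in knots]
            if not remaining:
                break
            trials = [(k, *sse(knots + [k])) for k in remaining]
            best_k, best_sse, best_beta = min(trials, key=lambda r: r[1])
            knots = sorted(knots + [best_k])
            # refit in sorted knot order so coefficients line up
            best_sse, best_beta = sse(knots)
            path.append((list(knots), best_sse, best_beta))

        # GCV model-size selection (ties -> smaller model)
        def gcv(n_knots, sse_val):
            c = (2 + n_knots) + self.penalty * n_knots
            denom = (1.0 - c / n) ** 2
            return np.inf if denom <= 0 else (sse_val / n) / denom

        best = min(path, key=lambda p: (gcv(len(p[0]), p[1]), len(p[0])))
        sel_knots, sel_sse, sel_beta = best
        self.intercept_ = float(sel_beta[0])
        self.slope_ = float(sel_beta[1])
        self.hinges_ = [(float(k), float(c)) for k, c in zip(sel_knots, sel_beta[2:])]
        self.sse_ = sel_sse
        tss = float(np.sum((y - y.mean()) ** 2))
        self.r_squared_ = 1.0 - sel_sse / tss if tss > 0 else 1.0
        self.gcv_ = gcv(len(sel_knots), sel_sse)
        self.n_obs_ = n
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        out = self.intercept_ + self.slope_ * x
        for k, c in self.hinges_:
            out = out + c * np.maximum(0.0, x - k)
        return out


def mars_fit(x, y, max_terms: int = 2, **kwargs) -> HingeRegression:
    """Fit the hinge regression; requires >= 20 observations."""
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.size < 20:
        raise ValueError("breakpoint estimation needs at least 20 observations")
    return HingeRegression(max_terms=max_terms, **kwargs).fit(x, y)


@dataclass
class ClinicalRegressionReport:
    """One OLS per clinical score, each regressed on all model parameters."""

    models: dict = field(default_factory=dict)  # score name -> OlsResult

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, res in self.models.items():
            rows.append(
                {
                    "score": name,
                    "r_squared": res.r_squared,
                    "f_statistic": res.f_statistic,
                    "f_pvalue": res.f_pvalue,
                    "n_obs": res.n_obs,
                    "v_exec_coef": res.coefficients.get("v_exec", np.nan),
                    "v_inhib_coef": res.coefficients.get("v_inhib", np.nan),
                }
            )
        return pd.DataFrame(rows)


def stage_regression(table: pd.DataFrame, param_columns=PARAM_COLUMNS) -> OlsResult:
    """Regress linearly coded disease stage (0..4) on all model parameters."""
    cols = [c for c in param_columns if c in table.columns]
    return ols_fit(table[cols], table["stage"])


def clinical_regressions(
    params_table: pd.DataFrame,
    clinical: pd.DataFrame,
    param_columns=PARAM_COLUMNS,
) -> ClinicalRegressionReport:
    """Regress each clinical score on the fitted model parameters.

    TMS enters as log(TMS + 1) — controls legitimately score zero — TFC and
    CAG untransformed.  Tables are matched on ``subject_id``; subjects
    missing a score are dropped listwise for that score's model.
    """
    merged = params_table.merge(clinical, on="subject_id", how="inner")
    if merged.empty:
        raise ValueError("no overlapping subject ids between tables")
    cols = [c for c in param_columns if c in merged.columns]
    report = ClinicalRegressionReport()
    if "tms" in merged.columns:
        report.models["log_tms"] = ols_fit(merged[cols], np.log(merged["tms"] + 1.0))
    if "tfc" in merged.columns:
        report.models["tfc"] = ols_fit(merged[cols], merged["tfc"])
    if "cag" in merged.columns:
        report.models["cag"] = ols_fit(merged[cols], merged["cag"])
    return report
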