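"""Trait-level analysis: explaining and predicting baseline impulsivity.

Baseline impulsivity is measured once per participant by two
questionnaires: the 15-item Barratt Impulsiveness Scale short form (BIS-15,
with motor / nonplanning / attention subscales) and the UPPS impulsive
behaviour scale (urgency, lack of premeditation, lack of perseverance,
sensation seeking).  Three analyses relate the 15 whole-study passive
features to these scores:

1. pairwise Pearson correlations;
2. Lasso feature selection (penalty 0.05 on standardized predictors)
   followed by an OLS refit, reported with standardized coefficients, an
   overall F test and adjusted R²;
3. leave-one-subject-out (LOSO) prediction with a linear support-vector
   regressor, scored by MAE and the Pearson r between predicted and true
   scores.

The OLS p values are post-selection and therefore optimistic; the LOSO
block is the honest out-of-sample check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.svm import SVR

logger = logging.getLogger(__name__)

__all__ = [
    "TRAIT_COLUMNS",
    "TraitModelReport",
    "LosoPredictionReport",
    "correlate",
    "lasso_select",
    "ols_refit",
    "loso_svr",
    "run_trait_battery",
]

#: The nine trait outcomes (totals plus subscales), in report order.
TRAIT_COLUMNS = (
    "bis_total",
    "bis_motor",
    "bis_nonplanning",
    "bis_attention",
    "upps_total",
    "upps_urgency",
    "upps_perseverance",
    "upps_premeditation",
    "upps_sensation",
)

#: Default Lasso regularization strength on standardized predictors.
LASSO_PENALTY = 0.05


@dataclass
class TraitModelReport:
    """Summary of one Lasso-selected OLS trait model."""

    outcome: str
    selected: list[str]
    coef: dict[str, float]
    coef_p: dict[str, float]
    f_stat: float
    df1: int
    df2: int
    p_value: float
    r_squared: float
    adj_r_squared: float

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "selected": self.selected,
            "coef": self.coef,
            "coef_p": self.coef_p,
            "F": self.f_stat,
            "df": [self.df1, self.df2],
            "p": self.p_value,
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
        }


@dataclass
class LosoPredictionReport:
    """Leave-one-subject-out prediction summary for one trait."""

    outcome: str
    predicted: np.ndarray
    true: np.ndarray
    mae: float
    pearson_r: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "mae": self.mae,
            "pearson_r": self.pearson_r,
            "p": self.p_value,
        }


def correlate(features: pd.DataFrame, traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between features and trait scores.

    Complete cases per pair; returns (r, p) tables with features as rows.
    A constant column yields NaN (correlation undefined).
    """
    r = pd.DataFrame(index=features.columns, columns=traits.columns, dtype=float)
    p = pd.DataFrame(index=features.columns, columns=traits.columns, dtype=float)
    for fcol in features.columns:
        for tcol in traits.columns:
            pair = pd.concat([features[fcol], traits[tcol]], axis=1).dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"fewer than 3 complete cases for ({fcol}, {tcol})"
                )
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r.loc[fcol, tcol] = np.nan
                p.loc[fcol, tcol] = np.nan
                continue
            rv, pv = stats.pearsonr(x, y)
            r.loc[fcol, tcol] = rv
            p.loc[fcol, tcol] = pv
    return r, p


def standardize(X: np.ndarray) -> np.ndarray:
    """Column-standardize to mean 0, SD 1 (population SD)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def lasso_select(
    X: np.ndarray, y: np.ndarray, penalty: float = LASSO_PENALTY
) -> np.ndarray:
    """Indices of features with nonzero Lasso coefficients.

    ``X`` must be column-standardized and ``y`` centered; the same penalty
    is used across all trait models.  ``penalty = 0`` degenerates to OLS
    (all features kept, up to numerical zero).
    """
    if penalty == 0:
        fit = LinearRegression(fit_intercept=False).fit(X, y)
        coefs = fit.coef_
        return np.flatnonzero(np.abs(coefs) > 1e-10)
    model = Lasso(alpha=penalty, fit_intercept=False, max_iter=100_000, tol=1e-10)
    model.fit(X, y)
    return np.flatnonzero(model.coef_ != 0.0)


def ols_refit(
    X_selected: np.ndarray, y: np.ndarray, feature_names: list[str], outcome: str = ""
) -> TraitModelReport:
    """OLS refit on the Lasso-selected features.

    Predictors are standardized so the coefficients are comparable across
    features; reports the overall F(k, n − k − 1) test and adjusted R².
    """
    n, k = X_selected.shape
    if n <= k + 1:
        raise ValueError(f"n = {n} too small for k = {k} features")
    rank = np.linalg.matrix_rank(X_selected)
    if rank < k:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {k}); "
            f"collinear columns among {feature_names}"
        )
    Xs = sm.add_constant(standardize(X_selected))
    fit = sm.OLS(y, Xs).fit()
    coef = dict(zip(feature_names, fit.params[1:]))
    coef_p = dict(zip(feature_names, fit.pvalues[1:]))
    return TraitModelReport(
        outcome=outcome,
        selected=list(feature_names),
        coef=coef,
        coef_p=coef_p,
        f_stat=float(fit.fvalue),
        df1=int(fit.df_model),
        df2=int(fit.df_resid),
        p_value=float(fit.f_pvalue),
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
    )


def loso_svr(
    X: np.ndarray,
    y: np.ndarray,
    outcome: str = "",
    C: float = 1.0,
    epsilon: float = 0.1,
    reselect: bool = True,
    penalty: float = LASSO_PENALTY,
) -> LosoPredictionReport:
    """Leave-one-subject-out linear SVR prediction.

    For each participant a linear support-vector regressor is trained on
    the remaining n − 1; standardization statistics (and, when ``reselect``
    is true, the Lasso-selected feature subset) are learned on the training
    fold only, so the held-out participant never influences their own
    prediction.  Returns per-subject predictions, MAE, and Pearson r of
    predicted vs. true scores.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("LOSO needs at least 3 participants")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Z_tr = (X_tr - mu) / sd
        z_te = (X[i] - mu) / sd
        cols = np.arange(X.shape[1])
        if reselect:
            sel = lasso_select(Z_tr, y_tr - y_tr.mean(), penalty=penalty)
            if sel.size:
                cols = sel
        model = SVR(kernel="linear", C=C, epsilon=epsilon)
        model.fit(Z_tr[:, cols], y_tr)
        preds[i] = model.predict(z_te[cols].reshape(1, -1))[0]
    mae = float(np.abs(preds - y).mean())
    if np.ptp(y) == 0 or np.ptp(preds) == 0:
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(preds, y)
    return LosoPredictionReport(
        outcome=outcome, predicted=preds, true=y, mae=mae, pearson_r=float(r), p_value=float(p)
    )


def run_trait_battery(
    features: pd.DataFrame,
    traits: pd.DataFrame,
    penalty: float = LASSO_PENALTY,
) -> dict:
    """Run correlations, Lasso→OLS, and LOSO-SVR for every trait outcome.

    ``features`` is the participant × 15 whole-study feature matrix;
    ``traits`` holds the questionnaire scores, indexed identically.
    Participants missing any feature are dropped (complete-case analysis).
    Returns a JSON-serialisable report.
    """
    joined = features.join(traits, how="inner").dropna()
    X_all = joined[features.columns].to_numpy(dtype=float)
    reports: dict = {"correlations": {}, "regression": {}, "loso": {}}
    trait_cols = [c for c in traits.columns if c in joined.columns]
    r_tab, p_tab = correlate(joined[features.columns], joined[trait_cols])
    reports["correlations"] = {
        "r": r_tab.to_dict(),
        "p": p_tab.to_dict(),
    }
    Z = standardize(X_all)
    for outcome in trait_cols:
        y = joined[outcome].to_numpy(dtype=float)
        sel = lasso_select(Z, y - y.mean(), penalty=penalty)
        if sel.size == 0:
            logger.info("%s: Lasso selected no features (no model)", outcome)
            reports["regression"][outcome] = None
        else:
            names = [features.columns[j] for j in sel]
            try:
                rep = ols_refit(X_all[:, sel], y, names, outcome=outcome)
                reports["regression"][outcome] = rep.to_dict()
            except ValueError as exc:
                logger.warning("%s: refit failed (%s); no model", outcome, exc)
                reports["regression"][outcome] = None
        warnings.filterwarnings("ignore", message="Liblinear")
        loso = loso_svr(X_all, y, outcome=outcome, penalty=penalty)
        reports["loso"][outcome] = loso.to_dict()
    logger.warning(
        "OLS p values are post-selection (no correction applied) and optimistic"
    )
    return reports
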