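"""Daily-state analysis: predicting day-level outcomes from prior-24 h features.

Each participant-day pairs the 15 passive features from the 24-hour window
before the morning assessment with that day's outcomes: morning and evening
semantic differentials (0 = most positive … 10 = most negative), previous-day
differentials, positive/negative affect from the Photographic Affect Meter,
and the six metrics from the mobile active tasks (balloon risk task,
go/no-go, delay discounting).

Two complementary procedures are applied per outcome:

* a Gaussian generalized estimating equation (GEE) with exchangeable
  working correlation clustered by participant, summarised by the Pearson r
  between fitted and observed values and the estimated within-group
  correlation;
* a median-split binary classification (label 1 iff the value is strictly
  above the pooled median) with logistic regression under leave-one-
  subject-out cross-validation, reporting per-individual accuracies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

__all__ = [
    "OUTCOME_COLUMNS",
    "StateModelReport",
    "fit_gee",
    "median_binarize",
    "loso_classify",
    "run_state_battery",
]

#: Present-moment semantic differentials, assessed morning (am_) and evening (pm_).
DIFFERENTIALS_PRESENT = ("distracted", "impulsive", "thrill_seeking", "bored", "aimless")
#: Previous-day semantic differentials.
DIFFERENTIALS_PREV = (
    "prev_negative",
    "prev_impulsive",
    "prev_unproductive",
    "prev_stressed",
    "prev_unhealthy",
)
#: Affect scores and active-task metrics.
PAM_COLUMNS = ("pam_positive", "pam_negative")
TASK_COLUMNS = (
    "bart_risk",
    "bart_gains",
    "gng_latency",
    "gng_commission",
    "gng_omission",
    "dd_present_bias",
)

#: All day-level outcomes analysed by :func:`run_state_battery`.
OUTCOME_COLUMNS = (
    tuple(f"am_{d}" for d in DIFFERENTIALS_PRESENT)
    + tuple(f"pm_{d}" for d in DIFFERENTIALS_PRESENT)
    + DIFFERENTIALS_PREV
    + PAM_COLUMNS
    + TASK_COLUMNS
)


@dataclass
class StateModelReport:
    outcome: str
    coef: dict[str, float]
    pearson_r: float
    p_value: float
    wald_p: float
    within_group_corr: float
    accuracies: dict[str, float]
    accuracy_mean: float
    accuracy_sd: float

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "coef": self.coef,
            "pearson_r": self.pearson_r,
            "p": self.p_value,
            "wald_p": self.wald_p,
            "within_group_corr": self.within_group_corr,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "accuracies": self.accuracies,
        }


def fit_gee(
    daily_features: pd.DataFrame,
    outcome: pd.Series,
    groups: pd.Series,
    cov_struct: str = "exchangeable",
) -> tuple[dict[str, float], float, float, float, float]:
    """Gaussian GEE of one outcome on the daily features, clustered by
    participant.

    Returns ``(coefficients, pearson_r, p_value, within_group_corr,
    wald_p)``.  The Pearson r compares in-sample fitted values with
    observations (its p value ignores clustering and is presentational);
    ``wald_p`` is the joint cluster-robust Wald test of all feature
    coefficients and is the calibrated model-significance call.  The
    within-group correlation is the estimated exchangeable working
    correlation (0.0 under the independence structure).
    """
    X = sm.add_constant(np.asarray(daily_features, dtype=float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    y = np.asarray(outcome, dtype=float)
    if cov_struct == "exchangeable":
        cs = sm.cov_struct.Exchangeable()
    elif cov_struct == "independence":
        cs = sm.cov_struct.Independence()
    else:
        raise ValueError(f"unknown working correlation {cov_struct!r}")
    model = sm.GEE(y, X, groups=np.asarray(groups), family=sm.families.Gaussian(), cov_struct=cs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit()
    names = ["const"] + list(daily_features.columns)
    # (near-)zero residual variance breaks the GEE scale and correlation
    # estimates; the solution then coincides with OLS and there is no
    # residual clustering to speak of
    degenerate = not np.all(np.isfinite(fit.params)) or (
        np.isfinite(fit.scale) and fit.scale <= 1e-10 * (np.var(y) + 1e-30)
    ) or not np.isfinite(fit.scale)
    if degenerate:
        ols = sm.OLS(y, X).fit()
        coef = dict(zip(names, ols.params))
        fitted = np.asarray(ols.fittedvalues)
        r = float(stats.pearsonr(fitted, y)[0]) if np.ptp(y) > 0 else float("nan")
        return coef, r, 0.0, 0.0, float("nan")
    coef = dict(zip(names, fit.params))
    fitted = fit.fittedvalues
    if np.ptp(fitted) == 0 or np.ptp(y) == 0:
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(fitted, y)
    wgc = float(cs.dep_params) if cov_struct == "exchangeable" else 0.0
    # joint test of the feature coefficients with a Hotelling-type
    # small-sample F reference (k, m − k); the naive chi-square Wald is
    # grossly anti-conservative with ~15 covariates and ~26 clusters
    k = X.shape[1] - 1
    m = len(np.unique(np.asarray(groups)))
    b = fit.params[1:]
    V = np.asarray(fit.cov_params())[1:, 1:]
    if m > k:
        w_stat = float(b @ np.linalg.solve(V, b))
        f_stat = w_stat * (m - k) / (k * (m - 1))
        wald_p = float(1.0 - stats.f.cdf(f_stat, k, m - k))
    else:
        wald_p = float("nan")
    return coef, float(r), float(p), wgc, wald_p


def median_binarize(values: pd.Series | np.ndarray) -> np.ndarray:
    """Binary labels against the pooled median: 1 iff strictly above.

    The median is pooled across all participant-days; ties at the median
    are labelled 0 ("higher than" is strict), so the prevalence of 1 never
    exceeds one half.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("degenerate outcome: fewer than 2 distinct values")
    return (v > np.median(v)).astype(int)


def loso_classify(
    daily_features: pd.DataFrame,
    labels: np.ndarray,
    groups: pd.Series | np.ndarray,
) -> tuple[dict[str, float], float, float]:
    """Leave-one-subject-out logistic classification of day labels.

    For each participant a logistic regression is trained on all other
    participants' days (features standardized with training-fold
    statistics) and scored on the held-out participant's days.  Returns the
    per-individual accuracies and their mean and SD across individuals.
    A single-class training fold falls back to predicting the majority
    class, with a warning.
    """
    X = np.asarray(daily_features, dtype=float)
    y = np.asarray(labels, dtype=int)
    g = np.asarray(groups)
    subjects = pd.unique(g)
    if len(subjects) < 3:
        raise ValueError("LOSO classification needs at least 3 participants")
    accuracies: dict[str, float] = {}
    for subj in subjects:
        test = g == subj
        X_tr, y_tr = X[~test], y[~test]
        mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        if np.unique(y_tr).size < 2:
            logger.warning("training fold for %s has a single class", subj)
            pred = np.full(test.sum(), int(np.round(y_tr.mean())))
        else:
            clf = LogisticRegression(max_iter=5000)
            clf.fit((X_tr - mu) / sd, y_tr)
            pred = clf.predict((X[test] - mu) / sd)
        accuracies[str(subj)] = float((pred == y[test]).mean())
    acc = np.array(list(accuracies.values()))
    return accuracies, float(acc.mean()), float(acc.std(ddof=1))


def run_state_battery(
    daily_features: pd.DataFrame,
    daily: pd.DataFrame,
    groups: pd.Series | None = None,
    outcomes: tuple[str, ...] = OUTCOME_COLUMNS,
) -> dict[str, dict | None]:
    """GEE + median-split LOSO classification for every day-level outcome.

    ``daily_features`` and ``daily`` are aligned participant-day tables;
    ``groups`` defaults to the ``participant_id`` column of ``daily``.
    Complete cases per outcome; an entirely missing or degenerate outcome
    is skipped with a warning.  Returns one report per outcome keyed by
    outcome name.
    """
    if groups is None:
        groups = daily["participant_id"]
    reports: dict[str, dict | None] = {}
    feat_cols = list(daily_features.columns)
    for outcome in outcomes:
        if outcome not in daily.columns or daily[outcome].dropna().empty:
            logger.warning("outcome %s missing entirely; skipped", outcome)
            reports[outcome] = None
            continue
        mask = daily[outcome].notna() & daily_features.notna().all(axis=1).to_numpy()
        feats = daily_features.loc[mask, feat_cols]
        vals = daily.loc[mask, outcome]
        grp = np.asarray(groups)[np.asarray(mask)]
        try:
            coef, r, p, wgc, wald_p = fit_gee(feats, vals, grp)
            labels = median_binarize(vals)
            accs, acc_mean, acc_sd = loso_classify(feats, labels, grp)
        except ValueError as exc:
            logger.warning("outcome %s skipped: %s", outcome, exc)
            reports[outcome] = None
            continue
        reports[outcome] = StateModelReport(
            outcome=outcome,
            coef=coef,
            pearson_r=r,
            p_value=p,
            wald_p=wald_p,
            within_group_corr=wgc,
            accuracies=accs,
            accuracy_mean=acc_mean,
            accuracy_sd=acc_sd,
        ).to_dict()
    return reports
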