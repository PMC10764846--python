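"""Cox elastic-net risk model and survival statistics.

A Cox proportional-hazards model with an elastic-net penalty is fit on the
14 per-patient features; the penalty weight is chosen by cross-validated
partial log-likelihood.  The continuous risk score of a patient is the
linear combination of z-scored features weighted by the fitted coefficients
(training means/SDs are reused on validation cohorts), and the cohort is
stratified into high vs low risk at the mean training risk score.  Group
differences are summarized by Kaplan-Meier curves with the log-rank test,
the group hazard ratio with a Wald 95% CI, Harrell's c-index, and rank-sum
comparisons of feature values between risk groups.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.util import Surv

logger = logging.getLogger(__name__)

__all__ = [
    "CoxElasticNetRisk",
    "fit_cox_elastic_net",
    "risk_score",
    "stratify",
    "km_logrank",
    "hazard_ratio",
    "c_index",
    "compare_groups",
]


def _check_survival_frame(survival: pd.DataFrame) -> pd.DataFrame:
    missing = {"time", "event"} - set(survival.columns)
    if missing:
        raise ValueError(f"survival frame missing columns {sorted(missing)}")
    if (survival["time"] < 0).any():
        raise ValueError("negative survival times")
    return survival


def _breslow_partial_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                            beta: np.ndarray) -> float:
    """Breslow partial log-likelihood of a linear predictor X @ beta."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # decreasing time
    eta_o, time_o, event_o = eta[order], time[order], event[order]
    log_cum = np.logaddexp.accumulate(eta_o)
    # risk set at an event time t includes every subject with time >= t;
    # expand ties so tied subjects share the same cumulative term
    ll = 0.0
    i = 0
    n = len(time_o)
    while i < n:
        j = i
        while j + 1 < n and time_o[j + 1] == time_o[i]:
            j += 1
        denom = log_cum[j]
        for k in range(i, j + 1):
            if event_o[k]:
                ll += eta_o[k] - denom
        i = j + 1
    return float(ll)


class CoxElasticNetRisk(BaseEstimator):
    """Elastic-net penalized Cox model producing a mean-thresholded risk score.

    Parameters
    ----------
    alpha_ratio : float, default 0.5
        L1 fraction of the elastic-net penalty (1 = lasso, 0 = ridge).
    lambda_grid : sequence of float, optional
        Candidate penalty weights.  ``None`` derives a data-driven path;
        ``[0]`` fits the unpenalized Cox model.
    cv_folds : int, default 5
        Folds for cross-validated partial log-likelihood selection of lambda.
    random_state : int, default 0
        Seeds the fold assignment; the fit is deterministic given it.
    threshold_mode : {"train_mean", "cohort_mean"}, default "train_mean"
        Whether stratification uses the training-cohort mean risk score
        everywhere or recomputes the mean per cohort.

    Attributes
    ----------
    feature_names_ : list of str
    coef_ : pandas.Series, coefficient per feature (zeros allowed)
    train_means_, train_sds_ : pandas.Series, standardization constants
    risk_threshold_ : float, mean of training risk scores
    lambda_ : float, selected penalty weight
    dropped_features_ : list of constant features excluded from the fit
    """

    def __init__(self, alpha_ratio: float = 0.5,
                 lambda_grid: Sequence[float] | None = None,
                 cv_folds: int = 5, random_state: int = 0,
                 threshold_mode: str = "train_mean") -> None:
        self.alpha_ratio = alpha_ratio
        self.lambda_grid = lambda_grid
        self.cv_folds = cv_folds
        self.random_state = random_state
        self.threshold_mode = threshold_mode

    # -- internals ---------------------------------------------------------

    def _prepare(self, X: pd.DataFrame, fit: bool) -> np.ndarray:
        X = pd.DataFrame(X).copy()
        if fit:
            self.feature_names_ = list(X.columns)
            self.train_means_ = X.mean(skipna=True)
            sds = X.std(ddof=0, skipna=True)
            self.dropped_features_ = [f for f in X.columns
                                      if not np.isfinite(sds[f]) or sds[f] == 0]
            for f in self.dropped_features_:
                logger.warning("constant feature %s dropped from the fit", f)
            self.train_sds_ = sds.where(sds > 0, 1.0)
        else:
            unknown = set(X.columns) - set(self.feature_names_)
            missing = set(self.feature_names_) - set(X.columns)
            if unknown or missing:
                raise ValueError(f"feature mismatch: unknown={sorted(unknown)}, "
                                 f"missing={sorted(missing)}")
            X = X[self.feature_names_]
        n_missing = int(X.isna().sum().sum())
        if n_missing:
            logger.warning("imputing %d missing feature values with training means",
                           n_missing)
            X = X.fillna(self.train_means_)
        Z = (X - self.train_means_) / self.train_sds_
        Z[self.dropped_features_] = 0.0
        return Z.to_numpy(dtype=float)

    def _fit_at_lambda(self, Z: np.ndarray, y, lam: float) -> np.ndarray:
        if lam == 0:
            est = CoxPHSurvivalAnalysis(ties="breslow").fit(Z, y)
            return np.asarray(est.coef_, dtype=float)
        est = CoxnetSurvivalAnalysis(l1_ratio=self.alpha_ratio, alphas=[lam],
                                     fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Z, y)
        return est.coef_[:, 0].astype(float)

    def _lambda_path(self, Z: np.ndarray, y) -> np.ndarray:
        est = CoxnetSurvivalAnalysis(l1_ratio=self.alpha_ratio, n_alphas=30,
                                     fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Z, y)
        return np.asarray(est.alphas_, dtype=float)

    # -- estimator API -----------------------------------------------------

    def fit(self, X: pd.DataFrame, y: pd.DataFrame) -> "CoxElasticNetRisk":
        """Fit on a feature frame and a survival frame (columns time, event)."""
        y = _check_survival_frame(pd.DataFrame(y))
        X = pd.DataFrame(X)
        if len(X) != len(y):
            raise ValueError("features and survival have different lengths")
        time = y["time"].to_numpy(dtype=float)
        event = y["event"].to_numpy(dtype=bool)
        if event.sum() < 2:
            raise ValueError("need >= 2 observed events to fit a Cox model")
        Z = self._prepare(X, fit=True)
        active = [i for i, f in enumerate(self.feature_names_)
                  if f not in self.dropped_features_]
        Za = Z[:, active]
        y_struct = Surv.from_arrays(event=event, time=time)

        grid = (np.asarray(list(self.lambda_grid), dtype=float)
                if self.lambda_grid is not None else self._lambda_path(Za, y_struct))
        if len(grid) == 1:
            best_lambda = float(grid[0])
        else:
            best_lambda = self._select_lambda_cv(Za, y_struct, time, event, grid)
        beta_active = self._fit_at_lambda(Za, y_struct, best_lambda)

        beta = np.zeros(len(self.feature_names_))
        beta[active] = beta_active
        self.coef_ = pd.Series(beta, index=self.feature_names_)
        self.lambda_ = best_lambda
        train_scores = Z @ beta
        self.risk_threshold_ = float(np.mean(train_scores))
        logger.info("fitted Cox elastic net: lambda=%.4g, %d/%d nonzero features, "
                    "risk threshold %.4f", best_lambda,
                    int((beta != 0).sum()), len(beta), self.risk_threshold_)
        return self

    def _select_lambda_cv(self, Z: np.ndarray, y_struct, time: np.ndarray,
                          event: np.ndarray, grid: np.ndarray) -> float:
        kf = KFold(n_splits=self.cv_folds, shuffle=True,
                   random_state=self.random_state)
        cv_ll = np.zeros(len(grid))
        n_ok = np.zeros(len(grid))
        for train_idx, test_idx in kf.split(Z):
            if event[train_idx].sum() < 2 or event[test_idx].sum() < 1:
                continue
            for a, lam in enumerate(grid):
                try:
                    beta = self._fit_at_lambda(Z[train_idx], y_struct[train_idx], lam)
                except (ValueError, ArithmeticError):
                    continue
                cv_ll[a] += _breslow_partial_loglik(Z[test_idx], time[test_idx],
                                                    event[test_idx], beta)
                n_ok[a] += 1
        valid = n_ok == n_ok.max()
        best = int(np.flatnonzero(valid)[np.argmax(cv_ll[valid])])
        return float(grid[best])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Continuous risk score: sum_f coef_f * (x_f - mean_f) / sd_f,
        always using the training standardization constants."""
        if not hasattr(self, "coef_"):
            raise ValueError("model is not fitted")
        return self._prepare(pd.DataFrame(X), fit=False) @ self.coef_.to_numpy()

    def nonzero_features(self) -> list[str]:
        return [f for f, c in self.coef_.items() if c != 0]

    # -- persistence -------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "coefficients": self.coef_.to_dict(),
            "train_means": self.train_means_.to_dict(),
            "train_sds": self.train_sds_.to_dict(),
            "risk_threshold": self.risk_threshold_,
            "alpha_ratio": self.alpha_ratio,
            "lambda": self.lambda_,
            "cv_folds": self.cv_folds,
            "random_state": self.random_state,
            "threshold_mode": self.threshold_mode,
            "dropped_features": self.dropped_features_,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CoxElasticNetRisk":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        model = cls(alpha_ratio=payload["alpha_ratio"], cv_folds=payload["cv_folds"],
                    random_state=payload["random_state"],
                    threshold_mode=payload["threshold_mode"])
        model.coef_ = pd.Series(payload["coefficients"])
        model.feature_names_ = list(model.coef_.index)
        model.train_means_ = pd.Series(payload["train_means"])[model.feature_names_]
        model.train_sds_ = pd.Series(payload["train_sds"])[model.feature_names_]
        model.risk_threshold_ = payload["risk_threshold"]
        model.lambda_ = payload["lambda"]
        model.dropped_features_ = payload["dropped_features"]
        return model


# ---------------------------------------------------------------------------
# functional wrappers


def fit_cox_elastic_net(features: pd.DataFrame, survival: pd.DataFrame,
                        alpha_ratio: float = 0.5,
                        lambda_grid: Sequence[float] | None = None,
                        cv_folds: int = 5, seed: int = 0) -> CoxElasticNetRisk:
    return CoxElasticNetRisk(alpha_ratio=alpha_ratio, lambda_grid=lambda_grid,
                             cv_folds=cv_folds, random_state=seed
                             ).fit(features, survival)


def risk_score(model: CoxElasticNetRisk, features: pd.DataFrame) -> np.ndarray:
    return model.predict(features)


def stratify(scores: np.ndarray, model: CoxElasticNetRisk,
             survival: pd.DataFrame | None = None,
             patient_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """High/low risk split at the model threshold; ties go to low risk.

    With ``threshold_mode="cohort_mean"`` the threshold is recomputed as the
    mean score of the cohort at hand.
    """
    scores = np.asarray(scores, dtype=float)
    threshold = (float(np.mean(scores)) if model.threshold_mode == "cohort_mean"
                 else model.risk_threshold_)
    cohort = pd.DataFrame({
        "risk_score": scores,
        "group": np.where(scores > threshold, "high", "low"),
    })
    if patient_ids is not None:
        cohort.insert(0, "patient_id", list(patient_ids))
    if survival is not None:
        survival = _check_survival_frame(pd.DataFrame(survival).reset_index(drop=True))
        cohort["time"] = survival["time"].to_numpy()
        cohort["event"] = survival["event"].to_numpy().astype(int)
    if cohort["group"].nunique() < 2:
        logger.warning("degenerate stratification: every patient in the %s-risk group",
                       cohort["group"].iloc[0])
    return cohort


def km_logrank(cohort: pd.DataFrame) -> dict:
    """Kaplan-Meier curves per risk group and the two-sided log-rank p."""
    curves = {}
    for group in ("high", "low"):
        sub = cohort[cohort["group"] == group]
        if sub.empty:
            raise ValueError(f"empty {group}-risk group")
        km = KaplanMeierFitter(label=group).fit(sub["time"], sub["event"])
        curves[group] = km.survival_function_
    hi = cohort[cohort["group"] == "high"]
    lo = cohort[cohort["group"] == "low"]
    res = logrank_test(hi["time"], lo["time"], hi["event"], lo["event"])
    return {"km_curves": curves, "logrank_p": float(res.p_value),
            "statistic": float(res.test_statistic)}


def hazard_ratio(cohort: pd.DataFrame) -> dict:
    """Univariable Cox HR (high vs low risk) with Wald 95% CI and p."""
    df = cohort.assign(high=(cohort["group"] == "high").astype(int))
    events_per_group = df.groupby("high")["event"].sum()
    if len(events_per_group) < 2 or (events_per_group == 0).any():
        logger.warning("monotone likelihood: a group has no events; CI unbounded")
        return {"hr": float("nan"), "ci_low": 0.0, "ci_high": float("inf"),
                "wald_p": float("nan"), "flag": "monotone_likelihood"}
    cph = CoxPHFitter()
    cph.fit(df[["time", "event", "high"]], duration_col="time", event_col="event")
    beta = float(cph.params_["high"])
    se = float(cph.standard_errors_["high"])
    with np.errstate(over="ignore"):  # a huge SE legitimately gives an inf bound
        ci_low, ci_high = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
    return {"hr": float(np.exp(beta)),
            "ci_low": float(ci_low),
            "ci_high": float(ci_high),
            "wald_p": float(cph.summary.loc["high", "p"]),
            "beta": beta, "se": se}


def c_index(scores: np.ndarray, survival: pd.DataFrame) -> float:
    """Harrell's concordance of a risk score against (time, event).

    Higher score must predict earlier failure; score ties count 0.5.
    """
    survival = _check_survival_frame(pd.DataFrame(survival))
    try:
        return float(concordance_index(survival["time"], -np.asarray(scores),
                                       survival["event"]))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs for the c-index") from exc


def compare_groups(values: np.ndarray, groups: Sequence[str]) -> dict:
    """Two-sided rank-sum (Mann-Whitney) comparison of values between the
    high- and low-risk groups, with group medians."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    hi = values[groups == "high"]
    lo = values[groups == "low"]
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("both groups must be non-empty")
    medians = {"high": float(np.median(hi)), "low": float(np.median(lo))}
    if np.all(values == values[0]):
        logger.warning("all values tied; rank-sum p set to 1")
        return {"wilcoxon_p": 1.0, "group_medians": medians}
    stat, p = stats.mannwhitneyu(hi, lo, alternative="two-sided")
    return {"wilcoxon_p": float(p), "group_medians": medians, "statistic": float(stat)}
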