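"""Survey-weighted logistic regression for in-hospital/ED fatality.

The fatality model is

    logit P(death) = b0 + b_age*age + b_female*female + b_severe*severe
                     + b_tc*trauma_center + b_ped*pedestrian + b_tbi*TBI
                     + b_ped_tbi*pedestrian*TBI   (+ year indicators)

fitted by weighted maximum likelihood (IRLS), with variance from a sandwich
estimator whose score contributions are aggregated to the hospital (cluster)
level and centered within design strata:

    meat = sum_h n_h/(n_h-1) sum_{g in h} (s_g - sbar_h)(s_g - sbar_h)'

where s_g is the summed weighted score of cluster g. Without cluster/stratum
information every record is its own cluster and the estimator reduces to the
heteroskedasticity-robust (HC0) sandwich.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .survey import Z95


class SingleClassError(ValueError):
    """Outcome has a single class; the logistic model is not identified."""


class SurveyWeightedLogit(BaseEstimator):
    """Weighted logistic regression with cluster-robust (sandwich) variance.

    Parameters
    ----------
    tol : IRLS convergence tolerance on the max absolute coefficient change.
    max_iter : maximum IRLS iterations.
    drop_constant : drop zero-variance columns (with a warning) instead of
        failing on a singular information matrix.

    Attributes
    ----------
    coef_ : pandas Series of coefficients (including ``intercept``).
    cov_ : robust covariance as a DataFrame aligned with ``coef_``.
    converged_ : whether IRLS reached ``tol`` without separation diagnostics.
    n_weighted_ : sum of the analysis weights.
    dropped_terms_ : columns removed as degenerate.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100,
                 drop_constant: bool = True):
        self.tol = tol
        self.max_iter = max_iter
        self.drop_constant = drop_constant

    def fit(self, X, y, sample_weight=None, clusters=None, strata=None):
        X = pd.DataFrame(X).copy()
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise SingleClassError("outcome has a single class")
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)

        self.dropped_terms_ = []
        if self.drop_constant:
            for col in list(X.columns):
                if np.ptp(X[col].to_numpy(dtype=float)) == 0:
                    self.dropped_terms_.append(col)
                    X = X.drop(columns=[col])
            if self.dropped_terms_:
                warnings.warn(
                    f"dropping degenerate (constant) terms: {self.dropped_terms_}",
                    stacklevel=2)

        names = ["intercept"] + list(X.columns)
        M = np.column_stack([np.ones(len(y)), X.to_numpy(dtype=float)])

        beta = np.zeros(M.shape[1])
        converged = False
        for _ in range(self.max_iter):
            eta = M @ beta
            p = expit(eta)
            wls = w * np.clip(p * (1 - p), 1e-12, None)
            score = M.T @ (w * (y - p))
            info = (M * wls[:, None]).T @ M
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                warnings.warn("singular information matrix; fit not converged",
                              stacklevel=2)
                break
            beta = beta + step
            if np.max(np.abs(step)) < self.tol:
                converged = True
                break
        if np.max(np.abs(M @ beta)) > 30:
            warnings.warn(
                "very large linear predictor: possible quasi-separation",
                stacklevel=2)
            converged = False

        p = expit(M @ beta)
        wls = w * np.clip(p * (1 - p), 1e-12, None)
        info = (M * wls[:, None]).T @ M
        bread = np.linalg.inv(info)
        scores = M * (w * (y - p))[:, None]

        if clusters is None:
            meat = scores.T @ scores
        else:
            cl = pd.Series(np.asarray(clusters))
            g = pd.DataFrame(scores).groupby(cl.to_numpy()).sum().to_numpy()
            if strata is None:
                meat = g.T @ g
            else:
                st = pd.DataFrame({"s": np.asarray(strata), "c": cl.to_numpy()})
                cluster_stratum = st.drop_duplicates("c").set_index("c")["s"]
                order = pd.DataFrame(scores).groupby(cl.to_numpy()).sum()
                strat_of = cluster_stratum.loc[order.index].to_numpy()
                g = order.to_numpy()
                meat = np.zeros((g.shape[1], g.shape[1]))
                for s in np.unique(strat_of):
                    gh = g[strat_of == s]
                    n_h = len(gh)
                    if n_h == 1:
                        continue
                    d = gh - gh.mean(axis=0)
                    meat += n_h / (n_h - 1) * d.T @ d
        cov = bread @ meat @ bread
        cov = (cov + cov.T) / 2

        self.coef_ = pd.Series(beta, index=names)
        self.cov_ = pd.DataFrame(cov, index=names, columns=names)
        self.converged_ = converged
        self.n_weighted_ = float(w.sum())
        self.n_iter_ = None
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        return self

    def predict_proba(self, X):
        X = pd.DataFrame(X)[list(self.feature_names_in_)]
        eta = self.coef_["intercept"] + X.to_numpy(float) @ self.coef_.to_numpy()[1:]
        p = expit(eta)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


@dataclass
class FatalityModelFit:
    coefficients: pd.Series
    robust_covariance: pd.DataFrame
    odds_ratios: pd.DataFrame  # term, aor, ci_low, ci_high (intercept excluded)
    n_weighted: float
    converged: bool
    dropped_terms: list


MODEL_TERMS = ["age", "female", "severe", "trauma_center", "pedestrian",
               "tbi", "pedestrian_tbi"]


def _design_matrix(cohort: pd.DataFrame, include_year: bool,
                   severity_col: str, tbi_col: str) -> pd.DataFrame:
    ped = (cohort["mechanism"] == "pedestrian").astype(int).to_numpy()
    tbi = cohort[tbi_col].astype(int).to_numpy()
    X = pd.DataFrame({
        "age": cohort["age"].astype(float).to_numpy(),
        "female": cohort["female"].astype(int).to_numpy(),
        "severe": cohort[severity_col].astype(int).to_numpy(),
        "trauma_center": cohort["trauma_level12"].astype(int).to_numpy(),
        "pedestrian": ped,
        "tbi": tbi,
        "pedestrian_tbi": ped * tbi,
    }, index=cohort.index)
    if include_year:
        years = sorted(cohort["year"].unique())
        for yr in years[1:]:  # first year is the reference
            X[f"year_{yr}"] = (cohort["year"] == yr).astype(int).to_numpy()
    return X


def fit_fatality_model(cohort: pd.DataFrame, include_year: bool = False,
                       severity_col: str = "severe",
                       tbi_col: str = "tbi_primary") -> FatalityModelFit:
    """Fit the fatality model on an annotated cohort table.

    Requires the cohort columns produced by the extraction/scoring stages
    (``mechanism``, the severity indicator, the TBI indicator) plus the
    design variables (``weight``, ``cluster_id``, ``stratum_id``). Year
    adjustment, when requested, enters as calendar-year indicator covariates
    against the earliest year.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    est = SurveyWeightedLogit()
    X = _design_matrix(cohort, include_year, severity_col, tbi_col)
    est.fit(X, cohort["died"].to_numpy(),
            sample_weight=cohort["weight"].to_numpy(dtype=float),
            clusters=cohort["cluster_id"].to_numpy(),
            strata=cohort["stratum_id"].to_numpy())
    return FatalityModelFit(
        coefficients=est.coef_,
        robust_covariance=est.cov_,
        odds_ratios=odds_ratio_table(est.coef_, est.cov_),
        n_weighted=est.n_weighted_,
        converged=est.converged_,
        dropped_terms=est.dropped_terms_,
    )


def odds_ratio_table(fit, cov: pd.DataFrame | None = None) -> pd.DataFrame:
    """Adjusted odds ratios with robust 95% CIs (intercept excluded).

    Accepts a :class:`FatalityModelFit` or a coefficient Series plus its
    covariance matrix.
    """
    if isinstance(fit, FatalityModelFit):
        coef, cov = fit.coefficients, fit.robust_covariance
    else:
        coef = fit
        if cov is None:
            raise ValueError("covariance matrix required with a coefficient series")
    rows = []
    for term in coef.index:
        if term == "intercept":
            continue
        b = coef[term]
        se = float(np.sqrt(max(float(cov.loc[term, term]), 0.0)))
        with np.errstate(over="ignore"):  # unstable terms may render as inf
            rows.append((term, float(np.exp(b)),
                         float(np.exp(b - Z95 * se)), float(np.exp(b + Z95 * se))))
    return pd.DataFrame(rows, columns=["term", "aor", "ci_low", "ci_high"])


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return float(round(x, -int(np.floor(np.log10(abs(x)))) + sig - 1))


def render_odds_ratio_table(table: pd.DataFrame) -> str:
    """Plain-text report with odds ratios rounded to two significant figures."""
    lines = ["Variable                  Adjusted Odds Ratio (95% CI)"]
    for r in table.itertuples():
        lines.append(
            f"{r.term:<25} {_round_sig(r.aor):g} "
            f"({_round_sig(r.ci_low):g}, {_round_sig(r.ci_high):g})")
    return "\n".join(lines)
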