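"""Multivariate logistic risk-factor model for a target adverse event.

Event presence (1/0 per case) is regressed on suspected-drug exposure
indicators plus demographic covariates (female, age in years, height in cm,
weight in kg) by maximum likelihood on complete cases. Effects are reported
as unit odds ratios exp(beta) with Wald 95% intervals, and for continuous
covariates additionally as range odds ratios exp(beta * (max - min)) over
the observed span — the per-unit OR of age (say 1.02/year) understates a
covariate whose observed range is 100 years, and the range OR makes the two
scales comparable. Model fit is summarised by McFadden's pseudo-R²
(1 - logL/logL0 against the intercept-only model).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .contingency import Z_95
from .errors import DegenerateDesignError, SeparationWarning

COVARIATE_COLUMNS = {"female": None, "age": "age_years",
                     "height": "height_cm", "weight": "weight_kg"}


def build_design(cases: pd.DataFrame, outcome_terms, drug_terms,
                 covariates=("female", "age", "height", "weight")
                 ) -> tuple[pd.DataFrame, pd.Series, int]:
    """Build the complete-case design matrix and outcome vector.

    Drug indicators are 0/1 from suspected-drug set membership; female is
    coded 1 (male 0); continuous covariates stay in natural units. Cases
    missing any used covariate are dropped and counted.

    Returns (X, y, n_dropped_missing); X has no intercept column (the
    fitter adds one). Raises DegenerateDesignError naming any predictor
    that is constant on the complete cases.
    """
    terms = frozenset([outcome_terms] if isinstance(outcome_terms, str)
                      else outcome_terms)
    cases = cases.reset_index(drop=True)
    cols = {}
    for drug in drug_terms:
        cols[drug] = np.fromiter((float(drug in s) for s in cases["suspected_drugs"]),
                                 dtype=float, count=len(cases))
    for cov in covariates:
        if cov == "female":
            sex = cases["sex"]
            v = np.where(sex == "female", 1.0,
                         np.where(sex == "male", 0.0, np.nan))
        else:
            v = cases[COVARIATE_COLUMNS[cov]].to_numpy(dtype=float)
        cols[cov] = v
    X = pd.DataFrame(cols)
    y = pd.Series(np.fromiter((bool(terms & s) for s in cases["events"]),
                              dtype=float, count=len(cases)), name="event")
    complete = ~X.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    X, y = X.loc[complete].reset_index(drop=True), y.loc[complete].reset_index(drop=True)
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise DegenerateDesignError(f"predictor {col!r} is constant on complete cases")
    if y.nunique() <= 1:
        raise DegenerateDesignError("outcome is constant on complete cases")
    return X, y, n_dropped


class LogisticRiskModel(BaseEstimator):
    """Maximum-likelihood logistic regression over the merged case table.

    Parameters
    ----------
    outcome_terms : str or iterable of str
        Preferred terms defining the outcome event.
    drug_terms : list of str
        Drugs entered as exposure indicators.
    covariates : sequence among {"female", "age", "height", "weight"}
    tol, max_iter : Newton convergence control.

    Attributes (after fit)
    ----------------------
    terms_, coef_, se_, pvalues_ : per-predictor arrays (intercept excluded
        from `terms_` ordering; see `summary_frame`).
    or_, or_ci_ : unit odds ratios exp(beta) and Wald 95% intervals.
    range_or_ : DataFrame of range odds ratios for continuous covariates.
    pseudo_r2_ : McFadden's 1 - logL/logL0.
    n_used_, n_dropped_, converged_, n_iter_
    """

    def __init__(self, outcome_terms, drug_terms, covariates=("female", "age", "height", "weight"),
                 tol: float = 1e-8, max_iter: int = 50):
        self.outcome_terms = outcome_terms
        self.drug_terms = drug_terms
        self.covariates = covariates
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, cases: pd.DataFrame, y=None):
        X, yy, n_dropped = build_design(cases, self.outcome_terms,
                                        self.drug_terms, self.covariates)
        self._fit_arrays(X, yy)
        self.n_dropped_ = n_dropped
        return self

    def _fit_arrays(self, X: pd.DataFrame, y: pd.Series):
        """Fit from a pre-built design matrix (no intercept column)."""
        Xc = sm.add_constant(X, has_constant="add")
        model = sm.Logit(y, Xc)
        converged = True
        try:
            res = model.fit(disp=0, method="newton",
                            maxiter=self.max_iter, tol=self.tol)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            warnings.warn("possible separation or non-convergence; "
                          "refitting with damped steps — estimates are provisional",
                          SeparationWarning)
            res = model.fit(disp=0, method="bfgs", maxiter=5 * self.max_iter)
            converged = False
        if not converged:
            warnings.warn("logistic fit did not converge", SeparationWarning)

        params = res.params
        self.result_ = res
        self.terms_ = [c for c in Xc.columns]
        self.coef_ = params.to_numpy()
        self.se_ = res.bse.to_numpy()
        self.pvalues_ = res.pvalues.to_numpy()
        self.or_ = np.exp(self.coef_)
        self.or_ci_ = np.exp(np.column_stack([
            self.coef_ - Z_95 * self.se_, self.coef_ + Z_95 * self.se_]))
        self.pseudo_r2_ = float(1.0 - res.llf / res.llnull)
        self.n_used_ = int(len(y))
        self.converged_ = converged
        self.n_iter_ = int(res.mle_retvals.get("iterations", -1)) \
            if hasattr(res, "mle_retvals") else -1
        self._X = X
        return self

    def summary_frame(self) -> pd.DataFrame:
        """Per-term odds ratios, intervals and p-values (intercept included)."""
        return pd.DataFrame({
            "term": self.terms_,
            "coef": self.coef_,
            "se": self.se_,
            "odds_ratio": self.or_,
            "ci_low": self.or_ci_[:, 0],
            "ci_high": self.or_ci_[:, 1],
            "p_value": self.pvalues_,
        })

    def range_odds_ratios(self) -> pd.DataFrame:
        """Odds ratios over each continuous covariate's observed span.

        Range OR = exp(beta * (max - min)); interval endpoints transform
        identically and are reported low-to-high. Zero-span terms are
        reported as missing.
        """
        rows = []
        for cov in self.covariates:
            if cov == "female" or cov not in self._X.columns:
                continue
            i = self.terms_.index(cov)
            span = float(self._X[cov].max() - self._X[cov].min())
            if span == 0:
                rows.append({"term": cov, "span": 0.0, "odds_ratio": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan,
                             "p_value": self.pvalues_[i]})
                continue
            lo = np.exp((self.coef_[i] - Z_95 * self.se_[i]) * span)
            hi = np.exp((self.coef_[i] + Z_95 * self.se_[i]) * span)
            rows.append({"term": cov, "span": span,
                         "odds_ratio": float(np.exp(self.coef_[i] * span)),
                         "ci_low": float(min(lo, hi)),
                         "ci_high": float(max(lo, hi)),
                         "p_value": self.pvalues_[i]})
        return pd.DataFrame(rows)


def fit(design: pd.DataFrame, outcome: pd.Series, tol: float = 1e-8,
        max_iter: int = 50) -> LogisticRiskModel:
    """Fit directly from a design matrix (thin functional wrapper)."""
    model = LogisticRiskModel(outcome_terms=(), drug_terms=(), covariates=(),
                              tol=tol, max_iter=max_iter)
    model._fit_arrays(design, outcome)
    model.n_dropped_ = 0
    return model
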