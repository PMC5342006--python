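"""Transferable marker-based risk models and concordance evaluation.

A proportional-hazards model is fitted on a training cohort over one or more
marker indicators, optionally with age and stage covariates.  The fitted
linear predictor transfers to validation cohorts as a per-subject risk
score, evaluated by (i) the hazard ratio of the score in a univariate Cox
fit on the validation outcomes and (ii) the Gönen–Heller concordance
probability estimate (CPE), a model-based concordance measure that is a
function of the scores alone and therefore unaffected by censoring:

    K = 2/(n(n-1)) * sum_{i<j} [ I(s_i >= s_j)/(1+exp(s_j-s_i))
                               + I(s_j > s_i)/(1+exp(s_i-s_j)) ]

K = 0.5 when all scores are equal (no discrimination) and approaches 1 for
strongly separated scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import CoxFit, _fit_cox, _check_survival, km_estimate, logrank_p

__all__ = ["RiskModel", "RiskEvaluation", "fit_risk_model", "predict_risk", "evaluate_risk", "cpe"]

COVARIATES = ("age_gt65", "stage_34")


@dataclass
class RiskModel:
    """Fitted proportional-hazards risk model over named design variables."""

    marker_names: list[str]
    with_covariates: bool
    coefficients: pd.Series
    training_cohort: str = ""
    fit: CoxFit | None = None

    @property
    def design(self) -> list[str]:
        return list(self.coefficients.index)

    def to_dict(self) -> dict:
        return {
            "marker_names": self.marker_names,
            "with_covariates": self.with_covariates,
            "coefficients": self.coefficients.to_dict(),
            "training_cohort": self.training_cohort,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        return cls(
            marker_names=list(d["marker_names"]),
            with_covariates=bool(d["with_covariates"]),
            coefficients=pd.Series(d["coefficients"], dtype=float),
            training_cohort=d.get("training_cohort", ""),
        )


@dataclass
class RiskEvaluation:
    """Transfer performance of a risk model on one validation cohort."""

    hr: float
    ci_lower: float
    ci_upper: float
    p_value: float
    cpe: float
    km_curves: dict = field(default_factory=dict)
    logrank_split_p: float = np.nan
    applicable: bool = True
    note: str = ""


def fit_risk_model(
    training: pd.DataFrame,
    markers: list[str],
    with_covariates: bool = False,
    cohort: str = "",
) -> RiskModel:
    """Fit a Cox model on training outcomes over marker indicators.

    ``training`` needs ``time``, ``event``, the marker indicator columns and,
    when ``with_covariates``, ``age_gt65`` and ``stage_34``.  A marker that
    is constant in the training cohort is a hard error: the model cannot be
    identified there.
    """
    _check_survival(training)
    design = list(markers) + (list(COVARIATES) if with_covariates else [])
    for v in design:
        if v not in training.columns:
            raise KeyError(f"design variable {v!r} missing from training data")
        if training[v].nunique() < 2:
            raise ValueError(f"design variable {v!r} is constant in the training cohort")
    fit = _fit_cox(training, design)
    return RiskModel(
        marker_names=list(markers),
        with_covariates=with_covariates,
        coefficients=fit.coefficients.copy(),
        training_cohort=cohort,
        fit=fit,
    )


def predict_risk(model: RiskModel, cohort: pd.DataFrame) -> pd.Series:
    """Per-subject risk score: the linear predictor Σ β·x of the model."""
    for v in model.design:
        if v not in cohort.columns:
            raise KeyError(f"design variable {v!r} missing from cohort")
    X = cohort[model.design].to_numpy(dtype=float)
    return pd.Series(X @ model.coefficients.to_numpy(), index=cohort.index, name="risk")


def cpe(scores) -> float:
    """Gönen–Heller concordance probability estimate from risk scores.

    Model-based: depends only on the fitted linear predictors, so censoring
    in the validation outcomes does not enter.  0.5 means no discrimination.
    """
    s = np.asarray(scores, dtype=float)
    n = s.size
    if n < 2:
        raise ValueError("CPE needs at least two subjects")
    diff = s[:, None] - s[None, :]  # diff[i, j] = s_i - s_j
    iu, ju = np.triu_indices(n, k=1)
    d = diff[iu, ju]
    term = np.where(d >= 0, 1.0 / (1.0 + np.exp(-d)), 0.0) + np.where(
        d < 0, 1.0 / (1.0 + np.exp(d)), 0.0
    )
    # ties (d == 0) contribute 1/2 through the first term
    return float(2.0 / (n * (n - 1)) * term.sum())


def evaluate_risk(scores: pd.Series, validation: pd.DataFrame) -> RiskEvaluation:
    """Evaluate transferred risk scores on a validation cohort.

    Fits outcome ~ score by univariate Cox (HR per unit of linear
    predictor, Wald 95% CI and p), computes the CPE of the scores, and
    derives Kaplan–Meier curves for a median split of the scores (ties to
    the low-risk group).  Constant scores make the evaluation
    not-applicable.
    """
    _check_survival(validation)
    s = scores.reindex(validation.index)
    if s.isna().any():
        raise ValueError("scores missing for some validation subjects")
    if s.nunique() < 2:
        return RiskEvaluation(
            hr=np.nan,
            ci_lower=np.nan,
            ci_upper=np.nan,
            p_value=np.nan,
            cpe=0.5,
            applicable=False,
            note="constant risk scores; model not applicable to this cohort",
        )
    df = validation[["time", "event"]].copy()
    df["risk"] = s
    fit = _fit_cox(df, ["risk"])
    k = cpe(s.to_numpy())
    high = (s > s.median()).astype(int).to_numpy()
    times = df["time"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)
    curves = km_estimate(times, events, high)
    if 0 < high.sum() < len(high):
        _, lr_p = logrank_p(times, events, high)
    else:
        lr_p = np.nan
    return RiskEvaluation(
        hr=float(fit.hazard_ratios.iloc[0]),
        ci_lower=float(fit.ci_lower.iloc[0]),
        ci_upper=float(fit.ci_upper.iloc[0]),
        p_value=float(fit.p_values.iloc[0]),
        cpe=k,
        km_curves=curves,
        logrank_split_p=lr_p,
    )
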