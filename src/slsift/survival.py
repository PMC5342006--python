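"""Survival-marker evaluation: Kaplan–Meier, log-rank, Cox and VIF.

Marker indicators (IHC abnormality calls or fold-change rules on expression)
are evaluated against overall survival with the product-limit estimator, the
Mantel–Haenszel log-rank test, univariate Cox proportional-hazards models,
and multivariate Cox models with bidirectional stepwise selection under AIC.
Variance inflation factors flag collinear indicator sets; ties in event
times use the Efron approximation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "km_estimate",
    "logrank_p",
    "cox_univariate",
    "cox_multivariate_stepwise",
    "vif",
    "ExpressionMarkerRule",
    "expression_marker_indicator",
    "CoxFit",
]


def km_estimate(times, events, group_labels=None) -> dict:
    """Kaplan–Meier survival curves, one per group.

    Returns ``{group: DataFrame(time, survival)}``; the curve starts at 1,
    is non-increasing, and steps only at observed event times.  With no
    events the curve stays flat at 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if group_labels is None:
        group_labels = np.zeros(len(times), dtype=int)
    group_labels = np.asarray(group_labels)
    curves = {}
    for g in np.unique(group_labels):
        mask = group_labels == g
        if not mask.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return curves


def logrank_p(times, events, group_labels) -> tuple[float, float]:
    """Mantel–Haenszel log-rank test between survival curves.

    Returns ``(chi-square statistic, p-value)``; the statistic has k−1
    degrees of freedom for k groups.  Every group must be non-empty.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group_labels = np.asarray(group_labels)
    groups, counts = np.unique(group_labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")
    res = multivariate_logrank_test(times, group_labels, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """A fitted proportional-hazards model over named indicators/covariates."""

    variables: list[str]
    coefficients: pd.Series
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p_values: pd.Series
    aic: float
    log_likelihood: float
    selection_trace: list[tuple[str, str, float]] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p_values,
            }
        )


def _fit_cox(df: pd.DataFrame, variables: list[str]) -> CoxFit:
    cph = CoxPHFitter()
    if variables:
        cph.fit(
            df[["time", "event", *variables]],
            duration_col="time",
            event_col="event",
        )
        s = cph.summary
        return CoxFit(
            variables=list(variables),
            coefficients=s["coef"].copy(),
            hazard_ratios=s["exp(coef)"].copy(),
            ci_lower=np.exp(s["coef lower 95%"]).copy(),
            ci_upper=np.exp(s["coef upper 95%"]).copy(),
            p_values=s["p"].copy(),
            aic=float(cph.AIC_partial_),
            log_likelihood=float(cph.log_likelihood_),
        )
    # null model: no covariates, AIC = -2 * log partial likelihood of the
    # empty linear predictor
    ll = _null_partial_loglik(df["time"].to_numpy(), df["event"].to_numpy())
    empty = pd.Series(dtype=float)
    return CoxFit([], empty, empty, empty, empty, empty, -2.0 * ll, ll)


def _null_partial_loglik(times: np.ndarray, events: np.ndarray) -> float:
    """Efron/Breslow-identical null partial log-likelihood (β = 0)."""
    order = np.argsort(times, kind="mergesort")
    t, e = times[order], events[order]
    ll = 0.0
    n = len(t)
    for utime in np.unique(t[e == 1]):
        d = int(((t == utime) & (e == 1)).sum())
        at_risk = int((t >= utime).sum())
        # at beta=0 the Efron denominator for the j-th of d deaths is at_risk - j
        for j in range(d):
            ll -= np.log(at_risk - j)
    return ll


def cox_univariate(dataset: pd.DataFrame, variable: str) -> CoxFit:
    """Univariate Cox proportional-hazards fit for one named indicator.

    ``dataset`` needs columns ``time``, ``event`` and the variable.  The
    variable must vary across subjects and the data must contain events.
    """
    _check_survival(dataset)
    if dataset[variable].nunique() < 2:
        raise ValueError(f"variable {variable!r} is constant in the data")
    return _fit_cox(dataset, [variable])


def cox_multivariate_stepwise(
    dataset: pd.DataFrame, candidates: list[str], criterion: str = "AIC"
) -> CoxFit:
    """Bidirectional stepwise Cox model selection under AIC.

    Starts from the full candidate model and, at each step, applies the
    single add-or-drop move that most reduces AIC, stopping when no move
    improves it.  Returns the final fit with the selection trace
    (``(action, variable, AIC)`` triples).
    """
    if criterion != "AIC":
        raise ValueError("only AIC selection is supported")
    _check_survival(dataset)
    candidates = list(candidates)
    current = [v for v in candidates if dataset[v].nunique() > 1]
    best = _fit_cox(dataset, current)
    trace = [("start", "+".join(current) or "<null>", best.aic)]
    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, str, str, list[str]]] = []
        for v in current:
            trial = [w for w in current if w != v]
            fit = _fit_cox(dataset, trial)
            moves.append((fit.aic, "drop", v, trial))
        for v in candidates:
            if v not in current and dataset[v].nunique() > 1:
                trial = current + [v]
                fit = _fit_cox(dataset, trial)
                moves.append((fit.aic, "add", v, trial))
        if moves:
            moves.sort(key=lambda m: m[0])
            best_aic, action, var, trial = moves[0]
            if best_aic < best.aic - 1e-9:
                current = trial
                best = _fit_cox(dataset, current)
                trace.append((action, var, best.aic))
                improved = True
    best.selection_trace = trace
    return best


def vif(indicator_matrix: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 − R²) with intercept.

    Perfectly collinear columns report +inf.
    """
    X = indicator_matrix.to_numpy(dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("VIF needs at least two variables")
    if n <= k:
        raise ValueError("VIF needs more observations than variables")
    out = {}
    for j, name in enumerate(indicator_matrix.columns):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass(frozen=True)
class ExpressionMarkerRule:
    """Fold-change rule flagging subjects by directional over/under-expression.

    ``genes`` and ``directions`` run in parallel; direction ``"up"`` requires
    expression ≥ cutoff × reference, ``"down"`` requires ≤ reference/cutoff
    (boundaries inclusive).  ``fold_cutoffs`` may carry per-gene overrides;
    the default cutoff applies otherwise.  ``reference`` chooses the
    comparison baseline: ``"matched-normal"`` consumes precomputed log2
    tumor/normal ratios; ``"cohort-median"`` divides by the per-gene cohort
    median of absolute expression.
    """

    genes: tuple[str, ...]
    directions: tuple[str, ...]
    fold_cutoff: float = 2.0
    fold_cutoffs: dict = field(default_factory=dict)
    reference: str = "matched-normal"

    def __post_init__(self):
        if len(self.genes) != len(self.directions):
            raise ValueError("genes and directions must align")
        if not all(d in ("up", "down") for d in self.directions):
            raise ValueError("directions must be 'up' or 'down'")
        cuts = [self.fold_cutoffs.get(g, self.fold_cutoff) for g in self.genes]
        if any(c <= 1 for c in cuts):
            raise ValueError("fold cutoffs must exceed 1")
        if self.reference not in ("matched-normal", "cohort-median"):
            raise ValueError("reference must be 'matched-normal' or 'cohort-median'")

    def cutoff_for(self, gene: str) -> float:
        return float(self.fold_cutoffs.get(gene, self.fold_cutoff))

    @property
    def name(self) -> str:
        arrow = {"up": "↑", "down": "↓"}
        return "-".join(f"{g}{arrow[d]}" for g, d in zip(self.genes, self.directions))


def expression_marker_indicator(
    expression: pd.DataFrame, rule: ExpressionMarkerRule
) -> pd.Series:
    """Per-subject 0/1 indicator for a fold-change marker rule.

    With ``reference="matched-normal"`` the input is a subject × gene table
    of log2 tumor/normal ratios; with ``"cohort-median"`` it is absolute
    expression, referenced to the per-gene cohort median.  A subject is
    flagged iff every gene in the rule passes its directional cutoff.
    """
    for g in rule.genes:
        if g not in expression.columns:
            raise KeyError(f"gene {g!r} not in expression table")
    if rule.reference == "matched-normal":
        logr = expression[list(rule.genes)]
    else:
        sub = expression[list(rule.genes)]
        med = sub.median(axis=0)
        if (med <= 0).any():
            raise ValueError("cohort-median reference needs positive expression")
        logr = np.log2(sub) - np.log2(med)
    flag = pd.Series(True, index=expression.index)
    for g, d in zip(rule.genes, rule.directions):
        t = np.log2(rule.cutoff_for(g))
        if d == "up":
            flag &= logr[g] >= t
        else:
            flag &= logr[g] <= -t
    return flag.astype(int)


def _check_survival(dataset: pd.DataFrame) -> None:
    if not {"time", "event"} <= set(dataset.columns):
        raise ValueError("dataset needs 'time' and 'event' columns")
    if (dataset["time"] < 0).any():
        raise ValueError("negative survival time")
    if dataset["event"].sum() == 0:
        raise ValueError("dataset contains no events")
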