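"""Multivariable Cox proportional-hazards modelling of overall survival.

Provides the adjusted per-ELN hazard-ratio machinery: a Cox fit wrapper
(Efron tie handling through lifelines by default, with an internal
Breslow-ties Newton solver as the alternative), per-ELN-count hazard-ratio
sequences against a reference count, scaled-Schoenfeld proportional-hazards
diagnostics, reverse Kaplan-Meier follow-up, and stratified subgroup
re-fits that report non-estimable strata as "NE" instead of raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from ._design import (
    SURVIVAL_ADJUSTMENT,
    EstimationError,
    build_design,
    eln_level_design,
    modal_eln,
)
from .stage_migration import EffectEstimate, EffectSequence, _sequence_from_fit

__all__ = [
    "CoxFit",
    "PHDiagnostic",
    "fit_cox",
    "fit_eln_cox",
    "estimate_hr_sequence",
    "test_ph_assumption",
    "reverse_km_median_followup",
    "subgroup_analysis",
    "evaluate_partial_loglik",
    "SURVIVAL_ADJUSTMENT",
]


class DomainError(ValueError):
    pass


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``coefficients`` maps design-column name to ``(log HR, se)``; the
    baseline cumulative hazard is the Breslow-type estimator at the MLE
    with covariates on their design scale (uncentred dummies).
    """

    coefficients: dict
    ties_method: str
    log_partial_likelihood: float
    baseline_cumulative_hazard: pd.Series
    n: int
    n_events: int
    design_columns: list = field(default_factory=list)
    _design: pd.DataFrame | None = None
    _durations: np.ndarray | None = None
    _events: np.ndarray | None = None
    _cph: object | None = None

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coefficients[c][0] for c in self.design_columns])

    def effect(self, name: str, label: str = "") -> EffectEstimate:
        b, se = self.coefficients[name]
        return EffectEstimate(
            scale="hazard ratio", log_point=b, se_log=se, n_used=self.n, label=label or name
        )

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.design_columns].to_numpy(float) @ self.beta

    def predict_survival(self, X: pd.DataFrame, times: np.ndarray) -> np.ndarray:
        """Survival matrix (len(times) x len(X)) from the Breslow baseline."""
        H0 = _step_interp(self.baseline_cumulative_hazard, np.asarray(times, float))
        risk = np.exp(self.linear_predictor(X))
        return np.exp(-np.outer(H0, risk))


@dataclass
class PHDiagnostic:
    """Scaled-Schoenfeld proportional-hazards test results."""

    per_covariate: pd.DataFrame  # index covariate; columns chi2, p
    global_chi2: float
    global_p: float
    time_transform: str = "km"


def _step_interp(series: pd.Series, times: np.ndarray) -> np.ndarray:
    """Right-continuous step-function interpolation of a cumulative hazard."""
    x = series.index.to_numpy(float)
    y = series.to_numpy(float)
    idx = np.searchsorted(x, times, side="right") - 1
    out = np.where(idx >= 0, y[np.clip(idx, 0, len(y) - 1)], 0.0)
    return out


def _prepare(cohort: pd.DataFrame, covariates, duration_col, event_col):
    for cov in covariates:
        if cov not in cohort.columns:
            raise EstimationError(f"covariate {cov!r} not in cohort")
        if cohort[cov].nunique(dropna=False) <= 1:
            raise EstimationError(f"covariate {cov!r} is constant")
    X = build_design(cohort, covariates)
    T = pd.to_numeric(cohort[duration_col], errors="coerce").to_numpy(float)
    E = pd.to_numeric(cohort[event_col], errors="coerce").to_numpy(float).astype(int)
    if E.sum() < 1:
        raise EstimationError("no events in cohort")
    return X, T, E


def _breslow_baseline(X, T, E, beta) -> pd.Series:
    lp = X.to_numpy(float) @ beta
    w = np.exp(lp)
    order = np.argsort(T, kind="stable")
    Ts, Es, ws = T[order], E[order], w[order]
    # risk set = all with time >= t (event-before-censoring at ties)
    rev_cum = np.cumsum(ws[::-1])[::-1]
    uniq, idx0 = np.unique(Ts, return_index=True)
    H, times = [], []
    h = 0.0
    for t, i0 in zip(uniq, idx0):
        block = slice(i0, i0 + np.searchsorted(Ts[i0:], t, side="right"))
        d = Es[block].sum()
        if d > 0:
            h += d / rev_cum[i0]
            times.append(t)
            H.append(h)
    return pd.Series(H, index=pd.Index(times, name="time"), name="cumhaz")


def evaluate_partial_loglik(X, T, E, beta, ties_method: str = "efron") -> float:
    """Cox partial log-likelihood at an arbitrary coefficient vector.

    Used as an independent check that fitted coefficients maximise the
    objective; supports Efron and Breslow tie corrections.
    """
    Xa = np.asarray(X, float)
    beta = np.asarray(beta, float)
    T = np.asarray(T, float)
    E = np.asarray(E, int)
    lp = Xa @ beta
    w = np.exp(lp)
    order = np.argsort(T, kind="stable")
    Ts, Es, ws, lps = T[order], E[order], w[order], lp[order]
    rev_cum = np.concatenate([np.cumsum(ws[::-1])[::-1], [0.0]])
    ll = 0.0
    uniq, idx0 = np.unique(Ts, return_index=True)
    for t, i0 in zip(uniq, idx0):
        i1 = i0 + np.searchsorted(Ts[i0:], t, side="right")
        ev = Es[i0:i1].astype(bool)
        d = int(ev.sum())
        if d == 0:
            continue
        ll += lps[i0:i1][ev].sum()
        s0 = rev_cum[i0]
        s0_tie = ws[i0:i1][ev].sum()
        if ties_method == "breslow":
            ll -= d * np.log(s0)
        else:
            for l in range(d):
                ll -= np.log(s0 - (l / d) * s0_tie)
    return float(ll)


def _cox_score_info(Xs, Es, blocks, beta, ties_method):
    """Partial log-likelihood, score and information at ``beta``.

    ``Xs``/``Es`` are sorted by time; ``blocks`` delimit tie groups.  Risk
    sets are accumulated from the largest time downwards, with the Efron
    within-tie denominators where requested.
    """
    p = Xs.shape[1]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _score_info_core(Xs, Es, blocks, beta, ties_method, p)


def _score_info_core(Xs, Es, blocks, beta, ties_method, p):
    w = np.exp(Xs @ beta)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))
    for i0, i1 in reversed(blocks):
        xb, wb = Xs[i0:i1], w[i0:i1]
        S0 += wb.sum()
        S1 += wb @ xb
        S2 += (xb * wb[:, None]).T @ xb
        ev = Es[i0:i1].astype(bool)
        d = int(ev.sum())
        if d == 0:
            continue
        xe = xb[ev]
        ll += float((xe @ beta).sum())
        grad += xe.sum(axis=0)
        if ties_method == "efron" and d > 1:
            we = wb[ev]
            S0t = we.sum()
            S1t = we @ xe
            S2t = (xe * we[:, None]).T @ xe
            for l in range(d):
                c = l / d
                denom = S0 - c * S0t
                m = (S1 - c * S1t) / denom
                ll -= np.log(denom)
                grad -= m
                info += (S2 - c * S2t) / denom - np.outer(m, m)
        else:
            m = S1 / S0
            ll -= d * np.log(S0)
            grad -= d * m
            info += d * (S2 / S0 - np.outer(m, m))
    return ll, grad, info


def _cox_newton(X: pd.DataFrame, T, E, ties_method: str = "efron", tol: float = 1e-8, maxiter: int = 50):
    """Newton-Raphson maximiser of the Cox partial likelihood.

    Step-halving keeps the likelihood monotone; a ridge rescue handles
    transient singular information (for example, a dummy covariate whose
    coefficient wanders far before the rest settle).
    """
    Xa = X.to_numpy(float)
    n, p = Xa.shape
    order = np.argsort(T, kind="stable")
    Xs, Ts, Es = Xa[order], np.asarray(T, float)[order], np.asarray(E, int)[order]
    uniq, idx0 = np.unique(Ts, return_index=True)
    blocks = list(zip(idx0, np.append(idx0[1:], n)))
    beta = np.zeros(p)
    ll, grad, info = _cox_score_info(Xs, Es, blocks, beta, ties_method)
    for _ in range(maxiter):
        ridge = 0.0
        while True:
            try:
                step = np.linalg.solve(info + ridge * np.eye(p), grad)
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10, 1e-6 * max(np.abs(np.diag(info)).max(), 1.0))
                if ridge > 1e12:
                    raise EstimationError("singular information matrix in Cox fit")
        # trust region: a Newton step for a near-separated dummy level can
        # overshoot into exp() overflow territory
        big = np.max(np.abs(step))
        if big > 2.0:
            step = step * (2.0 / big)
        # step-halving line search on the partial likelihood
        accepted = False
        for _half in range(40):
            ll_new, grad_new, info_new = _cox_score_info(Xs, Es, blocks, beta + step, ties_method)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12 * abs(ll):
                accepted = True
                break
            step = step / 2
        if not accepted:
            break  # no ascent direction left; convergence checked below
        beta = beta + step
        ll, grad, info = ll_new, grad_new, info_new
        if np.max(np.abs(grad)) <= tol * (1.0 + abs(ll)):
            break
    else:
        if np.max(np.abs(grad)) > 1e-3 * (1.0 + abs(ll)):
            raise EstimationError("Cox fit did not converge")
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return beta, se, float(ll)


def _fit_breslow(X: pd.DataFrame, T, E, tol=1e-8, maxiter=50):
    return _cox_newton(X, T, E, ties_method="breslow", tol=tol, maxiter=maxiter)


def fit_cox(
    cohort: pd.DataFrame,
    covariates,
    ties_method: str = "efron",
    duration_col: str = "survival_months",
    event_col: str = "death",
) -> CoxFit:
    """Fit a multivariable Cox PH model.

    Categorical covariates are dummy-coded against their first observed
    level; a constant covariate or a cohort with zero events raises an
    :class:`EstimationError` naming the problem.
    """
    X, T, E = _prepare(cohort, covariates, duration_col, event_col)
    cph = None
    if ties_method == "efron":
        df = X.copy()
        df["_T"], df["_E"] = T, E
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cph.fit(df, duration_col="_T", event_col="_E")
            except Exception as exc:  # lifelines raises ConvergenceError subclasses
                raise EstimationError(f"Cox fit failed: {exc}") from exc
        beta = cph.params_.to_numpy()
        se = cph.standard_errors_.to_numpy()
        ll = float(cph.log_likelihood_)
    elif ties_method == "breslow":
        beta, se, ll = _fit_breslow(X, T, E)
    else:
        raise ValueError(f"unknown ties_method {ties_method!r}")

    coeffs = {c: (float(b), float(s)) for c, b, s in zip(X.columns, beta, se)}
    return CoxFit(
        coefficients=coeffs,
        ties_method=ties_method,
        log_partial_likelihood=ll,
        baseline_cumulative_hazard=_breslow_baseline(X, T, E, beta),
        n=len(X),
        n_events=int(E.sum()),
        design_columns=list(X.columns),
        _design=X,
        _durations=T,
        _events=E,
        _cph=cph,
    )


def fit_eln_cox(
    cohort: pd.DataFrame, adjustment_set=SURVIVAL_ADJUSTMENT, ties_method: str = "efron"
) -> tuple[CoxFit, EffectEstimate]:
    """Adjusted hazard ratio per additional examined node (ELN continuous)."""
    fit = fit_cox(cohort, ["eln"] + list(adjustment_set), ties_method=ties_method)
    return fit, fit.effect("eln", "overall survival, per additional ELN")


def estimate_hr_sequence(
    cohort: pd.DataFrame,
    adjustment_set=SURVIVAL_ADJUSTMENT,
    reference_eln="modal",
    min_count_per_level: int = 5,
    ties_method: str = "efron",
) -> EffectSequence:
    """Adjusted hazard ratio for each ELN count level against a reference.

    Mirrors :func:`elnthresh.stage_migration.estimate_or_sequence` with the
    Cox model in place of the logistic model; the adjustment set includes
    the positive-node count by default.
    """
    if reference_eln == "modal":
        reference_eln = modal_eln(cohort)
    reference_eln = int(reference_eln)
    subset, dummies, levels, omitted = eln_level_design(
        cohort, reference_eln, min_count_per_level, estimable="events"
    )
    X = pd.concat([dummies, build_design(subset, adjustment_set)], axis=1)
    T = subset["survival_months"].to_numpy(float)
    E = subset["death"].to_numpy(int)
    if E.sum() < 1:
        raise EstimationError("no events in cohort")
    beta, se, _ = _cox_newton(X, T, E, ties_method=ties_method)
    params = pd.Series(beta, index=X.columns)
    bses = pd.Series(se, index=X.columns)
    n_used = len(X)
    return _sequence_from_fit(
        subset, params, bses, n_used, levels, omitted, reference_eln,
        scale="hazard ratio", adjustment_set=list(adjustment_set),
        min_count_per_level=min_count_per_level,
    )


def test_ph_assumption(fit: CoxFit, time_transform: str = "km") -> PHDiagnostic:
    """Scaled-Schoenfeld residuals test of the PH assumption.

    Per-covariate chi-square tests correlate each covariate's scaled
    Schoenfeld residuals with a transform of event time (Kaplan-Meier
    transform by default; ``"identity"``, ``"log"`` and ``"rank"`` are
    accepted); the global test is the joint score test over all
    covariates.
    """
    if fit.n_events < 2:
        raise DomainError("PH diagnostic requires at least 2 events")
    train = fit._design.copy()
    train["_T"], train["_E"] = fit._durations, fit._events
    cph = fit._cph
    if cph is None:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(train, duration_col="_T", event_col="_E")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = proportional_hazard_test(cph, train, time_transform=time_transform)
    summ = res.summary.reset_index()
    # lifelines indexes by (covariate, transform)
    cov_col = summ.columns[0]
    per = pd.DataFrame(
        {
            "chi2": summ["test_statistic"].to_numpy(float),
            "p": summ["p"].to_numpy(float),
        },
        index=summ[cov_col].astype(str).to_list(),
    )

    # Grambsch-Therneau global test: joint score statistic over covariates
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sch = cph.compute_residuals(train, kind="schoenfeld")
    # residual rows are the event records, indexed by original row label
    times = train.loc[sch.index, "_T"].to_numpy(float)
    g = _transform_times(times, fit, time_transform)
    ghat = g - g.mean()
    S = sch.to_numpy(float)
    z = ghat @ S
    m = S.shape[0]
    V = cph.variance_matrix_.to_numpy(float)
    denom = float((ghat**2).sum())
    chi2 = float(m / denom * z @ V @ z)
    p = float(stats.chi2.sf(chi2, df=S.shape[1]))
    return PHDiagnostic(per_covariate=per, global_chi2=chi2, global_p=p, time_transform=time_transform)


def _transform_times(times, fit, transform):
    if transform == "identity":
        return times.astype(float)
    if transform == "log":
        return np.log(times.astype(float))
    if transform == "rank":
        return stats.rankdata(times).astype(float)
    # Kaplan-Meier transform: 1 - KM estimate of the censoring-ignored
    # event-time distribution evaluated at the event times
    kmf = KaplanMeierFitter().fit(fit._durations, fit._events)
    surv = kmf.survival_function_["KM_estimate"]
    return 1.0 - _km_at(surv, times)


def _km_at(surv: pd.Series, times: np.ndarray) -> np.ndarray:
    x = surv.index.to_numpy(float)
    y = surv.to_numpy(float)
    idx = np.searchsorted(x, times, side="right") - 1
    return np.where(idx >= 0, y[np.clip(idx, 0, len(y) - 1)], 1.0)


def reverse_km_median_followup(times, events) -> float:
    """Median follow-up by the reverse Kaplan-Meier method.

    Censoring is treated as the event and death as censoring; an undefined
    median (the reverse curve never reaches 0.5) returns ``nan``.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise DomainError("no records")
    if np.any(times <= 0):
        raise DomainError("follow-up times must be positive")
    kmf = KaplanMeierFitter().fit(times, 1 - events)
    med = kmf.median_survival_time_
    return float(med) if np.isfinite(med) else float("nan")


def subgroup_analysis(
    cohort: pd.DataFrame,
    by: str | None,
    estimator,
    adjustment_set,
    min_stratum: int = 2,
) -> pd.DataFrame:
    """Refit an effect within each category of a stratifying covariate.

    ``estimator(sub_cohort, adjustment_set)`` must return an
    :class:`EffectEstimate`.  The stratifying covariate is removed from
    the adjustment set before refitting.  Strata where estimation fails
    (too few cases, no events, separation) are reported as ``NE`` with the
    reason, never raised.  ``by=None`` evaluates the entire cohort as a
    single stratum.
    """
    if by is not None and by not in cohort.columns:
        raise DomainError(f"stratification covariate {by!r} not in cohort")
    adj = [a for a in adjustment_set if a != by]
    if by is None:
        strata = [("overall", cohort)]
    else:
        col = cohort[by]
        if isinstance(col.dtype, pd.CategoricalDtype):
            cats = [c for c in col.cat.categories]
        else:
            cats = sorted(col.dropna().unique())
        strata = [(str(c), cohort[col == c]) for c in cats]
    rows = []
    for name, sub in strata:
        base = {"stratum": name, "n": len(sub)}
        if len(sub) < min_stratum:
            rows.append({**base, "estimate": "NE", "note": "too few cases"})
            continue
        try:
            est = estimator(sub.reset_index(drop=True), adj)
            rows.append(
                {
                    **base,
                    "estimate": est.point,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p": est.p_value,
                    "note": "",
                }
            )
        except Exception as exc:
            rows.append({**base, "estimate": "NE", "note": str(exc)})
    return pd.DataFrame(rows)
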