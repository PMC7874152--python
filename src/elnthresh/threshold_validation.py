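"""Validation of a candidate examined-lymph-node threshold.

A candidate threshold t is validated by dichotomizing the cohort at
ELN >= t and asking whether examining at least t nodes is independently
associated with (i) better overall survival (multivariable Cox model),
(ii) higher declared nodal stages (proportional-odds migration model),
and (iii) useful discrimination of survival (time-dependent ROC of the
multivariable Cox risk score incorporating the dichotomized ELN term).

Adjusted survival curves use the corrected-group-prognosis method: the
model-predicted curve is averaged over every patient's covariates with
the group indicator fixed, separately for each group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from ._design import SURVIVAL_ADJUSTMENT, EstimationError
from .stage_migration import MIGRATION_ADJUSTMENT, EffectEstimate, _fit_ordinal
from .staging import NODAL_STAGES
from .survival_models import CoxFit, fit_cox, subgroup_analysis

__all__ = [
    "ThresholdValidation",
    "TimeDependentAUCResult",
    "dichotomize_and_fit",
    "adjusted_survival_curves",
    "time_dependent_auc",
]

GROUP_COL = "eln_ge_threshold"


class DomainError(ValueError):
    pass


@dataclass
class ThresholdValidation:
    """Dichotomized-threshold validation bundle."""

    threshold: int
    hr_above_vs_below: EffectEstimate
    or_migration_above_vs_below: EffectEstimate
    n_above: int
    n_below: int
    cox_fit: CoxFit
    adjusted_curves: pd.DataFrame | None = None  # columns: time, below, above
    subgroup_table: pd.DataFrame | None = None
    auc: "TimeDependentAUCResult | None" = None

    def to_dict(self) -> dict:
        out = {
            "threshold": self.threshold,
            "n_above": self.n_above,
            "n_below": self.n_below,
            "hr_above_vs_below": self.hr_above_vs_below.to_dict(),
            "or_migration_above_vs_below": self.or_migration_above_vs_below.to_dict(),
        }
        if self.auc is not None:
            out["iauc"] = self.auc.iauc
        return out


@dataclass
class TimeDependentAUCResult:
    """Incident/dynamic (or cumulative/dynamic) AUC(t) and integrated AUC."""

    time_grid: np.ndarray
    auc_t: np.ndarray
    iauc: float
    weighting: str
    n_events_used: int
    variant: str = "incident"


def dichotomize_and_fit(
    cohort: pd.DataFrame,
    threshold: int,
    survival_adjustment=SURVIVAL_ADJUSTMENT,
    migration_adjustment=MIGRATION_ADJUSTMENT,
    subgroup_by: list | None = None,
    with_curves: bool = True,
    with_auc: bool = True,
    auc_variant: str = "incident",
    horizon_pct: float = 95.0,
) -> ThresholdValidation:
    """Validate one ELN threshold on a cohort.

    The indicator ELN >= threshold replaces continuous ELN in both the
    Cox and the ordinal migration model.  Raises a :class:`DomainError`
    naming the threshold when either side of the dichotomy is empty.
    """
    work = cohort.copy().reset_index(drop=True)
    ind = (work["eln"] >= threshold).astype(float)
    if ind.sum() == 0 or ind.sum() == len(ind):
        raise DomainError(
            f"threshold {threshold} leaves an empty ELN group "
            f"(observed range {int(work['eln'].min())}-{int(work['eln'].max())})"
        )
    work[GROUP_COL] = ind

    fit = fit_cox(work, [GROUP_COL] + list(survival_adjustment))
    hr = fit.effect(GROUP_COL, f"ELN >= {threshold} vs < {threshold}")

    from ._design import build_design  # local import to avoid cycle noise

    stage = pd.Categorical(work["n_stage"], categories=NODAL_STAGES, ordered=True)
    present = [s for i, s in enumerate(NODAL_STAGES) if (np.asarray(stage.codes) == i).any()]
    compact = pd.Categorical(stage.astype(str), categories=present, ordered=True)
    X = build_design(work, migration_adjustment)
    X.insert(0, GROUP_COL, ind)
    or_mig = _fit_ordinal(np.asarray(compact.codes), X, GROUP_COL)
    or_mig.label = f"higher declared stage, ELN >= {threshold} vs < {threshold}"

    result = ThresholdValidation(
        threshold=int(threshold),
        hr_above_vs_below=hr,
        or_migration_above_vs_below=or_mig,
        n_above=int(ind.sum()),
        n_below=int(len(ind) - ind.sum()),
        cox_fit=fit,
    )
    if with_curves:
        result.adjusted_curves = adjusted_survival_curves(fit, work, GROUP_COL)
    if subgroup_by:
        def _estimator(sub, adj):
            sfit = fit_cox(sub, [GROUP_COL] + list(adj))
            return sfit.effect(GROUP_COL)

        tables = []
        for cov in subgroup_by:
            tab = subgroup_analysis(work, cov, _estimator, survival_adjustment)
            tab.insert(0, "stratified_by", cov)
            tables.append(tab)
        result.subgroup_table = pd.concat(tables, ignore_index=True)
    if with_auc:
        risk = fit.linear_predictor(fit._design)
        horizon = float(np.percentile(work["survival_months"], horizon_pct))
        result.auc = time_dependent_auc(
            work, risk, horizon=horizon, variant=auc_variant
        )
    return result


def adjusted_survival_curves(fit: CoxFit, cohort: pd.DataFrame, group_col: str) -> pd.DataFrame:
    """Corrected-group-prognosis adjusted survival curves.

    For each group value g, every patient's covariate vector is scored
    with the indicator set to g and the model-predicted survival curves
    are averaged; the result is one adjusted curve per group on the
    event-time grid.  Curves start at 1 and are non-increasing.
    """
    if group_col not in fit.design_columns:
        raise DomainError(f"group indicator {group_col!r} is not in the fitted model")
    X = fit._design.copy()
    times = np.concatenate([[0.0], fit.baseline_cumulative_hazard.index.to_numpy(float)])
    out = {"time": times}
    for g, name in ((0.0, "below"), (1.0, "above")):
        Xg = X.copy()
        Xg[group_col] = g
        surv = _mean_survival(fit, Xg, times)
        out[name] = surv
    return pd.DataFrame(out)


def _mean_survival(fit: CoxFit, X: pd.DataFrame, times: np.ndarray, chunk: int = 2000) -> np.ndarray:
    from .survival_models import _step_interp

    H0 = _step_interp(fit.baseline_cumulative_hazard, times)
    risk = np.exp(fit.linear_predictor(X))
    total = np.zeros(len(times))
    for i in range(0, len(risk), chunk):
        total += np.exp(-np.outer(H0, risk[i : i + chunk])).sum(axis=1)
    return total / len(risk)


def time_dependent_auc(
    cohort: pd.DataFrame,
    risk_scores,
    time_grid=None,
    horizon: float | None = None,
    variant: str = "incident",
    duration_col: str = "survival_months",
    event_col: str = "death",
) -> TimeDependentAUCResult:
    """Time-dependent ROC AUC of a survival risk score.

    ``variant="incident"`` (incident cases / dynamic controls): AUC(t) is
    the probability that a subject failing exactly at t carries a higher
    score than a subject still at risk beyond t; ``"cumulative"`` takes
    cases as all failures up to t.  Tied scores contribute 1/2.  The
    integrated AUC is the weighted average over the event-time grid with
    weights proportional to 2*f(t)*S(t), both estimated from the
    Kaplan-Meier curve of the event-time distribution, normalised to sum
    to one.
    """
    T = np.asarray(cohort[duration_col], float)
    E = np.asarray(cohort[event_col], int)
    score = np.asarray(risk_scores, float)
    if not np.all(np.isfinite(score)):
        raise DomainError("risk scores must be finite")
    if horizon is None:
        horizon = float(np.percentile(T, 95.0))
    if time_grid is None:
        time_grid = np.unique(T[(E == 1) & (T <= horizon)])
    time_grid = np.asarray(time_grid, float)
    if len(time_grid) == 0:
        raise DomainError("no events before the horizon")

    aucs = np.empty(len(time_grid))
    for i, t in enumerate(time_grid):
        if variant == "incident":
            case = (T == t) & (E == 1)
        elif variant == "cumulative":
            case = (T <= t) & (E == 1)
        else:
            raise ValueError(f"unknown AUC variant {variant!r}")
        control = T > t
        sc, sn = score[case], score[control]
        if len(sc) == 0 or len(sn) == 0:
            aucs[i] = np.nan
            continue
        # P(case score > control score) + 0.5 P(tie), via rank comparison
        greater = (sc[:, None] > sn[None, :]).sum()
        ties = (sc[:, None] == sn[None, :]).sum()
        aucs[i] = (greater + 0.5 * ties) / (len(sc) * len(sn))

    valid = ~np.isnan(aucs)
    time_grid, aucs = time_grid[valid], aucs[valid]
    if len(time_grid) == 0:
        raise DomainError("no evaluable time points")

    # iAUC weights ~ 2 f(t) S(t) from the KM estimate of the event-time law
    kmf = KaplanMeierFitter().fit(T, E)
    surv = kmf.survival_function_.iloc[:, 0]
    km_x = surv.index.to_numpy(float)
    km_y = surv.to_numpy(float)
    idx = np.searchsorted(km_x, time_grid, side="right") - 1
    S_t = np.where(idx >= 0, km_y[np.clip(idx, 0, len(km_y) - 1)], 1.0)
    idx_prev = np.searchsorted(km_x, time_grid, side="left") - 1
    S_tminus = np.where(idx_prev >= 0, km_y[np.clip(idx_prev, 0, len(km_y) - 1)], 1.0)
    f_t = np.maximum(S_tminus - S_t, 0.0)
    w = 2.0 * f_t * S_t
    if w.sum() <= 0:
        w = np.ones_like(w)
    w = w / w.sum()
    iauc = float((w * aucs).sum())
    return TimeDependentAUCResult(
        time_grid=time_grid,
        auc_t=aucs,
        iauc=iauc,
        weighting="2*f(t)*S(t), Kaplan-Meier estimated, normalised",
        n_events_used=int(((E == 1) & (T <= horizon)).sum()),
        variant=variant,
    )
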