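"""Multivariable logistic models of nodal-stage migration.

Stage migration is quantified by regressing the declared nodal stage on
the examined-lymph-node (ELN) count with multivariable adjustment:

* binomial logistic regression of node-positive (N1-N3b) versus
  node-negative (N0) status — the negative-to-positive migration model;
* multinomial logistic regression over the five declared stages with N0
  as baseline, together with a proportional-odds (ordinal) summary that
  condenses lower-to-higher migration into a single odds ratio per
  additional examined node.

The per-ELN odds-ratio *sequence* enters ELN as dummy-coded count levels
against a reference level (by default the cohort's most frequent count),
which is what the downstream smoothing and breakpoint machinery consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from ._design import (
    MIGRATION_ADJUSTMENT,
    EstimationError,
    build_design,
    check_two_classes,
    eln_level_design,
    modal_eln,
)
from .staging import NODAL_STAGES

__all__ = [
    "EffectEstimate",
    "EffectSequence",
    "MultinomialMigrationResult",
    "fit_binomial_migration",
    "fit_multinomial_migration",
    "estimate_or_sequence",
    "MIGRATION_ADJUSTMENT",
    "EstimationError",
]

#: conventional 95% Wald multiplier (the +/-1.96 arithmetic of registry
#: effect tables)
_Z95 = 1.96


@dataclass
class EffectEstimate:
    """One adjusted effect size on the odds- or hazard-ratio scale."""

    scale: str  # "odds ratio" | "hazard ratio"
    log_point: float
    se_log: float
    n_used: int
    label: str = ""

    @property
    def point(self) -> float:
        return float(np.exp(self.log_point))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.log_point - _Z95 * self.se_log))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.log_point + _Z95 * self.se_log))

    @property
    def p_value(self) -> float:
        if self.se_log == 0:
            return float("nan")
        z = self.log_point / self.se_log
        return float(2 * stats.norm.sf(abs(z)))

    def covers(self, ratio: float) -> bool:
        """Whether the 95% CI contains the given ratio."""
        return self.ci_low <= ratio <= self.ci_high

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "label": self.label,
        }


@dataclass
class EffectSequence:
    """Ordered per-ELN adjusted effects against a reference count.

    ``table`` has one row per retained ELN level with columns
    ``eln, n, log_point, se_log, point, ci_low, ci_high, p_value,
    is_reference``; the reference row has ``log_point = 0`` and
    ``se_log = 0`` exactly.
    """

    table: pd.DataFrame
    scale: str
    reference_eln: int
    adjustment_set: list = field(default_factory=list)
    min_count_per_level: int = 5
    omitted_levels: list = field(default_factory=list)

    @property
    def eln(self) -> np.ndarray:
        return self.table["eln"].to_numpy(int)

    @property
    def log_points(self) -> np.ndarray:
        return self.table["log_point"].to_numpy(float)

    def write(self, path, sep: str = ",") -> None:
        self.table.to_csv(path, sep=sep, index=False)


@dataclass
class MultinomialMigrationResult:
    """Per-stage odds ratios (N0 baseline) and the ordinal summary."""

    per_category: dict  # stage -> EffectEstimate or None (not estimable)
    ordinal: EffectEstimate

    @property
    def not_estimable(self) -> list:
        return [k for k, v in self.per_category.items() if v is None]


def _fit_logit(y, X, what: str):
    """Newton ML fit with separation and convergence diagnostics."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(np.asarray(y, float), Xc).fit(disp=0, method="newton", tol=1e-10, maxiter=100)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise EstimationError(f"{what}: perfect separation detected ({exc})") from exc
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"{what}: singular design matrix ({exc})") from exc
    if not res.mle_retvals.get("converged", False):
        raise EstimationError(f"{what}: logistic fit did not converge")
    return res


def fit_binomial_migration(
    cohort: pd.DataFrame, adjustment_set=MIGRATION_ADJUSTMENT
) -> EffectEstimate:
    """Adjusted odds ratio of declared node-positive status per additional
    examined node (ELN entered as continuous)."""
    y = (cohort["pln"].to_numpy(int) > 0).astype(float)
    check_two_classes(y, "node-positive outcome")
    X = build_design(cohort, adjustment_set)
    X.insert(0, "eln", cohort["eln"].to_numpy(float))
    res = _fit_logit(y, X, "binomial migration model")
    return EffectEstimate(
        scale="odds ratio",
        log_point=float(res.params["eln"]),
        se_log=float(res.bse["eln"]),
        n_used=int(res.nobs),
        label="node-positive vs node-negative, per additional ELN",
    )


def fit_multinomial_migration(
    cohort: pd.DataFrame, adjustment_set=MIGRATION_ADJUSTMENT
) -> MultinomialMigrationResult:
    """Per-stage (N1..N3b vs N0) odds ratios and a proportional-odds
    summary, both per additional examined node.

    Stages absent from the cohort are flagged not estimable rather than
    raising.  The ordinal summary is a proportional-odds logistic model
    over the ordered declared stages; its exponentiated slope is the
    single lower-to-higher migration odds ratio reported by convention.
    """
    stage = pd.Categorical(cohort["n_stage"], categories=NODAL_STAGES, ordered=True)
    codes = np.asarray(stage.codes)
    if (codes == 0).sum() == 0:
        raise EstimationError("reference stage N0 absent from cohort")
    present = [s for i, s in enumerate(NODAL_STAGES) if (codes == i).any()]
    if len(present) < 2:
        raise EstimationError("fewer than two observed nodal stages")

    X = build_design(cohort, adjustment_set)
    X.insert(0, "eln", cohort["eln"].to_numpy(float))

    # multinomial with N0 baseline on the observed categories
    compact = pd.Categorical(stage.astype(str), categories=present, ordered=True)
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mres = sm.MNLogit(np.asarray(compact.codes), Xc).fit(disp=0, method="newton", maxiter=100)
    per_category: dict = {s: None for s in NODAL_STAGES[1:]}
    eln_row = list(Xc.columns).index("eln")
    for j, s in enumerate(present[1:]):
        per_category[s] = EffectEstimate(
            scale="odds ratio",
            log_point=float(mres.params.iloc[eln_row, j]),
            se_log=float(mres.bse.iloc[eln_row, j]),
            n_used=int(mres.nobs),
            label=f"{s} vs N0, per additional ELN",
        )

    ordinal = _fit_ordinal(np.asarray(compact.codes), X, "eln")
    return MultinomialMigrationResult(per_category=per_category, ordinal=ordinal)


def _fit_ordinal(codes: np.ndarray, X: pd.DataFrame, term: str) -> EffectEstimate:
    """Proportional-odds logistic fit; returns the effect for ``term``."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(codes, X, distr="logit")
        res = model.fit(disp=0, method="bfgs", maxiter=500, gtol=1e-8)
        if not res.mle_retvals.get("converged", True):
            res = model.fit(disp=0, method="bfgs", start_params=res.params, maxiter=500)
    return EffectEstimate(
        scale="odds ratio",
        log_point=float(res.params[term]),
        se_log=float(res.bse[term]),
        n_used=int(res.nobs),
        label="lower-to-higher nodal stage (proportional odds)",
    )


def estimate_or_sequence(
    cohort: pd.DataFrame,
    outcome: str = "binomial",
    adjustment_set=MIGRATION_ADJUSTMENT,
    reference_eln="modal",
    min_count_per_level: int = 5,
) -> EffectSequence:
    """Adjusted odds ratio for each ELN count level against a reference.

    ELN enters as dummy-coded categorical levels (one per observed count
    with at least ``min_count_per_level`` patients); sparser counts are
    omitted, never pooled.  ``outcome`` is ``"binomial"`` (node-positive
    vs N0) or ``"multinomial-ordinal"`` (proportional-odds over declared
    stages).  The reference entry has OR = 1 and zero standard error by
    construction.
    """
    if reference_eln == "modal":
        reference_eln = modal_eln(cohort)
    reference_eln = int(reference_eln)
    screen = "binomial" if outcome == "binomial" else "stage"
    subset, dummies, levels, omitted = eln_level_design(
        cohort, reference_eln, min_count_per_level, estimable=screen
    )
    X = pd.concat([dummies, build_design(subset, adjustment_set)], axis=1)

    if outcome == "binomial":
        y = (subset["pln"].to_numpy(int) > 0).astype(float)
        check_two_classes(y, "node-positive outcome")
        try:
            res = _fit_logit(y, X, "per-level migration model")
        except EstimationError:
            # joint quasi-separation despite the per-level screen: fall back
            # to a quasi-Newton fit (finite estimates, very wide intervals)
            Xc = sm.add_constant(X, has_constant="add")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, Xc).fit(disp=0, method="bfgs", maxiter=1000)
        params, bses, n_used = res.params, res.bse, int(res.nobs)
    elif outcome == "multinomial-ordinal":
        stage = pd.Categorical(subset["n_stage"], categories=NODAL_STAGES, ordered=True)
        present = [s for i, s in enumerate(NODAL_STAGES) if (np.asarray(stage.codes) == i).any()]
        compact = pd.Categorical(stage.astype(str), categories=present, ordered=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = OrderedModel(np.asarray(compact.codes), X, distr="logit").fit(
                disp=0, method="bfgs", maxiter=500, gtol=1e-7
            )
        params, bses, n_used = res.params, res.bse, int(res.nobs)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")

    return _sequence_from_fit(
        subset, params, bses, n_used, levels, omitted, reference_eln,
        scale="odds ratio", adjustment_set=list(adjustment_set),
        min_count_per_level=min_count_per_level,
    )


def _sequence_from_fit(
    subset, params, bses, n_used, levels, omitted, reference_eln, scale,
    adjustment_set, min_count_per_level,
) -> EffectSequence:
    counts = subset["eln"].value_counts()
    rows = []
    for k in levels:
        if k == reference_eln:
            rows.append((k, int(counts[k]), 0.0, 0.0, True))
        else:
            name = f"eln[{k}]"
            rows.append((k, int(counts[k]), float(params[name]), float(bses[name]), False))
    tab = pd.DataFrame(rows, columns=["eln", "n", "log_point", "se_log", "is_reference"])
    tab["point"] = np.exp(tab["log_point"])
    tab["ci_low"] = np.exp(tab["log_point"] - _Z95 * tab["se_log"])
    tab["ci_high"] = np.exp(tab["log_point"] + _Z95 * tab["se_log"])
    z = np.divide(tab["log_point"], tab["se_log"], out=np.full(len(tab), np.nan), where=tab["se_log"] > 0)
    tab["p_value"] = 2 * stats.norm.sf(np.abs(z))
    tab = tab[["eln", "n", "log_point", "se_log", "point", "ci_low", "ci_high", "p_value", "is_reference"]]
    tab = tab.sort_values("eln").reset_index(drop=True)
    return EffectSequence(
        table=tab,
        scale=scale,
        reference_eln=reference_eln,
        adjustment_set=adjustment_set,
        min_count_per_level=min_count_per_level,
        omitted_levels=omitted,
    )
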