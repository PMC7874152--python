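"""Design-matrix construction shared by the logistic and Cox models."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .staging import CATEGORY_LEVELS

#: Adjustment set of the stage-migration (logistic) models: factors
#: plausibly associated with ELN or PLN number before or during surgery.
MIGRATION_ADJUSTMENT = [
    "diagnosis_year",
    "sex",
    "age_group",
    "location",
    "local_invasion",
    "grade",
    "size_group",
    "resection_type",
]

#: Adjustment set of the survival (Cox) models: the migration set plus the
#: positive-node count.  ``margin_positive`` is appended by callers when
#: the column is complete cohort-wide.
SURVIVAL_ADJUSTMENT = MIGRATION_ADJUSTMENT + ["pln"]

_CONTINUOUS_CENTER = {"diagnosis_year": 2013.0, "age_years": 65.0, "size_cm": 4.0}


class EstimationError(RuntimeError):
    """A model fit failed (non-convergence, separation, degenerate data)."""


def build_design(cohort: pd.DataFrame, covariates, drop_first: bool = True) -> pd.DataFrame:
    """Dummy-code categorical covariates and pass numeric ones through.

    Categorical columns use their canonical level order with the first
    *observed* level as reference; all-zero dummy columns (levels absent
    from the cohort) are dropped so the design has full column rank for
    any subgroup.
    """
    parts = []
    for cov in covariates:
        if cov not in cohort.columns:
            raise EstimationError(f"covariate {cov!r} not in cohort")
        col = cohort[cov]
        if cov in CATEGORY_LEVELS:
            levels = [l for l in CATEGORY_LEVELS[cov] if (col.astype(object) == l).any()]
            ref_levels = levels[1:] if drop_first else levels
            for level in ref_levels:
                parts.append(
                    pd.Series((col.astype(object) == level).astype(float), name=f"{cov}[{level}]")
                )
        else:
            vals = pd.to_numeric(col, errors="coerce").astype(float)
            vals = vals - _CONTINUOUS_CENTER.get(cov, 0.0)
            parts.append(vals.rename(cov))
    if not parts:
        return pd.DataFrame(index=cohort.index)
    X = pd.concat(parts, axis=1)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    return X[keep]


def eln_level_design(
    cohort: pd.DataFrame,
    reference_eln: int,
    min_count_per_level: int,
    estimable: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[int], list[int]]:
    """Dummy-code ELN as categorical levels against a reference count.

    Returns ``(subset, dummies, levels, omitted)`` where ``subset`` is the
    cohort restricted to levels with at least ``min_count_per_level``
    patients, ``dummies`` has one column ``eln[k]`` per retained
    non-reference level, ``levels`` lists retained counts in order and
    ``omitted`` the dropped sparse counts.

    ``estimable`` adds a per-level identifiability screen: a level whose
    dummy coefficient would diverge (monotone likelihood) is omitted like
    a sparse one.  ``"binomial"`` requires both node-positive and
    node-negative patients in the level; ``"stage"`` at least two distinct
    declared stages; ``"events"`` at least one death.
    """
    counts = cohort["eln"].value_counts()
    levels = sorted(int(k) for k, v in counts.items() if v >= min_count_per_level)
    omitted = sorted(int(k) for k, v in counts.items() if v < min_count_per_level)
    if estimable is not None:
        keep = []
        for k in levels:
            sub = cohort[cohort["eln"] == k]
            if estimable == "binomial":
                ok = (sub["pln"] > 0).any() and (sub["pln"] == 0).any()
            elif estimable == "stage":
                ok = sub["n_stage"].nunique() >= 2
            elif estimable == "events":
                ok = (sub["death"] == 1).any()
            else:
                raise ValueError(f"unknown estimability screen {estimable!r}")
            (keep if ok or k == reference_eln else omitted).append(k)
        levels, omitted = keep, sorted(omitted)
    if reference_eln not in levels:
        modal = int(counts.idxmax()) if len(counts) else None
        raise EstimationError(
            f"reference ELN level {reference_eln} has fewer than "
            f"{min_count_per_level} patients; the modal count is {modal}"
        )
    subset = cohort[cohort["eln"].isin(levels)].reset_index(drop=True)
    dummies = pd.DataFrame(index=subset.index)
    for k in levels:
        if k == reference_eln:
            continue
        dummies[f"eln[{k}]"] = (subset["eln"] == k).astype(float)
    return subset, dummies, levels, omitted


def modal_eln(cohort: pd.DataFrame) -> int:
    """The most frequent examined-node count (smallest wins ties)."""
    counts = cohort["eln"].value_counts()
    top = counts[counts == counts.max()].index
    return int(min(top))


def check_two_classes(y: np.ndarray, what: str) -> None:
    if len(np.unique(y)) < 2:
        raise EstimationError(f"{what} has fewer than two observed classes")
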