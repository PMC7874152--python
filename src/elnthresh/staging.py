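"""Cohort data model, nodal-stage assignment, and eligibility filtering.

The analyzable unit is one resected, non-metastatic gastric adenocarcinoma
patient: demographics, tumor factors, the number of examined lymph nodes
(ELN), the number of positive lymph nodes (PLN), declared nodal stage, and
overall-survival follow-up.  Cohorts are held as :class:`pandas.DataFrame`
objects with the column contract in :data:`COHORT_COLUMNS`; simulated
cohorts additionally carry ``latent_``-prefixed ground-truth columns that
are excluded from analysis exports by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NODAL_STAGES",
    "COHORT_COLUMNS",
    "LATENT_COLUMNS",
    "ExclusionLog",
    "assign_nodal_stage",
    "compute_lnr",
    "apply_eligibility_filters",
    "derive_columns",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
]


class DomainError(ValueError):
    """An input violates a documented precondition."""


#: Ordered nodal-stage categories (AJCC 7th edition, gastric).
NODAL_STAGES = ["N0", "N1", "N2", "N3a", "N3b"]

#: PLN-count boundaries of the nodal stages: N0=0, N1=1-2, N2=3-6,
#: N3a=7-15, N3b>=16.
_STAGE_BINS = [0, 1, 3, 7, 16]

SEX_LEVELS = ["male", "female"]
AGE_GROUPS = ["<50", "50-59", "60-69", "70-79", ">=80"]
LOCATION_LEVELS = ["cardia", "fundus_body", "antrum_pylorus", "other"]
INVASION_LEVELS = ["mucosa_submucosa", "muscularis_subserosa", "serosa", "adjacent"]
GRADE_LEVELS = ["well", "intermediate", "poor"]
SIZE_GROUPS = ["<2", "2-4", "4-6", "6-8", ">=8"]
RESECTION_LEVELS = ["partial_subtotal", "total_near_total", "nos"]

CATEGORY_LEVELS = {
    "sex": SEX_LEVELS,
    "age_group": AGE_GROUPS,
    "location": LOCATION_LEVELS,
    "local_invasion": INVASION_LEVELS,
    "grade": GRADE_LEVELS,
    "size_group": SIZE_GROUPS,
    "resection_type": RESECTION_LEVELS,
    "n_stage": NODAL_STAGES,
}

#: Analysis columns of a cohort file, in canonical order.
COHORT_COLUMNS = [
    "id",
    "sex",
    "age_years",
    "age_group",
    "diagnosis_year",
    "location",
    "local_invasion",
    "grade",
    "size_cm",
    "size_group",
    "resection_type",
    "margin_positive",
    "eln",
    "pln",
    "n_stage",
    "lnr",
    "survival_months",
    "death",
]

#: Simulation ground-truth columns (never used by estimators).
LATENT_COLUMNS = ["latent_total_nodes", "latent_true_positive_nodes", "latent_true_n_stage"]

#: Fields that must be non-missing for a record to enter multivariable
#: models.  ``margin_positive`` is intentionally absent: it is allowed to be
#: missing cohort-wide (registry data often lack it) and only enters
#: adjustment when complete.
REQUIRED_FIELDS = [
    "sex",
    "age_years",
    "diagnosis_year",
    "location",
    "local_invasion",
    "grade",
    "size_cm",
    "resection_type",
    "eln",
    "pln",
    "survival_months",
    "death",
]

ELIGIBLE_YEARS = (2010, 2016)
MIN_SURVIVAL_MONTHS = 3.0

# Exclusion reasons, applied in this order; a record failing several rules
# is attributed to the first.
REASON_METASTATIC = "metastatic disease"
REASON_YEAR = "diagnosis year outside 2010-2016"
REASON_NO_ELN = "no examined nodes"
REASON_SHORT_SURVIVAL = "survival <3 months"
REASON_MISSING = "missing data"
EXCLUSION_ORDER = [
    REASON_METASTATIC,
    REASON_YEAR,
    REASON_NO_ELN,
    REASON_SHORT_SURVIVAL,
    REASON_MISSING,
]


def assign_nodal_stage(pln):
    """Declared nodal stage from the positive-node count.

    0 -> N0, 1-2 -> N1, 3-6 -> N2, 7-15 -> N3a, >=16 -> N3b.  Accepts a
    scalar or array-like; returns a string or an ordered Categorical.
    """
    arr = np.asarray(pln)
    if arr.size and (np.any(~np.isfinite(arr.astype(float))) or np.any(arr.astype(float) % 1 != 0)):
        raise DomainError("positive-node count must be a non-negative integer")
    if np.any(arr < 0):
        raise DomainError("positive-node count must be a non-negative integer")
    idx = np.searchsorted(_STAGE_BINS, arr, side="right") - 1
    stages = np.asarray(NODAL_STAGES, dtype=object)[idx]
    if np.isscalar(pln) or arr.ndim == 0:
        return str(stages if arr.ndim == 0 else stages[0])
    return pd.Categorical(stages, categories=NODAL_STAGES, ordered=True)


def compute_lnr(pln, eln):
    """Lymph-node ratio PLN/ELN.

    Raises :class:`DomainError` when ``eln`` is zero (such records are
    ineligible) or when ``pln`` exceeds ``eln``.
    """
    pln_a = np.asarray(pln, dtype=float)
    eln_a = np.asarray(eln, dtype=float)
    if np.any(eln_a < 1):
        raise DomainError("ELN count must be >= 1 (records with 0 examined nodes are ineligible)")
    if np.any(pln_a < 0) or np.any(pln_a > eln_a):
        raise DomainError("PLN count must lie in [0, ELN]")
    out = pln_a / eln_a
    return float(out) if np.isscalar(pln) else out


@dataclass
class ExclusionLog:
    """Per-rule exclusion counts plus per-record reasons."""

    n_input: int = 0
    n_retained: int = 0
    counts: dict = field(default_factory=dict)
    reasons: pd.Series = None  # indexed by excluded record id

    @property
    def n_excluded(self) -> int:
        return int(sum(self.counts.values()))

    def reconciles(self) -> bool:
        """Removals plus retained must equal the input size."""
        return self.n_retained + self.n_excluded == self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
            "counts": {k: int(v) for k, v in self.counts.items()},
        }


def derive_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Derive grouped and computed columns from their continuous sources.

    ``age_group``, ``size_group``, ``lnr`` and ``n_stage`` are always
    recomputed from ``age_years``, ``size_cm``, ``pln``/``eln``; stored
    copies are never trusted, which makes inconsistency impossible.
    """
    out = df.copy()
    out["age_group"] = pd.Categorical(
        np.asarray(AGE_GROUPS, dtype=object)[
            np.searchsorted([0, 50, 60, 70, 80], out["age_years"].to_numpy(float), side="right") - 1
        ],
        categories=AGE_GROUPS,
        ordered=True,
    )
    out["size_group"] = pd.Categorical(
        np.asarray(SIZE_GROUPS, dtype=object)[
            np.searchsorted([0, 2, 4, 6, 8], out["size_cm"].to_numpy(float), side="right") - 1
        ],
        categories=SIZE_GROUPS,
        ordered=True,
    )
    out["lnr"] = compute_lnr(out["pln"].to_numpy(), out["eln"].to_numpy())
    out["n_stage"] = assign_nodal_stage(out["pln"].to_numpy())
    for col, levels in CATEGORY_LEVELS.items():
        if col in out.columns and not isinstance(out[col].dtype, pd.CategoricalDtype):
            out[col] = pd.Categorical(out[col], categories=levels, ordered=True)
    return out


def apply_eligibility_filters(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the eligibility rules and log every removal.

    Rules, applied in order with first-matching-reason attribution:

    1. a truthy ``metastatic`` flag column, when present (stage I-III only);
    2. diagnosis year outside 2010-2016;
    3. ELN missing or 0;
    4. overall survival < 3 months;
    5. any required analysis field missing.

    Returns the retained cohort (with derived columns recomputed) and an
    :class:`ExclusionLog`.  Filtering is idempotent.
    """
    df = records.copy()
    n_input = len(df)
    reason = pd.Series(pd.NA, index=df.index, dtype="object")

    if "metastatic" in df.columns:
        flag = df["metastatic"].fillna(0).astype(float) > 0
        reason[flag & reason.isna()] = REASON_METASTATIC

    year = pd.to_numeric(df.get("diagnosis_year"), errors="coerce")
    bad_year = year.isna() | (year < ELIGIBLE_YEARS[0]) | (year > ELIGIBLE_YEARS[1])
    reason[bad_year & reason.isna()] = REASON_YEAR

    eln = pd.to_numeric(df.get("eln"), errors="coerce")
    reason[(eln.isna() | (eln < 1)) & reason.isna()] = REASON_NO_ELN

    surv = pd.to_numeric(df.get("survival_months"), errors="coerce")
    reason[(surv.isna() | (surv < MIN_SURVIVAL_MONTHS)) & reason.isna()] = REASON_SHORT_SURVIVAL

    missing = pd.Series(False, index=df.index)
    for col in REQUIRED_FIELDS:
        if col not in df.columns:
            missing |= True
        else:
            missing |= df[col].isna()
    # PLN > ELN is a recording error treated as missing data.
    pln = pd.to_numeric(df.get("pln"), errors="coerce")
    missing |= pln > eln
    reason[missing & reason.isna()] = REASON_MISSING

    keep = reason.isna()
    retained = derive_columns(df.loc[keep])
    excluded = reason[~keep]
    counts = {r: int((excluded == r).sum()) for r in EXCLUSION_ORDER if (excluded == r).any()}
    ids = df["id"].astype(str) if "id" in df.columns else df.index.astype(str)
    log = ExclusionLog(
        n_input=n_input,
        n_retained=len(retained),
        counts=counts,
        reasons=pd.Series(excluded.to_numpy(), index=ids[~keep.to_numpy()]),
    )
    return retained.reset_index(drop=True), log


def validate_cohort(df: pd.DataFrame, latent: bool = False, strict: bool = True) -> None:
    """Check the cohort column contract; raise naming the first violation.

    ``strict=False`` checks only structure and category values, tolerating
    eligibility violations (0 ELNs, short survival) that the filters are
    expected to remove; the analyzable cohort must pass ``strict=True``.
    """
    required = COHORT_COLUMNS + (LATENT_COLUMNS if latent else [])
    for col in required:
        if col not in df.columns:
            raise DomainError(f"cohort is missing required column {col!r}")
    for col, levels in CATEGORY_LEVELS.items():
        bad = ~df[col].astype(object).isin(levels) & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DomainError(
                f"invalid value {df[col].iloc[row]!r} in column {col!r} at row {row}"
            )
    if not strict:
        return
    for col in ["eln", "survival_months"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals <= 0).any():
            row = int(np.flatnonzero((vals <= 0).to_numpy())[0])
            raise DomainError(f"non-positive value in column {col!r} at row {row}")
    if (df["pln"] > df["eln"]).any():
        row = int(np.flatnonzero((df["pln"] > df["eln"]).to_numpy())[0])
        raise DomainError(f"pln exceeds eln at row {row}")


def write_cohort(df: pd.DataFrame, path, sep: str = ",", latent: bool = False) -> None:
    """Write a cohort as delimited UTF-8 text.

    Latent ground-truth columns are dropped unless ``latent=True``.
    """
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    if latent:
        cols += [c for c in LATENT_COLUMNS if c in df.columns]
    df.to_csv(path, sep=sep, index=False, columns=cols)


def read_cohort(path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited cohort file (comma default, tab accepted) and
    validate it.  Derived columns are recomputed on load."""
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    validate_cohort(df, strict=False)
    return df
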