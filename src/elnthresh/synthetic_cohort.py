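"""Synthetic cohorts with an explicit stage-migration mechanism.

The generator emulates the structure of registry cohorts of resected
non-metastatic gastric adenocarcinoma:

* each patient carries a latent regional-node burden — ``N_tot`` total
  regional nodes of which ``K`` truly harbour metastases;
* pathology examines ``ELN`` of the ``N_tot`` nodes; the detected positive
  count ``PLN`` is a hypergeometric draw (sampling without replacement), so
  the declared nodal stage depends on how many nodes were examined — the
  stage-migration (Will Rogers) mechanism;
* overall survival follows a Weibull proportional-hazards model driven by
  the covariates and the *true* burden ``K`` (not the declared stage), plus
  an optional direct ELN log-hazard term ``g(ELN)`` used to plant a known
  structural breakpoint for recovery experiments;
* censoring combines an administrative horizon with random (exponential)
  loss to follow-up.

Under this mechanism examining more nodes yields more detected positives,
higher declared stages, and — among patients *declared* node-negative —
fewer occult positives and hence better observed survival, with no direct
causal ELN effect.  Defaults are calibrated to a US-like registry cohort:
mean ELN about 20, about 45% declared node-negative, mean detected PLN
about 4.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import staging
from .staging import GRADE_LEVELS, INVASION_LEVELS, SIZE_GROUPS

__all__ = [
    "SimulationConfig",
    "ConfigurationError",
    "generate_cohort",
    "sample_detected_pln",
    "simulate_survival",
    "scenario_config",
    "US_MARGINALS",
    "CHINA_MARGINALS",
]


class ConfigurationError(ValueError):
    """A simulation-configuration field violates its contract."""


class DomainError(ValueError):
    pass


#: Covariate category->probability tables shaped like a US registry cohort.
US_MARGINALS = {
    "sex": {"male": 0.63, "female": 0.37},
    "age_group": {"<50": 0.12, "50-59": 0.21, "60-69": 0.28, "70-79": 0.26, ">=80": 0.13},
    "location": {"cardia": 0.28, "fundus_body": 0.13, "antrum_pylorus": 0.30, "other": 0.29},
    "local_invasion": {
        "mucosa_submucosa": 0.23,
        "muscularis_subserosa": 0.54,
        "serosa": 0.17,
        "adjacent": 0.06,
    },
    "grade": {"well": 0.05, "intermediate": 0.28, "poor": 0.67},
    "size_group": {"<2": 0.17, "2-4": 0.30, "4-6": 0.26, "6-8": 0.14, ">=8": 0.13},
    "resection_type": {"partial_subtotal": 0.70, "total_near_total": 0.22, "nos": 0.08},
    "diagnosis_year": {str(y): 1 / 7 for y in range(2010, 2017)},
}

#: China-like variant: younger patients, deeper invasion, more examined nodes.
CHINA_MARGINALS = {
    "sex": {"male": 0.68, "female": 0.32},
    "age_group": {"<50": 0.28, "50-59": 0.33, "60-69": 0.28, "70-79": 0.10, ">=80": 0.01},
    "location": {"cardia": 0.23, "fundus_body": 0.24, "antrum_pylorus": 0.53, "other": 0.00},
    "local_invasion": {
        "mucosa_submucosa": 0.15,
        "muscularis_subserosa": 0.20,
        "serosa": 0.52,
        "adjacent": 0.13,
    },
    "grade": {"well": 0.10, "intermediate": 0.29, "poor": 0.61},
    "size_group": {"<2": 0.12, "2-4": 0.36, "4-6": 0.31, "6-8": 0.14, ">=8": 0.07},
    "resection_type": {"partial_subtotal": 0.70, "total_near_total": 0.28, "nos": 0.02},
    "diagnosis_year": {str(y): 1 / 7 for y in range(2010, 2017)},
}

_AGE_BOUNDS = {"<50": (30, 50), "50-59": (50, 60), "60-69": (60, 70), "70-79": (70, 80), ">=80": (80, 92)}
_SIZE_BOUNDS = {"<2": (0.4, 2), "2-4": (2, 4), "4-6": (4, 6), "6-8": (6, 8), ">=8": (8, 14)}


@dataclass
class TotalNodesDist:
    """Latent regional-node count: minimum + negative binomial."""

    mean: float = 55.0
    dispersion: float = 8.0
    minimum: int = 8


@dataclass
class PositiveNodesModel:
    """Latent true-positive count K: zero-inflated negative binomial.

    The zero-inflation (truly node-negative) probability follows a logit
    that decreases with depth of local invasion; the positive-count part is
    log-linear in invasion, grade and size group.
    """

    zero_inflation_logit: float = 1.1
    zero_inflation_invasion_slope: float = -1.7
    log_mean: float = 1.55
    invasion_coef: float = 0.45
    grade_coef: float = 0.25
    size_coef: float = 0.12
    dispersion: float = 0.9


@dataclass
class ElnDist:
    """Examined-node count: negative binomial truncated to [1, N_tot]."""

    mean: float = 21.0
    dispersion: float = 2.7
    # multiplicative shift of the mean by resection type (more extensive
    # resections yield more nodes)
    resection_factor: dict = field(
        default_factory=lambda: {"partial_subtotal": 0.95, "total_near_total": 1.25, "nos": 0.90}
    )


@dataclass
class SurvivalModel:
    """Weibull proportional-hazards overall-survival model (months)."""

    shape: float = 1.1
    scale: float = 95.0
    #: additive log-hazards for covariate levels, keyed "column:level"
    coefficients: dict = field(
        default_factory=lambda: {
            "sex:female": -0.05,
            "age_group:50-59": 0.15,
            "age_group:60-69": 0.35,
            "age_group:70-79": 0.65,
            "age_group:>=80": 1.05,
            "local_invasion:muscularis_subserosa": 0.45,
            "local_invasion:serosa": 0.95,
            "local_invasion:adjacent": 1.30,
            "grade:intermediate": 0.15,
            "grade:poor": 0.40,
            "size_group:2-4": 0.15,
            "size_group:4-6": 0.30,
            "size_group:6-8": 0.45,
            "size_group:>=8": 0.60,
        }
    )
    #: per true positive node (the burden that actually drives prognosis)
    burden_loghr: float = 0.13
    #: optional direct ELN log-hazard g(ELN) as piecewise-linear knots
    #: [(eln, log-hazard), ...]; linear interpolation, flat beyond the ends.
    eln_loghazard_knots: list | None = None


@dataclass
class Censoring:
    horizon: float = 84.0  # administrative horizon, months
    rate: float = 0.017  # exponential loss-to-follow-up rate per month


@dataclass
class SimulationConfig:
    n_patients: int = 1000
    seed: int = 0
    covariate_marginals: dict = field(default_factory=lambda: _copy_marginals(US_MARGINALS))
    total_nodes_dist: TotalNodesDist = field(default_factory=TotalNodesDist)
    positive_nodes_model: PositiveNodesModel = field(default_factory=PositiveNodesModel)
    eln_dist: ElnDist = field(default_factory=ElnDist)
    survival_model: SurvivalModel = field(default_factory=SurvivalModel)
    censoring: Censoring = field(default_factory=Censoring)
    #: "hypergeometric" (stage migration) or "full" (PLN := K, no migration)
    detection: str = "hypergeometric"
    #: fraction of records violating each eligibility rule, keyed by rule
    #: name: year, eln, survival, missing
    eligibility_noise: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (isinstance(self.n_patients, (int, np.integer)) and self.n_patients >= 1):
            raise ConfigurationError("n_patients must be a positive integer")
        for cov, table in self.covariate_marginals.items():
            probs = np.asarray(list(table.values()), dtype=float)
            if np.any(probs < 0) or np.any(probs > 1):
                raise ConfigurationError(f"covariate_marginals[{cov!r}] has probabilities outside [0,1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"covariate_marginals[{cov!r}] does not sum to 1")
        if self.total_nodes_dist.mean <= self.total_nodes_dist.minimum:
            raise ConfigurationError("total_nodes_dist.mean must exceed total_nodes_dist.minimum")
        if self.total_nodes_dist.dispersion <= 0:
            raise ConfigurationError("total_nodes_dist.dispersion must be positive")
        if self.eln_dist.mean <= 0 or self.eln_dist.dispersion <= 0:
            raise ConfigurationError("eln_dist mean and dispersion must be positive")
        if self.survival_model.shape <= 0:
            raise ConfigurationError("survival_model.shape must be positive")
        if self.survival_model.scale <= 0:
            raise ConfigurationError("survival_model.scale must be positive")
        if self.censoring.horizon <= 3:
            raise ConfigurationError("censoring.horizon must exceed 3 months")
        if self.censoring.rate < 0:
            raise ConfigurationError("censoring.rate must be non-negative")
        if self.detection not in ("hypergeometric", "full"):
            raise ConfigurationError("detection must be 'hypergeometric' or 'full'")
        for rule, frac in self.eligibility_noise.items():
            if rule not in ("year", "eln", "survival", "missing"):
                raise ConfigurationError(f"eligibility_noise has unknown rule {rule!r}")
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"eligibility_noise[{rule!r}] must lie in [0,1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _copy_marginals(m):
    return {k: dict(v) for k, v in m.items()}


def _nb_draw(rng, mean, dispersion, size):
    """Negative binomial parameterised by mean and shape (dispersion)."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def sample_detected_pln(total_nodes, positive_nodes, eln, rng):
    """Detected positive-node count under examination of ``eln`` of
    ``total_nodes`` nodes: a hypergeometric draw without replacement.

    Vectorised over array inputs.  Returned counts lie in
    ``[max(0, eln - (total - positive)), min(eln, positive)]``.
    """
    total = np.asarray(total_nodes)
    pos = np.asarray(positive_nodes)
    e = np.asarray(eln)
    if np.any(pos < 0) or np.any(pos > total):
        raise DomainError("positive_nodes must lie in [0, total_nodes]")
    if np.any(e < 1) or np.any(e > total):
        raise DomainError("eln must lie in [1, total_nodes]")
    return rng.hypergeometric(pos, total - pos, e)


def _eval_eln_loghazard(knots, eln):
    if not knots:
        return np.zeros(np.shape(eln))
    pts = sorted(knots)
    xs = np.asarray([p[0] for p in pts], dtype=float)
    ys = np.asarray([p[1] for p in pts], dtype=float)
    return np.interp(np.asarray(eln, dtype=float), xs, ys)


def simulate_survival(linear_predictor, survival_model, censoring, rng):
    """Draw (observed time, event) from the Weibull PH model.

    Event time T satisfies S(t) = exp(-(t/scale)^shape * exp(lp)); the
    observed time is min(T, random censoring, administrative horizon) and
    the event indicator is 1 iff T is the minimum.
    """
    if survival_model.shape <= 0 or survival_model.scale <= 0:
        raise DomainError("Weibull shape and scale must be positive")
    lp = np.asarray(linear_predictor, dtype=float)
    u = rng.exponential(1.0, size=lp.shape)
    t_event = survival_model.scale * (u / np.exp(lp)) ** (1.0 / survival_model.shape)
    t_event = np.maximum(t_event, 1e-9)
    if censoring.rate > 0:
        t_cens = rng.exponential(1.0 / censoring.rate, size=lp.shape)
    else:
        t_cens = np.full(lp.shape, np.inf)
    t_cens = np.minimum(t_cens, censoring.horizon)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate one cohort; deterministic given ``config.seed``.

    Returns a cohort DataFrame satisfying the :mod:`elnthresh.staging`
    contract, with latent ground-truth columns ``latent_total_nodes``,
    ``latent_true_positive_nodes`` and ``latent_true_n_stage``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    df = pd.DataFrame({"id": [f"P{i:06d}" for i in range(n)]})
    for cov, table in config.covariate_marginals.items():
        levels = list(table.keys())
        probs = np.asarray(list(table.values()), dtype=float)
        probs = probs / probs.sum()
        df[cov] = rng.choice(levels, size=n, p=probs)
    df["diagnosis_year"] = df["diagnosis_year"].astype(int)

    # continuous age / size drawn uniformly within the sampled group
    a_lo = df["age_group"].map({k: v[0] for k, v in _AGE_BOUNDS.items()}).to_numpy(float)
    a_hi = df["age_group"].map({k: v[1] for k, v in _AGE_BOUNDS.items()}).to_numpy(float)
    df["age_years"] = np.round(a_lo + rng.random(n) * (a_hi - a_lo), 1)
    s_lo = df["size_group"].map({k: v[0] for k, v in _SIZE_BOUNDS.items()}).to_numpy(float)
    s_hi = df["size_group"].map({k: v[1] for k, v in _SIZE_BOUNDS.items()}).to_numpy(float)
    df["size_cm"] = np.round(s_lo + rng.random(n) * (s_hi - s_lo), 1)
    # size_group "<2" spans [0.4, 2): keep strictly below the boundary
    df["size_cm"] = np.minimum(df["size_cm"], s_hi - 0.1)
    df["margin_positive"] = 0

    tn = config.total_nodes_dist
    total_nodes = tn.minimum + _nb_draw(rng, tn.mean - tn.minimum, tn.dispersion, n)

    pm = config.positive_nodes_model
    inv_idx = df["local_invasion"].map({l: i for i, l in enumerate(INVASION_LEVELS)}).to_numpy(float)
    grade_idx = df["grade"].map({l: i for i, l in enumerate(GRADE_LEVELS)}).to_numpy(float)
    size_idx = df["size_group"].map({l: i for i, l in enumerate(SIZE_GROUPS)}).to_numpy(float)
    logit_zero = pm.zero_inflation_logit + pm.zero_inflation_invasion_slope * inv_idx
    p_zero = 1.0 / (1.0 + np.exp(-logit_zero))
    truly_negative = rng.random(n) < p_zero
    mean_k = np.exp(pm.log_mean + pm.invasion_coef * inv_idx + pm.grade_coef * grade_idx + pm.size_coef * size_idx)
    k_pos = 1 + _nb_draw(rng, np.maximum(mean_k - 1, 0.05), pm.dispersion, n)
    true_k = np.where(truly_negative, 0, k_pos)
    true_k = np.minimum(true_k, total_nodes)

    ed = config.eln_dist
    res_factor = df["resection_type"].map(ed.resection_factor).to_numpy(float)
    eln = 1 + _nb_draw(rng, np.maximum(ed.mean * res_factor - 1, 0.5), ed.dispersion, n)
    eln = np.clip(eln, 1, total_nodes)

    if config.detection == "full":
        # full-knowledge pathology examines the entire latent node basin,
        # so every true positive is found; N_tot is independent of the
        # burden K, keeping ELN free of outcome information
        eln = total_nodes.copy()
        pln = true_k.copy()
    else:
        pln = sample_detected_pln(total_nodes, true_k, eln, rng)

    sm = config.survival_model
    lp = np.zeros(n)
    for key, beta in sm.coefficients.items():
        col, level = key.split(":", 1)
        lp += beta * (df[col].astype(str) == level).to_numpy(float)
    lp += sm.burden_loghr * true_k
    lp += _eval_eln_loghazard(sm.eln_loghazard_knots, eln)
    lp -= lp.mean()  # centre so baseline scale keeps its interpretation
    time, event = simulate_survival(lp, sm, config.censoring, rng)

    df["eln"] = eln.astype(int)
    df["pln"] = pln.astype(int)
    df["survival_months"] = np.round(time, 2)
    # rounding may hit 0.0; keep times strictly positive
    df.loc[df["survival_months"] <= 0, "survival_months"] = 0.01
    df["death"] = event
    df["latent_total_nodes"] = total_nodes.astype(int)
    df["latent_true_positive_nodes"] = true_k.astype(int)
    df["latent_true_n_stage"] = staging.assign_nodal_stage(true_k)

    df = staging.derive_columns(df)
    # noise is planted after derivation: corrupted records are meant to be
    # caught (and re-derived) by the eligibility filters downstream
    _inject_eligibility_noise(df, config.eligibility_noise, rng)
    return df


def _inject_eligibility_noise(df, noise, rng):
    """Corrupt a random fraction of records per eligibility rule, for
    filter testing."""
    n = len(df)
    for rule, frac in noise.items():
        if frac <= 0:
            continue
        idx = rng.choice(n, size=max(1, int(round(frac * n))), replace=False)
        if rule == "year":
            df.loc[df.index[idx], "diagnosis_year"] = 2009
        elif rule == "eln":
            df.loc[df.index[idx], "eln"] = 0
            df.loc[df.index[idx], "pln"] = 0
        elif rule == "survival":
            df.loc[df.index[idx], "survival_months"] = 1.5
            df.loc[df.index[idx], "death"] = 1
        elif rule == "missing":
            df.loc[df.index[idx], "grade"] = pd.NA


def scenario_config(scenario: str, n: int, seed: int, marginals: str = "us") -> SimulationConfig:
    """Preset study conditions.

    * ``"null"`` — no ELN-stage and no ELN-survival dependence: detection
      is full knowledge (PLN = K) and g(ELN) = 0;
    * ``"migration"`` — hypergeometric detection, no direct ELN effect:
      every survival association flows through misclassification;
    * ``"planted-breakpoint"`` — migration plus a direct ELN log-hazard
      declining at -0.03 per node up to a knot at ELN = 33 and flat after.
    """
    marg = _copy_marginals(US_MARGINALS if marginals == "us" else CHINA_MARGINALS)
    cfg = SimulationConfig(n_patients=n, seed=seed, covariate_marginals=marg)
    if marginals == "china":
        cfg.eln_dist = ElnDist(mean=31.0, dispersion=2.2)
        cfg.total_nodes_dist = TotalNodesDist(mean=62.0, dispersion=8.0, minimum=8)
    if scenario == "null":
        cfg.detection = "full"
    elif scenario == "migration":
        pass
    elif scenario == "planted-breakpoint":
        knot, slope = 33.0, -0.03
        cfg.survival_model.eln_loghazard_knots = [
            (1.0, slope * 1.0),
            (knot, slope * knot),
            (150.0, slope * knot),
        ]
        # keep the staging-side migration mechanism at full strength but
        # shrink the latent-burden survival channel so the planted direct
        # effect is the dominant survival signal (a well-defined truth for
        # breakpoint-recovery experiments)
        cfg.survival_model.burden_loghr = 0.03
    else:
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    return cfg
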