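"""Cox modelling, PH diagnostics, reverse Kaplan-Meier, subgroups."""

import numpy as np
import pandas as pd
import pytest

from elnthresh import survival_models as sv
from elnthresh.stage_migration import EstimationError
from elnthresh.survival_models import (
    DomainError,
    estimate_hr_sequence,
    evaluate_partial_loglik,
    fit_cox,
    fit_eln_cox,
    reverse_km_median_followup,
    subgroup_analysis,
)

check_ph = sv.test_ph_assumption


def _toy4():
    return pd.DataFrame(
        {
            "survival_months": [1.0, 2.0, 3.0, 4.0],
            "death": [1, 1, 1, 0],
            "z": [1.0, 0.0, 1.0, 0.0],
        }
    )


def test_cox_matches_brute_force_partial_likelihood():
    """The fitted coefficient maximises the hand-written partial
    likelihood of the 4-record toy data (grid search oracle)."""

    def hand_loglik(b):
        # event at t=1 (z=1), risk {1,2,3,4}; t=2 (z=0), risk {2,3,4};
        # t=3 (z=1), risk {3,4}; t=4 censored
        eb = np.exp(b)
        return (
            b - np.log(eb + 1 + eb + 1)
            + 0.0 - np.log(1 + eb + 1)
            + b - np.log(eb + 1)
        )

    grid = np.arange(-5, 5, 1e-4)
    oracle = grid[np.argmax([hand_loglik(b) for b in grid])]
    fit = fit_cox(_toy4(), ["z"])
    assert fit.coefficients["z"][0] == pytest.approx(oracle, abs=1e-3)


def test_constant_covariate_and_zero_events_raise():
    df = _toy4()
    df["c"] = 1.0
    with pytest.raises(EstimationError, match="'c'"):
        fit_cox(df, ["c"])
    dead = _toy4()
    dead["death"] = 0
    with pytest.raises(EstimationError, match="events"):
        fit_cox(dead, ["z"])


def test_true_hazard_ratio_coverage():
    """Two-group exponential data with true HR 2: the 95% CI covers 2 in
    at least 90 of 100 seeded replicates."""
    covered = 0
    for seed in range(100):
        rng = np.random.default_rng(1000 + seed)
        z = rng.integers(0, 2, 2000).astype(float)
        t = rng.exponential(1.0 / np.exp(np.log(2.0) * z))
        c = rng.exponential(2.0, 2000)
        df = pd.DataFrame(
            {"survival_months": np.minimum(t, c), "death": (t <= c).astype(int), "z": z}
        )
        fit = fit_cox(df, ["z"])
        eff = fit.effect("z")
        covered += eff.covers(2.0)
    assert covered >= 90


def test_efron_equals_breslow_without_ties():
    rng = np.random.default_rng(3)
    n = 300
    df = pd.DataFrame(
        {
            "survival_months": rng.exponential(30, n) + rng.random(n) * 1e-3,
            "death": rng.integers(0, 2, n),
            "z": rng.normal(size=n),
            "w": rng.integers(0, 2, n).astype(float),
        }
    )
    assert df["survival_months"].nunique() == n
    fe = fit_cox(df, ["z", "w"], ties_method="efron")
    fb = fit_cox(df, ["z", "w"], ties_method="breslow")
    for c in ["z", "w"]:
        # identical estimands when event times are unique; engines agree
        # to solver precision
        assert fe.coefficients[c][0] == pytest.approx(fb.coefficients[c][0], abs=1e-6)
    be, se, llb = sv._cox_newton(fb._design, df["survival_months"].to_numpy(),
                                 df["death"].to_numpy(), "efron")
    bb, _, _ = sv._cox_newton(fb._design, df["survival_months"].to_numpy(),
                              df["death"].to_numpy(), "breslow")
    np.testing.assert_allclose(be, bb, atol=1e-9)


def test_partial_likelihood_is_maximised(migration_cohort):
    sub = migration_cohort.iloc[:400]
    fit = fit_cox(sub, ["eln", "pln"])
    X = fit._design.to_numpy(float)
    T, E = fit._durations, fit._events
    ll_hat = evaluate_partial_loglik(X, T, E, fit.beta, "efron")
    rng = np.random.default_rng(7)
    for _ in range(50):
        delta = rng.normal(size=len(fit.beta))
        delta *= 0.1 / np.linalg.norm(delta)
        assert evaluate_partial_loglik(X, T, E, fit.beta + delta, "efron") <= ll_hat + 1e-9


def test_baseline_cumulative_hazard_monotone(migration_cohort):
    fit = fit_cox(migration_cohort.iloc[:800], ["eln", "pln"])
    h = fit.baseline_cumulative_hazard.to_numpy()
    assert (np.diff(h) >= 0).all()
    assert fit.n_events <= fit.n


class TestReverseKM:
    def test_all_censored_gives_censoring_time(self):
        assert reverse_km_median_followup([24.0] * 8, [0] * 8) == pytest.approx(24.0)

    def test_all_deaths_not_estimable(self):
        # the reverse curve never drops below 1: no censoring event occurs
        assert np.isnan(reverse_km_median_followup([5, 10, 15], [1, 1, 1]))

    def test_six_record_product_limit_oracle(self):
        # censorings at 20, 40, 50; reverse-KM: S(20)=4/5=0.8,
        # S(40)=0.8*2/3=0.533, S(50)=0.533*1/2=0.267 -> median 50
        times = [10, 20, 30, 40, 50, 60]
        events = [1, 0, 1, 0, 0, 1]
        assert reverse_km_median_followup(times, events) == pytest.approx(50.0)

    def test_empty_input_raises(self):
        with pytest.raises(DomainError):
            reverse_km_median_followup([], [])


class TestPHDiagnostics:
    def test_requires_events(self):
        df = _toy4()
        df["death"] = [1, 0, 0, 0]
        fit = fit_cox(df, ["z"])
        with pytest.raises(DomainError):
            check_ph(fit)

    def test_detects_sign_reversal(self):
        """An effect that reverses direction at t=24 months violates PH
        and is flagged by the scaled-Schoenfeld test."""
        rng = np.random.default_rng(5)
        n = 2000
        z = rng.integers(0, 2, n).astype(float)
        # piecewise hazard: HR=2.2 before t=24, HR=1/2.2 after
        lam1, t_switch = 1 / 40, 24.0
        t1 = rng.exponential(1 / (lam1 * 2.2**z))
        t2 = t_switch + rng.exponential(1 / (lam1 * 2.2 ** (-z)))
        t = np.where(t1 <= t_switch, t1, t2)
        df = pd.DataFrame({
            "survival_months": np.minimum(t, 84.0),
            "death": (t <= 84.0).astype(int),
            "z": z,
        })
        fit = fit_cox(df, ["z"])
        diag = check_ph(fit)
        assert diag.per_covariate.loc["z", "p"] < 0.05
        assert diag.global_p < 0.05

    def test_consistent_data_not_systematically_flagged(self):
        rng = np.random.default_rng(6)
        n = 600
        z = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.4 * z)) * 30
        df = pd.DataFrame({
            "survival_months": np.minimum(t, 84.0),
            "death": (t <= 84.0).astype(int),
            "z": z,
        })
        diag = check_ph(fit_cox(df, ["z"]))
        assert 0.0 <= diag.per_covariate["p"].iloc[0] <= 1.0
        assert 0.0 <= diag.global_p <= 1.0


class TestSubgroups:
    def test_whole_cohort_stratum_equals_overall_fit(self, migration_cohort):
        adj = ["sex", "age_group", "pln"]
        _, overall = fit_eln_cox(migration_cohort, adj)
        table = subgroup_analysis(
            migration_cohort, None, lambda sub, a: fit_eln_cox(sub, a)[1], adj
        )
        assert table.loc[0, "estimate"] == pytest.approx(overall.point, abs=1e-9)

    def test_identity_when_stratifier_unused(self, migration_cohort):
        adj = ["age_group", "pln"]
        _, overall = fit_eln_cox(migration_cohort, adj)
        table = subgroup_analysis(
            migration_cohort.assign(allgrp="all"),
            "allgrp",
            lambda sub, a: fit_eln_cox(sub, a)[1],
            adj,
        )
        assert table.loc[0, "estimate"] == pytest.approx(overall.point, abs=1e-9)

    def test_empty_stratum_reported_ne(self, migration_cohort):
        young = migration_cohort[migration_cohort["age_group"] != ">=80"].reset_index(drop=True)
        table = subgroup_analysis(
            young, "age_group", lambda sub, a: fit_eln_cox(sub, a)[1], ["sex", "pln"]
        )
        row = table[table["stratum"] == ">=80"].iloc[0]
        assert row["estimate"] == "NE"

    def test_effect_confined_to_one_stratum_is_localised(self):
        """ELN improves survival in males only: the male CI excludes 1,
        the female CI covers 1."""
        rng = np.random.default_rng(17)
        n = 20_000
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        eln = rng.integers(5, 41, n)
        lp = np.where(sex == "male", -0.03 * (eln - 20), 0.0)
        t = rng.exponential(1 / np.exp(lp)) * 40
        df = pd.DataFrame({
            "sex": pd.Categorical(sex, categories=["male", "female"]),
            "eln": eln,
            "pln": 0,
            "survival_months": np.minimum(t, 84.0),
            "death": (t <= 84.0).astype(int),
        })
        table = subgroup_analysis(
            df, "sex", lambda sub, a: fit_cox(sub, ["eln"]).effect("eln"), ["sex"]
        )
        male = table[table["stratum"] == "male"].iloc[0]
        female = table[table["stratum"] == "female"].iloc[0]
        assert male["ci_high"] < 1.0
        assert female["ci_low"] < 1.0 < female["ci_high"]


def test_hr_sequence_reference_unity(migration_cohort):
    seq = estimate_hr_sequence(migration_cohort, adjustment_set=["sex", "pln"])
    ref = seq.table[seq.table["is_reference"]]
    assert ref["log_point"].iloc[0] == 0.0 and ref["se_log"].iloc[0] == 0.0
    assert seq.scale == "hazard ratio"
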