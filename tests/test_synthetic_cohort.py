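"""Generator contracts: detection mechanism, survival model, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from elnthresh import staging
from elnthresh import synthetic_cohort as sc
from elnthresh.synthetic_cohort import (
    Censoring,
    ConfigurationError,
    DomainError,
    SimulationConfig,
    SurvivalModel,
    generate_cohort,
    sample_detected_pln,
    scenario_config,
    simulate_survival,
)


class TestCohortContract:
    def test_bounds_and_stage_consistency(self):
        cfg = SimulationConfig(n_patients=1000, seed=7)
        df = generate_cohort(cfg)
        assert len(df) == 1000
        assert (df["eln"] >= 1).all()
        assert (df["eln"] <= df["latent_total_nodes"]).all()
        assert (df["pln"] >= 0).all()
        assert (df["pln"] <= np.minimum(df["eln"], df["latent_true_positive_nodes"])).all()
        expected = staging.assign_nodal_stage(df["pln"].to_numpy())
        assert (df["n_stage"].astype(str) == np.asarray(expected).astype(str)).all()
        assert (df["survival_months"] > 0).all()

    def test_full_knowledge_detection_removes_migration(self):
        cfg = SimulationConfig(n_patients=3000, seed=5, detection="full")
        df = generate_cohort(cfg)
        assert (df["n_stage"].astype(str) == df["latent_true_n_stage"].astype(str)).all()

    def test_hypergeometric_detection_migrates_some_records(self, migration_cohort):
        migrated = (
            migration_cohort["n_stage"].astype(str)
            != migration_cohort["latent_true_n_stage"].astype(str)
        )
        assert migrated.mean() > 0

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_patients=500, seed=42)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        staging.write_cohort(generate_cohort(cfg), a, latent=True)
        staging.write_cohort(generate_cohort(SimulationConfig(n_patients=500, seed=42)), b, latent=True)
        assert a.read_bytes() == b.read_bytes()

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="n_patients"):
            generate_cohort(SimulationConfig(n_patients=0))
        bad = SimulationConfig(n_patients=10)
        bad.covariate_marginals["sex"] = {"male": 0.7, "female": 0.7}
        with pytest.raises(ConfigurationError, match="sex"):
            generate_cohort(bad)
        bad2 = SimulationConfig(n_patients=10, censoring=Censoring(horizon=2.0))
        with pytest.raises(ConfigurationError, match="horizon"):
            generate_cohort(bad2)

    def test_eligibility_noise_plants_violations(self):
        cfg = SimulationConfig(
            n_patients=2000,
            seed=3,
            eligibility_noise={"year": 0.02, "eln": 0.02, "survival": 0.02, "missing": 0.02},
        )
        df = generate_cohort(cfg)
        _, log = staging.apply_eligibility_filters(df)
        for reason in [
            staging.REASON_YEAR,
            staging.REASON_NO_ELN,
            staging.REASON_SHORT_SURVIVAL,
            staging.REASON_MISSING,
        ]:
            assert log.counts.get(reason, 0) > 0


class TestDetection:
    def test_hypergeometric_closed_form_mean(self):
        rng = np.random.default_rng(0)
        draws = sample_detected_pln(
            np.full(100_000, 40), np.full(100_000, 8), np.full(100_000, 20), rng
        )
        # E = n*K/N = 20*8/40 = 4; allow 4 Monte-Carlo standard errors
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 4.0) < 4 * se

    def test_degenerate_compositions(self):
        rng = np.random.default_rng(1)
        assert (sample_detected_pln(np.full(200, 30), np.zeros(200, int), np.full(200, 10), rng) == 0).all()
        assert (sample_detected_pln(np.full(200, 25), np.full(200, 25), np.full(200, 12), rng) == 12).all()

    def test_bound_violations_raise(self):
        rng = np.random.default_rng(2)
        with pytest.raises(DomainError):
            sample_detected_pln(10, 11, 5, rng)
        with pytest.raises(DomainError):
            sample_detected_pln(10, 5, 0, rng)
        with pytest.raises(DomainError):
            sample_detected_pln(10, 5, 11, rng)

    def test_detected_count_stochastically_increasing_in_eln(self):
        """Examining more nodes can only shift detected positives upward."""
        rng = np.random.default_rng(3)
        n = 20_000
        lo = sample_detected_pln(np.full(n, 40), np.full(n, 8), np.full(n, 10), rng)
        hi = sample_detected_pln(np.full(n, 40), np.full(n, 8), np.full(n, 25), rng)
        for k in range(9):
            cdf_lo = (lo <= k).mean()
            cdf_hi = (hi <= k).mean()
            assert cdf_hi <= cdf_lo + 0.015

    def test_mean_detected_matches_independent_simulation_oracle(self):
        """Cohort-level detection agrees with re-simulating the
        hypergeometric draw from the same latent parameters."""
        df = generate_cohort(SimulationConfig(n_patients=50_000, seed=9))
        sel = df[df["eln"] == 20]
        assert len(sel) > 300
        oracle_rng = np.random.default_rng(12345)
        reps = np.empty(40)
        N = sel["latent_total_nodes"].to_numpy()
        K = sel["latent_true_positive_nodes"].to_numpy()
        for r in range(40):
            reps[r] = oracle_rng.hypergeometric(K, N - K, 20).mean()
        # the observed mean is one more replicate of the same draw
        spread = reps.std(ddof=1) * np.sqrt(1 + 1 / len(reps))
        assert abs(sel["pln"].mean() - reps.mean()) < 3 * max(spread, 1e-3)

    def test_occult_burden_declines_with_eln_among_declared_n0(self):
        """The mechanism behind the node-negative survival signal: among
        declared-N0 patients with occult disease, deeper sampling leaves
        smaller residual burden."""
        df = generate_cohort(SimulationConfig(n_patients=50_000, seed=21))
        n0 = df[(df["pln"] == 0) & (df["latent_true_positive_nodes"] > 0)]
        bins = pd.cut(n0["eln"], [0, 10, 20, 30, 200])
        means = n0.groupby(bins, observed=True)["latent_true_positive_nodes"].mean()
        assert len(means) == 4
        assert (np.diff(means.to_numpy()) < 0).all()


class TestSurvivalDraws:
    def test_exponential_median_closed_form(self):
        rng = np.random.default_rng(4)
        model = SurvivalModel(shape=1.0, scale=50.0, coefficients={}, burden_loghr=0.0)
        cens = Censoring(horizon=np.inf, rate=0.0)
        t, e = simulate_survival(np.zeros(100_000), model, cens, rng)
        assert e.all()
        assert np.median(t) == pytest.approx(50.0 * np.log(2), rel=0.02)

    def test_proportional_hazards_halves_median(self):
        rng = np.random.default_rng(5)
        model = SurvivalModel(shape=1.0, scale=50.0, coefficients={}, burden_loghr=0.0)
        cens = Censoring(horizon=np.inf, rate=0.0)
        t0, _ = simulate_survival(np.zeros(100_000), model, cens, rng)
        t1, _ = simulate_survival(np.full(100_000, np.log(2)), model, cens, rng)
        assert np.median(t1) / np.median(t0) == pytest.approx(0.5, rel=0.03)

    def test_administrative_horizon_caps_times(self):
        rng = np.random.default_rng(6)
        model = SurvivalModel(shape=1.0, scale=500.0, coefficients={}, burden_loghr=0.0)
        t, e = simulate_survival(np.zeros(5000), model, Censoring(horizon=84.0, rate=0.0), rng)
        assert (t <= 84.0).all()
        assert (e[t >= 84.0] == 0).all()

    def test_nonpositive_weibull_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(DomainError):
            simulate_survival(np.zeros(5), SurvivalModel(shape=0.0), Censoring(), rng)


def test_scenarios_differ_only_where_documented():
    null = scenario_config("null", 100, 1)
    mig = scenario_config("migration", 100, 1)
    plant = scenario_config("planted-breakpoint", 100, 1)
    assert null.detection == "full" and mig.detection == "hypergeometric"
    assert mig.survival_model.eln_loghazard_knots is None
    assert plant.survival_model.eln_loghazard_knots is not None
    with pytest.raises(ConfigurationError):
        scenario_config("bogus", 100, 1)
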