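"""End-to-end orchestration: simulate/load -> filter -> fit -> breakpoint
-> validate, with reproducible artifacts.

Every run writes delimited tables plus a machine-readable ``summary.json``
carrying the configuration hash and seed; re-running with an identical
configuration and seed reproduces the summary byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import breakpoint as bp
from . import stage_migration as smig
from . import staging
from . import survival_models as sv
from . import synthetic_cohort as sc
from . import threshold_validation as tv

logger = logging.getLogger("elnthresh")

__all__ = ["RunConfig", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and parameter."""


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    # input: either a cohort file or a simulation scenario
    cohort_path: str | None = None
    scenario: str = "migration"  # null | migration | planted-breakpoint
    n_patients: int = 20000
    seed: int = 0
    marginals: str = "us"  # us | china

    # analysis options
    reference_eln: str | int = "modal"
    min_count_per_level: int = 5
    adjustment_migration: list = field(default_factory=lambda: list(smig.MIGRATION_ADJUSTMENT))
    adjustment_survival: list = field(default_factory=lambda: list(sv.SURVIVAL_ADJUSTMENT))
    bandwidth: float = bp.DEFAULT_BANDWIDTH
    robustify_iterations: int = 3
    min_segment: int = 3
    weighting: str | None = "inverse_variance"
    scan_on: str = "smoothed"
    permutations: int = 0
    thresholds: list | None = None  # override; default: detected breakpoints
    horizon_pct: float = 95.0
    auc_variant: str = "incident"
    with_ordinal: bool = True

    # output
    out_dir: str = "elnthresh_run"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.cohort_path is None and self.scenario not in ("null", "migration", "planted-breakpoint"):
            raise PipelineError(f"config: unknown scenario {self.scenario!r}")
        if not 0 < self.bandwidth <= 1:
            raise PipelineError(f"config: bandwidth must lie in (0, 1], got {self.bandwidth}")
        if self.min_segment < 2:
            raise PipelineError("config: min_segment must be at least 2")
        if self.min_count_per_level < 1:
            raise PipelineError("config: min_count_per_level must be at least 1")
        if not 0 < self.horizon_pct <= 100:
            raise PipelineError(f"config: horizon_pct must lie in (0, 100], got {self.horizon_pct}")
        if self.auc_variant not in ("incident", "cumulative"):
            raise PipelineError(f"config: unknown auc_variant {self.auc_variant!r}")
        if self.n_patients < 1:
            raise PipelineError("config: n_patients must be positive")
        if self.scan_on not in ("smoothed", "raw"):
            raise PipelineError(f"config: scan_on must be 'smoothed' or 'raw', got {self.scan_on!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write artifacts under ``config.out_dir``.

    Returns the artifact dictionary (in-memory objects plus the summary).
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"config": config}
    summary: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
    }
    timings: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            timings[name] = round(time.time() - t0, 2)
            logger.info("stage %s done in %.1fs", name, time.time() - t0)

        return deco

    @stage("cohort")
    def _cohort():
        if config.cohort_path:
            artifacts["cohort_raw"] = staging.read_cohort(config.cohort_path)
        else:
            cfg = sc.scenario_config(config.scenario, config.n_patients, config.seed, config.marginals)
            artifacts["cohort_raw"] = sc.generate_cohort(cfg)
        summary["n_input"] = len(artifacts["cohort_raw"])

    @stage("filter")
    def _filter():
        cohort, log = staging.apply_eligibility_filters(artifacts["cohort_raw"])
        artifacts["cohort"] = cohort
        artifacts["exclusions"] = log
        staging.write_cohort(cohort, out / "cohort.csv")
        (out / "exclusion_log.json").write_text(json.dumps(log.to_dict(), indent=2, sort_keys=True))
        summary["exclusions"] = log.to_dict()
        summary["n_analyzed"] = len(cohort)

    @stage("fit")
    def _fit():
        cohort = artifacts["cohort"]
        est = smig.fit_binomial_migration(cohort, config.adjustment_migration)
        summary["or_binomial_per_eln"] = est.to_dict()
        if config.with_ordinal:
            mres = smig.fit_multinomial_migration(cohort, config.adjustment_migration)
            summary["or_multinomial_per_eln"] = {
                "ordinal_summary": mres.ordinal.to_dict(),
                "per_category": {
                    k: (v.to_dict() if v is not None else "NE") for k, v in mres.per_category.items()
                },
            }
            artifacts["multinomial"] = mres
        _, hr = sv.fit_eln_cox(cohort, config.adjustment_survival)
        summary["hr_per_eln"] = hr.to_dict()
        orseq = smig.estimate_or_sequence(
            cohort,
            outcome="binomial",
            adjustment_set=config.adjustment_migration,
            reference_eln=config.reference_eln,
            min_count_per_level=config.min_count_per_level,
        )
        hrseq = sv.estimate_hr_sequence(
            cohort,
            adjustment_set=config.adjustment_survival,
            reference_eln=config.reference_eln,
            min_count_per_level=config.min_count_per_level,
        )
        artifacts["or_sequence"], artifacts["hr_sequence"] = orseq, hrseq
        orseq.write(out / "or_sequence.csv")
        hrseq.write(out / "hr_sequence.csv")
        summary["reference_eln"] = {"or": orseq.reference_eln, "hr": hrseq.reference_eln}
        summary["median_followup_months"] = sv.reverse_km_median_followup(
            cohort["survival_months"], cohort["death"]
        )

    @stage("breakpoint")
    def _breakpoint():
        bkp = {}
        for key, seq in (("or_binomial", artifacts["or_sequence"]), ("hr", artifacts["hr_sequence"])):
            series, res = bp.sequence_breakpoint(
                seq,
                bandwidth=config.bandwidth,
                robustify_iterations=config.robustify_iterations,
                min_segment=config.min_segment,
                weighting=config.weighting,
                use=config.scan_on,
                permutations=config.permutations,
                rng=config.seed,
            )
            artifacts[f"{key}_series"] = series
            artifacts[f"{key}_breakpoint"] = res
            pd.DataFrame(
                {"eln": series.x, "log_effect": series.y_raw, "smoothed": series.y_fit}
            ).to_csv(out / f"{key}_smoothed.csv", index=False)
            pd.DataFrame(
                sorted(res.candidate_scan.items()), columns=["split_eln", "f_statistic"]
            ).to_csv(out / f"{key}_scan.csv", index=False)
            bkp[key] = {
                "break_eln": res.break_x,
                "f_statistic": res.f_statistic,
                "p_value": res.p_value,
                "no_break": res.no_break,
            }
            if res.permutation_p is not None:
                bkp[key]["permutation_p"] = res.permutation_p
        summary["breakpoints"] = bkp
        summary["minimal_threshold_eln"] = bkp["or_binomial"]["break_eln"]
        summary["optimal_threshold_eln"] = bkp["hr"]["break_eln"]

    @stage("validate")
    def _validate():
        cohort = artifacts["cohort"]
        thresholds = config.thresholds
        if thresholds is None:
            thresholds = sorted(
                {
                    int(summary["minimal_threshold_eln"]),
                    int(summary["optimal_threshold_eln"]),
                }
            )
        validations = {}
        artifacts["validations"] = {}
        for t in thresholds:
            val = tv.dichotomize_and_fit(
                cohort,
                t,
                survival_adjustment=config.adjustment_survival,
                migration_adjustment=config.adjustment_migration,
                auc_variant=config.auc_variant,
                horizon_pct=config.horizon_pct,
            )
            artifacts["validations"][t] = val
            validations[str(t)] = val.to_dict()
            val.adjusted_curves.to_csv(out / f"adjusted_curves_eln{t}.csv", index=False)
            pd.DataFrame({"time": val.auc.time_grid, "auc": val.auc.auc_t}).to_csv(
                out / f"auc_eln{t}.csv", index=False
            )
        summary["validation"] = validations

    summary_clean = _round_floats(summary)
    (out / "summary.json").write_text(json.dumps(summary_clean, indent=2, sort_keys=True))
    # timings are logged separately: they must not perturb the reproducible
    # summary contract
    (out / "timings.json").write_text(json.dumps(timings, indent=2, sort_keys=True))
    artifacts["summary"] = summary_clean
    artifacts["timings"] = timings
    return artifacts
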