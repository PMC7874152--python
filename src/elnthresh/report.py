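"""Human-readable report rendering for pipeline runs.

Produces a Markdown report plus figures: per-ELN effect sequences with
the LOWESS curve and breakpoint marker, adjusted survival curves for the
threshold dichotomy, and the time-dependent AUC panel with the
integrated AUC.  The machine-readable contract is ``summary.json``;
figures and the report are conveniences.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["render_report"]


class ReportError(RuntimeError):
    pass


def render_report(run_dir, out_name: str = "report.md") -> Path:
    """Render ``report.md`` and figures from a pipeline output directory."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise ReportError(f"missing artifact: {summary_path}")
    summary = json.loads(summary_path.read_text())

    lines = ["# Examined-lymph-node threshold analysis", ""]
    lines += [f"Configuration hash `{summary['config_hash']}`, seed {summary['seed']}.", ""]

    lines += ["## Cohort", ""]
    lines += [f"- records in: {summary.get('n_input', 'NA')}"]
    lines += [f"- records analyzed: {summary.get('n_analyzed', 'NA')}"]
    exc = summary.get("exclusions", {})
    for reason, count in exc.get("counts", {}).items():
        lines += [f"- excluded, {reason}: {count}"]
    if "median_followup_months" in summary:
        lines += [f"- median follow-up (reverse Kaplan-Meier): {summary['median_followup_months']:.1f} months"]
    lines += [""]

    lines += ["## Stage migration and survival per additional examined node", ""]
    for key, label in [
        ("or_binomial_per_eln", "OR, node-positive vs node-negative"),
        ("hr_per_eln", "HR, overall survival"),
    ]:
        if key in summary:
            e = summary[key]
            lines += [
                f"- {label}: {e['point']:.3f} (95% CI {e['ci_low']:.3f}-{e['ci_high']:.3f}, p={e['p_value']:.2g})"
            ]
    if "or_multinomial_per_eln" in summary:
        e = summary["or_multinomial_per_eln"]["ordinal_summary"]
        lines += [
            f"- OR, lower-to-higher declared stage (proportional odds): "
            f"{e['point']:.3f} (95% CI {e['ci_low']:.3f}-{e['ci_high']:.3f})"
        ]
    lines += [""]

    if "breakpoints" in summary:
        lines += ["## Structural breakpoints (Chow sup-F on LOWESS-fitted sequences)", ""]
        lines += ["| sequence | breakpoint (ELN) | F | p |", "|---|---|---|---|"]
        for key, row in summary["breakpoints"].items():
            lines += [
                f"| {key} | {row['break_eln']:.0f} | {row['f_statistic']:.1f} | {row['p_value']:.3g} |"
            ]
        lines += [""]
        lines += [
            f"Minimal threshold (negative-to-positive migration): **{summary['minimal_threshold_eln']:.0f} ELNs**; "
            f"optimal threshold (survival): **{summary['optimal_threshold_eln']:.0f} ELNs**.",
            "",
        ]
        _plot_sequences(run_dir, summary)

    if summary.get("validation"):
        lines += ["## Threshold validation", ""]
        for t, val in summary["validation"].items():
            hr, orm = val["hr_above_vs_below"], val["or_migration_above_vs_below"]
            lines += [
                f"### ELN >= {t} (n above {val['n_above']}, below {val['n_below']})",
                "",
                f"- adjusted HR: {hr['point']:.2f} (95% CI {hr['ci_low']:.2f}-{hr['ci_high']:.2f}, p={hr['p_value']:.2g})",
                f"- adjusted migration OR: {orm['point']:.2f} (95% CI {orm['ci_low']:.2f}-{orm['ci_high']:.2f})",
            ]
            if "iauc" in val:
                lines += [f"- integrated AUC of the adjusted Cox model: {val['iauc']:.3f}"]
            lines += [""]
            _plot_validation(run_dir, t)
    else:
        lines += ["## Threshold validation", "", "Validation stage was not run.", ""]

    report = run_dir / out_name
    report.write_text("\n".join(lines))
    return report


def _plot_sequences(run_dir: Path, summary: dict) -> None:
    import pandas as pd

    for key, label in [("or_binomial", "log OR"), ("hr", "log HR")]:
        f = run_dir / f"{key}_smoothed.csv"
        if not f.exists():
            continue
        df = pd.read_csv(f)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(df["eln"], df["log_effect"], "o", ms=3, color="tab:blue", label="per-level estimate")
        ax.plot(df["eln"], df["smoothed"], "-", color="tab:red", label="LOWESS (bandwidth 2/3)")
        brk = summary["breakpoints"][key]["break_eln"]
        ax.axvline(brk, color="tab:green", ls="--", label=f"breakpoint {brk:.0f}")
        ax.set_xlabel("examined lymph nodes")
        ax.set_ylabel(label)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(run_dir / f"fig_{key}_sequence.png", dpi=120)
        plt.close(fig)


def _plot_validation(run_dir: Path, threshold: str) -> None:
    import pandas as pd

    curves = run_dir / f"adjusted_curves_eln{threshold}.csv"
    if curves.exists():
        df = pd.read_csv(curves)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.step(df["time"], df["below"], where="post", label=f"ELN < {threshold}")
        ax.step(df["time"], df["above"], where="post", label=f"ELN >= {threshold}")
        ax.set_xlabel("months")
        ax.set_ylabel("adjusted survival")
        ax.set_ylim(0, 1)
        ax.legend()
        fig.tight_layout()
        fig.savefig(run_dir / f"fig_adjusted_survival_eln{threshold}.png", dpi=120)
        plt.close(fig)
    aucf = run_dir / f"auc_eln{threshold}.csv"
    if aucf.exists():
        df = pd.read_csv(aucf)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(df["time"], df["auc"], ".", ms=3)
        ax.axhline(0.5, color="grey", ls=":")
        ax.set_xlabel("months")
        ax.set_ylabel("AUC(t)")
        ax.set_ylim(0, 1)
        fig.tight_layout()
        fig.savefig(run_dir / f"fig_auc_eln{threshold}.png", dpi=120)
        plt.close(fig)
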