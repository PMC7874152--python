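# elnthresh

Threshold analysis of the examined-lymph-node (ELN) count in resected
non-metastatic gastric adenocarcinoma.

## The problem

How many regional lymph nodes must be removed and examined after
gastrectomy?  Too few examined nodes and patients with occult nodal
metastases are declared node-negative — the stage-migration (Will
Rogers) phenomenon — which misguides adjuvant therapy and makes
under-sampled strata look prognostically worse.  Registry analyses
address this by asking two questions: after multivariable adjustment,
how do the odds of a higher declared nodal stage and the hazard of
death change *per additional examined node*, and at which ELN count do
those trends structurally flatten?

`elnthresh` implements that analysis as a reusable, tested pipeline for
epidemiologists and surgical-oncology outcomes researchers:

1. **Cohort model and eligibility filters** (`elnthresh.staging`) —
   patient-level records with AJCC 7th-edition nodal staging
   (N0 = 0, N1 = 1–2, N2 = 3–6, N3a = 7–15, N3b ≥ 16 positive nodes),
   lymph-node ratio, and the standard registry eligibility rules
   (surgery 2010–2016, ≥ 1 examined node, survival ≥ 3 months, complete
   analysis variables) with a fully reconciled exclusion log.
2. **Stage-migration models** (`elnthresh.stage_migration`) — binomial
   logistic regression of declared node-positivity and
   multinomial/proportional-odds models over the five declared stages,
   each per additional ELN with multivariable adjustment; per-ELN-level
   odds-ratio sequences against the modal examined count.
3. **Survival models** (`elnthresh.survival_models`) — multivariable Cox
   proportional-hazards regression (Efron ties; Breslow optional), per-ELN
   hazard-ratio sequences, scaled-Schoenfeld PH diagnostics, reverse
   Kaplan–Meier follow-up, and subgroup analyses with the registry "NE"
   (not estimable) convention.
4. **Breakpoint engine** (`elnthresh.breakpoint`) — LOWESS smoothing
   (tricube local-linear, bandwidth 2/3, bisquare robustification) of the
   log-effect sequences and structural-break location by a Chow-type
   sup-F scan, with naive and permutation-calibrated p-values.
5. **Threshold validation** (`elnthresh.threshold_validation`) —
   dichotomized Cox and ordinal migration models at a candidate
   threshold, corrected-group-prognosis adjusted survival curves, and
   incident/dynamic time-dependent ROC with the integrated AUC.
6. **Synthetic cohorts** (`elnthresh.synthetic_cohort`) — a generator
   with an explicit stage-migration mechanism: latent regional nodes,
   hypergeometric detection of true positives among the examined nodes,
   and Weibull proportional-hazards survival driven by the *true* nodal
   burden, with optional planted breakpoints for recovery experiments.

The statistical core, for ELN count `e` entered as dummy-coded levels
against the modal count `e*`:

```
logit P(N+ | e, x)   = α_e + xβ            (per-level OR_e = exp(α_e))
λ(t | e, x)          = λ0(t) exp(γ_e + xδ) (per-level HR_e = exp(γ_e))
F(c) = [(RSS_pooled − RSS_≤c − RSS_>c)/2] / [(RSS_≤c + RSS_>c)/(n − 4)]
```

with `{log OR_e}` and `{log HR_e}` LOWESS-smoothed over `e` and the
breakpoint `ĉ = argmax_c F(c)`.  The survival breakpoint is the
*optimal* threshold; the negative-to-positive migration breakpoint is
the *minimal* threshold.

## Worked example

```bash
elnthresh run --scenario planted-breakpoint --n 8000 --seed 3 --out run1
elnthresh report --run-dir run1
```

The run simulates a US-like cohort of 8,000 patients whose survival
carries a planted log-hazard knot at 33 examined nodes on top of the
stage-migration mechanism, then runs filter → fit → breakpoint →
validate.  `run1/summary.json` from this exact invocation contains
(abridged):

```
"or_binomial_per_eln":  {"point": 1.0233, "ci_low": 1.0188, "ci_high": 1.0279}
"hr_per_eln":           {"point": 0.9678, "ci_low": 0.9638, "ci_high": 0.9718}
"minimal_threshold_eln": 25.0
"optimal_threshold_eln": 37.0
"validation": {"37": {"hr_above_vs_below": {"point": 0.555, ...},
                      "or_migration_above_vs_below": {"point": 2.147, ...},
                      "iauc": 0.679}}
```

Read: each additional examined node raises the adjusted odds of declared
node-positive disease by ~2.3% and lowers the adjusted death hazard by
~3.2%; the smoothed hazard-ratio sequence bends at 37 examined nodes
(planted truth: 33; the location tightens at larger n); patients with at
least that many examined nodes have roughly half the adjusted mortality
hazard and 2.1-fold the odds of a higher declared stage, and the
adjusted Cox model incorporating the dichotomized ELN count
discriminates survival with an integrated AUC of 0.68.  `report.md` renders the same numbers with the effect-sequence,
adjusted-survival and AUC(t) figures.

## Scope notes

The package analyses cohort *files* with the documented column layout
(see `elnthresh.staging.COHORT_COLUMNS`); retrieval or parsing of any
specific registry's export format, ICD-O-3 coding, and station-level
(D1/D2 compartment) node topology are out of scope.  Observational
associations estimated here do not establish that examining more nodes
causes better survival; see `docs/methods.md` for the model's
assumptions and limitations.
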