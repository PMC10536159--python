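# Methods

## Problem and scope

Spontaneous-report databases such as FAERS accumulate reports of suspected
adverse drug reactions. Disproportionality analysis asks, for a target drug
and each adverse-event term, whether the pair is reported more often than
expected if drug and event were independent. `faersig` implements the
standard four-algorithm screen (ROR, PRR, BCPNN information component,
EBGM) on FAERS-style quarterly tables, together with the ETL steps the
analysis needs (parsing, case deduplication, exposure flagging, date
windowing, PT→SOC aggregation) and a simulator for validating the whole
chain against known ground truth. It does not attempt to reproduce absolute
counts from the real FAERS extract (not shipped) or a licensed MedDRA
dictionary.

## Data model and preprocessing

**Counting unit.** All contingency tables count (deduplicated case,
distinct term at level) pairs. A case reporting three PTs contributes three
PT-level units; if two of those PTs share a SOC, it contributes two — not
three — SOC-level units. With this unit, `a` equals the number of exposed
cases reporting the term, matching the "case numbers" convention of
published FAERS screens.

**Deduplication.** FAERS re-publishes a case with each follow-up. We keep,
per `caseid`, the row with the highest `caseversion`, breaking ties by
latest `fda_dt` (null dates sort before any dated record — an arbitrary but
fixed rule), then by highest `primaryid`. This is the FDA-recommended
current-record rule; the operation is idempotent and the output count equals
the number of distinct caseids.

**Exposure.** FAERS drug names are uncurated free text, so the target is
matched by case-insensitive word-boundary substring against a synonym list
("epirubicin" matches "EPIRUBICIN HYDROCHLORIDE" but not "EPIRUBICINE"),
restricted to configurable role codes (default PS, primary suspect only).

**Age conversion.** FAERS `age_cod` units are converted to years with
factors DEC→×10, YR→×1, MON→÷12, WK→÷52.18, DY→÷365.25, HR→÷8766; unknown
codes and negative values become null. Age bins are left-closed
([20,30), …, [80,∞)) so integer bin edges land in the upper bin.

**Date window.** Applied on `fda_dt` after deduplication and exposure
flagging, inclusive of both quarter boundaries; null dates are dropped with
a logged count.

**PT→SOC mapping.** MedDRA is licensed, so the package consumes any
two-column-plus-code hierarchy table and never ships dictionary content.
Terms are normalized (trim, case-fold, collapse whitespace) exactly once on
load; duplicate PTs with conflicting SOCs are a hard error; unmapped PTs are
returned with an explicit marker and counted, never silently dropped.
Multi-axial PTs must be pre-reduced to their primary SOC.

## Statistics

With cells a, b, c, d and N = a+b+c+d:

- ROR = ad/bc, CI = exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)), z = 1.96.
- PRR = (a/(a+b))/(c/(c+d)), CI = exp(ln PRR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d))).
- IC = log₂(aN/((a+b)(a+c))); EBGM = aN/((a+b)(a+c)) with
  EBGM05 = EBGM·exp(−z·√(1/a+1/b+1/c+1/d)). IC = log₂(EBGM) holds
  identically (the two are one closed form on two scales), and published
  screens that obey this identity are reproduced by construction. "EBGM"
  here is the unshrunk observed/expected reporting ratio with a Wald-style
  interval; the full two-gamma MGPS posterior is out of scope.
- V(IC): the delta-method variance of the log₂ observed/expected ratio,
  V(IC) = (1/ln 2)²·(1/a − 1/(a+b) − 1/(a+c) + 1/N), clipped at 0 in
  degenerate corners. `ic_variance="bayes"` switches the SD to the
  closed-form Bayesian credibility variance of the classic BCPNN
  (Dirichlet/Beta priors with α₁=β₁=1, α=β=2, γ₁₁=1); the IC point estimate
  is unchanged, so the IC/EBGM identity is preserved under both variants.
- Chi-square: Pearson on the 2×2, Yates-corrected by default (the MHRA
  convention paired with PRR), switchable; always computed on the raw
  counts; degenerate margins give NaN.

**Signal rules.** ROR: a ≥ 3 and ROR lower bound > 1. PRR: same form.
BCPNN: IC − 2SD > 0, with bands (0,1.5] "+", (1.5,3] "++", >3 "+++".
EBGM: EBGM05 > 2. Consensus ("ADR") = all four. Screens report the cascade
of counts (all terms with a ≥ 1, ROR∧PRR, ROR∧PRR∧BCPNN, consensus) and are
ranked by EBGM descending, ties by a descending then term name, for
deterministic output. No multiplicity adjustment is applied — these are
fixed per-term threshold rules, as is conventional for screening.

**Zero cells.** Any zero cell leaves the ratio statistics undefined. The
default policy adds 0.5 to all four cells of affected tables only, flagging
them `continuity_corrected`, so screens stay total while marking affected
rows; `zero_cell="strict"` propagates NaN instead (NaN never flags). The
min-a gate always uses the raw count.

**Reverse screen.** For one event PT, every drug appearing as primary
suspect on a case reporting that event is screened against it with the same
machinery (that drug vs all others). Combination products — names
containing the `\` ingredient separator — are excluded by default because a
two-ingredient product cannot attribute the signal to a single substance.

**A note on monotonicity.** The odds ratio is strictly increasing in `a`
with b, c, d fixed; the observed/expected ratio EBGM is not, since `a`
enters both margins (e.g. (1,1,1,10) → 3.25 but (2,1,1,10) → 3.11).
Similarly EBGM/PRR → c/(a+c) as d → ∞, approaching 1 only in the rare-event
regime a ≪ c. The test suite asserts these corrected forms.

## The simulator

`synthetic_data.generate` draws, per case: one PS drug (the target with
probability `p_target_ps` = 0.12, else a weighted catalogue choice, with
optional SS/C concomitants); independent Bernoulli reaction PTs; sex, age
bin, country and outcome codes from fixed marginals; and a receipt date
uniform over the window (2014Q1–2023Q1 by default). The demographic
marginals (65% female, 29% age unknown, modal bin 50–59, country mix led by
CN/IT/FR/GB/DE, hospitalization ≈ 33%, death and life-threatening ≈ 5.6%
each, disability ≈ 2.8%) mirror a published epirubicin reporting cohort so
the descriptive summary exercises realistic shapes.

**Association injection.** An injected (drug, pt, θ) multiplies the
conditional odds of the PT given that the drug is the case's PS drug:
q = θp/(1 − p + θp). The case-level exposure–event odds ratio is then
exactly θ. Under the (case, distinct-term) counting unit the screen's ROR
estimand is θ/(1 + (θ−1)p), an attenuation below 2% at the default rare
baselines (p = 0.002) — the injectable terms are deliberately rare so that
θ is the effective estimand, as it is for rare events in real data.

**At-least-one-reaction redraw.** FAERS reports always list a reaction, so
empty PT draws are redrawn. This scales every PT marginal within an
exposure arm by the same factor 1/(1 − ∏(1 − q_k)), which cancels from the
ROR (it divides both a/c and b/d), leaving calibration and recovery
unaffected; the ground-truth expected counts use the exact conditional
marginal.

**Duplicates.** `inject_duplicates` appends, for a seeded fraction of
cases, an earlier version: strictly lower `caseversion`, receipt date 30–180
days earlier, perturbed `primaryid`, truncated reaction list and no
outcomes — content that must lose deduplication. Originals are emitted at
caseversion 2 so a strictly lower version always exists.

**Event catalogue.** 36 PTs in three tiers — 6 common constitutional terms
(p 0.10–0.25), 20 mid-frequency terms (p 0.008–0.06), 10 rare terms
(p 0.002). The tier gap keeps the calibration population (expected a ≥ 5 at
20,000 cases) in the regime where the Wald interval's normal approximation
is adequate, while the rare tier hosts injections.

**Randomness.** One root seed feeds named `SeedSequence` child streams
(drugs, events, demographics, dates, duplicates), so each stage is
independently reproducible and written quarters are byte-identical across
reruns.

**What the simulator does not emulate.** PTs are conditionally independent
given exposure (no event co-occurrence syndromes); drug names are clean
(no misspellings, one salt form); reporting rates are time-constant; there
is no masking/competition bias from other strong signals, no
stratification-worthy confounding by age or sex, and no within-case
correlation between demographics and events. Passing tests therefore
demonstrate correctness of the estimators and plumbing under a clean
reporting model, not robustness to real FAERS data quality.

## Validation conditions

The statistical validation in `tests/test_acceptance.py` uses: exact
agreement (1e−12 relative) with an independently coded scalar oracle on
1,200 random tables; null calibration over 200 replicates of 20,000 cases
(pooled one-sided exceedance of the ROR lower bound within 0.025 ± 0.01 on
terms with expected a ≥ 5); and recovery of θ ∈ {2, 5, 10} over 100
replicates of 50,000 cases each (median within 10%, CI coverage in
[0.90, 0.98]). The published epirubicin reference table embedded in
`faersig.datasets` validates the formula identities (IC vs log₂ EBGM,
points implied by interval bounds) at printed precision.
`scripts/acceptance.py` re-runs these analyses at sizes chosen to finish in
about half a minute (100 null replicates; 60 recovery replicates at θ = 5;
10 at θ = 10).

## Known limitations

- Absolute reproduction of published FAERS counts is out of scope: it
  requires the full extract, a licensed MedDRA version, and the original
  drug-name curation.
- The EBGM here is the unshrunk relative reporting ratio; small-count rows
  are wilder than MGPS-shrunk values would be (the 0.5 correction and the
  a ≥ 3 gates are the only damping).
- One primary SOC per PT; multi-axial MedDRA is not modelled.
- No stratified or time-scan analyses; no FDR reporting.
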