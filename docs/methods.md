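# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `pvsignal`.

## Data model and counting units

A spontaneous reporting system stores *reports*: one per (case, version),
where a case is a patient–event episode that may be resubmitted.
Deduplication keeps, per case identifier, the version with the greatest
(receipt date, version id) — the standard FAERS convention — and sorts by
case id so the operation is deterministic and idempotent.

Two counting units are supported throughout, because they answer different
questions. *Case* counting (one unit per deduplicated case) drives the
descriptive tables and the primary 2×2 analysis; *drug-event-pair* counting
(one unit per case × matching preferred term) drives PT-level counts and
shares, where a case reporting both a subdural and a cerebral hematoma
legitimately contributes twice. Percentages are rounded half-up to two
decimals at the presentation layer only; machine-readable outputs keep full
precision.

Analysis-set selection keeps a case for drug *D* only if *D* carries the
primary-suspect role and at least one reaction falls in the target PT set.
The default target set covers subdural, cerebral, extradural and spinal
epidural hematoma in both English spellings, and is fully overridable.
Drug names are normalized by case-insensitive exact match against a
configurable synonym table; no fuzzy matching, for auditability. Age bands
are closed on the left: <18, 18–44, 45–64, ≥65; missing values map to an
"unspecified" pool that is reported but never silently dropped.

## Disproportionality statistics

For the 2×2 table (a, b, c, d) with N = a+b+c+d:

**ROR** = ad/(bc) with 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
**PRR** = [a/(a+b)]/[c/(c+d)] with 95% CI
exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))).
When any cell is zero, the Haldane–Anscombe correction adds 0.5 to all four
cells for these two statistics only; the Bayesian methods use their own
smoothing and never the correction. (The correction is applied for *any*
zero cell, not only b·c = 0, because the log-scale Wald interval is already
undefined at a = 0.) In stratified output, strata with a = 0 report NaN for
ROR/PRR rather than a corrected pseudo-estimate.

**BCPNN.** The information component is the posterior expectation of
log₂ p₁₁/(p₁·p·₁) under the classic closed-form model with hyperparameters
α₁ = β₁ = 1, α = β = 2, γ₁₁ = 1 and γ chosen so the prior IC expectation is
zero. The exact E(IC) and V(IC) expressions are reproduced in
`signals.py`; IC025 = E(IC) − 2√V(IC), the "−2 standard deviations" form.
The closed form is finite for every non-negative table, including a = 0.
Strength bands on IC025: (0, 1.5] weak, (1.5, 3] medium, > 3 strong. The
stratified module exports the stratum IC expectation and IC ± 2√V as the
"EIC" columns; no separate estimator is introduced.

**MGPS.** The relative reporting rate λ of each drug×PT cell gets a
two-component gamma mixture prior, fitted once per corpus by maximizing the
marginal likelihood (a two-component negative-binomial mixture) over the
*full* drug×event grid with expectations E = (row total × column total)/N —
the full grid, not just study drugs, because shrinkage strength depends on
the whole grid. Optimization runs L-BFGS-B on log/logit-transformed
parameters with box bounds (|log θ| ≤ log 10⁴); on sparse grids the
unconstrained MLE can drift toward a point-mass corner, and the bounded
optimum is then used with a logged warning. A grid with fewer than two
usable cells keeps the documented default prior (DuMouchel's classic
starting values α₁=0.2, β₁=0.1, α₂=2, β₂=4, P=⅓). Per cell, the posterior
is again a two-gamma mixture; EBGM = exp E[ln λ | data] via digamma, and
EBGM05 is the 5th posterior percentile obtained by root-finding on the
mixture CDF. The 5th percentile is the canonical lower bound for the
"EBGM05 > 2" rule; the 2.5th is available via a parameter for users who
want a central 95% interval.

**Joint criterion.** ROR flag: a ≥ 3 and CI low > 1; PRR flag: same; BCPNN
flag: IC025 > 0; MGPS flag: EBGM05 > 2 and a > 0. A joint signal is the
conjunction of all four. The chi-square PRR variant (PRR ≥ 2 & χ² ≥ 4) is
deliberately not implemented.

A note on shrinkage: EBGM always sits below the raw ratio a/E on elevated
cells, but it is *not* guaranteed to exceed 1 whenever a/E > 1 — for cells
with a raw ratio barely above 1 and little evidence, a proper prior
centered near 1 pulls the posterior geometric mean below 1. The test suite
therefore checks EBGM > 1 only on cells with substantial evidence
(n ≥ 10, raw ratio ≥ 2) and EBGM < raw ratio broadly.

## Time-to-onset

TTO is the whole-day interval from the primary-suspect drug's start date to
the event date. Records missing either date, or with negative intervals,
are excluded with per-reason tallies; partial dates (year or year-month
only) are treated as missing. Zero-day intervals are recoded to 0.5 days
by default (same-day events are clinically real, but the Weibull support
requires t > 0); an "exclude" policy is available.

The two-parameter Weibull (scale α days, shape β) is fitted by maximum
likelihood (Nelder–Mead on the log-parameters from a moment-based start);
95% CIs are asymptotic normal on (ln α, ln β) from the numerically
evaluated observed information, back-transformed — a parametric bootstrap
is available as an option. Fits are refused below n = 10 and on degenerate
(constant) samples. Classification from β and its CI: early failure
(β < 1, CI upper < 1), wear-out (β > 1, CI lower > 1), otherwise random —
including the rare inconsistent combinations, which fall back to random.
Reported medians and IQRs are empirical quantiles of the raw onsets, not
model-based. Median onset differences across drugs use the tie-corrected
Kruskal–Wallis H with a chi-square reference; when all pooled values are
identical the test degenerates and (H = 0, p = 1) is returned directly.
Cumulative onset curves are plain ECDFs ending at exactly 1. No censoring
or competing-risk model is attempted: only observed events are analyzed.

## Synthetic reporting-system generator

The generator exists so that every downstream stage can be tested against
known truth. Per raw report it draws: sex and an age band from configurable
mixtures (age uniform within band); one primary-suspect drug from a
marginal distribution (plus an occasional concomitant drug, which selection
must ignore); each PT independently as Bernoulli with probability
min(1, base_PT × λ(drug, PT) × stratum multiplier); an onset interval from
the drug's Weibull for target cases (rounded half-up to whole days, with a
background lag model otherwise), which fixes event and receipt dates;
reporter, country, seriousness and outcomes from fixed marginals; then
missingness per field, independently, completely at random; and finally a
duplicate version with probability `dup_rate` (version + 1, receipt + 1
day, reporter perturbed). Reports whose PT draws all come up empty are
redrawn — a report with no reaction cannot exist — and the closed-form
expected tables carry the conditioning term (1 − P(empty set)) exactly, so
`ground_truth_tables` stays an analytic oracle. Stratum multipliers attach
to pairs with an explicit λ, so null pairs remain null within every
stratum. All randomness flows from one seed; a fixed configuration is
byte-identical across runs.

**Default conditions.** Four antiplatelet drugs with signal multipliers in
the observed ratio (clopidogrel 27, aspirin 22, prasugrel 17, ticagrelor
8), warfarin 38 as positive control, rosuvastatin 0.4 as negative control,
against a pooled background drug; target PT baselines proportioned to the
observed subtype mix (subdural ≈ 63%); onset Weibulls per drug at the
fitted (α, β) values (e.g. aspirin 930.3/0.62, ticagrelor 66.3/0.51);
female multipliers 1.6 (clopidogrel, from the printed female/male ROR
ratio) and 1.3 (other study drugs), ≥65 attenuation 0.6, and an 18–44
prasugrel excess of 8; ~2.3% duplicate cases; missingness 13% age, 10%
sex, 30% event date, 70% start date — so roughly one case in five carries a
computable TTO, matching the observed yield. Drug marginals (3%, 3%, 1%,
0.5%, controls 1.5%) and the ~1% target-PT mass are set so that every
study drug accumulates workable target counts at desk-scale corpus sizes
(the default 20,000 raw reports; the acceptance script uses 100,000).

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: reporting-bias dynamics (media attention,
regulatory warnings, secular trends), informative missingness, drug-drug
interactions, correlated reactions within a report, real MedDRA coding
noise, and the real corpus size (a full SRS has ~10⁷ reports with target
rates orders of magnitude lower). One visible consequence of desk scale:
because the comparator rows of each 2×2 table contain the other signal
drugs at non-trivial marginals, realized RORs compress below the designed
multipliers (e.g. λ = 27 realizes near 13). This is the ordinary
denominator contamination of disproportionality statistics, amplified
here; ordering and control behavior are preserved, absolute magnitudes are
not the quantity being validated.

## Numerical and design choices

* Intervals use z = 1.959963984540054 throughout (two-sided 95%).
* EB05 root-finding brackets the mixture CDF adaptively on both ends and
  returns 0 if the prior concentrates essentially all lower-tail mass
  below ~1e-290 (pathological priors only).
* The percentage rounding is decimal half-up (1.005 → 1.01), not banker's
  rounding, matching how clinical tables are typically printed.
* Deduplication ties on receipt date break by version id, then output is
  sorted by case id — a pure function of the input set.
* A record with two study drugs as primary suspects is counted under both,
  with the multiplicity logged.
* The pipeline manifest records seed, config hash, per-stage row counts and
  a SHA-256 per output file; identical inputs reproduce identical bytes.

## Known limitations

* Disproportionality quantifies reporting asymmetry, not risk; nothing
  here estimates incidence or establishes causality.
* The BCPNN implementation is the closed-form approximation, not the
  Monte-Carlo credible-interval variant.
* The MGPS prior fit is a bounded local optimum; multimodality of the
  mixture likelihood is not explored beyond the documented start.
* TTO analysis ignores censoring: cases that would have onset after the
  reporting date are invisible, which biases β downward in principle in
  real data (the synthetic generator has no such mechanism).
* The single-corpus denominator is whatever corpus is supplied; whether
  that is a full database or a cleaned subset is the caller's choice and
  materially affects c and d.
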