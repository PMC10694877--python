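# Methods

## The disproportionality model

A spontaneous-report database is a biased sample of drug–event pairs: there
is no denominator of exposed patients, so absolute risks are not estimable.
Disproportionality analysis instead asks whether a target event is reported
*relatively* more often with a target drug than with everything else. For a
deduplicated report universe of size N, each report is cross-classified:

|                  | AAD case | all other reactions |
|------------------|----------|---------------------|
| target exposure  | a        | b                   |
| all other drugs  | c        | d                   |

The reporting odds ratio is ROR = ad/bc with the Woolf (log-normal)
confidence interval exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)). The 1.96
multiplier is fixed (not a configurable z) to match the published interval
exactly. A target is a signal when the lower 95% bound exceeds 1 **and**
a ≥ 3; the minimum-count rule suppresses signals carried by one or two
reports. The ROR is a reporting association, not a causal effect:
confounding by indication, stimulated reporting and channeling all survive
this design.

Counting decisions (all report-level, so the margins a+c and b+d are
identical for every target on a fixed dataset):

* **Exposure** means a primary-suspect (PS) drug record. Secondary-suspect,
  concomitant and interacting drugs do not count.
* The comparator is **all other drugs** — including drugs the dictionary
  cannot map — not "other antibiotics". Unmapped drugs therefore stay in
  the denominator population rather than being dropped.
* At class level a report exposed to two drugs of the same class counts
  once.
* A zero cell makes the estimate non-computable; no continuity correction
  is applied (the published method specifies none, and a ≥ 3 already
  excludes the sparse corner). Non-computable targets are excluded from
  ranked output with a logged warning.
* Ranking is by descending ROR, non-computable entries last, ties broken
  alphabetically so output is stable across runs.

## Case definition

AAD cases are flagged by matching reaction records against a configurable
MedDRA PT list (CSV of `pt_code,pt_name`). The packaged default is the
eight C. difficile / antibiotic-colitis terms of the published case series
(codes 10009657, 10037128, 10052815, 10058305, 10058852, 10061043,
10070027, 10078496). Note the list does **not** include the PT
"Antibiotic-associated diarrhoea" itself; the default reproduces the
published definition as printed, and a wider definition is a one-line
config change. Matching is by code, case-folded name, or either (default
"either": real FAERS REAC tables carry names, coded extracts carry
numbers). A report with several matching PTs counts once.

## Cleaning

* **Deduplication.** FAERS revises cases over time; versions share a
  `caseid`. The retained version is the numerically greatest `primaryid`
  (the standard convention that the highest version is the latest),
  tie-broken by latest event date, then lexicographically. The operation is
  idempotent and its removed count is reported in the attrition log.
* **Drug normalization** is a flat dictionary lookup (uppercased,
  whitespace-collapsed), not fuzzy matching; unmapped names are tallied
  into a review report. Combination products (amoxicillin-clavulanate,
  ampicillin-sulbactam, …) are distinct ingredients, not split into
  components, and the β-lactam + inhibitor combinations form their own
  "beta-lactamase inhibitors" class.
* **Ages** are normalized to years at parse time from the FAERS unit codes
  (DEC×10, MON/12, WK, DY, HR); an unknown unit yields a missing age. A
  blank unit with a numeric age is read as years. Age groups are <18,
  18–64, ≥65, unknown.
* **Dates** are 8/6/4-digit strings parsed to day/month/year precision.
  Invalid dates (month 13, day 40, non-numeric) are blanked-with-count by
  default; a strict mode raises instead. Spontaneous data is dirty, and
  silent coercion would hide it.
* **Continents** come from a packaged ISO-3166 alpha-2 → continent table
  covering the countries that dominate FAERS reporting; unmapped codes
  become "unknown", which is reported as its own category.

## Time to onset and outcomes

Onset is event date minus the PS drug's earliest therapy start date, per
drug–report pair (per-pair rather than per-report because the per-drug
medians need it). Records exist only when both dates have full day
precision; negative differences are excluded with a count. Bins are
half-open in days — [0,7), [7,28), [28,56), [56,84), [84,∞) — an exhaustive
partition matching the week labels of the published binning. Quartiles use
linear interpolation between order statistics (the default of mainstream
numerical environments; the published "quartile assay" names no method).

Outcome codes grade as DE=5, LT=DS=CA=4, HO=3, RI=2, OT=1. The severe
proportion is (grade 4 + grade 5 events)/(all outcome events). The
mortality rate divides death events by **outcome events** by default — the
arithmetic the published outcome table actually uses (805/6,692 = 12.03%) —
with a `reports` mode for the per-report wording that also appears in the
literature. The discrepancy between the two conventions is surfaced as an
option, not hidden.

## The synthetic-report generator

The generator emulates the report-level structure the pipeline consumes:
per-report demographics, 1–3 drug records with PS/SS/C roles, MedDRA-named
reactions, outcome events, therapy and event dates, duplicate case
versions, and partial/missing dates. Ground truth (exposures, case status,
drawn onsets, injected duplicates) is emitted alongside.

The planted effect is an odds multiplier θ per drug: an unexposed report is
an AAD case with baseline probability p₀, an exposed one with probability
p₁ = θp₀/(1 − p₀ + θp₀), so the population odds ratio of the 2×2 table is
exactly θ and the ROR is a consistent estimator of it in a single-drug
dataset. Under multiple exposures the largest θ wins (a documented
simplification, negligible at the ~2% exposure probabilities used); with
several elevated drugs planted, each drug's *marginal* ROR is attenuated
below its θ because the comparator contains the other elevated drugs —
the same dilution a real database exhibits.

Defaults, chosen once as the study conditions: n = 50,000 reports,
p₀ = 0.01, exposure 0.02 per drug, duplicate rate 0.10, partial-date rate
0.05, missing-date rate 0.10, onset log-normal with median 6 days
(σ_log = 0.9), demographic mixes approximating the published AAD case
series (≈43% aged ≥65, ≈51% female, reporting dominated by North America
and Europe), outcome mix approximating the published outcome distribution.
Dates are emitted as 8-digit strings and degraded by truncation (to 6 or 4
digits) or blanking. Event date = therapy start + drawn onset for exposed
cases, so time-to-onset is recoverable downstream.

What the generator does **not** model — and hence what passing tests do not
establish about real data: correlated co-prescription, conflicting
demographics across versions of a case, MedDRA coding errors, reporting
trends over calendar time, and any form of confounding. The simulation
studies validate the *machinery* (counting, dedup, interval construction),
not the epidemiology.

## Validation studies and problem sizes

* **Exactness:** on generated data the pipeline's 2×2 cells equal the
  generator's bookkeeping exactly, with and without injected duplicates.
* **Coverage:** for θ ∈ {2, 5, 25} (single planted drug, n = 50,000,
  exposure 0.02, p₀ = 0.01), the 95% CI covers θ in ≥ 90% of 200 seeded
  replicates in the test suite (nominal 95% with Monte-Carlo slack).
* **Null calibration:** with all θ = 1 (the four default drugs), ≤ 7.5% of
  1,600 drug-level tests across 400 replicates are flagged — the signal
  rule is a one-sided 2.5% test, so ~2.5% is expected.
* **Onset bins:** empirical bin fractions from a high-signal dataset sit
  within 3 Monte-Carlo standard errors of the generating log-normal's bin
  probabilities (rounding to whole days is accounted for by half-integer
  cut points).

`scripts/acceptance.py` reruns these studies at reduced replicate counts
(60 replicates per θ and 150 null replicates at n = 20,000) so the whole
script completes in a few minutes on one CPU; the package treats the
full-size versions in `tests/test_acceptance.py` as the reference runs.
Replicate seeds are always `base_seed + i`, so every study is deterministic
given its arguments.

## Known limitations

* Flat-dictionary drug normalization will leave real-world verbatim
  variants unmapped; the unmapped-frequency report exists precisely to
  audit that loss. Unmapped drugs bias per-drug RORs toward the null only
  if they hide true exposures.
* The packaged class taxonomy covers the antibiotics of the published case
  series plus common relatives; it is an editable CSV, not an ontology.
* Percentages are formatted with half-up rounding at two decimals
  (documented because banker's rounding differs on exact ties).
* The pipeline holds the five tables in memory; it targets desk-scale
  extracts and simulations, not the full 18M-report database.
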