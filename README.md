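# aadsignal

Reporting-odds-ratio (ROR) signal detection for **antibiotic-associated
diarrhea (AAD)** in FAERS-style spontaneous-report data.

Spontaneous adverse-event databases such as the FDA Adverse Event Reporting
System (FAERS) collect voluntary post-marketing safety reports: demographics,
suspect and concomitant drugs, MedDRA-coded reactions, outcomes and therapy
dates, distributed as five quarterly ASCII tables (DEMO, DRUG, REAC, OUTC,
THER). `aadsignal` implements, as a reusable and tested pipeline, the
standard disproportionality workflow that pharmacoepidemiologists apply to
these tables to ask *which antibiotics are reported with AAD more often than
the rest of the database would predict*:

1. **Ingest** the five tables (`$`-delimited or CSV), parsing FAERS date and
   code conventions.
2. **Clean**: collapse case versions to the latest (`caseid` → greatest
   `primaryid`), normalize verbatim drug strings to ingredients through a
   flat dictionary, and assign each ingredient to one of fourteen antibiotic
   classes.
3. **Define cases** by a configurable MedDRA preferred-term (PT) list; the
   packaged default is the eight *C. difficile* / antibiotic-colitis PTs
   used in the published AAD case series.
4. **Measure disproportionality.** For each drug or class, reports are
   cross-classified exposure (primary suspect) × case into a 2×2 table
   (a, b / c, d) and

   ```
   ROR = ad / bc,   95% CI = exp( ln ROR ± 1.96 · √(1/a + 1/b + 1/c + 1/d) )
   ```

   A target is a *signal* when the lower 95% bound exceeds 1 and a ≥ 3.
   The ROR measures reporting disproportion, not causal risk.
5. **Summarize** time to onset (therapy start → event date; binned by week
   ranges and as per-drug median (Q1, Q3)), outcome severity (grades 1–5
   from the seven FAERS outcome codes), mortality, and case demographics.

Because real FAERS extracts are large, messy and not redistributable, the
package ships a first-class **synthetic-report generator**
(`aadsignal.synthetic_data`) that emits FAERS-like table sets with known
ground truth — planted per-drug odds multipliers, log-normal onset
distributions, duplicate case versions, partial dates — so every pipeline
stage is verifiable end to end without downloading anything.

## Worked example

```sh
# 1. simulate 50,000 reports with the default planted effects
#    (lincomycin 25x, ceftriaxone 15x, amoxicillin 6.5x, tobramycin 1x)
aadsignal simulate --out demo_data --seed 1

# 2. run the full pipeline on them
aadsignal run --in demo_data --out demo_out
```

`demo_out/fig2_signals_drug.tsv` then contains (seed 1):

```
target	level	a	ror	ci_lower	ci_upper	is_signal
lincomycin	drug	195	16.94	14.24	20.15	true
ceftriaxone	drug	128	10.17	8.33	12.42	true
amoxicillin	drug	56	3.61	2.73	4.77	true
tobramycin	drug	18	1.09	0.68	1.74	false
```

Reading it: 195 deduplicated AAD cases had lincomycin as primary suspect;
their reporting odds were ~17× those of all other drugs, the CI excludes 1
and a ≥ 3, so lincomycin is flagged. Tobramycin (planted multiplier 1)
correctly is not. The estimates sit below the planted multipliers because
the "all other drugs" comparator also contains the other elevated
antibiotics — exactly the dilution a real database shows. The same run also
writes `table3_demographics.tsv`, `table4_onset_bins.tsv`,
`tableS1_onset_quartiles.tsv`, `table5_outcomes.tsv`,
`fig2_signals_class.tsv`, `fig3_mortality.tsv` and `attrition.log`.

The same analysis is available as a library:

```python
from aadsignal import (CaseDefinition, DrugDictionary, SyntheticConfig,
                       analyze_tables, generate_dataset)

ts, truth = generate_dataset(SyntheticConfig(n_reports=50_000, seed=1))
result = analyze_tables(ts, truth.dictionary(), CaseDefinition.default())
for r in result.signals_drug:
    print(r.target, r.a, r.ror, (r.ci_lower, r.ci_upper), r.is_signal)
```

## Scope

Out of scope by design: downloading or parsing real FDA quarterly archives,
RxNorm/MedDRA database integration (flat dictionary files only), other
disproportionality statistics (PRR, BCPNN, EBGM), and figure rendering —
the signal tables are emitted as plot-ready TSV instead. See
`docs/methods.md` for the statistical model, parameter defaults and known
limitations.
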