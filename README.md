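# pwud-phenotype

Rule-based EHR phenotyping of hospitalizations of people who use drugs
(PWUD), for researchers studying how drug use is documented — and for
whom documentation fails — in hospital records.

Identifying PWUD hospitalizations from billing codes alone has high
specificity but poor sensitivity: drug use is often recorded only in the
free-text social history, never as a diagnosis. This package implements a
four-criterion phenotyping algorithm over encounter-level EMR data and
the statistics used to validate it and to quantify documentation
disparities:

- **B** — biomarkers: positive urine toxicology (opiate, fentanyl,
  oxycodone, methadone, cocaine, amphetamine, suboxone) or positive HCV
  antibody ∧ positive/quantifiable viral load;
- **D** — ICD-9/10 diagnosis codes in the drug-use, overdose and
  hepatitis-C families (F11, F14, F15, T400–T406, T436, B18.2, 070.4x/5x/7x),
  matched by dot-stripped prefix;
- **M** — medications for opioid use disorder (sublingual buprenorphine,
  oral methadone) in reconciliation, inpatient administration or at
  discharge;
- **N** — fuzzy keyword NLP over clinical notes: a 26-entry lexicon
  matched at token level under the optimal-string-alignment
  Damerau–Levenshtein distance (≤ 1 edit; exact-only for short acronyms
  so "SUD" never fires inside "sudden").

Included encounters (B ∨ D ∨ M ∨ N) are partitioned into the 16-cell
Venn diagram of {B,D,M,N}; the *highly documented* (BDMN) and *minimally
documented* (N-only) cells are compared by chart-review PPV
(Clopper–Pearson intervals), 2×2 odds ratios with Woolf CIs
(OR = ad/bc, SE = √(1/a+1/b+1/c+1/d)), and adjusted logistic models
(Wald CIs, exp(β ± 1.96·SE)). A synthetic-EMR generator provides
ground-truthed cohorts so the full pipeline is testable without any
clinical data.

## Worked example

```python
from pwud_phenotype import (
    KeywordLexicon, TwoByTwoTable, match_note, odds_ratio_2x2, ppv,
)
from pwud_phenotype.types import Note

lex = KeywordLexicon.default()
note = Note(note_type="nursing", text="h/o IVDU; uses herion daily per partner.")
for span in match_note(note, lex):
    print(span)

result = ppv(53, 99)
print(result.ppv_pct_rounded, result.ci95)

orr = odds_ratio_2x2(TwoByTwoTable(550, 174, 176, 114))
print(round(orr.or_point, 3), [round(x, 3) for x in orr.ci95])
```

prints

```
MatchSpan(note_index=0, start=4, end=8, matched_text='IVDU', lexicon_entry='IVDU', distance=0)
MatchSpan(note_index=0, start=10, end=21, matched_text='uses herion', lexicon_entry='Uses heroin', distance=1)
MatchSpan(note_index=0, start=15, end=21, matched_text='herion', lexicon_entry='heroin', distance=1)
54 (0.43230585712534936, 0.6362299751118026)
2.047 [1.531, 2.739]
```

The matcher found the exact acronym "IVDU" and recovered the misspelled
"herion" at edit distance 1, both as the single keyword and as part of
the phrase "Uses heroin", with character offsets into the original note.
A review sample in which 53 of 99 charts were confirmed has a PPV of 54%
(95% CI 43%–64%). The 2×2 table compares White/non-Hispanic versus
minoritized encounters across the highly- vs minimally-documented
groups: odds of being highly documented are 2.05 times higher (95% CI
1.53–2.74) for White/non-Hispanic encounters — i.e., minoritized
patients' drug use is disproportionately documented *only* in free text.

End to end from a shell:

```sh
pwud-phenotype run --seed 7 --out out/
pwud-phenotype generate --n 1000 --seed 7 --out cohort.jsonl
pwud-phenotype classify --cohort cohort.jsonl --out flags.csv
pwud-phenotype cohort --flags flags.csv --out cells.json
```

`run` writes the cohort (JSONL), per-encounter flags and NLP evidence
spans (CSV), the Venn partition (JSON), review samples with oracle
labels, and a summary with cell counts, PPVs and odds ratios.

See `docs/methods.md` for the model, the generator's assumptions, and
what the synthetic results do and do not demonstrate.

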