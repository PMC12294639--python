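# Methods

## Problem and model

`pwud-phenotype` implements a rule-based phenotyping algorithm that labels
hospitalization *encounters* (not patients) as likely involving a person
who uses drugs (PWUD — here cocaine, methamphetamine/other stimulants,
fentanyl, heroin and other opioids; alcohol and cannabis excluded). An
encounter enters the cohort when any of four criteria fires:

- **B — biomarkers.** Any positive urine toxicology among
  {opiate, fentanyl, oxycodone, methadone, cocaine, amphetamine,
  suboxone}, or a positive hepatitis-C antibody *conjoined with* a
  positive or quantifiable HCV viral load. Antibody alone never
  qualifies: a resolved or treated infection is common and carries no
  information about current use.
- **D — diagnosis codes.** Any ICD-10 code in the families F11, F14,
  F15, T400–T406, T436 or B18.2, or one of the ICD-9 hepatitis-C codes
  070.41, 070.44, 070.51, 070.54, 070.70, 070.71. ICD-10 comparison is by
  dot-stripped prefix (so `F11.20` and `T40.2X1A` match their families);
  ICD-9 comparison is dot-stripped exact equality. Historical and
  inactivated diagnoses count.
- **M — medications for opioid use disorder.** Sublingual buprenorphine
  or oral methadone in outpatient medication reconciliation, inpatient
  administration, or a discharge prescription. Oral methadone as a
  *discharge prescription* is accepted but logged as anomalous (OUD
  methadone is dispensed through opioid treatment programs and normally
  enters the record via reconciliation). Methadone prescribed for pain is
  indistinguishable in this data model and is deliberately not
  special-cased; it is a known false-positive mode.
- **N — keyword NLP.** A lexicon of 26 drug-use keywords and phrases
  (IVDU, FENTANYL, heroin, "injection drug use", PWID, ...) is matched
  over every note of the encounter, tolerating small misspellings.

Included encounters are partitioned into the cells of the {B,D,M,N} Venn
diagram. Two cells anchor the evaluation: the *highly documented* group
(all four criteria, "BDMN") and the *minimally documented* group (NLP
only). "X-only" always denotes the pure singleton cell.

## Keyword matching

Notes are tokenized into maximal alphanumeric runs (punctuation and
whitespace are boundaries) with character offsets into the original text;
matching is case-insensitive by default. Single-token entries match a
token when the optimal-string-alignment (OSA) Damerau–Levenshtein
distance — unit-cost substitution, insertion, deletion, adjacent
transposition — is at most `max_distance` (default 1). Transpositions are
included because they dominate clinical typos ("herion"). Phrase entries
match consecutive token runs, each word matched under the same rule, with
any run of separators between words.

Numerical/edge choices:

- **Acronym guard.** Entries whose longest token has fewer than 5
  characters (IVDU, IVDA, SUD, OUD, PWID) are never fuzzy-matched: one
  edit on a 3–4-letter acronym matches far too much. Combined with the
  word-boundary rule this guarantees, e.g., that "SUD" never fires inside
  "sudden".
- **Per-phrase distance.** A phrase span's reported distance is the
  maximum over its per-word distances; each word is independently bounded
  by `max_distance`, so the invariant `distance <= max_distance` holds.
- **Overlap resolution.** For one entry, overlapping candidate spans keep
  the lowest distance, ties broken leftmost then longest; overlapping
  matches of *distinct* entries are all reported (they are independent
  evidence).
- **Non-goals.** No negation or uncertainty handling ("denies IVDU"
  still fires — the algorithm detects presence of documentation, not
  polarity), no section segmentation, no learned NER. "Methadone",
  "suboxone" and "FENTANYL" match any mention including prescription
  context; this mirrors the algorithm's documented false-positive modes.

## Synthetic EMR generator

No real encounter data ships with the package. The generator emulates the
descriptive profile of a single-center PWUD hospitalization cohort: age
~ N(47.9, 13.8²) years clipped to [18, 95]; 62.4% male; 34.8% racially/
ethnically minoritized; SVI quartiles ~ (0.2275, 0.2275, 0.2705, 0.2745)
with quartile 1 the most vulnerable and 0.4% missing; 94.5% primary
English speakers; length of stay ~ N(38.7, 26.3²) days truncated at 0.

Each encounter draws a ground-truth label (`truth_pwud`, default
prevalence 0.55) and then plants signals conditionally on it. The
conditional rates are free parameters (per-analyte toxicology positivity,
ICD assignment 0.55/0.04 for PWUD/non-PWUD, MOUD 0.30/0.01, keyword
mention 0.60/0.08): no public source reports them conditionally on cohort
entry route, so they are loosely calibrated — chosen once so that at
cohort sizes of a few thousand every Venn cell is occupied — and are not
fitted quantities. Note text is template prose with slot-filled keywords;
planted keywords are perturbed to edit distance exactly 1 with
probability `misspelling_rate` (default 0.10), and non-PWUD notes carry
confusable distractor sentences ("sudden cardiac death", amphetamine
salts prescribed for ADHD) with probability `distractor_rate` (default
0.30). The distractor bank is verified, token by token, to be more than
one edit from every fuzzy-eligible lexicon word.

What the generator does *not* emulate: clinically realistic prose,
negated or historical mentions, repeat patients across encounters,
correlation between demographics and the truth label (demographics are
independent of `truth_pwud` by construction; documentation-disparity
effects are simulated separately, see below). Passing tests therefore
demonstrate the correctness of the *rules and arithmetic*, not the
real-world operating characteristics of the algorithm on clinical text.

## Evaluation arithmetic

- **PPV.** confirmed/reviewed with an exact Clopper–Pearson 95% interval;
  the printed percent rounds half away from zero (53/99 → 54%). Chart
  review is modeled as an oracle reading the synthetic ground truth; an
  external review-label CSV can replace it.
- **Odds ratios.** Cross-product OR with Woolf CIs,
  `SE = sqrt(1/a + 1/b + 1/c + 1/d)`, chosen because it reproduces the
  published intervals to display precision. If exactly one cell is zero
  the Haldane–Anscombe 0.5 correction is applied and flagged; two zero
  cells in a cross pattern raise.
- **Adjusted models.** Binomial-GLM logistic regression (IRLS,
  convergence tolerance 1e-8, max 100 iterations) with Wald intervals
  `exp(β ± 1.96·SE)`. Outcome = membership in the highly documented
  (BDMN) cell versus NLP-only; references are minoritized race and SVI
  quartiles 1–2, so OR > 1 means higher odds of being highly documented.
  Two models are fitted: the race OR adjusted for age, sex and SVI, and
  the SVI OR adjusted for age, sex and race. Rows with missing SVI are
  deleted listwise in models containing SVI, with the dropped count
  reported. Perfect separation is detected (runaway coefficients or
  non-convergence) and flagged rather than raised.

## Scope of reproduction

The quantities that depend only on published summary counts are
recomputed exactly: PPV percents from the chart-review counts (40/93 →
43%, 53/99 → 54%), unadjusted ORs and CIs from the 2×2 margins (2.05,
1.53–2.74; 1.34, 1.01–1.77), and the comparison-group sizes (726, 288)
from a flag table built to the published cell counts.

The original cohort's totals (how many encounters each criterion
captured), its descriptive means, and its *adjusted* odds ratios cannot
be reproduced here: they require the individual-level EMR records, which
are not and cannot be distributed. The adjusted model is instead
validated by **parameter recovery**: cohorts of 20,000 encounters are
simulated from a logistic model with known coefficients (OR 2.0 for
race, 1.4 for SVI half) and the fitted ORs are required to recover the
generating values to within 5% on average over 20 seeds. No published
adjusted estimate appears anywhere in the package source.

## Problem sizes and determinism

Default test and acceptance runs use cohorts of 300–2,000 synthetic
encounters for pipeline checks, 10,000 for marginal-recovery checks, and
20 × 20,000 simulated rows for parameter recovery; these sizes make the
binomial/SE tolerances quoted above meaningful while keeping runs quick.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configuration implies
byte-identical artifacts, which the test suite asserts on whole output
trees.
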