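"""Synthetic electronic-medical-record generator.

Real encounter-level EMR extracts of hospitalized people who use drugs
(PWUD) cannot be shared, so this module generates cohorts with a known
ground-truth label (``truth_pwud``) whose marginal structure emulates the
descriptive profile of a single-center PWUD hospitalization cohort: mean
age ~47.9 (SD 13.8) years, 62.4% male, 34.8% racially/ethnically
minoritized, SVI quartiles split roughly 45/55 between the most- and
least-vulnerable halves, with 0.4% missing SVI.

Signals are planted conditionally on the truth label:

* urine-toxicology positives and the HCV antibody/viral-load pair
  (biomarker criterion B);
* drug-related ICD-9/10 codes from the default code table (criterion D);
* medication records for sublingual buprenorphine / oral methadone
  (criterion M);
* clinical-note sentences carrying lexicon keywords, optionally perturbed
  by one-edit misspellings, plus confusable distractor sentences in
  non-PWUD notes (criterion N and its false-positive traps).

The prose is template-based, not clinically realistic: the keyword matcher
operates at token level, so sentence templates with slot-filled keywords
exercise everything the detector can see.

All randomness flows from one integer seed through a single
``numpy.random.Generator``; identical configs give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .text_matching import KeywordLexicon, dl_distance
from .types import (
    ConfigurationError,
    DiagnosisCode,
    Encounter,
    LabResult,
    MedicationRecord,
    Note,
    NOTE_TYPES,
    TOX_ANALYTES,
)

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"

RngLike = Union[int, np.random.Generator]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ConditionalRate:
    """A probability conditional on the ground-truth PWUD label."""

    pwud: float
    non_pwud: float

    def __post_init__(self) -> None:
        for name, v in (("pwud", self.pwud), ("non_pwud", self.non_pwud)):
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"ConditionalRate.{name} must be in [0,1], got {v}")

    def for_label(self, truth: bool) -> float:
        return self.pwud if truth else self.non_pwud


def _default_tox_rates() -> dict[str, ConditionalRate]:
    # Loosely calibrated: per-analyte positivity among true PWUD dominated
    # by fentanyl/cocaine, near-zero among non-PWUD encounters.
    return {
        "opiate": ConditionalRate(0.19, 0.010),
        "fentanyl": ConditionalRate(0.45, 0.010),
        "oxycodone": ConditionalRate(0.09, 0.010),
        "methadone": ConditionalRate(0.22, 0.005),
        "cocaine": ConditionalRate(0.30, 0.010),
        "amphetamine": ConditionalRate(0.16, 0.010),
        "suboxone": ConditionalRate(0.10, 0.003),
        "hcv_antibody": ConditionalRate(0.20, 0.030),
    }


@dataclass
class GenerationConfig:
    """Knobs of the synthetic cohort generator.

    Demographic distributions default to the descriptive marginals the
    generator emulates; conditional signal rates are free parameters chosen
    so that, at cohort sizes of a few thousand, every cell of the
    {B,D,M,N} Venn partition is populated.
    """

    n_encounters: int = 4548
    prevalence_pwud: float = 0.55
    race_dist: dict[str, float] = field(
        default_factory=lambda: {"minoritized": 0.348, "white_nonhispanic": 0.652}
    )
    svi_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.2275, 2: 0.2275, 3: 0.2705, 4: 0.2745}
    )
    svi_missing_rate: float = 0.004
    sex_dist: dict[str, float] = field(
        default_factory=lambda: {"male": 0.624, "female": 0.376}
    )
    language_dist: dict[str, float] = field(
        default_factory=lambda: {"english": 0.945, "spanish": 0.027, "other": 0.028}
    )
    age_mean_sd: tuple[float, float] = (47.9, 13.8)
    los_mean_sd: tuple[float, float] = (38.7, 26.3)
    tox_positive_rates: dict[str, ConditionalRate] = field(default_factory=_default_tox_rates)
    hcv_vl_given_antibody: ConditionalRate = field(
        default_factory=lambda: ConditionalRate(0.65, 0.25)
    )
    icd_assignment_rate: ConditionalRate = field(
        default_factory=lambda: ConditionalRate(0.55, 0.04)
    )
    moud_rate: ConditionalRate = field(default_factory=lambda: ConditionalRate(0.30, 0.01))
    keyword_mention_rate: ConditionalRate = field(
        default_factory=lambda: ConditionalRate(0.60, 0.08)
    )
    misspelling_rate: float = 0.10
    distractor_rate: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if self.n_encounters < 1:
            raise ConfigurationError("n_encounters must be >= 1")
        for name in ("prevalence_pwud", "svi_missing_rate", "misspelling_rate", "distractor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0,1], got {v}")
        for name in ("race_dist", "svi_dist", "sex_dist", "language_dist"):
            dist = getattr(self, name)
            if any(p < 0 for p in dist.values()):
                raise ConfigurationError(f"{name} has a negative probability")
            total = float(sum(dist.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 (got {total!r})")
        for sd_name in ("age_mean_sd", "los_mean_sd"):
            if getattr(self, sd_name)[1] < 0:
                raise ConfigurationError(f"{sd_name} standard deviation must be >= 0")


# ---------------------------------------------------------------------------
# note text


def inject_misspelling(token: str, seed: RngLike) -> str:
    """Perturb ``token`` to a string at Damerau–Levenshtein distance exactly 1.

    One edit is drawn uniformly from {substitution, insertion, deletion,
    adjacent transposition}; impossible draws (e.g., transposition in "aa")
    are resampled. Deterministic given the seed.
    """
    if len(token) < 2:
        raise ValueError("token must have length >= 2 to misspell")
    rng = _as_rng(seed)
    folded = token.lower()
    for _ in range(100):
        op = rng.integers(4)
        chars = list(token)
        if op == 0:  # substitution
            i = int(rng.integers(len(chars)))
            c = _ALPHABET[int(rng.integers(26))]
            if c == chars[i].lower():
                continue
            chars[i] = c
        elif op == 1:  # insertion
            i = int(rng.integers(len(chars) + 1))
            chars.insert(i, _ALPHABET[int(rng.integers(26))])
        elif op == 2:  # deletion
            i = int(rng.integers(len(chars)))
            del chars[i]
        else:  # adjacent transposition
            positions = [i for i in range(len(chars) - 1) if chars[i].lower() != chars[i + 1].lower()]
            if not positions:
                continue
            i = positions[int(rng.integers(len(positions)))]
            chars[i], chars[i + 1] = chars[i + 1], chars[i]
        out = "".join(chars)
        if out.lower() != folded and dl_distance(out.lower(), folded) == 1:
            return out
    raise RuntimeError(f"could not misspell token {token!r}")  # pragma: no cover


#: Sentences guaranteed to contain no lexicon keyword, verbatim or within one
#: edit: near-miss traps ("sudden" vs the exact-only acronym SUD) and the
#: classic confusables (stimulants prescribed for ADHD, methadone-free pain
#: regimens). Checked against the default lexicon by the test suite.
DISTRACTOR_SENTENCES = (
    "Patient had a sudden episode of chest pain overnight.",
    "Sudden onset of shortness of breath, resolved with nebulizers.",
    "Prescribed amphetamine salts for ADHD, refilled at discharge.",
    "Chronic pain managed with morphine per the pain service.",
    "Continues home lisinopril and metformin without change.",
    "Denies tobacco; quit smoking ten years ago.",
    "Family history of sudden cardiac death in a sibling.",
)

_FILLER_SENTENCES = (
    "Vital signs stable overnight.",
    "Afebrile, hemodynamically stable.",
    "Tolerating oral intake without difficulty.",
    "Plan discussed with the care team.",
    "Ambulating in hallway with physical therapy.",
)

_KEYWORD_TEMPLATES = (
    "Social history notable for {kw}.",
    "Patient reports {kw} per intake interview.",
    "Chart documents {kw} on admission.",
    "Assessment: {kw}, counseled on harm reduction.",
)

_NOTE_OPENERS = {
    "nursing": "Nursing note:",
    "physician": "Physician progress note:",
    "discharge_summary": "Discharge summary:",
    "emergency": "Emergency department record:",
}


def _misspell_keyword(surface: str, rng: np.random.Generator) -> str:
    """Perturb one word of a keyword (preferring words long enough for the
    fuzzy matcher to recover)."""
    words = surface.split()
    eligible = [i for i, w in enumerate(words) if len(w) >= 5]
    if not eligible:
        eligible = [i for i, w in enumerate(words) if len(w) >= 2]
    i = eligible[int(rng.integers(len(eligible)))]
    words[i] = inject_misspelling(words[i], rng)
    return " ".join(words)


def render_note(
    note_type: str,
    keywords_to_plant: Sequence[str],
    misspelling_rate: float = 0.0,
    distractor_rate: float = 0.0,
    seed: RngLike = 0,
) -> Note:
    """Compose a synthetic note planting the given keywords.

    Each keyword appears once, perturbed to edit distance 1 with
    probability ``misspelling_rate``; with probability ``distractor_rate``
    one or two confusable distractor sentences are inserted.
    """
    if note_type not in NOTE_TYPES:
        raise ValueError(f"unknown note type: {note_type!r}")
    rng = _as_rng(seed)
    sentences = [_NOTE_OPENERS[note_type]]
    sentences.append(_FILLER_SENTENCES[int(rng.integers(len(_FILLER_SENTENCES)))])
    for kw in keywords_to_plant:
        rendered = kw
        if rng.random() < misspelling_rate:
            rendered = _misspell_keyword(kw, rng)
        template = _KEYWORD_TEMPLATES[int(rng.integers(len(_KEYWORD_TEMPLATES)))]
        sentences.append(template.format(kw=rendered))
    if rng.random() < distractor_rate:
        k = 1 + int(rng.integers(2))
        idx = rng.choice(len(DISTRACTOR_SENTENCES), size=k, replace=False)
        for i in sorted(int(x) for x in idx):
            sentences.append(DISTRACTOR_SENTENCES[i])
    sentences.append(_FILLER_SENTENCES[int(rng.integers(len(_FILLER_SENTENCES)))])
    return Note(note_type=note_type, text=" ".join(sentences))


# ---------------------------------------------------------------------------
# structured fields

# Child codes used to exercise dot-stripped prefix matching downstream.
_PWUD_DX_POOL = (
    ("ICD10", "F11.20"),
    ("ICD10", "F11.10"),
    ("ICD10", "F14.10"),
    ("ICD10", "F15.10"),
    ("ICD10", "T40.1X1A"),
    ("ICD10", "T40.2X1A"),
    ("ICD10", "T40.5X1A"),
    ("ICD10", "T43.621A"),
    ("ICD10", "B18.2"),
    ("ICD9", "070.41"),
    ("ICD9", "070.54"),
    ("ICD9", "070.70"),
)

# Benign background codes: never in the drug-use code table.
_BACKGROUND_DX_POOL = (
    ("ICD10", "I10"),
    ("ICD10", "E11.9"),
    ("ICD10", "J18.9"),
    ("ICD10", "K21.9"),
    ("ICD10", "N17.9"),
    ("ICD10", "F32.9"),
)


def _sample_categorical(rng: np.random.Generator, dist: dict) -> object:
    keys = list(dist.keys())
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _generate_labs(rng: np.random.Generator, truth: bool, config: GenerationConfig) -> list[LabResult]:
    labs: list[LabResult] = []
    for analyte in TOX_ANALYTES:
        rate = config.tox_positive_rates.get(analyte)
        if rate is None:
            continue
        if rng.random() < rate.for_label(truth):
            labs.append(LabResult(analyte=analyte, result="positive"))
        elif rng.random() < 0.3:  # some explicit negatives for realism
            labs.append(LabResult(analyte=analyte, result="negative"))
    ab_rate = config.tox_positive_rates.get("hcv_antibody")
    if ab_rate is not None and rng.random() < ab_rate.for_label(truth):
        labs.append(LabResult(analyte="hcv_antibody", result="positive"))
        if rng.random() < config.hcv_vl_given_antibody.for_label(truth):
            labs.append(
                LabResult(
                    analyte="hcv_viral_load",
                    result="quantified",
                    value=float(np.round(10 ** rng.uniform(3, 7), 1)),
                )
            )
        else:
            labs.append(LabResult(analyte="hcv_viral_load", result="negative"))
    return labs


def _generate_dx(rng: np.random.Generator, truth: bool, config: GenerationConfig) -> list[DiagnosisCode]:
    codes: list[DiagnosisCode] = []
    if rng.random() < config.icd_assignment_rate.for_label(truth):
        k = 1 + int(rng.integers(2))
        idx = rng.choice(len(_PWUD_DX_POOL), size=min(k, len(_PWUD_DX_POOL)), replace=False)
        for i in idx:
            system, code = _PWUD_DX_POOL[int(i)]
            codes.append(DiagnosisCode(system=system, code=code, active=bool(rng.random() < 0.8)))
    n_bg = int(rng.integers(3))
    if n_bg:
        idx = rng.choice(len(_BACKGROUND_DX_POOL), size=n_bg, replace=False)
        for i in idx:
            system, code = _BACKGROUND_DX_POOL[int(i)]
            codes.append(DiagnosisCode(system=system, code=code, active=True))
    return codes


def _generate_meds(rng: np.random.Generator, truth: bool, config: GenerationConfig) -> list[MedicationRecord]:
    meds: list[MedicationRecord] = []
    if rng.random() < config.moud_rate.for_label(truth):
        if rng.random() < 0.5:
            drug = "buprenorphine_sublingual"
            context = (
                "outpatient_reconciliation",
                "inpatient_administration",
                "discharge_prescription",
            )[int(rng.integers(3))]
            detail = "sublingual film"
        else:
            drug = "methadone_oral"
            # methadone for OUD is dispensed via clinics, not discharge scripts
            context = ("outpatient_reconciliation", "inpatient_administration")[int(rng.integers(2))]
            detail = "oral solution"
        meds.append(MedicationRecord(drug=drug, context=context, route_detail=detail))
    if rng.random() < 0.7:
        meds.append(
            MedicationRecord(
                drug="other",
                context=("outpatient_reconciliation", "inpatient_administration",
                         "discharge_prescription")[int(rng.integers(3))],
                route_detail="non-MOUD medication",
            )
        )
    return meds


def _generate_notes(
    rng: np.random.Generator, truth: bool, config: GenerationConfig, lexicon: KeywordLexicon
) -> list[Note]:
    n_notes = 1 + int(rng.integers(3))
    note_types = [NOTE_TYPES[int(rng.integers(len(NOTE_TYPES)))] for _ in range(n_notes)]
    mention = rng.random() < config.keyword_mention_rate.for_label(truth)
    planted: list[list[str]] = [[] for _ in range(n_notes)]
    if mention:
        surfaces = lexicon.surfaces()
        k = 1 + int(rng.integers(3))
        chosen = rng.choice(len(surfaces), size=min(k, len(surfaces)), replace=False)
        for i in chosen:
            planted[int(rng.integers(n_notes))].append(surfaces[int(i)])
    distractor_rate = 0.0 if truth else config.distractor_rate
    return [
        render_note(
            note_type=note_types[j],
            keywords_to_plant=planted[j],
            misspelling_rate=config.misspelling_rate,
            distractor_rate=distractor_rate,
            seed=rng,
        )
        for j in range(n_notes)
    ]


def generate_cohort(
    config: GenerationConfig, lexicon: Optional[KeywordLexicon] = None
) -> list[Encounter]:
    """Generate ``config.n_encounters`` synthetic encounters.

    Every encounter carries ``truth_pwud``; structured signals and note
    text are drawn conditionally on it at the configured rates. Identical
    configs (including seed) yield identical cohorts.
    """
    config.validate()
    lexicon = lexicon or KeywordLexicon.default()
    rng = np.random.default_rng(config.seed)
    encounters: list[Encounter] = []
    for i in range(config.n_encounters):
        truth = bool(rng.random() < config.prevalence_pwud)
        age = float(np.clip(rng.normal(*config.age_mean_sd), 18.0, 95.0).round(1))
        svi = None if rng.random() < config.svi_missing_rate else int(
            _sample_categorical(rng, config.svi_dist)
        )
        encounters.append(
            Encounter(
                encounter_id=f"enc-{config.seed}-{i:06d}",
                age=age,
                sex=str(_sample_categorical(rng, config.sex_dist)),
                race_eth=str(_sample_categorical(rng, config.race_dist)),
                svi_quartile=svi,
                primary_language=str(_sample_categorical(rng, config.language_dist)),
                length_of_stay=float(max(0.0, rng.normal(*config.los_mean_sd)).__round__(1)),
                labs=_generate_labs(rng, truth, config),
                dx_codes=_generate_dx(rng, truth, config),
                medications=_generate_meds(rng, truth, config),
                notes=_generate_notes(rng, truth, config, lexicon),
                truth_pwud=truth,
            )
        )
    return encounters


def structured_frame(encounters: Sequence[Encounter]) -> pd.DataFrame:
    """Flat DataFrame of the structured fields (one row per encounter)."""
    return pd.DataFrame(
        {
            "encounter_id": [e.encounter_id for e in encounters],
            "age": [e.age for e in encounters],
            "sex": [e.sex for e in encounters],
            "race_eth": [e.race_eth for e in encounters],
            "svi_quartile": [e.svi_quartile for e in encounters],
            "primary_language": [e.primary_language for e in encounters],
            "length_of_stay": [e.length_of_stay for e in encounters],
            "truth_pwud": [e.truth_pwud for e in encounters],
        }
    )


def simulate_documentation_outcomes(
    n: int,
    beta_race: float,
    beta_svi: float,
    beta_age: float = 0.0,
    beta_sex: float = 0.0,
    intercept: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate high- vs low-documentation membership from a known logit model.

    Covariates mirror the cohort marginals (race, SVI half, age, sex); the
    binary outcome (1 = highly documented) is drawn from
    ``logit^-1(intercept + beta_race*white + beta_svi*svi_34 + ...)``.
    Used to validate adjusted-model parameter recovery.
    """
    rng = np.random.default_rng(seed)
    white = (rng.random(n) < 0.652).astype(int)
    svi_34 = (rng.random(n) < 0.541).astype(int)
    age_z = rng.normal(size=n)
    male = (rng.random(n) < 0.624).astype(int)
    lin = intercept + beta_race * white + beta_svi * svi_34 + beta_age * age_z + beta_sex * male
    p = 1.0 / (1.0 + np.exp(-lin))
    outcome = (rng.random(n) < p).astype(int)
    return pd.DataFrame(
        {"outcome": outcome, "white": white, "svi_34": svi_34, "age_z": age_z, "male": male}
    )
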