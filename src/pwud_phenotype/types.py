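"""Core domain types for encounter-level EHR phenotyping.

The unit of analysis is the hospitalization *encounter*, not the patient:
one encounter carries structured fields (labs, diagnosis codes, medication
records, demographics) plus free-text clinical notes. Synthetic encounters
additionally carry a ground-truth drug-use label (``truth_pwud``) so every
downstream stage can be validated without access to real EMR data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

SCHEMA_VERSION = "1.0"

#: Closed vocabulary of laboratory analytes recognised by the biomarker rule.
ANALYTES = (
    "opiate",
    "fentanyl",
    "oxycodone",
    "methadone",
    "cocaine",
    "amphetamine",
    "suboxone",
    "hcv_antibody",
    "hcv_viral_load",
)

#: Urine-toxicology analytes: any positive result satisfies the biomarker rule.
TOX_ANALYTES = (
    "opiate",
    "fentanyl",
    "oxycodone",
    "methadone",
    "cocaine",
    "amphetamine",
    "suboxone",
)

LAB_RESULTS = ("positive", "negative", "quantified")

MOUD_DRUGS = ("buprenorphine_sublingual", "methadone_oral")
MED_DRUGS = MOUD_DRUGS + ("other",)
MED_CONTEXTS = (
    "outpatient_reconciliation",
    "inpatient_administration",
    "discharge_prescription",
)

NOTE_TYPES = ("nursing", "physician", "discharge_summary", "emergency")

RACE_GROUPS = ("minoritized", "white_nonhispanic")
SEXES = ("male", "female")


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its contract."""


class SchemaError(ValueError):
    """Raised on serialized-artifact schema mismatches (version or columns)."""


@dataclass
class LabResult:
    """A single laboratory result.

    ``result`` is categorical; ``value`` optionally carries a numeric
    quantification (e.g., an HCV viral load in IU/mL).
    """

    analyte: str
    result: str
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte: {self.analyte!r}")
        if self.result not in LAB_RESULTS:
            raise ValueError(f"unknown lab result: {self.result!r}")


@dataclass
class DiagnosisCode:
    """An ICD-9 or ICD-10 diagnosis code attached to an encounter.

    ``active`` distinguishes current from historical/inactivated diagnoses;
    the diagnosis criterion counts both.
    """

    system: str
    code: str
    active: bool = True

    def __post_init__(self) -> None:
        if self.system not in ("ICD9", "ICD10"):
            raise ValueError(f"unknown code system: {self.system!r}")
        if not self.code:
            raise ValueError("diagnosis code must be non-empty")


@dataclass
class MedicationRecord:
    drug: str
    context: str
    route_detail: str = ""

    def __post_init__(self) -> None:
        if self.drug not in MED_DRUGS:
            raise ValueError(f"unknown drug category: {self.drug!r}")
        if self.context not in MED_CONTEXTS:
            raise ValueError(f"unknown medication context: {self.context!r}")


@dataclass
class Note:
    """One free-text clinical note. ``text`` may be empty."""

    note_type: str
    text: str = ""

    def __post_init__(self) -> None:
        if self.note_type not in NOTE_TYPES:
            raise ValueError(f"unknown note type: {self.note_type!r}")


@dataclass
class Encounter:
    """One hospitalization encounter with structured fields and notes."""

    encounter_id: str
    age: float
    sex: str
    race_eth: str
    svi_quartile: Optional[int]
    primary_language: str
    length_of_stay: float
    labs: list[LabResult] = field(default_factory=list)
    dx_codes: list[DiagnosisCode] = field(default_factory=list)
    medications: list[MedicationRecord] = field(default_factory=list)
    notes: list[Note] = field(default_factory=list)
    truth_pwud: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.length_of_stay < 0:
            raise ValueError("length_of_stay must be >= 0")
        if self.svi_quartile is not None and self.svi_quartile not in (1, 2, 3, 4):
            raise ValueError("svi_quartile must be in {1,2,3,4} or None")


@dataclass
class DomainFlags:
    """The four cohort-entry criteria for one encounter.

    b: biomarkers (urine toxicology / HCV rule)
    d: diagnosis codes (ICD-9/10 table)
    m: medications for opioid use disorder
    n: NLP keyword detection over the notes

    An encounter enters the cohort iff any flag is true. ``evidence`` maps
    each domain letter to human-readable provenance strings for audit.
    """

    b: bool = False
    d: bool = False
    m: bool = False
    n: bool = False
    evidence: dict[str, list[str]] = field(default_factory=lambda: {
        "b": [], "d": [], "m": [], "n": []
    })

    @property
    def included(self) -> bool:
        return self.b or self.d or self.m or self.n

    def as_set(self) -> frozenset[str]:
        """The Venn-cell key: the subset of {B,D,M,N} that is true."""
        return frozenset(
            letter for letter, on in zip("BDMN", (self.b, self.d, self.m, self.n)) if on
        )
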