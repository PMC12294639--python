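"""The four cohort-entry criteria.

An encounter enters the drug-use cohort when any of four domains fires:

* **B** (biomarkers) — any positive urine toxicology among the recognised
  analytes, or a positive HCV antibody *conjoined* with a positive or
  quantifiable HCV viral load (antibody alone is insufficient: resolved or
  treated infection is common and is not evidence of current use);
* **D** (diagnosis codes) — any ICD-9/10 code in the configured table of
  drug-use, overdose and hepatitis-C families, counting historical and
  inactivated diagnoses;
* **M** (medications for opioid use disorder) — sublingual buprenorphine
  or oral methadone in outpatient reconciliation, inpatient
  administration, or a discharge prescription;
* **N** (NLP) — keyword evidence in any clinical note (see
  :mod:`.text_matching`).

ICD-10 matching is by dot-stripped prefix ("F11.20" and "T40.2X1A" both
match their families); ICD-9 matching is dot-stripped exact equality.
Methadone prescribed for pain is indistinguishable in this data model and
is deliberately not special-cased — a known false-positive mode.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .text_matching import KeywordLexicon, MatcherConfig, detect_encounter
from .types import (
    DiagnosisCode,
    DomainFlags,
    Encounter,
    LabResult,
    MedicationRecord,
    MOUD_DRUGS,
    MED_CONTEXTS,
    TOX_ANALYTES,
)

logger = logging.getLogger(__name__)

DEFAULT_ICD10_PREFIXES = (
    "F11", "F14", "F15", "T400", "T401", "T402", "T403", "T404", "T405", "T406",
    "T436", "B182",
)
DEFAULT_ICD9_CODES = ("07041", "07044", "07051", "07054", "07070", "07071")


def _strip_dots(code: str) -> str:
    return code.replace(".", "").upper()


@dataclass
class CodeTable:
    """The ICD code families defining the diagnosis criterion."""

    icd10_prefixes: tuple[str, ...] = DEFAULT_ICD10_PREFIXES
    icd9_codes: tuple[str, ...] = DEFAULT_ICD9_CODES
    descriptions: dict[str, str] = field(default_factory=dict)
    version: str = "default"

    def __post_init__(self) -> None:
        self.icd10_prefixes = tuple(_strip_dots(p) for p in self.icd10_prefixes)
        self.icd9_codes = tuple(_strip_dots(c) for c in self.icd9_codes)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CodeTable":
        """Read a code table from CSV with columns system,code,description."""
        path = Path(path)
        with path.open(newline="", encoding="utf-8") as fh:
            rows = [r for r in csv.DictReader(_skip_comments(fh)) if r.get("code")]
        return cls._from_rows(rows, version=path.stem)

    @classmethod
    def default(cls) -> "CodeTable":
        text = resources.files("pwud_phenotype.data").joinpath("icd_codes.csv").read_text(
            encoding="utf-8"
        )
        rows = [r for r in csv.DictReader(_skip_comments(text.splitlines())) if r.get("code")]
        return cls._from_rows(rows, version="default")

    @classmethod
    def _from_rows(cls, rows: list[dict], version: str) -> "CodeTable":
        icd10, icd9, desc = [], [], {}
        for row in rows:
            system = row["system"].strip().upper()
            code = _strip_dots(row["code"].strip())
            if system == "ICD10":
                icd10.append(code)
            elif system == "ICD9":
                icd9.append(code)
            else:
                raise ValueError(f"unknown code system in table: {row['system']!r}")
            desc[code] = row.get("description", "").strip()
        return cls(
            icd10_prefixes=tuple(icd10), icd9_codes=tuple(icd9),
            descriptions=desc, version=version,
        )


def _skip_comments(lines):
    for line in lines:
        if not line.lstrip().startswith("#"):
            yield line


def eval_biomarkers(labs: list[LabResult]) -> tuple[bool, list[str]]:
    """Biomarker criterion B.

    True iff any urine-toxicology analyte is positive, or HCV antibody is
    positive together with a positive/quantified viral load.
    """
    evidence: list[str] = []
    hcv_ab = hcv_vl = False
    for lab in labs:
        if lab.analyte in TOX_ANALYTES:
            if lab.result == "positive":
                evidence.append(f"positive urine toxicology: {lab.analyte}")
        elif lab.analyte == "hcv_antibody":
            hcv_ab = hcv_ab or lab.result == "positive"
        elif lab.analyte == "hcv_viral_load":
            hcv_vl = hcv_vl or lab.result in ("positive", "quantified")
        else:  # pragma: no cover - closed vocabulary enforced upstream
            logger.warning("ignoring unknown analyte %r", lab.analyte)
    if hcv_ab and hcv_vl:
        evidence.append("HCV antibody positive with positive/quantifiable viral load")
    return bool(evidence), evidence


def eval_diagnoses(
    codes: list[DiagnosisCode], table: Optional[CodeTable] = None
) -> tuple[bool, list[str]]:
    """Diagnosis criterion D. Inactive (historical) codes count."""
    table = table or CodeTable.default()
    evidence: list[str] = []
    for dx in codes:
        stripped = _strip_dots(dx.code)
        hit = None
        if dx.system == "ICD10":
            for prefix in table.icd10_prefixes:
                if stripped.startswith(prefix):
                    hit = prefix
                    break
        else:
            if stripped in table.icd9_codes:
                hit = stripped
        if hit is not None:
            label = table.descriptions.get(hit, hit)
            status = "active" if dx.active else "inactive"
            evidence.append(f"{dx.system} {dx.code} ({status}): {label}")
    return bool(evidence), evidence


def eval_medications(meds: list[MedicationRecord]) -> tuple[bool, list[str]]:
    """MOUD criterion M.

    Sublingual buprenorphine or oral methadone in any of the three
    recognised contexts. Oral methadone appearing as a *discharge
    prescription* still counts but is logged as anomalous: methadone for
    OUD is dispensed through opioid treatment programs and normally enters
    the record via reconciliation, not a discharge script.
    """
    evidence: list[str] = []
    for med in meds:
        if med.drug in MOUD_DRUGS and med.context in MED_CONTEXTS:
            if med.drug == "methadone_oral" and med.context == "discharge_prescription":
                logger.warning(
                    "anomalous record: oral methadone as discharge prescription"
                )
            evidence.append(f"{med.drug} via {med.context}")
    return bool(evidence), evidence


def classify_encounter(
    encounter: Encounter,
    table: Optional[CodeTable] = None,
    lexicon: Optional[KeywordLexicon] = None,
    matcher_config: Optional[MatcherConfig] = None,
) -> DomainFlags:
    """Evaluate all four criteria for one encounter."""
    b, ev_b = eval_biomarkers(encounter.labs)
    d, ev_d = eval_diagnoses(encounter.dx_codes, table)
    m, ev_m = eval_medications(encounter.medications)
    n, spans = detect_encounter(encounter, lexicon, matcher_config)
    ev_n = [
        f"note[{s.note_index}] {s.start}-{s.end} {s.matched_text!r} ~ "
        f"{s.lexicon_entry!r} (distance {s.distance})"
        for s in spans
    ]
    return DomainFlags(b=b, d=d, m=m, n=n, evidence={"b": ev_b, "d": ev_d, "m": ev_m, "n": ev_n})
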