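"""Serialization contracts: JSONL cohorts, CSV flag/span tables, YAML config.

All artifacts are UTF-8 text and carry explicit schema versions so a
mismatch between writer and reader fails loudly rather than silently.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .synthetic_emr import ConditionalRate, GenerationConfig
from .text_matching import MatchSpan
from .types import (
    DiagnosisCode,
    DomainFlags,
    Encounter,
    LabResult,
    MedicationRecord,
    Note,
    SCHEMA_VERSION,
    SchemaError,
)

FLAG_COLUMNS = ["encounter_id", "b", "d", "m", "n",
                "evidence_b", "evidence_d", "evidence_m", "evidence_n"]
SPAN_COLUMNS = ["encounter_id", "note_index", "start", "end",
                "matched_text", "lexicon_entry", "distance"]


def encounter_to_dict(encounter: Encounter) -> dict:
    d = dataclasses.asdict(encounter)
    d["schema_version"] = SCHEMA_VERSION
    return d


def encounter_from_dict(d: dict) -> Encounter:
    d = dict(d)
    version = d.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"schema version mismatch: expected {SCHEMA_VERSION!r}, found {version!r}"
        )
    return Encounter(
        encounter_id=d["encounter_id"],
        age=d["age"],
        sex=d["sex"],
        race_eth=d["race_eth"],
        svi_quartile=d["svi_quartile"],
        primary_language=d["primary_language"],
        length_of_stay=d["length_of_stay"],
        labs=[LabResult(**x) for x in d.get("labs", [])],
        dx_codes=[DiagnosisCode(**x) for x in d.get("dx_codes", [])],
        medications=[MedicationRecord(**x) for x in d.get("medications", [])],
        notes=[Note(**x) for x in d.get("notes", [])],
        truth_pwud=d.get("truth_pwud"),
    )


def write_cohort_jsonl(encounters: Iterable[Encounter], path: str | Path) -> None:
    """One encounter per line, notes embedded, schema-versioned."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for e in encounters:
            fh.write(json.dumps(encounter_to_dict(e), sort_keys=True) + "\n")


def read_cohort_jsonl(path: str | Path) -> list[Encounter]:
    path = Path(path)
    encounters: list[Encounter] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
                encounters.append(encounter_from_dict(record))
            except SchemaError:
                raise
            except Exception as exc:
                raise SchemaError(f"malformed record at line {lineno}: {exc}") from exc
    return encounters


def flags_to_frame(flags: Iterable[tuple[str, DomainFlags]]) -> pd.DataFrame:
    rows = []
    for encounter_id, f in flags:
        rows.append(
            {
                "encounter_id": encounter_id,
                "b": int(f.b), "d": int(f.d), "m": int(f.m), "n": int(f.n),
                "evidence_b": " | ".join(f.evidence.get("b", [])),
                "evidence_d": " | ".join(f.evidence.get("d", [])),
                "evidence_m": " | ".join(f.evidence.get("m", [])),
                "evidence_n": " | ".join(f.evidence.get("n", [])),
            }
        )
    return pd.DataFrame(rows, columns=FLAG_COLUMNS)


def frame_to_flags(frame: pd.DataFrame) -> list[tuple[str, DomainFlags]]:
    require_columns(frame, ["encounter_id", "b", "d", "m", "n"])
    out = []
    for row in frame.itertuples(index=False):
        flags = DomainFlags(b=bool(row.b), d=bool(row.d), m=bool(row.m), n=bool(row.n))
        out.append((str(row.encounter_id), flags))
    return out


def spans_to_frame(spans: Iterable[tuple[str, MatchSpan]]) -> pd.DataFrame:
    rows = [
        {
            "encounter_id": eid,
            "note_index": s.note_index,
            "start": s.start,
            "end": s.end,
            "matched_text": s.matched_text,
            "lexicon_entry": s.lexicon_entry,
            "distance": s.distance,
        }
        for eid, s in spans
    ]
    return pd.DataFrame(rows, columns=SPAN_COLUMNS)


def require_columns(frame: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


def read_flags_csv(path: str | Path) -> list[tuple[str, DomainFlags]]:
    return frame_to_flags(pd.read_csv(path))


def generation_config_from_dict(d: dict) -> GenerationConfig:
    """Build a GenerationConfig from a plain (YAML-friendly) mapping."""
    d = dict(d)
    for key in ("tox_positive_rates",):
        if key in d:
            d[key] = {k: ConditionalRate(**v) for k, v in d[key].items()}
    for key in ("hcv_vl_given_antibody", "icd_assignment_rate", "moud_rate",
                "keyword_mention_rate"):
        if key in d and isinstance(d[key], dict):
            d[key] = ConditionalRate(**d[key])
    for key in ("age_mean_sd", "los_mean_sd"):
        if key in d:
            d[key] = tuple(d[key])
    if "svi_dist" in d:
        d["svi_dist"] = {int(k): float(v) for k, v in d["svi_dist"].items()}
    config = GenerationConfig(**d)
    config.validate()
    return config


def load_generation_config(path: str | Path, seed: Optional[int] = None) -> GenerationConfig:
    """Read a GenerationConfig from a YAML file.

    The seed must be present in the file or supplied explicitly.
    """
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if seed is not None:
        raw["seed"] = seed
    if "seed" not in raw:
        raise SchemaError("seed must be given in the config file or as a flag")
    return generation_config_from_dict(raw)
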