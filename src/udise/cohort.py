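"""Cohort file I/O.

Two interchangeable on-disk forms:

* CSV — UTF-8, comma-separated, header required, columns
  ``patient_id,system,score``; the score column holds a uDISE score
  string or a whitespace-separated foreign token string.
* JSON — a list of records ``{"patient_id": ..., "system": ...}`` with
  either a ``"score"`` string or an expanded ``"findings"`` list
  (``{"structure","degree","configuration"}`` for uDISE records,
  ``{"site","grade","configuration"}`` for foreign ones); the expanded
  form is the authoritative way to carry configuration-bearing foreign
  findings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

from .core import Configuration, SiteFinding, Structure, UdiseProfile
from .notation import (
    SYSTEMS,
    ForeignToken,
    format_udise,
    parse_foreign,
    parse_udise,
    validate_foreign,
)


class CohortError(ValueError):
    pass


@dataclass
class CohortRecord:
    patient_id: str
    system: str  # "UDISE" or a foreign system id
    payload: Union[UdiseProfile, list[ForeignToken]]

    @property
    def is_udise(self) -> bool:
        return self.system == "UDISE"


def _payload_from_score(system: str, score: str):
    if system == "UDISE":
        return parse_udise(score)
    return parse_foreign(system, score)


def _payload_from_findings(system: str, findings: list[dict]):
    if system == "UDISE":
        parsed = []
        for f in findings:
            cfg = f.get("configuration")
            parsed.append(
                SiteFinding(
                    Structure.from_code(str(f["structure"])),
                    int(f["degree"]),
                    Configuration.from_code(str(cfg)) if cfg else None,
                )
            )
        return UdiseProfile(parsed)
    tokens = []
    for f in findings:
        token = ForeignToken(
            system, f.get("site"),
            f["grade"] if isinstance(f["grade"], str) else int(f["grade"]),
            f.get("configuration"),
        )
        errs = validate_foreign(token)
        if errs:
            raise CohortError("; ".join(errs))
        tokens.append(token)
    return tokens


def _build_record(patient_id, system, score=None, findings=None) -> CohortRecord:
    pid = str(patient_id).strip() if patient_id is not None else ""
    if not pid:
        raise CohortError("empty patient_id")
    system = str(system).strip().upper()
    if system not in ("UDISE", *SYSTEMS):
        raise CohortError(f"{pid}: unknown system {system!r}")
    if findings is not None:
        payload = _payload_from_findings(system, findings)
    elif score is not None and str(score).strip():
        payload = _payload_from_score(system, str(score).strip())
    else:
        raise CohortError(f"{pid}: record has neither score nor findings")
    return CohortRecord(pid, system, payload)


def read_cohort(path: Union[str, Path]) -> list[CohortRecord]:
    """Read a CSV or JSON cohort file; patient ids must be unique."""
    path = Path(path)
    if not path.exists():
        raise CohortError(f"no such file: {path}")
    records: list[CohortRecord] = []
    if path.suffix.lower() == ".json":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        if not isinstance(doc, list):
            raise CohortError(f"{path}: expected a JSON list of records")
        for rec in doc:
            records.append(
                _build_record(rec.get("patient_id"), rec.get("system", "UDISE"),
                              rec.get("score"), rec.get("findings"))
            )
    else:
        try:
            frame = pd.read_csv(path, dtype=str)
        except Exception as err:
            raise CohortError(f"{path}: malformed CSV ({err})") from err
        required = {"patient_id", "system", "score"}
        if not required.issubset(frame.columns):
            raise CohortError(
                f"{path}: CSV needs columns {sorted(required)} "
                f"(found {list(frame.columns)})"
            )
        for _, row in frame.iterrows():
            records.append(
                _build_record(row["patient_id"], row["system"], row["score"])
            )
    if not records:
        raise CohortError(f"{path}: empty cohort")
    ids = [r.patient_id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise CohortError(f"{path}: duplicate patient ids {sorted(dupes)}")
    return records


def read_cohort_lenient(
    path: Union[str, Path]
) -> tuple[list[CohortRecord], list[str]]:
    """Like :func:`read_cohort` but collects per-record violations instead
    of failing on the first bad record.  File-level problems (missing
    file, malformed CSV/JSON, no records) still raise."""
    path = Path(path)
    if not path.exists():
        raise CohortError(f"no such file: {path}")
    raw: list[tuple] = []
    if path.suffix.lower() == ".json":
        with open(path, "r", encoding="utf-8") as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as err:
                raise CohortError(f"{path}: malformed JSON ({err})") from err
        if not isinstance(doc, list):
            raise CohortError(f"{path}: expected a JSON list of records")
        raw = [(rec.get("patient_id"), rec.get("system", "UDISE"),
                rec.get("score"), rec.get("findings")) for rec in doc]
    else:
        try:
            frame = pd.read_csv(path, dtype=str)
        except Exception as err:
            raise CohortError(f"{path}: malformed CSV ({err})") from err
        required = {"patient_id", "system", "score"}
        if not required.issubset(frame.columns):
            raise CohortError(
                f"{path}: CSV needs columns {sorted(required)} "
                f"(found {list(frame.columns)})"
            )
        raw = [(row["patient_id"], row["system"], row["score"], None)
               for _, row in frame.iterrows()]
    if not raw:
        raise CohortError(f"{path}: empty cohort")
    records, errors = [], []
    for pid, system, score, findings in raw:
        try:
            records.append(_build_record(pid, system, score, findings))
        except Exception as err:
            errors.append(f"{pid}: {err}")
    seen: set[str] = set()
    for r in records:
        if r.patient_id in seen:
            errors.append(f"{r.patient_id}: duplicate patient_id")
        seen.add(r.patient_id)
    return records, errors


def write_cohort_csv(
    profiles: list[UdiseProfile], path: Union[str, Path],
    id_prefix: str = "P",
) -> None:
    frame = pd.DataFrame(
        {
            "patient_id": [f"{id_prefix}{i+1:04d}" for i in range(len(profiles))],
            "system": "UDISE",
            "score": [format_udise(p) for p in profiles],
        }
    )
    frame.to_csv(path, index=False)


def write_cohort_json(
    profiles: list[UdiseProfile], path: Union[str, Path],
    id_prefix: str = "P",
) -> None:
    doc = [
        {
            "patient_id": f"{id_prefix}{i+1:04d}",
            "system": "UDISE",
            "score": format_udise(p),
        }
        for i, p in enumerate(profiles)
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
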