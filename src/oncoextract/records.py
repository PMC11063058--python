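"""Per-report extraction records and their JSON contract.

An :class:`ExtractionRecord` mirrors the constrained output the extraction
prompt demands from a model: for each attribute, the value *as stated* in the
report, the *estimated* canonical category, a certainty degree in [0, 1], and
the supporting evidence, plus a free-text ``comment`` that is always the last
key of the serialized object.  Records serialize to one JSON object per
report; corpora of records are JSONL (one object per line).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .vocab import UNKNOWN, VOCABULARIES, normalize_label

#: Attribute key order for the lung task; ``comment`` is serialized last.
LUNG_ATTRIBUTES = ("pT", "pN", "stage", "histology", "tumor_size_max_dimension")
OSTEO_ATTRIBUTES = ("grade", "margin")

#: Attributes scored in evaluation (tumor size is an intermediate question).
LUNG_SCORED_ATTRIBUTES = ("pT", "pN", "stage", "histology")

TASK_ATTRIBUTES = {"lung": LUNG_ATTRIBUTES, "osteosarcoma": OSTEO_ATTRIBUTES}


@dataclass
class AttributeEstimate:
    """One attribute's extracted/estimated value with certainty and evidence."""

    stated: str = UNKNOWN
    estimated: object = UNKNOWN  # category string, or float (cm) for tumor size
    certainty: float = 0.0
    evidence: str = ""

    def to_dict(self) -> dict:
        return {
            "stated": self.stated,
            "estimated": self.estimated,
            "certainty": self.certainty,
            "evidence": self.evidence,
        }


@dataclass
class ExtractionRecord:
    """Structured output for one pathology report."""

    report_id: str
    task: str = "lung"
    attributes: dict[str, AttributeEstimate] = field(default_factory=dict)
    comment: str = ""
    backend_id: str = ""
    model_tag: str = ""
    temperature: float = 0.0
    seed: int = 0
    parse_failed: bool = False

    def estimate(self, attribute: str) -> object:
        est = self.attributes.get(attribute)
        return est.estimated if est is not None else UNKNOWN

    def certainty(self, attribute: str) -> float | None:
        est = self.attributes.get(attribute)
        return est.certainty if est is not None else None

    def to_dict(self) -> dict:
        # comment must be the last key of the attribute payload.
        payload: dict = {"report_id": self.report_id, "task": self.task}
        for name in TASK_ATTRIBUTES[self.task]:
            if name in self.attributes:
                payload[name] = self.attributes[name].to_dict()
        for name in self.attributes:  # any extra attributes, stable order
            if name not in payload:
                payload[name] = self.attributes[name].to_dict()
        payload["comment"] = self.comment
        payload["_meta"] = {
            "backend_id": self.backend_id,
            "model_tag": self.model_tag,
            "temperature": self.temperature,
            "seed": self.seed,
            "parse_failed": self.parse_failed,
        }
        return payload

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), ensure_ascii=False)

    @classmethod
    def from_dict(cls, payload: dict) -> "ExtractionRecord":
        meta = payload.get("_meta", {})
        task = payload.get("task", "lung")
        rec = cls(
            report_id=payload.get("report_id", ""),
            task=task,
            comment=payload.get("comment", ""),
            backend_id=meta.get("backend_id", ""),
            model_tag=meta.get("model_tag", ""),
            temperature=float(meta.get("temperature", 0.0)),
            seed=int(meta.get("seed", 0)),
            parse_failed=bool(meta.get("parse_failed", False)),
        )
        for name, value in payload.items():
            if name in ("report_id", "task", "comment", "_meta"):
                continue
            if isinstance(value, dict):
                rec.attributes[name] = AttributeEstimate(
                    stated=value.get("stated", UNKNOWN),
                    estimated=value.get("estimated", UNKNOWN),
                    certainty=float(value.get("certainty", 0.0)),
                    evidence=value.get("evidence", ""),
                )
        return rec

    @classmethod
    def from_json(cls, text: str) -> "ExtractionRecord":
        return cls.from_dict(json.loads(text))


def validate_record(rec: ExtractionRecord) -> list[str]:
    """Return a list of invariant violations (empty iff the record is valid).

    Checks: all task attributes present; certainty in [0, 1]; estimated values
    in their closed vocabularies (tumor size must be a positive number or
    Unknown); evidence non-empty whenever an estimate is not Unknown.
    """
    violations: list[str] = []
    required = TASK_ATTRIBUTES.get(rec.task)
    if required is None:
        return [f"task: unknown task profile {rec.task!r}"]
    for name in required:
        if name not in rec.attributes:
            violations.append(f"{name}: attribute missing")
    for name, est in rec.attributes.items():
        if not (0.0 <= est.certainty <= 1.0):
            violations.append(f"{name}: certainty {est.certainty} outside [0, 1]")
        if name == "tumor_size_max_dimension":
            if est.estimated != UNKNOWN:
                if not isinstance(est.estimated, (int, float)) or est.estimated <= 0:
                    violations.append(f"{name}: estimated size must be a positive number or Unknown")
        elif name in VOCABULARIES:
            if est.estimated not in VOCABULARIES[name]:
                violations.append(f"{name}: estimated {est.estimated!r} not in vocabulary")
        if est.estimated != UNKNOWN and not est.evidence:
            violations.append(f"{name}: evidence empty for a non-Unknown estimate")
    return violations


def normalize_record(rec: ExtractionRecord) -> ExtractionRecord:
    """Normalize every categorical estimate in place and clamp certainties."""
    for name, est in rec.attributes.items():
        if name in VOCABULARIES and isinstance(est.estimated, str):
            est.estimated = normalize_label(est.estimated, name)
        est.certainty = min(1.0, max(0.0, float(est.certainty)))
    return rec


# ---------------------------------------------------------------------------
# JSONL corpus I/O

def write_records(records: Iterable[ExtractionRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_records(path: str | Path) -> list[ExtractionRecord]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(ExtractionRecord.from_json(line))
    return out


def iter_records(path: str | Path) -> Iterator[ExtractionRecord]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield ExtractionRecord.from_json(line)
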