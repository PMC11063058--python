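"""Tolerant parsing of constrained-JSON model responses.

Models instructed to "output nothing beyond the required JSON file" still
occasionally wrap the object in prose or code fences, so the parser scans for
the first balanced-brace JSON object rather than parsing the full text.
Unparseable input never raises: it yields an all-Unknown record with the
``parse_failed`` flag set, so batch runs degrade per report, not globally.
"""

from __future__ import annotations

import json

from .records import AttributeEstimate, ExtractionRecord, TASK_ATTRIBUTES, normalize_record
from .vocab import UNKNOWN, VOCABULARIES

_KEY_ALIASES = {
    "pt": "pT",
    "pn": "pN",
    "stage": "stage",
    "tumor_stage": "stage",
    "overall_stage": "stage",
    "histology": "histology",
    "histological_diagnosis": "histology",
    "tumor_size_max_dimension": "tumor_size_max_dimension",
    "tumor size max_dimension": "tumor_size_max_dimension",
    "max_dimension": "tumor_size_max_dimension",
    "grade": "grade",
    "margin": "margin",
    "margin_status": "margin",
}


def iter_json_objects(raw: str):
    """Yield every parseable top-level JSON object embedded in ``raw``."""
    depth = 0
    start = None
    in_string = False
    escape = False
    for i, ch in enumerate(raw):
        if in_string:
            if escape:
                escape = False
            elif ch == "\\":
                escape = True
            elif ch == '"':
                in_string = False
            continue
        if ch == '"':
            in_string = True
        elif ch == "{":
            if depth == 0:
                start = i
            depth += 1
        elif ch == "}":
            if depth > 0:
                depth -= 1
                if depth == 0 and start is not None:
                    candidate = raw[start : i + 1]
                    try:
                        obj = json.loads(candidate)
                    except json.JSONDecodeError:
                        pass
                    else:
                        if isinstance(obj, dict):
                            yield obj
                    start = None


def _coerce_estimate(name: str, value: object) -> AttributeEstimate:
    if isinstance(value, dict):
        est = AttributeEstimate(
            stated=str(value.get("stated", UNKNOWN)),
            estimated=value.get("estimated", UNKNOWN),
            certainty=_to_float(value.get("certainty", 0.0)),
            evidence=str(value.get("evidence", "")),
        )
    else:  # bare scalar answer
        est = AttributeEstimate(stated=str(value), estimated=value, certainty=1.0, evidence=str(value))
    if name == "tumor_size_max_dimension":
        est.estimated = _to_size(est.estimated)
    elif name in VOCABULARIES and not isinstance(est.estimated, str):
        est.estimated = str(est.estimated)
    return est


def _to_float(value: object) -> float:
    try:
        return float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return 0.0


def _to_size(value: object) -> object:
    if isinstance(value, (int, float)) and value > 0:
        return float(value)
    if isinstance(value, str):
        token = value.strip().rstrip(".").removesuffix("cm").strip()
        try:
            size = float(token)
        except ValueError:
            return UNKNOWN
        return size if size > 0 else UNKNOWN
    return UNKNOWN


def parse_response(raw: str, report_id: str = "", task: str = "lung") -> ExtractionRecord:
    """Parse a model response into a normalized :class:`ExtractionRecord`.

    Locates the first well-formed JSON object in ``raw`` (tolerating
    surrounding prose), routes every categorical attribute through the label
    normalizer, and clamps certainties to [0, 1].
    """
    rec = ExtractionRecord(report_id=report_id, task=task)
    payload = None
    if raw:
        for obj in iter_json_objects(raw):
            payload = obj
            break
    if payload is None:
        rec.parse_failed = True
        for name in TASK_ATTRIBUTES[task]:
            rec.attributes[name] = AttributeEstimate()
        return rec

    seen = {}
    for key, value in payload.items():
        canonical = _KEY_ALIASES.get(key.strip().casefold().replace(" ", "_"))
        if key.strip().casefold() == "tumor size max_dimension":
            canonical = "tumor_size_max_dimension"
        if canonical and canonical not in seen:
            seen[canonical] = _coerce_estimate(canonical, value)
    for name in TASK_ATTRIBUTES[task]:
        rec.attributes[name] = seen.get(name, AttributeEstimate())
    rec.comment = str(payload.get("comment", ""))
    return normalize_record(rec)
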