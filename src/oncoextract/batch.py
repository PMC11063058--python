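"""Batch orchestration of extraction runs over a cohort.

One record per manifest report, in manifest order; per-report status (ok,
parse-failed, skipped-oversize, failed); bounded retries for online backends;
resumable from a partial records file; full parameter echo in the run log.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from .backends import Backend
from .corpus import Cohort
from .parsing import parse_response
from .prompts import build_prompt, estimate_tokens
from .records import ExtractionRecord, read_records, write_records

STATUS_OK = "ok"
STATUS_PARSE_FAILED = "parse-failed"
STATUS_OVERSIZE = "skipped-oversize"
STATUS_FAILED = "failed"


@dataclass
class RunResult:
    records: list = field(default_factory=list)
    log: list = field(default_factory=list)

    def status_counts(self) -> dict:
        counts: dict[str, int] = {}
        for event in self.log:
            if "status" in event:
                counts[event["status"]] = counts.get(event["status"], 0) + 1
        return counts


def run_batch(
    cohort: Cohort,
    backend: Backend,
    version: str = "v4",
    temperature: float = 0.0,
    seed: int = 0,
    max_context_tokens: int = 16384,
    records_path: str | Path | None = None,
    log_path: str | Path | None = None,
    resume: bool = False,
    max_retries: int = 2,
    retry_wait_s: float = 0.0,
) -> RunResult:
    """Run ``backend`` over every report in the cohort manifest.

    With ``resume=True`` and an existing ``records_path``, reports already
    present in the file are kept as-is and only the missing ones are
    processed; the merged file is rewritten in manifest order, so an
    interrupted-then-resumed run produces the same file as an uninterrupted
    one (for a deterministic backend).
    """
    profile = cohort.config.task
    existing: dict[str, ExtractionRecord] = {}
    if resume and records_path is not None and Path(records_path).exists():
        existing = {rec.report_id: rec for rec in read_records(records_path)}

    result = RunResult()
    result.log.append(
        {
            "event": "run-start",
            "backend_id": backend.id,
            "model_tag": backend.model_tag,
            "prompt_version": version,
            "task": profile,
            "temperature": temperature,
            "seed": seed,
            "max_context_tokens": max_context_tokens,
            "n_reports": len(cohort.manifest),
            "resumed": bool(existing),
        }
    )

    for rid in cohort.manifest["report_id"]:
        if rid in existing:
            result.records.append(existing[rid])
            result.log.append({"report_id": rid, "status": "resumed"})
            continue
        text = cohort.reports[rid]
        prompt = build_prompt(text, version=version, profile=profile)
        n_tokens = estimate_tokens(prompt)
        if n_tokens > max_context_tokens:
            rec = parse_response("", report_id=rid, task=profile)
            rec.parse_failed = False  # nothing was sent, so nothing failed to parse
            rec.comment = f"skipped: prompt estimated at {n_tokens} tokens exceeds context window"
            status = STATUS_OVERSIZE
        else:
            raw, status = _complete_with_retries(
                backend, prompt, temperature, seed, max_retries, retry_wait_s, result.log, rid
            )
            rec = parse_response(raw, report_id=rid, task=profile)
            if status is None:
                status = STATUS_PARSE_FAILED if rec.parse_failed else STATUS_OK
        rec.backend_id = backend.id
        rec.model_tag = backend.model_tag
        rec.temperature = temperature
        rec.seed = seed
        result.records.append(rec)
        result.log.append({"report_id": rid, "status": status, "tokens": n_tokens})

    if records_path is not None:
        write_records(result.records, records_path)
    if log_path is not None:
        log_path = Path(log_path)
        log_path.parent.mkdir(parents=True, exist_ok=True)
        with open(log_path, "w", encoding="utf-8") as fh:
            for event in result.log:
                fh.write(json.dumps(event) + "\n")
    return result


def _complete_with_retries(backend, prompt, temperature, seed, max_retries, retry_wait_s,
                           log, rid):
    wait = retry_wait_s
    for attempt in range(max_retries + 1):
        try:
            return backend.complete(prompt, temperature=temperature, seed=seed), None
        except Exception as exc:  # backend unreachable: per-report failure, run continues
            log.append({"report_id": rid, "event": "attempt-failed", "attempt": attempt,
                        "error": str(exc)})
            if attempt < max_retries and wait > 0:
                time.sleep(wait)
                wait *= 2
    return "", STATUS_FAILED
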