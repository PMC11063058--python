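"""Keyword/subword dictionary baseline for attribute extraction.

A traditional-NLP reference point: an entity dictionary is compiled from
annotated training spans, candidate spans in a new report are scored against
the dictionary by character-trigram Jaccard similarity over a subword
normalization, and — when several entities match one attribute — the most
severe label wins.  The overall stage, when not matched directly in the text,
is filled in by the AJCC7 grouping of the extracted pT and pN.

The subword scheme is a greedy longest-match tokenizer over a vocabulary
induced from the training spans (whole words plus frequent character
fragments); it is deliberately isolated behind the dictionary interface.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .ajcc7 import stage_group
from .records import AttributeEstimate, ExtractionRecord, TASK_ATTRIBUTES
from .vocab import UNKNOWN, n_level, stage_numeral, t_level

logger = logging.getLogger(__name__)

_WORD_RE = re.compile(r"[a-z0-9/]+")


def _words(text: str) -> list[str]:
    return _WORD_RE.findall(text.casefold())


def _char_ngrams(token: str, n: int = 3) -> set[str]:
    padded = f"#{token}#"
    if len(padded) <= n:
        return {padded}
    return {padded[i : i + n] for i in range(len(padded) - n + 1)}


def trigram_jaccard(a: str, b: str) -> float:
    """Character-trigram Jaccard similarity between two spans (0..1)."""
    ga = set().union(*(_char_ngrams(w) for w in _words(a)) or [set()])
    gb = set().union(*(_char_ngrams(w) for w in _words(b)) or [set()])
    if not ga and not gb:
        return 1.0
    if not ga or not gb:
        return 0.0
    return len(ga & gb) / len(ga | gb)


# ---------------------------------------------------------------------------
# Severity orders for "most severe entity wins"

def _severity(attribute: str, label: str) -> tuple:
    if attribute == "pT":
        lvl = t_level(label)
        return (lvl if lvl is not None else -1, len(label))
    if attribute == "pN":
        lvl = n_level(label)
        return (lvl if lvl is not None else -1,)
    if attribute == "stage":
        num = stage_numeral(label)
        return (num if num is not None else -1, label)
    return (0,)


@dataclass
class KeywordDictionary:
    """Annotated entity dictionary: span -> (attribute, label)."""

    entries: list = field(default_factory=list)  # {attribute, span, tokens, label}
    vocabulary: list = field(default_factory=list)  # subword units, longest first

    def tokenize(self, text: str) -> list[str]:
        """Greedy longest-match subword tokenization over the induced vocab."""
        units = sorted(set(self.vocabulary), key=len, reverse=True)
        out: list[str] = []
        for word in _words(text):
            i = 0
            while i < len(word):
                for unit in units:
                    if word.startswith(unit, i):
                        out.append(unit)
                        i += len(unit)
                        break
                else:
                    out.append(word[i])
                    i += 1
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"entries": self.entries, "vocabulary": self.vocabulary}, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "KeywordDictionary":
        payload = json.loads(Path(path).read_text())
        return cls(entries=payload["entries"], vocabulary=payload["vocabulary"])


def build_dictionary(annotated_examples: list) -> KeywordDictionary:
    """Compile a dictionary from (span text, attribute, label) examples.

    Duplicate spans with conflicting labels keep the most frequent label (ties
    broken by first occurrence) and log the conflict.
    """
    if not annotated_examples:
        raise ValueError("annotated example set is empty")

    word_counts: Counter = Counter()
    fragment_counts: Counter = Counter()
    for span, _attr, _label in annotated_examples:
        for w in _words(span):
            word_counts[w] += 1
            for k in (4, 3):
                for i in range(len(w) - k + 1):
                    fragment_counts[w[i : i + k]] += 1
    vocabulary = sorted(word_counts) + sorted(
        f for f, c in fragment_counts.items() if c >= 2
    )

    by_span: dict = {}
    order: dict = {}
    for idx, (span, attribute, label) in enumerate(annotated_examples):
        key = (attribute, " ".join(_words(span)))
        by_span.setdefault(key, Counter())[label] += 1
        order.setdefault((key, label), idx)

    dictionary = KeywordDictionary(vocabulary=vocabulary)
    for (attribute, span), labels in by_span.items():
        if len(labels) > 1:
            logger.warning("conflicting labels for span %r (%s): %s", span, attribute,
                           dict(labels))
        top = max(labels, key=lambda lab: (labels[lab], -order[((attribute, span), lab)]))
        dictionary.entries.append(
            {
                "attribute": attribute,
                "span": span,
                "tokens": dictionary.tokenize(span),
                "label": top,
            }
        )
    return dictionary


def _candidate_spans(text: str, max_words: int = 10) -> list[str]:
    spans = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        spans.append(line)
        words = line.split()
        for width in (1, 2, 3, 5, max_words):
            if len(words) > width:
                for i in range(len(words) - width + 1):
                    spans.append(" ".join(words[i : i + width]))
    return spans


def keyword_extract(report_text: str, dictionary: KeywordDictionary,
                    report_id: str = "", task: str = "lung",
                    threshold: float = 0.5) -> ExtractionRecord:
    """Extract attributes by dictionary span matching.

    Candidate spans are scored by trigram Jaccard against every dictionary
    entry; per attribute the most severe matched label wins, with the top
    span similarity reported as the certainty.  A missing stage is inferred
    from the extracted pT/pN via the AJCC7 grouping table.
    """
    rec = ExtractionRecord(report_id=report_id, task=task, backend_id="keyword")
    matches: dict[str, list] = {}
    if report_text and report_text.strip():
        candidates = _candidate_spans(report_text)
        for entry in dictionary.entries:
            best, best_span = 0.0, ""
            for span in candidates:
                sim = trigram_jaccard(span, entry["span"])
                if sim > best:
                    best, best_span = sim, span
            if best >= threshold:
                matches.setdefault(entry["attribute"], []).append(
                    (entry["label"], best, best_span)
                )

    for name in TASK_ATTRIBUTES[task]:
        found = matches.get(name)
        if not found:
            rec.attributes[name] = AttributeEstimate()
            continue
        label = max(found, key=lambda m: (_severity(name, m[0]), m[1]))[0]
        top = max(found, key=lambda m: m[1])
        rec.attributes[name] = AttributeEstimate(
            stated=top[2], estimated=label, certainty=round(top[1], 3),
            evidence=f"dictionary match: {top[2]!r}",
        )

    if task == "lung":
        stage_est = rec.attributes.get("stage")
        if stage_est is None or stage_est.estimated == UNKNOWN:
            pt = rec.estimate("pT")
            pn = rec.estimate("pN")
            if pt != UNKNOWN and pn != UNKNOWN:
                stage, rationale = stage_group(str(pt), str(pn))
                if stage != UNKNOWN:
                    rec.attributes["stage"] = AttributeEstimate(
                        stated=UNKNOWN, estimated=stage,
                        certainty=min(rec.attributes["pT"].certainty,
                                      rec.attributes["pN"].certainty),
                        evidence=rationale[0],
                    )
        rec.attributes.setdefault("tumor_size_max_dimension", AttributeEstimate())
    rec.comment = "keyword-dictionary baseline"
    return rec


def build_training_annotations(cohort) -> list:
    """Derive (span, attribute, label) training annotations from a cohort.

    Mimics entity-level annotation of the training split: the canonical fact
    lines of each valid training report are labeled with the engine-derived
    reference labels.  Stage has no explicit span in the reports, so the
    baseline must infer it by aggregation — as a span-matching method on
    narrative pathology text would have to.
    """
    from .corpus import _diagnosis_lines, _node_lines, _nodule_lines  # canonical phrasing

    annotations = []
    manifest = cohort.manifest
    train = manifest[(manifest["split"] == "train") & (manifest["validity"] == "valid")]
    for row in train.itertuples():
        facts = cohort.facts[row.report_id]
        if cohort.config.task == "lung":
            for line in _nodule_lines(facts):
                annotations.append((line, "pT", row.pT))
            for line in _node_lines(facts):
                annotations.append((line, "pN", row.pN))
            annotations.append((_diagnosis_lines(facts)[0], "histology", row.histology))
        else:
            facts_lines = _diagnosis_lines(facts)
            for line in facts_lines:
                if line.startswith("Histologic grade"):
                    annotations.append((line, "grade", row.grade))
                elif line.startswith("Resection margins"):
                    annotations.append((line, "margin", row.margin))
    return annotations
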