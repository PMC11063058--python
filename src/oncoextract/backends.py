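"""Pluggable extraction backends.

All backends satisfy one contract: ``complete(prompt, temperature, seed) ->
raw text``.  The deterministic mock backend is a perfect reader of the
synthetic corpus with *configurable, independently sampled error modes*
calibrated on the dominant mistakes observed when LLMs apply staging rules:

* size-rule errors — the tumor size is read correctly but mapped to the wrong
  T category ("T1 -> T2", "T3 -> T2");
* node-count rule — the N category is derived from the *number* of positive
  nodes instead of the anatomic stations involved, inflating N1 to N2;
* terminology confusion — an N1 station name is misread as mediastinal
  involvement (again N1 -> N2);
* incorrect stage rule — correct pT/pN, but (T3, N0) or (T2b, N1) is grouped
  as "Stage IIIA" instead of IIB;
* unknown output — an attribute is answered "Unknown" despite evidence;
* hallucination on blank input — with no report in the prompt the backend
  fabricates a fixed "attractor" record, byte-identical across calls at
  temperature 0.

With every probability at zero the mock's response encodes exactly the AJCC7
engine's ground truth, which is what makes end-to-end accuracy/coverage
invariants and parameter-recovery tests possible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass

import numpy as np

from .ajcc7 import PathologyFacts, stage_case, stage_group
from .corpus import parse_report
from .vocab import UNKNOWN, coarsen_t

REPORT_MARKER = "Pathology report:\n"


class BackendError(RuntimeError):
    """Raised when a backend cannot produce a completion."""


@dataclass
class ErrorProfile:
    """Per-mode error probabilities for the mock backend.

    ``feature_relief`` (0..1) scales down an error mode when the prompt
    carries the feature that targets it: the tumor-size subquestion counters
    size-rule errors, the evidence instruction counters terminology confusion,
    and the worked stage example counters the false stage-grouping rule.  At
    the default 0.0 the prompt version does not change the error rates; at 1.0
    a targeted mode is fully suppressed, which makes accuracy non-decreasing
    across the prompt ladder case by case.  The node-count rule is never
    relieved: deriving N from counts persisted under every prompt variant.
    """

    p_size_rule_error: float = 0.0
    p_node_count_rule: float = 0.0
    p_terminology_confusion: float = 0.0
    p_stage_rule_error: float = 0.0
    p_unknown_output: float = 0.0
    hallucinate_on_blank: bool = False
    certainty_noise: float = 0.0
    feature_relief: float = 0.0

    def validate(self) -> None:
        for name in (
            "p_size_rule_error",
            "p_node_count_rule",
            "p_terminology_confusion",
            "p_stage_rule_error",
            "p_unknown_output",
            "feature_relief",
        ):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.certainty_noise < 0:
            raise ValueError("certainty_noise must be >= 0")


ZERO_ERRORS = ErrorProfile()

#: The fixed fabricated record emitted for instruction-only prompts when
#: hallucination is enabled: a plausible, internally consistent lung case.
ATTRACTOR_PAYLOAD = {
    "pT": {
        "stated": "Unknown",
        "estimated": "T2a",
        "certainty": 0.9,
        "evidence": "The tumor is 3.5 cm in greatest dimension.",
    },
    "pN": {
        "stated": "Unknown",
        "estimated": "N0",
        "certainty": 0.9,
        "evidence": "All examined lymph nodes are negative for metastasis.",
    },
    "stage": {
        "stated": "Unknown",
        "estimated": "Stage IB",
        "certainty": 0.9,
        "evidence": "Based on the estimated pT category (T2a) and pN category (N0), "
        "the tumor stage is determined to be Stage IB according to AJCC7 criteria.",
    },
    "histology": {
        "stated": "Adenocarcinoma",
        "estimated": "Lung Adenocarcinoma",
        "certainty": 0.9,
        "evidence": "The pathology report states the histologic diagnosis as adenocarcinoma.",
    },
    "tumor_size_max_dimension": {
        "stated": "3.5 cm",
        "estimated": 3.5,
        "certainty": 0.9,
        "evidence": "The tumor is 3.5 cm in greatest dimension.",
    },
    "comment": "Findings consistent with resected lung adenocarcinoma.",
}

#: False stage-grouping patterns: (T, N) combinations the incorrect rule maps
#: to Stage IIIA although the grouping table says stage II.
FALSE_STAGE_RULE_PATTERNS = {("T3", "N0"), ("T2b", "N1")}


def false_stage_rule_applies(pt: str, pn: str) -> bool:
    return ((coarsen_t(pt), pn) in FALSE_STAGE_RULE_PATTERNS
            or (pt, pn) in FALSE_STAGE_RULE_PATTERNS)


def _prompt_features(instruction: str) -> frozenset:
    """Recover prompt-version features by inspecting the instruction block."""
    features = set()
    if "max_dimension" in instruction:
        features.add("size_subquestion")
    if "please answer the value as" in instruction.casefold():
        features.add("evidence_instruction")
    if '"Stage IB"' in instruction:
        features.add("stage_example")
    return frozenset(features)


class Backend:
    """Backend contract: deterministic/online capability flags + complete()."""

    id: str = "backend"
    deterministic: bool = True
    online: bool = False
    model_tag: str = ""

    def complete(self, prompt: str, temperature: float = 0.0, seed: int = 0) -> str:
        raise NotImplementedError


def _report_text(prompt: str) -> str:
    marker = prompt.find(REPORT_MARKER)
    if marker < 0:
        return ""
    return prompt[marker + len(REPORT_MARKER):]


class MockLLMBackend(Backend):
    """Deterministic stand-in for a chat-completion service.

    Reads the report embedded in the prompt with the corpus fact parser,
    stages it with the AJCC7 engine, then applies the configured error modes.
    At temperature 0 the completion is a pure function of (prompt, seed);
    temperature > 0 adds seed-driven variance in estimates and certainties.
    """

    online = False
    deterministic = True

    def __init__(self, profile: ErrorProfile | None = None, backend_id: str = "mock-llm",
                 model_tag: str = "mock-llm-1"):
        self.profile = profile or ErrorProfile()
        self.profile.validate()
        self.id = backend_id
        self.model_tag = model_tag

    # -- helpers -----------------------------------------------------------

    def _rng(self, prompt: str, seed: int) -> np.random.Generator:
        return np.random.default_rng((seed, zlib.crc32(prompt.encode("utf-8"))))

    def _certainty(self, rng: np.random.Generator, temperature: float) -> float:
        scale = self.profile.certainty_noise + 0.05 * temperature
        return float(np.clip(1.0 - abs(rng.normal(0.0, scale)) if scale > 0 else 1.0, 0.0, 1.0))

    def complete(self, prompt: str, temperature: float = 0.0, seed: int = 0) -> str:
        report = _report_text(prompt)
        instruction = prompt.split(REPORT_MARKER)[0]
        # error draws keyed on the report content, not the instruction text,
        # so the same case sees the same draws under every prompt version
        rng = self._rng(report or prompt, seed)
        facts = parse_report(report) if report.strip() else None
        if facts is None:
            return self._irregular_response(rng, temperature)
        if "osteosarcoma" in instruction.casefold() or facts.grade is not None:
            return self._osteo_response(facts, rng, temperature)
        return self._lung_response(facts, rng, temperature, _prompt_features(instruction))

    def _irregular_response(self, rng: np.random.Generator, temperature: float) -> str:
        if not self.profile.hallucinate_on_blank:
            payload = {
                name: {"stated": UNKNOWN, "estimated": UNKNOWN, "certainty": 0.0, "evidence": ""}
                for name in ("pT", "pN", "stage", "histology", "tumor_size_max_dimension")
            }
            payload["comment"] = "No report content is available to support any estimation."
            return json.dumps(payload)
        payload = json.loads(json.dumps(ATTRACTOR_PAYLOAD))  # deep copy
        if temperature > 0:
            for key in ("pT", "pN", "stage", "histology", "tumor_size_max_dimension"):
                payload[key]["certainty"] = round(
                    float(np.clip(0.9 - abs(rng.normal(0.0, 0.05 * temperature)), 0.0, 1.0)), 3
                )
        return json.dumps(payload)

    # -- lung task ---------------------------------------------------------

    def _lung_response(self, facts: PathologyFacts, rng: np.random.Generator,
                       temperature: float, features: frozenset = frozenset()) -> str:
        p = self.profile
        relief = p.feature_relief
        p_size = p.p_size_rule_error * (1 - relief * ("size_subquestion" in features))
        p_term = p.p_terminology_confusion * (1 - relief * ("evidence_instruction" in features))
        p_stage = p.p_stage_rule_error * (1 - relief * ("stage_example" in features))

        tnm = stage_case(facts)
        size = facts.max_dimension_cm
        size_txt = f"{size:g} cm" if size is not None else UNKNOWN

        # error-mode draws, in a fixed order for determinism
        u_size, u_count, u_term, u_stage = rng.random(4)

        pt_out = tnm.pT
        pt_evidence = (
            f"The pathology report states the tumor is {size_txt} in greatest dimension; "
            f"the estimated pT category is {tnm.pT} according to AJCC 7th edition for lung "
            "carcinoma staging manual."
        )
        size_err = u_size < p_size and coarsen_t(tnm.pT) in ("T1", "T3")
        if size_err:
            pt_out = "T2"
            pt_evidence = (
                f"Based on the tumor size of {size_txt}, it falls within the range of T2 "
                "category according to AJCC 7th edition for lung carcinoma staging manual."
            )

        total_pos = sum(f.positive for f in facts.nodes)
        total_ex = sum(f.examined for f in facts.nodes)
        pn_out = tnm.pN
        pn_evidence = (
            f"The pathology report states that {total_pos} out of {total_ex} lymph nodes are "
            f"positive for metastasis; the involved stations correspond to {tnm.pN} "
            "according to AJCC 7th edition guidelines."
        )
        count_err = u_count < p.p_node_count_rule and tnm.pN == "N1"
        term_err = u_term < p_term and tnm.pN == "N1"
        if count_err:
            pn_out = "N2"
            pn_evidence = (
                f"The pathology report states that {total_pos} out of {total_ex} lymph nodes "
                "are positive for metastasis. Based on this information, the pN category can "
                "be estimated as N2 according to AJCC 7th edition for lung carcinoma staging "
                "manual."
            )
        elif term_err:
            pn_out = "N2"
            pn_evidence = (
                "The involved lymph node station is interpreted as mediastinal involvement, "
                "corresponding to N2 according to AJCC 7th edition guidelines."
            )

        # stage follows the (possibly distorted) components unless the false
        # grouping rule fires on a matching pattern
        stage_out, _ = stage_group(pt_out, pn_out, tnm.pM)
        stage_evidence = (
            f"Based on the estimated pT category ({pt_out}) and pN category ({pn_out}), the "
            f"tumor stage is determined to be Stage {stage_out} according to AJCC7 criteria."
        )
        if u_stage < p_stage and false_stage_rule_applies(pt_out, pn_out):
            stage_out = "IIIA"
            stage_evidence = (
                f"Based on the estimated pT category ({pt_out}) and pN category ({pn_out}), "
                "the tumor stage is determined to be Stage IIIA according to AJCC7 criteria."
            )

        estimates = {
            "pT": (UNKNOWN, pt_out, pt_evidence),
            "pN": (UNKNOWN, pn_out, pn_evidence),
            "stage": (
                UNKNOWN,
                stage_out if stage_out == UNKNOWN else f"Stage {stage_out}",
                stage_evidence,
            ),
            "histology": (
                facts.diagnosis_text or UNKNOWN,
                facts.histology,
                f"The pathology report states the histologic diagnosis as "
                f"{facts.diagnosis_text or 'unknown'}.",
            ),
            "tumor_size_max_dimension": (
                size_txt,
                size if size is not None else UNKNOWN,
                f"The tumor's greatest dimension is stated as {size_txt}.",
            ),
        }

        if "size_subquestion" not in features:
            estimates.pop("tumor_size_max_dimension")

        payload = {}
        for name, (stated, estimated, evidence) in estimates.items():
            if rng.random() < p.p_unknown_output or (
                temperature > 0 and rng.random() < 0.1 * temperature
            ):
                payload[name] = {
                    "stated": UNKNOWN, "estimated": UNKNOWN, "certainty": 0.0, "evidence": "",
                }
                continue
            certainty = self._certainty(rng, temperature)
            if estimated == UNKNOWN:
                certainty, evidence = 0.0, ""
            payload[name] = {
                "stated": stated,
                "estimated": estimated,
                "certainty": round(certainty, 3),
                "evidence": evidence,
            }
        payload["comment"] = (
            f"Resected lung specimen; estimates follow AJCC 7th edition "
            f"({facts.diagnosis_text or 'diagnosis not stated'})."
        )
        return json.dumps(payload)

    # -- osteosarcoma task -------------------------------------------------

    def _osteo_response(self, facts: PathologyFacts, rng: np.random.Generator,
                        temperature: float) -> str:
        p = self.profile
        payload = {}
        for name, value in (("grade", facts.grade), ("margin", facts.margin)):
            unknown = value is None or rng.random() < p.p_unknown_output
            if unknown:
                payload[name] = {
                    "stated": UNKNOWN, "estimated": UNKNOWN, "certainty": 0.0, "evidence": "",
                }
            else:
                phrase = f"{value} grade" if name == "grade" else f"margins {value}"
                payload[name] = {
                    "stated": phrase,
                    "estimated": value,
                    "certainty": round(self._certainty(rng, temperature), 3),
                    "evidence": f"The pathology report states: {phrase}.",
                }
        payload["comment"] = "Osteosarcoma resection specimen."
        return json.dumps(payload)


class OpenAIBackend(Backend):
    """Adapter for a live chat-completion API (same contract as the mock).

    Requires the ``openai`` package and an API key; network access and billing
    are the caller's responsibility, so this backend is exercised manually,
    never in the test suite.
    """

    online = True
    deterministic = False

    def __init__(self, model_tag: str = "gpt-3.5-turbo-16k", api_key: str | None = None,
                 backend_id: str = "openai"):
        self.model_tag = model_tag
        self.api_key = api_key
        self.id = backend_id

    def complete(self, prompt: str, temperature: float = 0.0, seed: int = 0) -> str:
        try:
            from openai import OpenAI
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise BackendError("the 'openai' package is required for the API backend") from exc
        client = OpenAI(api_key=self.api_key)  # pragma: no cover
        response = client.chat.completions.create(  # pragma: no cover
            model=self.model_tag,
            temperature=temperature,
            messages=[{"role": "user", "content": prompt}],
        )
        return response.choices[0].message.content or ""  # pragma: no cover


BACKENDS = {"mock": MockLLMBackend, "openai": OpenAIBackend}
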