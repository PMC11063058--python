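"""Versioned extraction prompts with constrained JSON output.

Four prompt versions trace an iterative prompt-engineering ladder, each adding
exactly one feature on top of the previous one:

* ``v1`` — multiple-choice output format: the model may only answer from the
  closed vocabularies, and must emit a single JSON object and nothing else.
* ``v2`` — evidence-based inference: answer "Unknown" when no evidence exists,
  and include "comment" as the last key of the JSON file.
* ``v3`` — chain-of-thought via an intermediate question: also report the
  tumor's greatest dimension in centimeters.
* ``v4`` — a worked example for stage grouping (T2a + N0, no metastasis
  evidence -> "Stage IB" under AJCC 7th-edition criteria).

A blank report yields a prompt that contains only the instruction block —
exactly the condition under which constrained LLMs are known to fabricate a
fixed "attractor" response at temperature 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .vocab import HISTOLOGY_VOCAB, N_VOCAB, T_VOCAB

PROMPT_VERSION_IDS = ("v1", "v2", "v3", "v4")


@dataclass(frozen=True)
class PromptVersion:
    """Feature flags for one rung of the prompt ladder."""

    id: str
    multiple_choice_output: bool = True
    evidence_instruction: bool = False
    size_subquestion: bool = False
    stage_example: bool = False

    @property
    def features(self) -> frozenset:
        return frozenset(
            name
            for name in (
                "multiple_choice_output",
                "evidence_instruction",
                "size_subquestion",
                "stage_example",
            )
            if getattr(self, name)
        )


PROMPT_VERSIONS: dict[str, PromptVersion] = {
    "v1": PromptVersion("v1"),
    "v2": PromptVersion("v2", evidence_instruction=True),
    "v3": PromptVersion("v3", evidence_instruction=True, size_subquestion=True),
    "v4": PromptVersion(
        "v4", evidence_instruction=True, size_subquestion=True, stage_example=True
    ),
}

_T_CHOICES = ", ".join(T_VOCAB)
_N_CHOICES = ", ".join(N_VOCAB)
_HISTOLOGY_CHOICES = ", ".join(HISTOLOGY_VOCAB)

_JSON_INSTRUCTION = (
    "Please make sure to output the whole set of answers together as a single JSON file, "
    "and don't output anything beyond the required JSON file."
)

_EVIDENCE_INSTRUCTION = (
    "Please ensure to make valid inferences for attribute estimation based on evidence. "
    "If there is no available evidence provided to make an estimation, please answer the "
    'value as "Unknown." Include "comment" as the last key of the JSON file.'
)

_SIZE_SUBQUESTION = (
    "tumor size max_dimension: [<the greatest dimension of tumor in Centimeters (cm)>, "
    "'Unknown']"
)

_STAGE_EXAMPLE = (
    "Please estimate the tumor stage category based on your estimated pT category and pN "
    "category and use AJCC7 criteria. For example, if pT is estimated as T2a and pN as N0, "
    "without information showing distant metastasis, then by AJCC7 criteria, the tumor stage "
    'is "Stage IB".'
)

_PER_ATTRIBUTE = (
    "For each attribute, provide 4 outputs: the extracted value as stated in the pathology "
    "report, the estimated value based on AJCC 7th edition for lung carcinoma staging "
    "manual, the certainty degree of the estimation, and the supporting evidence for the "
    "estimation."
)


def build_prompt(report_text: str, version: str = "v4", profile: str = "lung") -> str:
    """Assemble the instruction block for ``version`` and append the report.

    For a blank report the returned prompt contains only the instruction part.
    """
    if version not in PROMPT_VERSIONS:
        raise ValueError(f"unknown prompt version {version!r}")
    if profile not in ("lung", "osteosarcoma"):
        raise ValueError(f"unknown task profile {profile!r}")
    v = PROMPT_VERSIONS[version]

    lines: list[str] = []
    if profile == "lung":
        lines.append(
            "Read the pathology report and extract the pathologic primary tumor category "
            "(pT), pathologic lymph node category (pN), overall tumor stage, and "
            "histological diagnosis."
        )
        lines.append(f'For pT, answer with exactly one of: "{_T_CHOICES}".')
        lines.append(f'For pN, answer with exactly one of: "{_N_CHOICES}".')
        lines.append(
            'For the tumor stage, answer with exactly one of: "Stage IA, Stage IB, '
            'Stage IIA, Stage IIB, Stage IIIA, Stage IIIB, Stage IV, Unknown".'
        )
        lines.append(
            f"For the histological diagnosis, answer with exactly one of: "
            f'"{_HISTOLOGY_CHOICES}".'
        )
        if v.size_subquestion:
            lines.append("Also estimate: " + _SIZE_SUBQUESTION)
        if v.stage_example:
            lines.append(_STAGE_EXAMPLE)
    else:
        lines.append(
            "Read the pathology report and extract the histologic grade and the resection "
            "margin status of the osteosarcoma."
        )
        lines.append('For the grade, answer with exactly one of: "low, intermediate, high, Unknown".')
        lines.append('For the margin status, answer with exactly one of: "negative, positive, Unknown".')
    lines.append(_PER_ATTRIBUTE)
    if v.evidence_instruction:
        lines.append(_EVIDENCE_INSTRUCTION)
    lines.append(_JSON_INSTRUCTION)

    instruction = "\n".join(lines)
    if not report_text or not report_text.strip():
        return instruction + "\n"
    return instruction + "\n\nPathology report:\n" + report_text


def estimate_tokens(text: str, estimator=None) -> int:
    """Estimate the token count of ``text``.

    The default heuristic is ceil(len/4) — monotone non-decreasing in text
    length, which is all the context-window gate needs.  An exact tokenizer
    can be plugged in via ``estimator`` (any callable text -> int).
    """
    if estimator is not None:
        return int(estimator(text))
    return math.ceil(len(text) / 4)
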