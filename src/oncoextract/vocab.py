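"""Closed vocabularies and label normalization for pathology-report attributes.

Every label that enters the pipeline — whether from a reference manifest, a
model response, or the staging engine — passes through :func:`normalize_label`
so that comparisons are always canonical-vs-canonical.  ``Unknown`` is a
first-class value: it is excluded from accuracy scoring but counted against
coverage.
"""

from __future__ import annotations

import logging

logger = logging.getLogger(__name__)

# Multiple-choice vocabularies offered to the model (pT list as printed in the
# extraction prompt; pN completed with N3/NX from the staging manual).
T_VOCAB = ("T0", "Tis", "T1", "T1a", "T1b", "T2", "T2a", "T2b", "T3", "T4", "TX", "Unknown")
N_VOCAB = ("N0", "N1", "N2", "N3", "NX", "Unknown")
STAGE_VOCAB = ("IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IV", "Unknown")
HISTOLOGY_VOCAB = ("Lung Adenocarcinoma", "Lung Squamous Cell Carcinoma", "Other", "Unknown")
GRADE_VOCAB = ("low", "intermediate", "high", "Unknown")
MARGIN_VOCAB = ("negative", "positive", "Unknown")

UNKNOWN = "Unknown"

#: attribute name -> vocabulary
VOCABULARIES: dict[str, tuple[str, ...]] = {
    "pT": T_VOCAB,
    "pN": N_VOCAB,
    "stage": STAGE_VOCAB,
    "histology": HISTOLOGY_VOCAB,
    "grade": GRADE_VOCAB,
    "margin": MARGIN_VOCAB,
}

#: Uncertainty spellings mapped to Unknown (registry convention for
#: "Not Available" / "Not Specified" / "Cannot be determined" entries).
UNCERTAIN_SYNONYMS = frozenset(
    {
        "",
        "unknown",
        "not available",
        "not specified",
        "cannot be determined",
        "can not be determined",
        "not reported",
        "n/a",
        "na",
        "none",
        "nan",
    }
)

_HISTOLOGY_SYNONYMS = {
    "lung adenocarcinoma": "Lung Adenocarcinoma",
    "adenocarcinoma": "Lung Adenocarcinoma",
    "luad": "Lung Adenocarcinoma",
    "lung squamous cell carcinoma": "Lung Squamous Cell Carcinoma",
    "squamous cell carcinoma": "Lung Squamous Cell Carcinoma",
    "lusc": "Lung Squamous Cell Carcinoma",
    "other": "Other",
}

_GRADE_SYNONYMS = {
    "low": "low",
    "low grade": "low",
    "intermediate": "intermediate",
    "intermediate grade": "intermediate",
    "high": "high",
    "high grade": "high",
}

_MARGIN_SYNONYMS = {
    "negative": "negative",
    "free": "negative",
    "uninvolved": "negative",
    "positive": "positive",
    "involved": "positive",
}


def _fold(raw: str) -> str:
    return " ".join(raw.strip().casefold().split())


def normalize_label(raw: object, attribute: str) -> str:
    """Map a raw string to its canonical category for ``attribute``.

    Strips ``p``/``Stage`` prefixes, case-folds, trims, maps uncertainty
    synonyms (and the empty string) to ``Unknown``.  Unmappable non-empty
    strings normalize to ``Unknown`` with a logged warning; a category is
    never invented.
    """
    if attribute not in VOCABULARIES:
        raise KeyError(f"unknown attribute {attribute!r}")
    if raw is None:
        return UNKNOWN
    if not isinstance(raw, str):
        raw = str(raw)
    folded = _fold(raw)
    if folded in UNCERTAIN_SYNONYMS:
        return UNKNOWN

    vocab = VOCABULARIES[attribute]
    lookup = {v.casefold(): v for v in vocab}

    if attribute in ("pT", "pN"):
        if folded.startswith("p"):
            folded = folded[1:]
        folded = folded.replace(" ", "")
    elif attribute == "stage":
        if folded.startswith("stage"):
            folded = folded[len("stage"):].strip()
        folded = folded.replace(" ", "")
    elif attribute == "histology":
        if folded in _HISTOLOGY_SYNONYMS:
            return _HISTOLOGY_SYNONYMS[folded]
    elif attribute == "grade":
        if folded in _GRADE_SYNONYMS:
            return _GRADE_SYNONYMS[folded]
    elif attribute == "margin":
        if folded in _MARGIN_SYNONYMS:
            return _MARGIN_SYNONYMS[folded]

    if folded in lookup:
        return lookup[folded]
    logger.warning("unmappable %s label %r -> Unknown", attribute, raw)
    return UNKNOWN


# ---------------------------------------------------------------------------
# T/N/stage structure helpers

_T_LEVEL = {
    "T0": 0, "Tis": 0,
    "T1": 1, "T1a": 1, "T1b": 1,
    "T2": 2, "T2a": 2, "T2b": 2,
    "T3": 3, "T4": 4,
}

_STAGE_NUMERAL = {
    "IA": 1, "IB": 1,
    "IIA": 2, "IIB": 2,
    "IIIA": 3, "IIIB": 3,
    "IV": 4,
}


def t_level(t: str) -> int | None:
    """Numeric T level (T1a -> 1, T4 -> 4); None for TX/Unknown/non-numeric."""
    return _T_LEVEL.get(t)


def coarsen_t(t: str) -> str:
    """Pool T subcategories to their level: T1a/T1b -> T1, T2a/T2b -> T2."""
    if t in ("T1a", "T1b"):
        return "T1"
    if t in ("T2a", "T2b"):
        return "T2"
    return t


def n_level(n: str) -> int | None:
    """Numeric N level (N0 -> 0 ... N3 -> 3); None for NX/Unknown."""
    if n in ("N0", "N1", "N2", "N3"):
        return int(n[1])
    return None


def stage_numeral(stage: str) -> int | None:
    """Roman stage level of a stage group (IA -> 1 ... IV -> 4)."""
    return _STAGE_NUMERAL.get(stage)


def coarsen_stage(stage: str) -> str:
    """Pool stage groups to their Roman level: IA/IB -> I, IIIA/IIIB -> III."""
    num = stage_numeral(stage)
    if num is None:
        return stage
    return ("I", "II", "III", "IV")[num - 1]


def coarsen(label: str, attribute: str) -> str:
    """Pool a label to level granularity for its attribute (identity for
    attributes without subcategories)."""
    if attribute == "pT":
        return coarsen_t(label)
    if attribute == "stage":
        return coarsen_stage(label)
    return label
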