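"""Deterministic AJCC 7th-edition lung-carcinoma staging engine.

Maps machine-readable pathology facts — tumor nodules with sizes and invasion
descriptors, lymph-node station findings, metastasis evidence — to pathologic
pT, pN, pM and the overall stage group, with a human-readable rationale naming
every fired rule.  The rule content (size ladder, descriptor minimums, station
levels, grouping table) ships as a versioned JSON data file so the engine is
auditable row by row.

The engine doubles as the ground-truth oracle for the synthetic corpus and as
the reference grouping used by the error-taxonomy analysis: a stage error in a
model's output is classified against *this* engine's grouping of the reference
pT/pN.

Conventions adopted where the manual leaves formatting latitude:

* Size boundaries are closed above: a tumor of exactly 3.0 cm is T1b, exactly
  5.0 cm is T2a, exactly 7.0 cm is T2b.
* When the size ladder and a descriptor rule disagree, the maximum T level
  wins and the rationale records both fired rules.
* pM defaults to "M0-assumed" when no metastasis evidence exists; only
  explicit evidence of distant metastasis yields M1 (-> stage IV).
* The number of positive nodes at a station never influences the N level;
  only the set of involved stations does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

from .vocab import UNKNOWN, t_level, n_level

# ---------------------------------------------------------------------------
# Rule table

_RULES = json.loads(
    resources.files("oncoextract.data").joinpath("ajcc7_lung_rules.json").read_text()
)

RULES_VERSION: str = _RULES["version"]

INVASION_FLAGS = frozenset(r["flag"] for r in _RULES["t_descriptor_rules"])
NODE_STATIONS = frozenset(_RULES["n_station_levels"])

_SIZE_LADDER = [(r["max_cm"], r["t"], r["citation"]) for r in _RULES["t_size_ladder"]]
_DESCRIPTOR_RULES = {
    r["flag"]: (r["min_t"], r["citation"]) for r in _RULES["t_descriptor_rules"]
}
_MULTINODULE = {r["pattern"]: (r["min_t"], r["citation"]) for r in _RULES["t_multinodule_rules"]}
_STATION_LEVEL = dict(_RULES["n_station_levels"])
_N_CITATIONS = {int(k): v for k, v in _RULES["n_citations"].items()}
_STAGE_TABLE = {(row["t"], row["n"]): row["stage"] for row in _RULES["stage_grouping"]}
_COARSE_T_ROWS = dict(_RULES["coarse_t_rows"])


class FactsError(ValueError):
    """Raised for malformed pathology facts (e.g. non-positive tumor size)."""


# ---------------------------------------------------------------------------
# Fact types

@dataclass
class TumorNodule:
    """A tumor nodule: greatest dimension in cm, location, and descriptors.

    ``size_cm`` may be None when the report documents a tumor without a
    recoverable measurement.
    """

    size_cm: float | None
    laterality: str = "right"  # {left, right}
    lobe: str = "upper"        # {upper, middle, lower}
    invades: frozenset = frozenset()

    def __post_init__(self):
        if self.size_cm is not None:
            if not (self.size_cm > 0) or self.size_cm != self.size_cm:
                raise FactsError(f"tumor size must be finite and positive, got {self.size_cm}")
        if self.laterality not in ("left", "right"):
            raise FactsError(f"laterality must be left/right, got {self.laterality!r}")
        if self.lobe not in ("upper", "middle", "lower"):
            raise FactsError(f"lobe must be upper/middle/lower, got {self.lobe!r}")
        bad = set(self.invades) - INVASION_FLAGS
        if bad:
            raise FactsError(f"unknown invasion flags: {sorted(bad)}")
        self.invades = frozenset(self.invades)


@dataclass
class NodeStationFinding:
    """Lymph nodes examined at one station: ``positive``/``examined``."""

    station: str
    positive: int
    examined: int

    def __post_init__(self):
        if self.station not in NODE_STATIONS:
            raise FactsError(f"unknown node station {self.station!r}")
        if not (0 <= self.positive <= self.examined):
            raise FactsError(
                f"need 0 <= positive <= examined, got {self.positive}/{self.examined}"
            )


@dataclass
class PathologyFacts:
    """Everything the staging rules need, decoupled from report wording."""

    nodules: list[TumorNodule] = field(default_factory=list)
    nodes: list[NodeStationFinding] = field(default_factory=list)
    metastasis_evidence: str = "absent"  # {absent, present, unknown}
    histology: str = UNKNOWN
    diagnosis_text: str = ""
    grade: str | None = None    # osteosarcoma profile
    margin: str | None = None   # osteosarcoma profile

    def __post_init__(self):
        if self.metastasis_evidence not in ("absent", "present", "unknown"):
            raise FactsError(
                f"metastasis_evidence must be absent/present/unknown, got {self.metastasis_evidence!r}"
            )

    @property
    def max_dimension_cm(self) -> float | None:
        sizes = [n.size_cm for n in self.nodules if n.size_cm is not None]
        return max(sizes) if sizes else None

    def to_dict(self) -> dict:
        return {
            "nodules": [
                {
                    "size_cm": n.size_cm,
                    "laterality": n.laterality,
                    "lobe": n.lobe,
                    "invades": sorted(n.invades),
                }
                for n in self.nodules
            ],
            "nodes": [
                {"station": f.station, "positive": f.positive, "examined": f.examined}
                for f in self.nodes
            ],
            "metastasis_evidence": self.metastasis_evidence,
            "histology": self.histology,
            "diagnosis_text": self.diagnosis_text,
            "grade": self.grade,
            "margin": self.margin,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PathologyFacts":
        return cls(
            nodules=[
                TumorNodule(
                    size_cm=n["size_cm"],
                    laterality=n["laterality"],
                    lobe=n["lobe"],
                    invades=frozenset(n.get("invades", ())),
                )
                for n in payload.get("nodules", ())
            ],
            nodes=[
                NodeStationFinding(f["station"], f["positive"], f["examined"])
                for f in payload.get("nodes", ())
            ],
            metastasis_evidence=payload.get("metastasis_evidence", "absent"),
            histology=payload.get("histology", UNKNOWN),
            diagnosis_text=payload.get("diagnosis_text", ""),
            grade=payload.get("grade"),
            margin=payload.get("margin"),
        )


@dataclass
class TNMAssignment:
    """pT/pN/pM plus the overall stage group and the fired-rule rationale."""

    pT: str
    pN: str
    pM: str
    stage: str
    rationale: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# T classification

def _size_ladder_t(size_cm: float) -> tuple[str, str]:
    for max_cm, t, citation in _SIZE_LADDER:
        if max_cm is None or size_cm <= max_cm:
            return t, citation
    raise AssertionError("size ladder is not exhaustive")


def classify_pt(facts: PathologyFacts) -> tuple[str, list[str]]:
    """Classify the pathologic primary-tumor category.

    Size ladder on the largest nodule, overridden upward by invasion
    descriptors and by multi-nodule rules (separate nodule in the same lobe ->
    T3; different ipsilateral lobe -> T4).  No nodules -> T0; a documented
    tumor with no size and no descriptors -> TX.
    """
    rationale: list[str] = []
    if not facts.nodules:
        return "T0", ["No primary tumor nodule identified -> T0"]

    candidates: list[tuple[int, str, str]] = []  # (level, category, citation)

    size = facts.max_dimension_cm
    if size is not None:
        t, citation = _size_ladder_t(size)
        candidates.append((t_level(t), t, f"Greatest dimension {size:g} cm: {citation}"))

    for nod in facts.nodules:
        for flag in sorted(nod.invades):
            min_t, citation = _DESCRIPTOR_RULES[flag]
            if min_t is not None:
                candidates.append((t_level(min_t), min_t, citation))

    # multi-nodule patterns over distinct (laterality, lobe) locations
    locs = [(n.laterality, n.lobe) for n in facts.nodules]
    if len(locs) > len(set(locs)):
        min_t, citation = _MULTINODULE["same_lobe"]
        candidates.append((t_level(min_t), min_t, citation))
    for side in ("left", "right"):
        lobes = {lobe for lat, lobe in set(locs) if lat == side}
        if len(lobes) > 1:
            min_t, citation = _MULTINODULE["different_ipsilateral_lobe"]
            candidates.append((t_level(min_t), min_t, citation))

    if not candidates:
        return "TX", ["Tumor documented but size and descriptors unavailable -> TX"]

    best_level = max(level for level, _, _ in candidates)
    # among candidates at the winning level, keep the most specific category
    at_best = [(t, c) for level, t, c in candidates if level == best_level]
    subcat = [(t, c) for t, c in at_best if len(t) == 3]
    winner_t, winner_cit = (subcat or at_best)[0]
    rationale.append(f"{winner_cit} -> {winner_t}")
    for level, t, c in candidates:
        if (t, c) != (winner_t, winner_cit):
            rationale.append(f"(also fired, superseded by max-level tie-break: {c} -> {t})")
    return winner_t, rationale


# ---------------------------------------------------------------------------
# N classification

def classify_pn(facts: PathologyFacts) -> tuple[str, list[str]]:
    """Classify pathologic regional lymph-node involvement.

    The N level is the maximum station level over stations with at least one
    positive node; positive/examined counts never influence the level.  All
    positives zero -> N0; no nodes examined -> NX.
    """
    examined = [f for f in facts.nodes if f.examined > 0]
    if not examined:
        return "NX", ["No regional lymph nodes examined -> NX"]
    involved = [f for f in examined if f.positive > 0]
    if not involved:
        total = sum(f.examined for f in examined)
        return "N0", [f"All {total} examined regional nodes negative -> N0"]
    level = max(_STATION_LEVEL[f.station] for f in involved)
    stations = sorted({f.station for f in involved if _STATION_LEVEL[f.station] == level})
    return f"N{level}", [
        f"Positive nodes at {', '.join(s.replace('_', ' ') for s in stations)}: "
        f"{_N_CITATIONS[level]} -> N{level} (counts do not affect the level)"
    ]


# ---------------------------------------------------------------------------
# Stage grouping

def stage_group(t: str, n: str, m: str = "M0-assumed") -> tuple[str, list[str]]:
    """Look up the overall stage group for a (T, N, M) combination.

    M1 forces stage IV regardless of T and N.  TX, NX, T0, Tis and Unknown
    inputs yield stage Unknown (the grouping table does not define rows the
    closed stage vocabulary can express for them).  Coarse T1/T2 inputs — which
    arise only from model predictions, never from this engine — use their
    subcategory-a row, with which every same-level row agrees except T2b.
    """
    if m == "M1":
        return "IV", ["Distant metastasis (M1) -> Stage IV regardless of T and N"]
    if m not in ("M0", "M0-assumed", "MX"):
        raise FactsError(f"unknown pM value {m!r}")
    t_row = _COARSE_T_ROWS.get(t, t)
    if (t_row, n) not in _STAGE_TABLE:
        return UNKNOWN, [f"No stage group defined for ({t}, {n}, {m}) -> Unknown"]
    stage = _STAGE_TABLE[(t_row, n)]
    note = "" if t_row == t else f" (coarse {t} grouped via {t_row} row)"
    msuffix = "M0" if m == "M0" else "no evidence of distant metastasis (M0 assumed)"
    return stage, [
        f"({t}, {n}) with {msuffix}: {_RULES['stage_grouping_citation']} -> Stage {stage}{note}"
    ]


def _pm_from_facts(facts: PathologyFacts) -> str:
    return {"present": "M1", "absent": "M0-assumed", "unknown": "MX"}[facts.metastasis_evidence]


def stage_case(facts: PathologyFacts) -> TNMAssignment:
    """Full assignment: classify pT and pN, derive pM, group the stage."""
    pt, rt = classify_pt(facts)
    pn, rn = classify_pn(facts)
    pm = _pm_from_facts(facts)
    stage, rs = stage_group(pt, pn, pm)
    return TNMAssignment(pT=pt, pN=pn, pM=pm, stage=stage, rationale=rt + rn + rs)
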