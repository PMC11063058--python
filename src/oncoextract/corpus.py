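"""Synthetic pathology-report corpora with known ground truth.

Emulates cohorts of scanned lung-cancer (and pediatric osteosarcoma) pathology
reports: sectioned narrative text carrying tumor size(s), laterality/lobe,
invasion statements, lymph-node station counts ("a/b positive"), histology
wording — plus the irregularity classes real scanned cohorts exhibit (blank
files, OCR noise, missing report forms, typos, truncation).

Ground truth is *defined* as the AJCC7 engine's output on the sampled facts,
so the generator can never disagree with the staging oracle by construction.
Every fact appears exactly once in the rendered text, in canonical phrasing
that :func:`parse_report` recovers exactly (round-trip contract); template
styles vary layout, never the fact phrasing.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ajcc7 import NodeStationFinding, PathologyFacts, TumorNodule, stage_case
from .vocab import UNKNOWN

IRREGULAR_CLASSES = ("blank", "poor_scan", "missing_form")

#: canonical rendered phrase per histology class (the free-text diagnosis line)
HISTOLOGY_PHRASES = {
    "Lung Adenocarcinoma": "Lung adenocarcinoma",
    "Lung Squamous Cell Carcinoma": "Lung squamous cell carcinoma",
    "Other": "Adenosquamous carcinoma",
}
_PHRASE_TO_HISTOLOGY = {v: k for k, v in HISTOLOGY_PHRASES.items()}

#: canonical sentence per invasion descriptor (parser reverses this map)
INVASION_SENTENCES = {
    "visceral_pleura_surrounded_ok": "The tumor is surrounded by lung or visceral pleura.",
    "visceral_pleura_invaded": "The tumor invades the visceral pleura.",
    "chest_wall": "The tumor invades the chest wall.",
    "diaphragm": "The tumor invades the diaphragm.",
    "mediastinum": "The tumor invades the mediastinum.",
    "heart_great_vessels": "The tumor invades the heart and great vessels.",
    "main_bronchus": "The tumor involves the main bronchus.",
    "carina": "The tumor involves the carina.",
    "atelectasis_whole_lung": "Atelectasis of the entire lung is present.",
    "separate_nodule_same_lobe": "A separate tumor nodule is present in the same lobe.",
}
_SENTENCE_TO_FLAG = {v: k for k, v in INVASION_SENTENCES.items()}

METASTASIS_SENTENCES = {
    "absent": "No evidence of distant metastasis.",
    "present": "Evidence of distant metastasis is present.",
    "unknown": "Distant metastasis cannot be assessed.",
}
_SENTENCE_TO_METASTASIS = {v: k for k, v in METASTASIS_SENTENCES.items()}

STYLES = ("narrative", "tabular", "legacy")


class ConfigError(ValueError):
    """Raised for invalid corpus configurations."""


class AccountingError(ValueError):
    """Raised when cohort accounting would go negative."""


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class CorpusConfig:
    """Distributional knobs for the synthetic cohort.

    Defaults sketch a resected, predominantly non-metastatic lung-cancer case
    mix: tumor sizes lognormal around ~3 cm, nodal status mostly N0/N1,
    adenocarcinoma-heavy histology, and a ~15% irregular-report rate split
    over blank / poorly scanned / missing-form classes.
    """

    n_reports: int = 200
    seed: int = 0
    task: str = "lung"  # {lung, osteosarcoma}

    # tumor size (cm): lognormal, rounded to 0.1 cm
    size_log_mean: float = math.log(3.2)
    size_log_sd: float = 0.5
    size_min_cm: float = 0.4
    size_max_cm: float = 14.0
    p_size_missing: float = 0.02

    histology_mix: dict = field(
        default_factory=lambda: {
            "Lung Adenocarcinoma": 0.50,
            "Lung Squamous Cell Carcinoma": 0.42,
            "Other": 0.08,
        }
    )
    n_status_mix: dict = field(
        default_factory=lambda: {"N0": 0.64, "N1": 0.20, "N2": 0.14, "N3": 0.02}
    )
    invasion_probs: dict = field(
        default_factory=lambda: {
            "visceral_pleura_invaded": 0.10,
            "chest_wall": 0.05,
            "diaphragm": 0.02,
            "main_bronchus": 0.04,
            "mediastinum": 0.02,
            "heart_great_vessels": 0.01,
            "carina": 0.005,
            "atelectasis_whole_lung": 0.01,
            "separate_nodule_same_lobe": 0.02,
        }
    )
    p_surrounded_statement: float = 0.5
    p_multi_nodule: float = 0.05
    metastasis_mix: dict = field(
        default_factory=lambda: {"absent": 0.95, "present": 0.02, "unknown": 0.03}
    )

    # osteosarcoma profile
    grade_mix: dict = field(
        default_factory=lambda: {"low": 0.20, "intermediate": 0.20, "high": 0.60}
    )
    margin_mix: dict = field(default_factory=lambda: {"negative": 0.80, "positive": 0.20})

    # irregularities (fractions of n_reports, realized as rounded counts)
    irregular_fractions: dict = field(
        default_factory=lambda: {"blank": 0.04, "poor_scan": 0.07, "missing_form": 0.04}
    )
    ocr_intensity: float = 0.6
    typo_rate: float = 0.0  # word-level typo rate applied to *valid* reports

    styles: tuple = STYLES
    train_fraction: float = 0.1

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ConfigError("n_reports must be >= 0")
        if self.task not in ("lung", "osteosarcoma"):
            raise ConfigError(f"unknown task profile {self.task!r}")
        for name, mix in (
            ("histology_mix", self.histology_mix),
            ("n_status_mix", self.n_status_mix),
            ("metastasis_mix", self.metastasis_mix),
            ("grade_mix", self.grade_mix),
            ("margin_mix", self.margin_mix),
        ):
            if any(p < 0 for p in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must be non-negative and sum to 1")
        probs = list(self.invasion_probs.values()) + [
            self.p_surrounded_statement,
            self.p_multi_nodule,
            self.p_size_missing,
            self.typo_rate,
            self.train_fraction,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        fracs = self.irregular_fractions
        if set(fracs) - set(IRREGULAR_CLASSES):
            raise ConfigError(f"irregular classes must be among {IRREGULAR_CLASSES}")
        if any(not (0.0 <= f <= 1.0) for f in fracs.values()) or sum(fracs.values()) > 1.0:
            raise ConfigError("irregular fractions must be in [0, 1] and sum to <= 1")
        if any(s not in STYLES for s in self.styles):
            raise ConfigError(f"unknown style id in {self.styles}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["styles"] = list(self.styles)
        return d

    @classmethod
    def from_dict(cls, payload: dict) -> "CorpusConfig":
        payload = dict(payload)
        if "styles" in payload:
            payload["styles"] = tuple(payload["styles"])
        return cls(**payload)


def _choice(rng: np.random.Generator, mix: dict) -> str:
    keys = list(mix)
    return keys[rng.choice(len(keys), p=np.asarray([mix[k] for k in keys], dtype=float))]


# ---------------------------------------------------------------------------
# Fact sampling

def sample_facts(config: CorpusConfig, seed: int) -> PathologyFacts:
    """Draw one case's pathology facts from the configured distributions.

    Reproducible under a fixed seed; reference labels are whatever the AJCC7
    engine derives from the returned facts.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if config.task == "osteosarcoma":
        return PathologyFacts(
            nodules=[],
            nodes=[],
            metastasis_evidence="unknown",
            histology=UNKNOWN,
            diagnosis_text="Osteosarcoma",
            grade=_choice(rng, config.grade_mix),
            margin=_choice(rng, config.margin_mix),
        )

    def draw_size() -> float | None:
        if rng.random() < config.p_size_missing:
            return None
        raw = float(rng.lognormal(config.size_log_mean, config.size_log_sd))
        return round(min(max(raw, config.size_min_cm), config.size_max_cm), 1)

    laterality = "right" if rng.random() < 0.55 else "left"
    lobes = ("upper", "middle", "lower") if laterality == "right" else ("upper", "lower")
    lobe = lobes[rng.choice(len(lobes))]

    flags = {f for f, p in config.invasion_probs.items() if rng.random() < p}
    if not flags and rng.random() < config.p_surrounded_statement:
        flags = {"visceral_pleura_surrounded_ok"}
    nodules = [TumorNodule(draw_size(), laterality, lobe, frozenset(flags))]

    if rng.random() < config.p_multi_nodule:
        other_lobes = [l for l in lobes if l != lobe]
        nodules.append(
            TumorNodule(draw_size(), laterality, other_lobes[rng.choice(len(other_lobes))])
        )

    # nodal findings: realize a target N status as station-level counts
    target_n = _choice(rng, config.n_status_mix)
    nodes: list[NodeStationFinding] = []

    def add(station: str, positive: int) -> None:
        examined = int(rng.integers(max(positive, 1), max(positive, 1) + 12))
        nodes.append(NodeStationFinding(station, positive, examined))

    n1_station = ("hilar", "peribronchial", "intrapulmonary")[rng.choice(3, p=[0.5, 0.3, 0.2])]
    n2_station = ("ipsilateral_mediastinal", "subcarinal")[rng.choice(2, p=[0.6, 0.4])]
    add(n1_station, 0)
    if rng.random() < 0.7:
        add(n2_station, 0)
    if target_n == "N1":
        pos = min(int(rng.integers(1, 5)), nodes[0].examined)
        nodes[0] = NodeStationFinding(n1_station, pos, nodes[0].examined)
    elif target_n == "N2":
        pos = int(rng.integers(1, 4))
        if len(nodes) > 1:
            nodes[1] = NodeStationFinding(n2_station, min(pos, nodes[1].examined), nodes[1].examined)
        else:
            add(n2_station, pos)
        if rng.random() < 0.6:
            pos1 = min(int(rng.integers(1, 4)), nodes[0].examined)
            nodes[0] = NodeStationFinding(n1_station, pos1, nodes[0].examined)
    elif target_n == "N3":
        add(("scalene", "supraclavicular", "contralateral_mediastinal")[rng.choice(3)],
            int(rng.integers(1, 3)))

    histology = _choice(rng, config.histology_mix)
    return PathologyFacts(
        nodules=nodules,
        nodes=nodes,
        metastasis_evidence=_choice(rng, config.metastasis_mix),
        histology=histology,
        diagnosis_text=HISTOLOGY_PHRASES[histology],
    )


# ---------------------------------------------------------------------------
# Rendering

def _nodule_lines(facts: PathologyFacts) -> list[str]:
    lines = []
    for nod in facts.nodules:
        size = "not stated" if nod.size_cm is None else f"{nod.size_cm:.1f} cm"
        lines.append(
            f"Tumor size: {size} in greatest dimension ({nod.laterality} {nod.lobe} lobe)."
        )
        for flag in sorted(nod.invades):
            lines.append(INVASION_SENTENCES[flag])
    if not facts.nodules:
        lines.append("No tumor identified.")
    return lines


def _node_lines(facts: PathologyFacts) -> list[str]:
    if not facts.nodes:
        return ["No lymph nodes submitted for examination."]
    return [
        f"Lymph nodes: {f.positive}/{f.examined} positive for metastasis "
        f"({f.station.replace('_', ' ')} {f.positive}/{f.examined})."
        for f in facts.nodes
    ]


def _diagnosis_lines(facts: PathologyFacts) -> list[str]:
    lines = [f"Final diagnosis: {facts.diagnosis_text or 'See comment'}."]
    if facts.grade is not None:
        lines.append(f"Histologic grade: {facts.grade} grade.")
    if facts.margin is not None:
        lines.append(f"Resection margins: {facts.margin}.")
    lines.append(METASTASIS_SENTENCES[facts.metastasis_evidence])
    return lines


def render_report(facts: PathologyFacts, style: str = "narrative", seed: int = 0) -> str:
    """Render facts as a sectioned report in one of the template styles.

    Styles differ in headers, ordering and filler text only; the canonical
    fact phrasing is shared, so two styles of the same facts parse back to
    identical :class:`PathologyFacts`.
    """
    if style not in STYLES:
        raise ConfigError(f"unknown template style {style!r}")
    rng = np.random.default_rng(seed)
    specimen = "Lung, lobectomy" if facts.nodules else "Specimen received"
    if facts.grade is not None:
        specimen = "Bone, resection"
    accession = f"S-{rng.integers(10_000, 99_999)}"

    tumor = _nodule_lines(facts)
    nodes = _node_lines(facts)
    diagnosis = _diagnosis_lines(facts)

    if style == "narrative":
        parts = [
            "SURGICAL PATHOLOGY REPORT",
            f"Accession: {accession}",
            "",
            "SPECIMEN:",
            f"{specimen}.",
            "",
            "GROSS DESCRIPTION:",
            "The specimen is received in formalin and sectioned.",
            *tumor,
            "",
            "MICROSCOPIC EXAMINATION / LYMPH NODES:",
            *nodes,
            "",
            "FINAL DIAGNOSIS:",
            *diagnosis,
        ]
    elif style == "tabular":
        parts = [
            f"PATHOLOGY REPORT FORM {accession}",
            "=" * 40,
            f"Specimen type ....... {specimen}",
            "",
            "-- TUMOR --",
            *tumor,
            "-- REGIONAL LYMPH NODES --",
            *nodes,
            "-- DIAGNOSIS --",
            *diagnosis,
            "=" * 40,
            "End of report.",
        ]
    else:  # legacy
        parts = [
            f"(scanned document {accession})",
            "DEPARTMENT OF PATHOLOGY - CONSULTATION REPORT",
            "",
            "Clinical history: mass noted on imaging.",
            f"Specimen: {specimen}.",
            "Findings:",
            *tumor,
            *nodes,
            "Impression:",
            *diagnosis,
            "",
            "Dictated but not read.",
        ]
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# Fact parsing (round-trip contract)

_SIZE_RE = re.compile(
    r"^Tumor size: (?:(\d+(?:\.\d+)?) cm|not stated) in greatest dimension "
    r"\((left|right) (upper|middle|lower) lobe\)\.$"
)
_NODE_RE = re.compile(
    r"^Lymph nodes: (\d+)/(\d+) positive for metastasis \(([a-z ]+) \d+/\d+\)\.$"
)
_DIAG_RE = re.compile(r"^Final diagnosis: (.+)\.$")
_GRADE_RE = re.compile(r"^Histologic grade: (low|intermediate|high) grade\.$")
_MARGIN_RE = re.compile(r"^Resection margins: (negative|positive)\.$")


def parse_report(text: str) -> PathologyFacts | None:
    """Recover :class:`PathologyFacts` from a rendered report.

    Returns None when no recognizable findings are present (blank input,
    missing report forms, or noise that destroyed every fact line).  This is
    the reader the mock extraction backend and the round-trip tests use.
    """
    if not text or not text.strip():
        return None
    nodules: list[dict] = []
    nodes: list[NodeStationFinding] = []
    metastasis = None
    diagnosis = None
    grade = margin = None
    found = False

    for raw_line in text.splitlines():
        line = raw_line.strip()
        if not line:
            continue
        m = _SIZE_RE.match(line)
        if m:
            size = float(m.group(1)) if m.group(1) else None
            nodules.append(
                {"size_cm": size, "laterality": m.group(2), "lobe": m.group(3), "invades": set()}
            )
            found = True
            continue
        if line in _SENTENCE_TO_FLAG and nodules:
            nodules[-1]["invades"].add(_SENTENCE_TO_FLAG[line])
            continue
        m = _NODE_RE.match(line)
        if m:
            try:
                nodes.append(
                    NodeStationFinding(
                        m.group(3).replace(" ", "_"), int(m.group(1)), int(m.group(2))
                    )
                )
                found = True
            except Exception:
                pass
            continue
        if line in _SENTENCE_TO_METASTASIS:
            metastasis = _SENTENCE_TO_METASTASIS[line]
            continue
        m = _DIAG_RE.match(line)
        if m:
            diagnosis = m.group(1)
            found = True
            continue
        m = _GRADE_RE.match(line)
        if m:
            grade = m.group(1)
            found = True
            continue
        m = _MARGIN_RE.match(line)
        if m:
            margin = m.group(1)
            found = True
            continue
        # explicit negatives count as findings but leave the lists empty
        if line in ("No tumor identified.", "No lymph nodes submitted for examination."):
            found = True

    if not found:
        return None
    if diagnosis == "See comment":
        diagnosis = ""
    try:
        return PathologyFacts(
            nodules=[
                TumorNodule(n["size_cm"], n["laterality"], n["lobe"], frozenset(n["invades"]))
                for n in nodules
            ],
            nodes=nodes,
            metastasis_evidence=metastasis or "unknown",
            histology=_PHRASE_TO_HISTOLOGY.get(diagnosis, UNKNOWN),
            diagnosis_text=diagnosis or "",
            grade=grade,
            margin=margin,
        )
    except Exception:
        return None


# ---------------------------------------------------------------------------
# Corruption

_OCR_ALPHABET = list("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789#@%&*+=~^.,;:/ ")

MISSING_FORM_TEXT = (
    "SURGICAL PATHOLOGY REPORT\n"
    "Page 1 of 1\n"
    "Accession: __________\n"
    "[report form not available in the scanned record]\n"
)


def corrupt_report(text: str, mode: str, intensity: float = 0.3, seed: int = 0) -> str:
    """Apply one irregularity mode to a report text.

    ``blank`` -> empty string; ``ocr_noise`` -> character substitutions and
    insertions at a rate proportional to ``intensity`` (digits and punctuation
    included in the confusion alphabet, so size and count tokens can be
    damaged); ``missing_form`` -> boilerplate header without findings;
    ``typos`` -> word-level edits; ``truncate`` -> prefix cut.  Deterministic
    under a fixed seed; zero intensity is the identity for non-destructive
    modes.
    """
    if text is None:
        raise ValueError("text must not be None")
    if not (0.0 <= intensity <= 1.0):
        raise ValueError(f"intensity must lie in [0, 1], got {intensity}")
    if mode == "blank":
        return ""
    if mode == "missing_form":
        return MISSING_FORM_TEXT
    rng = np.random.default_rng(seed)
    if mode == "ocr_noise":
        rate = 0.25 * intensity
        out = []
        for ch in text:
            r = rng.random()
            if ch != "\n" and r < rate:
                out.append(_OCR_ALPHABET[rng.integers(len(_OCR_ALPHABET))])
                if rng.random() < 0.2:  # occasional insertion
                    out.append(_OCR_ALPHABET[rng.integers(len(_OCR_ALPHABET))])
            else:
                out.append(ch)
        return "".join(out)
    if mode == "typos":
        words = text.split(" ")
        for i, w in enumerate(words):
            if len(w) > 3 and rng.random() < intensity:
                j = int(rng.integers(1, len(w) - 1))
                if rng.random() < 0.5:  # transpose
                    words[i] = w[:j] + w[j + 1] + w[j] + w[j + 2:]
                else:  # drop a character
                    words[i] = w[:j] + w[j + 1:]
        return " ".join(words)
    if mode == "truncate":
        keep = int(round(len(text) * (1.0 - intensity)))
        return text[:keep]
    raise ValueError(f"unknown corruption mode {mode!r}")


# ---------------------------------------------------------------------------
# Cohort generation and accounting

def account_exclusions(downloaded: int, overlap: int, invalid_counts: dict) -> int:
    """Cohort accounting: valid = downloaded - overlap - sum(invalid counts)."""
    if downloaded < 0 or overlap < 0 or any(v < 0 for v in invalid_counts.values()):
        raise AccountingError("all counts must be >= 0")
    valid = downloaded - overlap - sum(invalid_counts.values())
    if valid < 0:
        raise AccountingError(
            f"exclusions ({overlap} overlap + {sum(invalid_counts.values())} invalid) "
            f"exceed downloaded count {downloaded}"
        )
    return valid


@dataclass
class Cohort:
    """A generated corpus: texts, underlying facts, manifest and accounting."""

    config: CorpusConfig
    reports: dict  # report_id -> text
    facts: dict    # report_id -> PathologyFacts (known even for irregular reports)
    manifest: pd.DataFrame
    accounting: dict

    def valid_ids(self) -> list[str]:
        return list(self.manifest.loc[self.manifest["validity"] == "valid", "report_id"])

    def reference_labels(self, report_id: str) -> dict:
        row = self.manifest.set_index("report_id").loc[report_id]
        keys = (
            ("pT", "pN", "stage", "histology")
            if self.config.task == "lung"
            else ("grade", "margin")
        )
        return {k: row[k] for k in keys}

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "reports").mkdir(parents=True, exist_ok=True)
        for rid, text in self.reports.items():
            (outdir / "reports" / f"{rid}.txt").write_text(text, encoding="utf-8")
        self.manifest.to_csv(outdir / "manifest.csv", index=False)
        (outdir / "accounting.json").write_text(json.dumps(self.accounting, indent=2))
        (outdir / "config.json").write_text(json.dumps(self.config.to_dict(), indent=2))
        with open(outdir / "facts.jsonl", "w", encoding="utf-8") as fh:
            for rid, f in self.facts.items():
                fh.write(json.dumps({"report_id": rid, **f.to_dict()}) + "\n")

    @classmethod
    def load(cls, outdir: str | Path) -> "Cohort":
        outdir = Path(outdir)
        config = CorpusConfig.from_dict(json.loads((outdir / "config.json").read_text()))
        manifest = pd.read_csv(outdir / "manifest.csv", keep_default_na=False)
        reports = {
            rid: (outdir / "reports" / f"{rid}.txt").read_text(encoding="utf-8")
            for rid in manifest["report_id"]
        }
        facts = {}
        with open(outdir / "facts.jsonl", encoding="utf-8") as fh:
            for line in fh:
                payload = json.loads(line)
                rid = payload.pop("report_id")
                facts[rid] = PathologyFacts.from_dict(payload)
        accounting = json.loads((outdir / "accounting.json").read_text())
        return cls(config, reports, facts, manifest, accounting)


def generate_cohort(config: CorpusConfig) -> Cohort:
    """Generate ``config.n_reports`` reports with manifest and accounting.

    Irregular fractions are realized exactly (rounded counts); the manifest's
    accounting identity (valid + overlap + invalid-by-class == downloaded)
    holds on every generated cohort; regeneration with the same seed is
    byte-identical.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    counts = {c: int(round(config.irregular_fractions.get(c, 0.0) * n)) for c in IRREGULAR_CLASSES}
    order = rng.permutation(n)
    validity = np.full(n, "valid", dtype=object)
    cursor = 0
    for cls_name in IRREGULAR_CLASSES:
        for k in range(counts[cls_name]):
            validity[order[cursor + k]] = cls_name
        cursor += counts[cls_name]

    n_train = int(round(config.train_fraction * n))
    reports: dict[str, str] = {}
    facts_map: dict[str, PathologyFacts] = {}
    rows = []
    for i in range(n):
        rid = f"SYN-{i:04d}"
        case_seed = int(rng.integers(0, 2**31 - 1))
        facts = sample_facts(config, case_seed)
        style = config.styles[case_seed % len(config.styles)]
        text = render_report(facts, style=style, seed=case_seed)
        if config.typo_rate > 0:
            text = corrupt_report(text, "typos", config.typo_rate, seed=case_seed)
        if validity[i] == "blank":
            text = corrupt_report(text, "blank", seed=case_seed)
        elif validity[i] == "poor_scan":
            text = corrupt_report(text, "ocr_noise", config.ocr_intensity, seed=case_seed)
        elif validity[i] == "missing_form":
            text = corrupt_report(text, "missing_form", seed=case_seed)

        tnm = stage_case(facts)
        row = {
            "report_id": rid,
            "split": "train" if i < n_train else "test",
            "validity": validity[i],
            "style": style,
        }
        if config.task == "lung":
            size = facts.max_dimension_cm
            row.update(
                pT=tnm.pT, pN=tnm.pN, stage=tnm.stage, histology=facts.histology,
                size_cm="" if size is None else size,
            )
        else:
            row.update(grade=facts.grade or UNKNOWN, margin=facts.margin or UNKNOWN)
        rows.append(row)
        reports[rid] = text
        facts_map[rid] = facts

    manifest = pd.DataFrame(rows)
    invalid_by_class = {c: counts[c] for c in IRREGULAR_CLASSES}
    accounting = {
        "downloaded": n,
        "overlap_excluded": 0,
        "invalid_by_class": invalid_by_class,
        "valid": account_exclusions(n, 0, invalid_by_class),
    }
    return Cohort(config, reports, facts_map, manifest, accounting)
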