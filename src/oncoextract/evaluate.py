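"""Registry-style evaluation of extraction records against reference labels.

The scoring protocol mirrors how curated cancer-registry comparisons are
reported:

* cases with uncertain values (``Unknown`` after normalization) in either the
  reference or the prediction are removed before scoring;
* **coverage** for an attribute is the number of reference-bearing cases with
  a non-Unknown prediction divided by the *total* number of valid reports;
* accuracy, support-weighted F1/recall/precision and Cohen's unweighted kappa
  are computed from the confusion matrix (reference in rows, prediction in
  columns); reported values are rounded to 2 decimals, full precision is kept
  internally, and the average row is computed from unrounded per-attribute
  metrics;
* stage errors are classified as *error propagation* (pT or pN also wrong, at
  pooled T/N level) or *incorrect rule* (stage wrong despite correct pT/pN);
* reproducibility between two runs is the rate of equivalent canonical
  estimates plus the mean absolute difference of certainty degrees;
* irregular inputs (blank / poor scan / missing form) are audited for
  fabricated ("hallucinated") responses and for convergence to a fixed
  attractor record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import ExtractionRecord, LUNG_SCORED_ATTRIBUTES, OSTEO_ATTRIBUTES
from .vocab import UNKNOWN, VOCABULARIES, coarsen, normalize_label

METRIC_NAMES = ("accuracy", "f1", "kappa", "recall", "precision")


class EvaluationError(ValueError):
    pass


def scored_attributes(task: str) -> tuple:
    return LUNG_SCORED_ATTRIBUTES if task == "lung" else OSTEO_ATTRIBUTES


# ---------------------------------------------------------------------------
# Pair filtering and coverage

def records_to_labels(records: list, attribute: str) -> dict:
    """Map report_id -> canonical predicted label; duplicate ids are an error."""
    labels: dict[str, str] = {}
    for rec in records:
        if rec.report_id in labels:
            raise EvaluationError(f"duplicate report id {rec.report_id!r}")
        est = rec.estimate(attribute)
        labels[rec.report_id] = (
            normalize_label(est, attribute) if isinstance(est, str) else str(est)
        )
    return labels


def filter_evaluable(preds: dict, refs: dict, n_valid_total: int | None = None):
    """Keep (reference, prediction) pairs where both are certain.

    ``preds`` maps every valid report id to its predicted label; ``refs`` maps
    reference-bearing ids to reference labels (Unknown references count as
    absent).  Returns the pair list and a coverage-statistics dict.
    """
    if n_valid_total is None:
        n_valid_total = len(preds)
    pairs = []
    n_with_reference = 0
    n_unknown_pred = 0
    for rid, ref in refs.items():
        if ref == UNKNOWN:
            continue
        if rid not in preds:
            continue
        n_with_reference += 1
        pred = preds[rid]
        if pred == UNKNOWN:
            n_unknown_pred += 1
            continue
        pairs.append((ref, pred))
    n_classified = n_with_reference - n_unknown_pred
    coverage = n_classified / n_valid_total if n_valid_total else 0.0
    stats = {
        "n_valid_total": n_valid_total,
        "n_with_reference": n_with_reference,
        "n_classified": n_classified,
        "n_unknown_predictions": n_unknown_pred,
        "coverage": coverage,
        "coverage_rounded": round(coverage, 2),
    }
    return pairs, stats


# ---------------------------------------------------------------------------
# Confusion matrices and metrics

def _label_order(labels: set, attribute: str | None) -> list:
    if attribute in VOCABULARIES:
        vocab = list(VOCABULARIES[attribute])
        ordered = [v for v in vocab if v in labels]
        extra = sorted(labels - set(vocab))
        return ordered + extra
    return sorted(labels)


def confusion(pairs: list, granularity: str = "fine",
              attribute: str | None = None) -> pd.DataFrame:
    """Square confusion matrix over observed ∪ reference labels.

    Rows are the reference, columns the prediction.  ``granularity="t_level"``
    pools subcategories (T1a/T1b -> T1; stage groups to Roman level).
    """
    if not pairs:
        raise EvaluationError("no evaluable pairs")
    if granularity not in ("fine", "t_level"):
        raise EvaluationError(f"unknown granularity {granularity!r}")
    if granularity == "t_level" and attribute is not None:
        pairs = [(coarsen(r, attribute), coarsen(p, attribute)) for r, p in pairs]
    labels = {r for r, _ in pairs} | {p for _, p in pairs}
    order = _label_order(labels, attribute if granularity == "fine" else None)
    if granularity == "t_level":
        order = sorted(labels)
    matrix = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for ref, pred in pairs:
        matrix.loc[ref, pred] += 1
    matrix.index.name = "reference"
    matrix.columns.name = "prediction"
    return matrix


def metrics(matrix: pd.DataFrame, average: str = "weighted") -> dict:
    """Accuracy, F1, Cohen's kappa, recall and precision from a matrix.

    ``average`` is the one-vs-rest averaging scheme for F1/recall/precision:
    support-weighted by default, with micro and macro exposed as variants.
    """
    m = matrix.to_numpy(dtype=float)
    n = m.sum()
    if n == 0:
        raise EvaluationError("metrics undefined on an empty matrix")
    tp = np.diag(m)
    row = m.sum(axis=1)  # reference support
    col = m.sum(axis=0)  # predicted count
    accuracy = tp.sum() / n

    with np.errstate(divide="ignore", invalid="ignore"):
        recall_c = np.where(row > 0, tp / np.where(row > 0, row, 1), 0.0)
        precision_c = np.where(col > 0, tp / np.where(col > 0, col, 1), 0.0)
        denom = recall_c + precision_c
        f1_c = np.where(denom > 0, 2 * recall_c * precision_c / np.where(denom > 0, denom, 1), 0.0)

    if average == "weighted":
        w = row / n
        recall, precision, f1 = (float(w @ x) for x in (recall_c, precision_c, f1_c))
    elif average == "macro":
        present = row > 0
        recall, precision, f1 = (float(x[present].mean()) for x in (recall_c, precision_c, f1_c))
    elif average == "micro":
        recall = precision = f1 = float(accuracy)
    else:
        raise EvaluationError(f"unknown averaging scheme {average!r}")

    pe = float(row @ col) / (n * n)
    kappa = 1.0 if pe >= 1.0 else (accuracy - pe) / (1.0 - pe)

    return {
        "accuracy": float(accuracy),
        "f1": f1,
        "kappa": float(kappa),
        "recall": recall,
        "precision": precision,
        "n": int(n),
    }


# ---------------------------------------------------------------------------
# Stage-error taxonomy

def classify_stage_errors(cases: pd.DataFrame) -> tuple[dict, pd.DataFrame]:
    """Split stage misclassifications into error propagation vs incorrect rule.

    ``cases`` needs columns ref_pT/ref_pN/ref_stage and pred_pT/pred_pN/
    pred_stage.  A case whose stage is wrong counts as *error propagation* if
    its pT or pN is also wrong at pooled (level) granularity, else as
    *incorrect rule*.  Cases with any Unknown among the six values are skipped.
    """
    rows = []
    counts = {"correct": 0, "error_propagation": 0, "incorrect_rule": 0, "skipped": 0}
    for case in cases.itertuples():
        values = [case.ref_pT, case.ref_pN, case.ref_stage,
                  case.pred_pT, case.pred_pN, case.pred_stage]
        if any(v == UNKNOWN for v in values):
            counts["skipped"] += 1
            continue
        stage_ok = case.pred_stage == case.ref_stage
        if stage_ok:
            kind, cause = "correct", "n/a"
        else:
            t_ok = coarsen(case.pred_pT, "pT") == coarsen(case.ref_pT, "pT")
            n_ok = case.pred_pN == case.ref_pN
            cause = "error_propagation" if not (t_ok and n_ok) else "incorrect_rule"
            kind = "misclassified"
        if kind == "correct":
            counts["correct"] += 1
        else:
            counts[cause] += 1
        rows.append(
            {
                "report_id": getattr(case, "report_id", ""),
                "attribute": "stage",
                "kind": kind,
                "stage_error_cause": cause,
            }
        )
    return counts, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reproducibility

def compare_runs(records_a: list, records_b: list, attributes: tuple | None = None) -> dict:
    """Equivalence rate and certainty MAE between two runs on the same reports."""
    a = {rec.report_id: rec for rec in records_a}
    b = {rec.report_id: rec for rec in records_b}
    if set(a) != set(b):
        raise EvaluationError("the two runs cover different report ids")
    if not a:
        raise EvaluationError("no records to compare")
    task = next(iter(a.values())).task
    if attributes is None:
        attributes = scored_attributes(task)
    equal = total = 0
    abs_errors = []
    for rid in a:
        for attr in attributes:
            ea, eb = a[rid].estimate(attr), b[rid].estimate(attr)
            total += 1
            if ea == eb:
                equal += 1
            ca, cb = a[rid].certainty(attr), b[rid].certainty(attr)
            if ca is not None and cb is not None:
                abs_errors.append(abs(ca - cb))
    return {
        "equivalence_rate": equal / total,
        "certainty_mae": float(np.mean(abs_errors)) if abs_errors else 0.0,
        "n_pairs": total,
    }


# ---------------------------------------------------------------------------
# Irregularity audit

def _fabrication_signature(rec: ExtractionRecord, attributes: tuple) -> tuple | None:
    estimates = tuple((a, str(rec.estimate(a))) for a in attributes)
    if all(v == UNKNOWN for _, v in estimates):
        return None
    return estimates


def audit_irregular(records: list, manifest: pd.DataFrame,
                    attributes: tuple | None = None) -> dict:
    """Audit responses to irregular inputs for hallucinations and attractors.

    Per irregular validity class: counts of all-Unknown responses (expected),
    fabricated responses (any non-Unknown estimate -> flagged hallucination),
    and parse failures; identical fabricated records across cases flag an
    attractor.
    """
    by_id = {rec.report_id: rec for rec in records}
    task = next(iter(by_id.values())).task if by_id else "lung"
    if attributes is None:
        attributes = scored_attributes(task)
    report: dict = {}
    irregular = manifest[manifest["validity"] != "valid"]
    for validity, group in irregular.groupby("validity"):
        expected = hallucinated = parse_failed = 0
        signatures: list[tuple] = []
        for rid in group["report_id"]:
            rec = by_id.get(rid)
            if rec is None:
                continue
            sig = _fabrication_signature(rec, attributes)
            if sig is not None:
                hallucinated += 1
                signatures.append(sig)
            elif rec.parse_failed:
                parse_failed += 1
            else:
                expected += 1
        attractor = False
        if signatures:
            _, top_count = max(
                ((s, signatures.count(s)) for s in set(signatures)), key=lambda x: x[1]
            )
            attractor = top_count >= 2
        report[str(validity)] = {
            "n": int(len(group)),
            "expected": expected,
            "hallucinated": hallucinated,
            "parse_failed": parse_failed,
            "attractor": attractor,
        }
    return report


# ---------------------------------------------------------------------------
# Full report

@dataclass
class EvaluationReport:
    """Per-attribute metrics table with coverage, taxonomy and audit blocks."""

    task: str
    granularity: str
    per_attribute: dict = field(default_factory=dict)
    average: dict = field(default_factory=dict)
    taxonomy: dict | None = None
    irregular: dict | None = None
    notes: list = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Table-1-style metric table, rounded to 2 decimals."""
        rows = []
        for attr, block in self.per_attribute.items():
            row = {"attribute": attr}
            row.update({m: round(block["metrics"][m], 2) for m in METRIC_NAMES})
            row["coverage"] = block["coverage"]["coverage_rounded"]
            rows.append(row)
        if self.average:
            avg = {"attribute": "Average"}
            avg.update({m: round(self.average[m], 2) for m in METRIC_NAMES})
            avg["coverage"] = round(self.average["coverage"], 2)
            rows.append(avg)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {
            "task": self.task,
            "granularity": self.granularity,
            "per_attribute": {
                attr: {
                    "metrics": block["metrics"],
                    "coverage": block["coverage"],
                    "confusion": {
                        "labels": list(block["confusion"].index),
                        "counts": block["confusion"].to_numpy().tolist(),
                    },
                }
                for attr, block in self.per_attribute.items()
            },
            "average": self.average,
            "taxonomy": self.taxonomy,
            "irregular": self.irregular,
            "notes": self.notes,
        }
        return out

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "evaluation.json").write_text(json.dumps(self.to_dict(), indent=2))
        self.table().to_csv(outdir / "metrics.csv", index=False)
        for attr, block in self.per_attribute.items():
            block["confusion"].to_csv(outdir / f"confusion_{attr}.csv")

    def summary(self) -> str:
        lines = [f"Evaluation ({self.task}, granularity={self.granularity})",
                 self.table().to_string(index=False)]
        if self.taxonomy:
            lines.append(f"Stage-error taxonomy: {self.taxonomy}")
        if self.irregular:
            lines.append(f"Irregularity audit: {self.irregular}")
        return "\n".join(lines)


def evaluate_records(records: list, cohort, granularity: str = "fine") -> EvaluationReport:
    """Score a records list against a cohort's manifest references."""
    manifest = cohort.manifest
    task = cohort.config.task
    attributes = scored_attributes(task)
    valid = manifest[manifest["validity"] == "valid"]
    valid_ids = set(valid["report_id"])
    n_valid_total = len(valid_ids)

    missing = valid_ids - {rec.report_id for rec in records}
    if missing:
        raise EvaluationError(f"records missing for valid reports: {sorted(missing)[:5]} ...")

    report = EvaluationReport(task=task, granularity=granularity)
    running = {m: [] for m in METRIC_NAMES}
    coverages = []
    frames = {}
    for attr in attributes:
        preds_all = records_to_labels([r for r in records if r.report_id in valid_ids], attr)
        refs = {
            str(row.report_id): normalize_label(str(getattr(row, attr)), attr)
            for row in valid.itertuples()
        }
        if granularity == "t_level":
            preds_all = {k: coarsen(v, attr) for k, v in preds_all.items()}
            refs = {k: coarsen(v, attr) for k, v in refs.items()}
        pairs, coverage = filter_evaluable(preds_all, refs, n_valid_total=n_valid_total)
        frames[attr] = (preds_all, refs)
        if not pairs:
            report.notes.append(f"{attr}: no evaluable pairs")
            continue
        matrix = confusion(pairs, granularity="fine", attribute=attr)
        mets = metrics(matrix)
        report.per_attribute[attr] = {
            "metrics": mets, "coverage": coverage, "confusion": matrix,
        }
        for m in METRIC_NAMES:
            running[m].append(mets[m])
        coverages.append(coverage["coverage"])

    if coverages:
        report.average = {m: float(np.mean(running[m])) for m in METRIC_NAMES}
        report.average["coverage"] = float(np.mean(coverages))

    if task == "lung" and all(a in frames for a in ("pT", "pN", "stage")):
        by_id = {rec.report_id: rec for rec in records if rec.report_id in valid_ids}
        rows = []
        for row in valid.itertuples():
            rid = str(row.report_id)
            rec = by_id[rid]
            rows.append(
                {
                    "report_id": rid,
                    "ref_pT": normalize_label(str(row.pT), "pT"),
                    "ref_pN": normalize_label(str(row.pN), "pN"),
                    "ref_stage": normalize_label(str(row.stage), "stage"),
                    "pred_pT": normalize_label(str(rec.estimate("pT")), "pT"),
                    "pred_pN": normalize_label(str(rec.estimate("pN")), "pN"),
                    "pred_stage": normalize_label(str(rec.estimate("stage")), "stage"),
                }
            )
        counts, _ = classify_stage_errors(pd.DataFrame(rows))
        report.taxonomy = counts

    if (manifest["validity"] != "valid").any():
        report.irregular = audit_irregular(records, manifest)
    return report
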