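"""Scoring protocol: filtering, coverage, confusion, metrics, taxonomy,
reproducibility, and the irregular-input audit."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    f1_score,
    precision_score,
    recall_score,
)

from oncoextract import (
    ErrorProfile,
    MockLLMBackend,
    build_prompt,
    classify_stage_errors,
    compare_runs,
    confusion,
    filter_evaluable,
    metrics,
    parse_response,
    audit_irregular,
)
from oncoextract.corpus import MISSING_FORM_TEXT
from oncoextract.evaluate import EvaluationError
from oncoextract.records import AttributeEstimate, ExtractionRecord
from oncoextract.vocab import UNKNOWN


def _coverage_setup(n_valid, n_ref, n_unknown_pred):
    """Dicts reproducing a coverage scenario from printed counts."""
    refs = {f"R{i}": "A" for i in range(n_ref)}
    preds = {f"R{i}": (UNKNOWN if i < n_unknown_pred else "A") for i in range(n_valid)}
    return preds, refs


class TestFilterAndCoverage:
    @pytest.mark.parametrize(
        "n_ref,n_unknown,expected",
        [
            (768, 15, 0.97),   # primary tumor attribute
            (753, 27, 0.94),   # nodal attribute
            (744, 18, 0.94),   # overall stage
            (762, 17, 0.96),   # histology
        ],
    )
    def test_printed_coverage_values_from_counts(self, n_ref, n_unknown, expected):
        preds, refs = _coverage_setup(774, n_ref, n_unknown)
        _, stats = filter_evaluable(preds, refs, n_valid_total=774)
        assert stats["coverage_rounded"] == expected
        assert stats["n_classified"] == n_ref - n_unknown

    def test_all_unknown_predictions(self):
        preds, refs = _coverage_setup(10, 8, 8)
        pairs, stats = filter_evaluable(preds, refs)
        assert pairs == [] and stats["coverage"] == 0.0

    def test_unknown_references_do_not_count(self):
        preds = {"a": "A", "b": "A"}
        refs = {"a": "A", "b": UNKNOWN}
        pairs, stats = filter_evaluable(preds, refs)
        assert stats["n_with_reference"] == 1 and len(pairs) == 1

    def test_conservation_identity(self):
        preds, refs = _coverage_setup(774, 753, 27)
        _, s = filter_evaluable(preds, refs, n_valid_total=774)
        n_missing_ref = 774 - s["n_with_reference"]
        assert s["n_classified"] + s["n_unknown_predictions"] + n_missing_ref == 774


class TestConfusion:
    def test_perfect_pairs_are_diagonal(self):
        pairs = [("T1a", "T1a")] * 3 + [("T2a", "T2a")] * 2
        m = confusion(pairs, attribute="pT")
        assert m.values.trace() == 5 and m.values.sum() == 5

    def test_misclassified_cell_percentages(self):
        # 67 T1->T2 and 12 T3->T2 among 753 classified cases
        pairs = (
            [("T1", "T2")] * 67 + [("T3", "T2")] * 12 + [("T1", "T1")] * 400
            + [("T2", "T2")] * 200 + [("T3", "T3")] * 74
        )
        m = confusion(pairs, attribute="pT")
        n = m.values.sum()
        assert n == 753
        assert round(100 * m.loc["T1", "T2"] / n, 1) == 8.9
        assert round(100 * m.loc["T3", "T2"] / n, 1) == 1.6

    def test_t_level_granularity_merges_subcategories(self):
        pairs = [("T1a", "T1b"), ("T1b", "T1a"), ("T2a", "T2b")]
        m = confusion(pairs, granularity="t_level", attribute="pT")
        assert list(m.index) == ["T1", "T2"]
        assert m.loc["T1", "T1"] == 2 and m.loc["T2", "T2"] == 1

    def test_rows_are_reference_columns_prediction(self):
        m = confusion([("A", "B")])
        assert m.loc["A", "B"] == 1 and m.loc["B", "A"] == 0

    def test_empty_pairs_rejected(self):
        with pytest.raises(EvaluationError):
            confusion([])


def _random_matrix(rng, k=4, n=200):
    labels = [f"C{i}" for i in range(k)]
    counts = rng.multinomial(n, rng.dirichlet(np.ones(k * k))).reshape(k, k)
    return pd.DataFrame(counts, index=labels, columns=labels)


class TestMetrics:
    def test_identity_matrix_scores_one(self):
        m = pd.DataFrame(np.eye(3, dtype=int) * 5, index=list("abc"), columns=list("abc"))
        result = metrics(m)
        assert all(result[k] == 1.0 for k in ("accuracy", "f1", "kappa", "recall", "precision"))

    def test_constant_predictor_on_balanced_classes(self):
        # references split 50/50, predictions always class "a"
        m = pd.DataFrame([[50, 0], [50, 0]], index=list("ab"), columns=list("ab"))
        result = metrics(m)
        assert result["accuracy"] == pytest.approx(0.5)
        assert result["kappa"] == pytest.approx(0.0)

    def test_weighted_recall_equals_accuracy_and_micro_f1_equals_accuracy(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            m = _random_matrix(rng)
            if m.values.sum() == 0:
                continue
            result = metrics(m)
            assert result["recall"] == pytest.approx(result["accuracy"], abs=1e-12)
            micro = metrics(m, average="micro")
            assert micro["f1"] == pytest.approx(result["accuracy"], abs=1e-12)

    def test_kappa_bounded_by_accuracy(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = _random_matrix(rng)
            result = metrics(m)
            assert result["kappa"] <= result["accuracy"] + 1e-12

    def test_agreement_with_sklearn_on_label_vectors(self):
        rng = np.random.default_rng(3)
        labels = np.array(["w", "x", "y", "z"])
        ref = labels[rng.integers(0, 4, 300)]
        pred = labels[rng.integers(0, 4, 300)]
        m = confusion(list(zip(ref, pred)))
        result = metrics(m)
        assert result["accuracy"] == pytest.approx(accuracy_score(ref, pred))
        assert result["f1"] == pytest.approx(f1_score(ref, pred, average="weighted"))
        assert result["recall"] == pytest.approx(recall_score(ref, pred, average="weighted"))
        assert result["precision"] == pytest.approx(
            precision_score(ref, pred, average="weighted", zero_division=0)
        )
        assert result["kappa"] == pytest.approx(cohen_kappa_score(ref, pred))

    def test_empty_matrix_rejected(self):
        with pytest.raises(EvaluationError):
            metrics(pd.DataFrame([[0]], index=["a"], columns=["a"]))


class TestStageErrorTaxonomy:
    def _frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["report_id", "ref_pT", "ref_pN", "ref_stage",
                     "pred_pT", "pred_pN", "pred_stage"],
        )

    def test_propagated_error(self):
        cases = self._frame([["c1", "T2a", "N0", "IIA", "T3", "N0", "IIIA"]])
        counts, detail = classify_stage_errors(cases)
        assert counts["error_propagation"] == 1 and counts["incorrect_rule"] == 0
        assert detail.iloc[0]["stage_error_cause"] == "error_propagation"

    def test_incorrect_rule_error(self):
        cases = self._frame([["c2", "T2b", "N1", "IIB", "T2b", "N1", "IIIA"]])
        counts, _ = classify_stage_errors(cases)
        assert counts["incorrect_rule"] == 1 and counts["error_propagation"] == 0

    def test_correct_case_and_unknown_skipped(self):
        cases = self._frame(
            [
                ["c3", "T1a", "N0", "IA", "T1a", "N0", "IA"],
                ["c4", "T1a", "N0", "IA", UNKNOWN, "N0", "IA"],
            ]
        )
        counts, _ = classify_stage_errors(cases)
        assert counts["correct"] == 1 and counts["skipped"] == 1

    def test_subcategory_shift_within_level_is_not_propagation(self):
        # pT differs only within the T2 level, so a stage error counts as rule
        cases = self._frame([["c5", "T2a", "N0", "IB", "T2b", "N0", "IIIA"]])
        counts, _ = classify_stage_errors(cases)
        assert counts["incorrect_rule"] == 1


def _record(rid, estimates, task="lung", parse_failed=False):
    rec = ExtractionRecord(report_id=rid, task=task, parse_failed=parse_failed)
    for name, (est, cert) in estimates.items():
        rec.attributes[name] = AttributeEstimate(
            stated=str(est), estimated=est, certainty=cert,
            evidence="e" if est != UNKNOWN else "",
        )
    return rec


class TestCompareRuns:
    def _records(self, estimates_list):
        return [
            _record(f"r{i}", est) for i, est in enumerate(estimates_list)
        ]

    def test_self_comparison_is_perfect(self):
        recs = self._records(
            [{"pT": ("T1a", 1.0), "pN": ("N0", 1.0), "stage": ("IA", 1.0),
              "histology": ("Other", 1.0)}] * 3
        )
        result = compare_runs(recs, recs)
        assert result["equivalence_rate"] == 1.0 and result["certainty_mae"] == 0.0

    def test_two_differing_estimates_out_of_eight(self):
        base = {"pT": ("T1a", 1.0), "pN": ("N0", 1.0), "stage": ("IA", 1.0),
                "histology": ("Other", 1.0)}
        a = self._records([base, base])
        changed = dict(base, pT=("T2a", 1.0), stage=("IB", 1.0))
        b = self._records([base, changed])
        assert compare_runs(a, b)["equivalence_rate"] == pytest.approx(0.75)

    def test_certainty_mae_single_pair(self):
        a = self._records([{"pT": ("T1a", 1.0), "pN": ("N0", 1.0), "stage": ("IA", 1.0),
                            "histology": ("Other", 1.0)}])
        b = self._records([{"pT": ("T1a", 0.9), "pN": ("N0", 1.0), "stage": ("IA", 1.0),
                            "histology": ("Other", 1.0)}])
        assert compare_runs(a, b)["certainty_mae"] == pytest.approx(0.1 / 4)

    def test_nonzero_temperature_runs_diverge_across_seeds(self, clean_cohort):
        """Two stochastic runs over the same cohort: estimates mostly agree
        but not perfectly, and certainties differ slightly — the paper-style
        run-to-run comparison on synthetic data."""
        from oncoextract import ErrorProfile, MockLLMBackend
        from oncoextract.batch import run_batch

        profile = ErrorProfile(certainty_noise=0.05)
        runs = [
            run_batch(clean_cohort, MockLLMBackend(profile), temperature=0.7, seed=s).records
            for s in (1, 2)
        ]
        result = compare_runs(*runs)
        assert 0.5 < result["equivalence_rate"] < 1.0
        assert 0.0 < result["certainty_mae"] < 0.3

    def test_id_mismatch_rejected(self):
        a = self._records([{"pT": ("T1a", 1.0)}])
        b = [_record("other", {"pT": ("T1a", 1.0)})]
        with pytest.raises(EvaluationError):
            compare_runs(a, b)


class TestAuditIrregular:
    def _manifest(self, n, validity="missing_form"):
        return pd.DataFrame(
            {"report_id": [f"m{i}" for i in range(n)], "validity": [validity] * n}
        )

    def test_five_ten_split_with_attractor(self):
        backend_plain = MockLLMBackend()
        backend_halluc = MockLLMBackend(ErrorProfile(hallucinate_on_blank=True))
        prompt = build_prompt(MISSING_FORM_TEXT, "v4")
        records = []
        for i in range(15):
            backend = backend_halluc if i < 10 else backend_plain
            records.append(parse_response(backend.complete(prompt), report_id=f"m{i}"))
        report = audit_irregular(records, self._manifest(15))
        block = report["missing_form"]
        assert block["expected"] == 5
        assert block["hallucinated"] == 10
        assert block["attractor"] is True

    def test_zero_irregular_cases(self):
        manifest = pd.DataFrame({"report_id": ["v1"], "validity": ["valid"]})
        rec = _record("v1", {"pT": ("T1a", 1.0)})
        assert audit_irregular([rec], manifest) == {}

    def test_blank_answered_unknown_counts_expected(self):
        rec = _record("m0", {a: (UNKNOWN, 0.0) for a in ("pT", "pN", "stage", "histology")})
        report = audit_irregular([rec], self._manifest(1, "blank"))
        assert report["blank"]["expected"] == 1 and report["blank"]["attractor"] is False
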