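"""Closed-form oracles for the mock backend's error structure.

Given a case's true facts and an error profile, enumerate every combination
of the four independent error events (size rule, node-count rule, terminology
confusion, false stage rule) with its probability and derive exactly which
attribute outcomes each combination produces.  This yields the profile-implied
expected accuracy and stage-error-taxonomy mix against which a sampled run
can be tested, independent of the backend's own sampling path.
"""

from itertools import product

from oncoextract import stage_case, stage_group
from oncoextract.backends import false_stage_rule_applies
from oncoextract.vocab import UNKNOWN, coarsen_t


def case_outcome_probabilities(facts, profile):
    """Per-case probabilities of correctness and stage-error causes.

    Returns a dict with P(pT correct), P(pN correct), P(stage correct),
    P(stage wrong & propagation), P(stage wrong & incorrect rule) — all
    conditional on the attribute being answered (the spurious-Unknown mode is
    independent of the error modes, so it cancels from accuracy).
    """
    tnm = stage_case(facts)
    p_events = {
        "size": profile.p_size_rule_error,
        "count": profile.p_node_count_rule,
        "term": profile.p_terminology_confusion,
        "rule": profile.p_stage_rule_error,
    }
    out = {"pT": 0.0, "pN": 0.0, "stage": 0.0, "propagation": 0.0, "incorrect_rule": 0.0}
    for size, count, term, rule in product((False, True), repeat=4):
        prob = 1.0
        for fired, name in ((size, "size"), (count, "count"), (term, "term"), (rule, "rule")):
            prob *= p_events[name] if fired else 1.0 - p_events[name]
        if prob == 0.0:
            continue

        pt = "T2" if size and coarsen_t(tnm.pT) in ("T1", "T3") else tnm.pT
        pn = "N2" if (count or term) and tnm.pN == "N1" else tnm.pN
        stage, _ = stage_group(pt, pn, tnm.pM)
        if rule and false_stage_rule_applies(pt, pn):
            stage = "IIIA"

        pt_ok = pt == tnm.pT
        pn_ok = pn == tnm.pN
        stage_ok = stage == tnm.stage
        out["pT"] += prob * pt_ok
        out["pN"] += prob * pn_ok
        if tnm.stage != UNKNOWN:
            out["stage"] += prob * stage_ok
            if not stage_ok:
                # taxonomy pools T to its level when deciding "also wrong"
                prop = coarsen_t(pt) != coarsen_t(tnm.pT) or not pn_ok
                out["propagation" if prop else "incorrect_rule"] += prob
    return out
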