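# Methods

## Problem setting

The package studies structured information extraction from free-text lung
pathology reports: given narrative text, recover pathologic T and N
categories, the overall AJCC 7th-edition stage group, the histologic class
(adenocarcinoma / squamous cell carcinoma / other / unknown), and the
tumor's greatest dimension; a second task profile extracts histologic grade
and resection-margin status from osteosarcoma reports. Because real report
archives are protected and LLM APIs are paid and non-deterministic, the
package closes the loop synthetically: a generator produces reports whose
ground truth is *defined* by the package's own staging engine, and a
deterministic mock extractor reproduces the dominant error classes observed
when LLMs do this task, so the evaluation machinery can be exercised and
validated end-to-end.

## Staging engine

The engine is a declarative rule system (shipped as a versioned JSON table,
one citation string per rule) with three layers:

1. **pT** — size ladder on the largest nodule with boundaries closed above
   (≤ 2 cm → T1a; ≤ 3 → T1b; ≤ 5 → T2a; ≤ 7 → T2b; > 7 → T3). Invasion
   descriptors impose minimum levels (visceral pleura or main bronchus → ≥
   T2a; chest wall, diaphragm, whole-lung atelectasis, same-lobe satellite →
   ≥ T3; mediastinum, heart/great vessels, carina → T4); separate nodules in
   different ipsilateral lobes → T4. When ladder and descriptors disagree the
   maximum T level wins and the rationale records both fired rules. No
   nodules → T0; a documented tumor with no measurable size or descriptors →
   TX.
2. **pN** — the N level is the maximum *station* level among stations with at
   least one positive node (hilar / peribronchial / intrapulmonary → N1;
   ipsilateral mediastinal / subcarinal → N2; contralateral, scalene,
   supraclavicular → N3). Positive/examined counts never influence the
   level. No nodes examined → NX.
3. **Stage group** — table lookup over (T, N, M); M1 forces stage IV. pM is
   "M0-assumed" when no metastasis evidence exists and "MX" when it cannot
   be assessed; both group like M0, since only explicit metastasis evidence
   should change the stage. TX/NX/T0/Tis/Unknown inputs group to Unknown —
   the closed stage vocabulary (IA…IV) has no occult/in-situ entries. Coarse
   T1/T2 inputs, which only arise from model predictions, use their
   subcategory-a row; every same-level row agrees except (T2b, N·), a
   documented approximation.

Boundary note: a 2.0 cm tumor is T1a under the closed-above convention; the
next rung covers tumors *more than* 2 cm. Tests pin this convention
explicitly because clinical prose sometimes describes 2.0 cm cases with the
">2 but <3" wording.

## Synthetic corpus

Defaults sketch a resected, predominantly non-metastatic cohort: lognormal
tumor sizes (median ≈ 3.2 cm, σ = 0.5, clipped to 0.4–14 cm, rounded to
0.1 cm), nodal mix N0 0.64 / N1 0.20 / N2 0.14 / N3 0.02, histology mix
adeno 0.50 / squamous 0.42 / other 0.08, 2% explicit metastasis, 5%
multi-nodule cases, small per-descriptor invasion probabilities, and a ~15%
irregular-report rate split 4% blank / 7% poorly scanned / 4% missing form
(matching the order of magnitude of invalid scans in public report
archives). Each case's facts are rendered once, in canonical phrasing, into
one of three template styles (narrative, tabular form, legacy consult) that
vary layout and filler but never the fact sentences; `parse_report` recovers
the facts exactly (the round-trip contract), and the engine's labels on
those facts are the manifest's reference labels, so generator and oracle
cannot disagree by construction.

What the generator does **not** emulate: real OCR geometry (noise is an
i.i.d. character-confusion model over letters, digits and punctuation),
free-text stylistic diversity beyond the three templates, contralateral
second primaries, and genuinely ambiguous wording. Passing tests therefore
demonstrate the correctness of the pipeline's logic under controlled
conditions, not clinical-grade NLP performance on real reports. Valid
reports are rendered typo-free by default (`typo_rate = 0`): real archives
contain typos at an unknown rate, and the round-trip and zero-error
invariants are defined on clean renderings; word-level typos remain a
first-class corruption mode for robustness experiments.

## Prompts and backends

The prompt ladder adds exactly one feature per version: v1 constrains output
to the closed multiple-choice vocabularies and a single JSON object; v2 adds
the answer-Unknown-without-evidence instruction and the trailing `comment`
key; v3 adds the tumor-size subquestion (chain-of-thought through an
intermediate quantity); v4 adds a worked stage-grouping example
(T2a + N0 → "Stage IB"). A blank report produces an instruction-only prompt.
Token counts are estimated by a pluggable heuristic (⌈chars/4⌉ by default)
and gate prompts against a configurable context window.

The mock backend reads the report from the prompt with the corpus parser,
stages it with the engine, and then distorts the truth through independent
error modes calibrated on the characteristic LLM failure classes: the
size-rule error answers coarse "T2" for T1/T3 truths (the wrong-rule
signature: correct extraction, wrong mapping); the node-count rule and
terminology confusion each inflate N1 to N2; the false stage rule groups
(T3, N0) and (T2b, N1) as Stage IIIA; a spurious-Unknown mode drives
coverage below 1; and on instruction-only prompts a hallucination flag emits
one fixed fabricated record — the "attractor" — byte-identical across calls
at temperature 0. Stage output is otherwise recomputed from the (possibly
distorted) components, which is what makes the propagation / incorrect-rule
taxonomy recoverable. Error draws are keyed on the report content and the
run seed, not on the instruction text, so the same case sees the same draws
under every prompt version; with `feature_relief > 0` a prompt feature
scales down its targeted error mode (size subquestion ↔ size rule, evidence
instruction ↔ terminology, stage example ↔ false stage rule; the node-count
rule is never relieved), giving case-wise monotone accuracy across the
ladder at full relief. At the default `feature_relief = 0` the profile's
probabilities apply as stated regardless of version.

The keyword baseline compiles a dictionary from canonical fact lines of the
training split labeled with engine references, tokenizes with a greedy
longest-match subword scheme induced from those spans, scores candidate
spans by character-trigram Jaccard (threshold 0.5), takes the most severe
matched label per attribute, and fills a missing stage by AJCC7 grouping of
the extracted components. Because the synthetic reports never state pT/pN
explicitly, the baseline is strong on histology (verbatim spans) and weak on
staging — the expected failure mode of span matching on narrative text.

## Evaluation conventions

* Uncertain values ("Not Available", "Not Specified", "Cannot be
  determined", "Unknown", empty strings) normalize to Unknown; pairs are
  scored only when both reference and prediction are certain.
* Coverage = (reference-bearing cases with a non-Unknown prediction) /
  (total valid reports). The denominator is deliberately the full valid
  count, not the reference-bearing subset — the only convention consistent
  with standard registry-style reporting of per-attribute coverage.
* F1/recall/precision are support-weighted one-vs-rest averages (micro and
  macro variants are exposed); weighted recall equals accuracy identically,
  and micro-F1 equals accuracy — both serve as internal consistency checks.
  Cohen's kappa is unweighted, computed from the matrix marginals.
* Reported tables round to 2 decimals; the average row is computed from
  unrounded per-attribute values.
* Stage-error taxonomy pools T to its level when deciding whether a
  component was "also misclassified"; a stage error with correct components
  is an incorrect-rule error.
* The irregularity audit counts all-Unknown responses as expected behavior,
  any non-Unknown estimate on an irregular input as a hallucination, and
  flags an attractor when at least two fabricated records are identical.

## Numerical and design choices

* Sizes are sampled and rendered at 0.1 cm resolution, so float round-trips
  are exact; probe grids use the same resolution.
* Determinism: every stochastic component takes a seed; cohort generation,
  mock completions and batch files are byte-reproducible for a fixed seed.
  Derived per-case seeds stay below 2^31.
* Degenerate inputs are first-class: empty facts stage as (T0, NX, Unknown);
  unparseable responses yield flagged all-Unknown records; empty cohorts and
  zero-report runs are valid.
* Problem sizes in the test suite (cohorts of 150–2000 reports, 1000-case
  round-trip, 100-matrix identity checks) were chosen to give 3-standard-
  error resolution on the recovered parameters while keeping the suite quick
  on a single CPU.

## Known limitations

* The engine covers AJCC 7th-edition lung rules only; no 8th-edition rules,
  no non-pulmonary TNM schemes, no pM substaging.
* Contralateral separate nodules (M1a territory) are not modeled; the
  generator keeps multi-nodule disease ipsilateral.
* The certainty degree emitted by backends is a score in [0, 1] with
  configurable noise, not a calibrated probability; calibration analysis is
  out of scope.
* The live-API adapter is a thin contract implementation, deliberately
  excluded from the automated suite.
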