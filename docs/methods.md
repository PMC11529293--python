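# Methods

This note documents the measurement model behind `phenoeval`: what each
metric assumes, which parameters matter, what the synthetic benchmark does
and does not emulate, and where the design was genuinely open.

## The definition model

A phenotype definition is treated as a flat, ordered list of concept rows
`(logic, vocabulary, code, name, count)`. This deliberately ignores the
richer cohort semantics real phenotype algorithms can carry (temporal
windows, value thresholds, nested boolean logic, OMOP cohort expressions):
curated definitions from phenotype libraries reduce to such code lists after
curation, and it is the shape a language model can be asked to emit in a
single table. The `count` column ("1" / "1+") is parsed, validated, and
reported, but participates in no comparison metric — no meaningful overlap
semantics exists for it, so it is carried as metadata only.

Code identity is the pair (canonical vocabulary, normalized code).
Normalization uppercases, trims, and — for the ICD family — strips the
period, so `Z91.010` and `Z91010` compare equal. Dotted and undotted ICD
renderings coexist across sources, and treating them as different codes
would systematically understate overlap for a purely typographic reason.
Vocabulary tokens resolve through a user-extensible alias table
(`ICD10` ≡ `ICD-10`, `SNOMED CT` ≡ `SNOMED`, case-insensitive); unknown
tokens are preserved verbatim and flagged as unrecognized rather than
rejected, because a model claiming a nonexistent vocabulary is itself a
finding. Duplicate rows are collapsed by code identity for every metric
(first occurrence kept), so repetition can neither inflate nor deflate a
score.

## Metrics

**Codes overlap** is 100 · |candidate ∩ reference| / |candidate| over
distinct code identities. The candidate's code count is the denominator for
all row-level metrics — the scores read as the *precision* of what the model
emitted, are comparable across metrics, and stay well-defined when the
model returns fewer codes than the reference. An empty candidate scores 0
with an `empty-candidate` diagnostic rather than NaN, keeping collection
aggregation total.

**Logic overlap** is defined in two tiers. Where codes match, each matched
pair either agrees or disagrees on inclusion/exclusion and the score is the
agreement fraction. Where *no* codes match, logical competence is still
measurable at the distribution level: the score falls back to
100 · (1 − TV), the complement of the total-variation distance between the
candidate's and the reference's label proportions. The fallback (on by
default, switchable in `EvalConfig`) exists because logic agreement is
observable in practice even for definitions with disjoint code sets; with
two labels, TV reduces to the absolute difference of the inclusion shares.

**Name similarity** is token-set Jaccard over case-folded,
punctuation-stripped word tokens. It is transparent, symmetric, and exactly
1 when the token sets coincide — so `"Angina, class I"` equals
`"angina class i"` — which matters because the hallucination verdicts
depend on an interpretable notion of "same name". Two names that both
tokenize to nothing are defined as similarity 0 (they carry no evidence of
agreement). **Strings overlap** assigns candidate names to reference names
greedily in descending similarity order, one-to-one, ties broken by
(candidate index, reference index); a candidate row overlaps when its
assigned similarity reaches the threshold (default 0.5, i.e., at least half
the union of tokens shared). The greedy assignment is deterministic, and
because the assignment itself is threshold-independent, the metric is
non-increasing in the threshold. Implementation note: similarity-1.0 pairs
are exactly the equal-token-set pairs, and token-set equality is transitive,
so they are assigned by hashing before the quadratic sweep over leftovers;
this is an exact optimization, not an approximation.

**Hallucination validation** checks each row in a fixed order — vocabulary
recognized and covered by a dictionary; normalized code matches the
vocabulary's shape pattern; code present in the dictionary; claimed name
within the name threshold (default 0.7) of the canonical name — and the
first failure decides the verdict. A real code with a wrong name
(`Z91.010` claimed as "Allergy to nuts" where the terminology says "Allergy
to peanuts", Jaccard 0.5) counts as a hallucination: the code-name pair, not
the bare code, is what a downstream cohort builder would act on. The shipped
shape patterns (SNOMED 6–18 digits; ICD-10 letter + two digits + up to four
more alphanumerics; ICD-10-CM letter + digit + up to five more) are
editable configuration, deliberately permissive: a code like `Z91010` is
shape-valid under ICD-10 and reports `unknown-code` there rather than
`malformed-code`, since vocabulary mislabeling between ICD-10 and ICD-10-CM
is common in model output and the two verdicts carry different information.
Validation consults only the vocabulary the row claims; rescuing a code via
another vocabulary is mapping's job, not validation's.

**Mapped codes overlap** recomputes the code metric after closing each code
over its single-hop crossmap image, counting a candidate code as matched
when its identity-or-image set intersects any reference code's
identity-or-image set. Single-hop (no transitive closure) keeps the
semantics auditable; any-match tolerates one-to-many mappings. Both choices
make the metric dominate plain codes overlap on every input, with exact
equality under an empty crossmap — the invariant the test suite enforces.

## The synthetic benchmark

`synthdata` generates dictionary-valid references (rows drawn without
replacement from synthetic per-vocabulary dictionaries, so codes exist with
their exact canonical names) and corrupts them with five per-row operators
mirroring observed LLM failure modes: **drop** (missing codes), **fabricate**
(invented codes), **rename** (wrong concept names), **flip-logic**
(inclusion/exclusion confusion), **re-vocabulary** (right code, wrong coding
system). Default reference structure: 70% SNOMED / 20% ICD-10-CM / 10%
ICD-10, 85% inclusion rows, half the rows requiring "1+" — one vocabulary
dominant and inclusion-heavy, as curated definitions typically are. Default
corruption rates (drop 0.10, fabricate 0.15, rename 0.15, flip 0.05,
re-vocabulary 0.05) describe a mid-quality extraction: clearly imperfect on
every axis without being dominated by any single failure mode.

Operators fire per row in a fixed order and are mutually exclusive except
rename + flip-logic, which may co-occur (a dropped row receives nothing
further; a fabricated row keeps its name and logic). This exclusivity is
what makes the ledger *exact* rather than asymptotic: fabricated codes are
drawn until absent from every dictionary and from the candidate so far;
re-vocabularied rows get a target vocabulary under which the code is
verifiably absent from both the target dictionary and the reference code
set; renames replace at least half the name tokens with synthetic gibberish
and record the resulting similarity. Consequently
`expected_metrics(ledger)` — intact-code share for codes overlap, unflipped
share of intact rows for logic, the same greedy assignment over
ledger-recorded names for strings, and fabricated + re-vocabularied +
below-threshold-renamed share for hallucination — reproduces the measured
metrics to machine precision, which the suite asserts operator by operator.
Randomness is NumPy's `default_rng` (PCG64), pinned by name so seeded
fixtures are portable.

What the generator does *not* emulate: prose-embedded multi-table responses
with inconsistent dialects (hand-written parser fixtures cover those),
near-miss fabricated codes adjacent to real ones, semantically plausible
renames (gibberish renames are unambiguous by design, so rename recovery is
exercised at the similarity extremes), and any correlation between row
quality and phenotype documentation depth. Passing the synthetic suite
therefore demonstrates that the *measurement machinery* is correct, not
that any particular model is good; scores on real model output depend on
dictionaries and crossmaps the user supplies.

## Numerical and procedural choices

- Percentages are computed in double precision and rendered to two decimals
  only at report boundaries; aggregates satisfy min ≤ average ≤ max by
  construction, with the average over phenotypes (not pooled over rows).
- The tolerant parser accepts markdown-pipe, delimited, and aligned-
  whitespace tables, preferring them in that order; the first table region
  wins and further regions are counted in diagnostics. Unparseable rows are
  skipped and recorded, never fatal; completely table-free text yields an
  empty candidate with a `no-table` diagnostic. The parser is total over
  arbitrary text.
- Reference files are read strictly (schema errors name the missing column;
  row errors carry the row index) because errors in curated input should
  fail loudly, not silently degrade a benchmark.
- Reports carry no timestamp, so identical inputs and configuration yield
  byte-identical JSON.
- The elicitation prompt is a fixed template with the phenotype name
  substituted verbatim; response acquisition is abstracted behind a
  text-in/text-out provider contract with a declared failure channel, and a
  provider failure in a batch is recorded and excluded from aggregation
  rather than raised.
- The acceptance script runs 10 phenotypes of 20 rows — comparable to the
  size of a curated definition collection — which is ample for exercising
  every code path while the ledger cross-check, being exact, needs no large
  sample.

## Known limitations

- Flat code lists only: no temporal logic, measurement thresholds, or nested
  cohort expressions.
- Toy dictionaries and crossmaps ship for testing; real ICD/SNOMED content
  and UMLS/OMOP crosswalks must be user-supplied (their licenses preclude
  bundling).
- The logic-overlap fallback is one defensible choice among several; it is
  configuration-switchable and reported with a diagnostic when used.
- Token-set Jaccard ignores word order and morphology ("renal failure,
  acute" ≡ "acute renal failure", but "nephropathy" ≁ "kidney disease");
  a semantic similarity would need an external ontology or embedding model,
  out of scope here.
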