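# phenoeval

An evaluation harness for **computational phenotype definitions** extracted
from large language models.

Electronic phenotyping selects patient cohorts from EHR data using codified
criteria. A phenotype definition, once curated, reduces to a flat table of
concept rows: inclusion/exclusion **logic**, the code's **vocabulary**
(SNOMED CT, ICD-10, ICD-10-CM, ...), the **concept code**, the **concept
name**, and a **code count** ("1" = required exactly once, "1+" = at least
once). LLMs can be prompted to emit definitions in this shape, but their
output is inconsistent and often contains *hallucinations* — codes that do
not exist in the claimed vocabulary, or real codes paired with wrong names.
`phenoeval` gives informaticians a reproducible way to measure how good such
extracted definitions actually are.

## What it computes

For a candidate definition $C$ scored against a reference $R$ (a curated
definition, or another model's output), with $\tilde{C}$, $\tilde{R}$ the
sets of normalized `(vocabulary, code)` pairs:

- **Codes overlap** $= 100\,|\tilde{C} \cap \tilde{R}| / |\tilde{C}|$ — the
  precision of the emitted codes (candidate count is the denominator).
- **Logic overlap** — among code-matched row pairs, the share with agreeing
  inclusion/exclusion labels; when no codes match, the complement of the
  total-variation distance between the two label distributions.
- **Strings overlap** — the share of candidate rows whose concept name can be
  greedily matched one-to-one to a reference name with token-set Jaccard
  similarity ≥ 0.5.
- **Hallucination rate** — the share of rows whose code fails validation
  against its vocabulary's dictionary (unknown vocabulary, malformed shape,
  absent code, or name dissimilar to the canonical name).
- **Mapped codes overlap** — codes overlap recomputed in a unified code space
  where a crossmap (e.g., an OMOP concept-relationship extract) bridges
  vocabularies; it always dominates the plain codes overlap.

Per-phenotype percentages aggregate into average/minimum/maximum across a
collection. A seeded synthetic generator produces dictionary-valid references
and corrupted candidates with an **exact error ledger**, so every metric can
be verified against planted ground truth without any external data.

## Worked example

```python
import phenoeval as pe

reference = pe.read_definition_table("""\
Logic,Vocabulary,Concept code,Concept name,Code count
Inclusion,SNOMED,194823009,Acute coronary insufficiency,1+
Inclusion,SNOMED,791000119109,Angina associated with type 2 diabetes mellitus,1
Inclusion,SNOMED,61490001,"Angina, class I",1+
Inclusion,SNOMED,41334000,"Angina, class II",1
Inclusion,SNOMED,85284003,"Angina, class III",1+
Inclusion,SNOMED,89323001,"Angina, class IV",1+
""", phenotype_name="angina")

response = """Certainly! Here is a computational phenotype for angina:

| Logic | Code vocabulary | Code identifier | Code name | Code count |
| --- | --- | --- | --- | --- |
| Inclusion | SNOMED | 194823009 | Acute coronary insufficiency | 1+ |
| Inclusion | SNOMED | 61490001 | Angina class I | 1 |
| Exclusion | SNOMED | 41334000 | Angina, class II | 1 |
| Inclusion | SNOMED | 99999999 | Nocturnal angina syndrome | 1+ |
"""
candidate = pe.parse_llm_table(response, phenotype_name="angina").definition

dictionary = pe.load_vocabulary(
    "\n".join(f"{r.code}\t{r.name}" for r in reference), "SNOMED")
report = pe.evaluate_pair(candidate, reference, pe.DictionarySet([dictionary]))
print(f"codes overlap:      {report.codes_overlap_pct:.2f}%")
print(f"logic overlap:      {report.logic_overlap_pct:.2f}%")
print(f"strings overlap:    {report.strings_overlap_pct:.2f}%")
print(f"hallucination rate: {report.hallucination_pct:.2f}%")
```

prints

```
codes overlap:      75.00%
logic overlap:      66.67%
strings overlap:    75.00%
hallucination rate: 25.00%
```

Three of the four candidate codes exist in the reference (75%); of those
three code-matched rows one has flipped logic (66.67% agreement); three names
match at Jaccard ≥ 0.5 — note "Angina class I" ≡ "Angina, class I" after
tokenization — while the invented "Nocturnal angina syndrome" does not (75%);
and one code, 99999999, is absent from the dictionary (25% hallucination).

## Command line

```sh
phenoeval prompt "atrial fibrillation"      # elicitation prompt text
phenoeval simulate --n-phenotypes 10 --seed 9 --out-dir bench/
phenoeval evaluate --reference-dir bench/reference --candidate-dir bench/candidate \
    --vocab "snomed=bench/dictionaries/snomed.tsv" --out results/report
phenoeval validate-codes defn.csv --vocab "ICD-10-CM=icd10cm.tsv"
phenoeval map --crossmap cm.csv --vocab SNOMED --code 44054006 --target ICD10CM
```

`evaluate` pairs reference and candidate files by stem, parses candidates
tolerantly (prose-wrapped markdown, delimited, or aligned tables), and writes
per-phenotype plus aggregate reports as CSV and JSON. Exit codes: 0 success,
1 usage error, 2 no pairs, 3 partial failures.

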