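"""Seeded synthetic references, corrupted candidates, and an exact error ledger.

No public corpus of model-generated phenotype definitions exists, so the
package ships a generator that makes every metric testable offline.  It
emulates the observed failure modes of LLM-extracted definitions — missing
codes, fabricated codes, wrong concept names, flipped inclusion/exclusion
logic, wrong vocabulary — as independent per-row corruption operators with
configurable rates.

The design goal is an *exact* ledger, not an asymptotic one: every operator
firing is recorded, fabricated codes are guaranteed absent from every
dictionary, and re-vocabularied codes are guaranteed absent from both the
target dictionary and the reference code set.  The ledger therefore fully
determines every metric value on the generated pair, and
:func:`expected_metrics` reproduces them without sampling error — the basis
for parameter-recovery tests.

Randomness comes from NumPy's ``default_rng`` (the PCG64 generator), pinned
by name so fixtures are portable across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .defmodel import (
    CapacityError,
    CodeCount,
    DefinitionRow,
    DictionarySet,
    LogicLabel,
    ParameterError,
    PhenotypeDefinition,
    VocabularyDictionary,
    VocabularyId,
)
from .metrics import greedy_name_matches, name_similarity

RNG_ALGORITHM = "PCG64"  # numpy.random.default_rng

# ---------------------------------------------------------------------------
# Synthetic vocabulary dictionaries
# ---------------------------------------------------------------------------

_ADJECTIVES = (
    "acute", "chronic", "recurrent", "severe", "mild", "secondary",
    "primary", "unstable", "congenital", "ischemic", "benign", "atypical",
)
_NOUNS = (
    "angina", "infarction", "insufficiency", "allergy", "diabetes",
    "nephropathy", "hypertension", "asthma", "anemia", "dermatitis",
    "neuropathy", "fibrillation", "stenosis", "embolism", "carditis",
)
_QUALIFIERS = (
    "type 1", "type 2", "class i", "class ii", "class iii", "class iv",
    "with complication", "without complication", "of left ventricle",
    "of upper limb", "in remission", "unspecified",
)

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_ALNUM = "0123456789" + _LETTERS


def _random_code(rng: np.random.Generator, vocabulary: VocabularyId) -> str:
    """A shape-valid code for the vocabulary (uniqueness handled by callers)."""
    v = vocabulary.canonical
    if v == "SNOMED":
        # 9-digit identifiers, no leading zero
        return str(rng.integers(10**8, 10**9))
    if v in ("ICD-10", "ICD-10-CM"):
        head = _LETTERS[rng.integers(0, 26)] + f"{rng.integers(0, 100):02d}"
        tail_len = int(rng.integers(0, 4)) if v == "ICD-10" else int(rng.integers(1, 5))
        tail = "".join(_ALNUM[rng.integers(0, 10)] for _ in range(tail_len))
        return head + tail
    if v == "CPT":
        return f"{rng.integers(0, 10000):04d}{_ALNUM[rng.integers(0, 10)]}"
    # generic fallback: 8 alphanumerics
    return "".join(_ALNUM[rng.integers(0, len(_ALNUM))] for _ in range(8))


def _synthetic_name(rng: np.random.Generator) -> str:
    return " ".join(
        (
            _ADJECTIVES[rng.integers(0, len(_ADJECTIVES))],
            _NOUNS[rng.integers(0, len(_NOUNS))],
            _QUALIFIERS[rng.integers(0, len(_QUALIFIERS))],
        )
    )


def synthesize_dictionary(
    vocabulary: VocabularyId | str,
    n_entries: int,
    seed: int,
    code_pattern: str = "",
) -> VocabularyDictionary:
    """Generate a synthetic vocabulary dictionary with shape-valid, unique codes.

    Names are clinically styled but synthetic; near-duplicate names occur by
    construction (shared adjective/noun pools), exercising the similarity
    machinery realistically.
    """
    if isinstance(vocabulary, str):
        vocabulary = VocabularyId.resolve(vocabulary)
    if n_entries < 1:
        raise ParameterError("n_entries must be >= 1")
    rng = np.random.default_rng(seed)
    entries: dict[str, str] = {}
    names_used: set[str] = set()
    while len(entries) < n_entries:
        code = _random_code(rng, vocabulary)
        if code in entries:
            continue
        name = _synthetic_name(rng)
        if name in names_used:
            name = f"{name} variant {len(entries)}"
        names_used.add(name)
        entries[code] = name
    return VocabularyDictionary(
        vocabulary=vocabulary, entries=entries, code_pattern=code_pattern
    )


def default_dictionaries(seed: int, n_entries: int = 400) -> DictionarySet:
    """A SNOMED + ICD-10 + ICD-10-CM dictionary set, seeded and disjoint."""
    return DictionarySet(
        [
            synthesize_dictionary("SNOMED", n_entries, seed),
            synthesize_dictionary("ICD-10", n_entries, seed + 1),
            synthesize_dictionary("ICD-10-CM", n_entries, seed + 2),
        ]
    )


# ---------------------------------------------------------------------------
# Reference sampling
# ---------------------------------------------------------------------------

#: Defaults emulate the curated corpus structure: one vocabulary dominant,
#: rows mostly inclusion criteria, a mix of "1" and "1+" counts.
DEFAULT_VOCAB_MIX: dict[str, float] = {"SNOMED": 0.7, "ICD-10-CM": 0.2, "ICD-10": 0.1}
DEFAULT_LOGIC_MIX: dict[str, float] = {"inclusion": 0.85, "exclusion": 0.15}
DEFAULT_AT_LEAST_ONCE_SHARE = 0.5


def sample_reference(
    n_rows: int,
    vocab_mix: Mapping[str, float] | None = None,
    logic_mix: Mapping[str, float] | None = None,
    dictionaries: DictionarySet | None = None,
    seed: int = 0,
    phenotype_name: str = "synthetic phenotype",
) -> PhenotypeDefinition:
    """Sample a dictionary-valid reference definition.

    Rows are drawn *without replacement* from dictionary entries, so every
    sampled code exists in its vocabulary with its exact canonical name.
    Deterministic per seed.
    """
    if n_rows < 1:
        raise ParameterError("n_rows must be >= 1")
    if dictionaries is None:
        dictionaries = default_dictionaries(seed=seed + 1_000_003, n_entries=max(400, n_rows * 2))
    vmix = dict(vocab_mix or DEFAULT_VOCAB_MIX)
    lmix = dict(logic_mix or DEFAULT_LOGIC_MIX)
    total_v = sum(vmix.values())
    if total_v <= 0:
        raise ParameterError("vocab_mix must have positive mass")
    p_incl = lmix.get("inclusion", 0.0) / max(sum(lmix.values()), 1e-12)

    rng = np.random.default_rng(seed)
    vocabs = sorted(vmix)
    probs = np.array([vmix[v] / total_v for v in vocabs])
    counts = rng.multinomial(n_rows, probs)

    rows: list[DefinitionRow] = []
    for vocab_name, k in zip(vocabs, counts):
        if k == 0:
            continue
        vocab = VocabularyId.resolve(vocab_name)
        dictionary = dictionaries.get(vocab)
        if dictionary is None or len(dictionary) == 0:
            raise CapacityError(f"no dictionary entries for vocabulary {vocab_name}")
        codes = sorted(dictionary.entries)
        if k > len(codes):
            raise CapacityError(
                f"requested {k} rows from {vocab_name} but dictionary holds {len(codes)}"
            )
        chosen = rng.choice(len(codes), size=int(k), replace=False)
        for idx in chosen:
            code = codes[int(idx)]
            logic = LogicLabel.INCLUSION if rng.random() < p_incl else LogicLabel.EXCLUSION
            count = (
                CodeCount.AT_LEAST_ONCE
                if rng.random() < DEFAULT_AT_LEAST_ONCE_SHARE
                else CodeCount.EXACTLY_ONCE
            )
            rows.append(
                DefinitionRow(
                    logic=logic,
                    vocabulary=vocab,
                    code=code,
                    name=dictionary.entries[code],
                    count=count,
                )
            )
    order = rng.permutation(len(rows))
    rows = [rows[int(i)] for i in order]
    return PhenotypeDefinition(
        phenotype_name=phenotype_name, rows=tuple(rows), source="reference"
    )


# ---------------------------------------------------------------------------
# Corruption
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorruptionProfile:
    """Per-row corruption rates; all probabilities in [0, 1].

    Operators apply per row in a fixed order and are mutually exclusive except
    rename and flip-logic, which may co-occur: drop, else fabricate-code, else
    {rename, flip-logic} independently, else (if neither fired) re-vocabulary.
    """

    p_drop: float = 0.0
    p_fabricate_code: float = 0.0
    p_rename: float = 0.0
    p_flip_logic: float = 0.0
    p_revocab: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_drop", "p_fabricate_code", "p_rename", "p_flip_logic", "p_revocab"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class RowCorruptionRecord:
    """What happened to one reference row."""

    reference_index: int
    dropped: bool = False
    fabricated: bool = False
    renamed: bool = False
    logic_flipped: bool = False
    revocabbed: bool = False
    original_logic: str = "inclusion"
    original_name: str = ""
    final_name: str | None = None  # None when dropped
    final_logic: str | None = None
    name_similarity_to_canonical: float | None = None  # set when renamed

    @property
    def fired(self) -> bool:
        return any(
            (self.dropped, self.fabricated, self.renamed, self.logic_flipped, self.revocabbed)
        )

    @property
    def code_intact(self) -> bool:
        return not self.dropped and not self.fabricated and not self.revocabbed


@dataclass
class CorruptionLedger:
    """Full per-row account of the injected errors; determines every metric."""

    profile: CorruptionProfile
    records: list[RowCorruptionRecord] = field(default_factory=list)

    @property
    def n_reference(self) -> int:
        return len(self.records)

    @property
    def n_candidate(self) -> int:
        return sum(1 for r in self.records if not r.dropped)

    def count(self, attribute: str) -> int:
        return sum(1 for r in self.records if getattr(r, attribute))

    @property
    def fired_records(self) -> list[RowCorruptionRecord]:
        return [r for r in self.records if r.fired]


def _fabricate_code(
    rng: np.random.Generator,
    vocabulary: VocabularyId,
    dictionaries: DictionarySet,
    used_keys: set[tuple[str, str]],
) -> str:
    """A shape-valid code guaranteed absent from every dictionary and the candidate."""
    for _ in range(10_000):
        code = _random_code(rng, vocabulary)
        in_any = any(code in d.entries for d in dictionaries)
        if not in_any and (vocabulary.canonical, code) not in used_keys:
            return code
    raise CapacityError("could not fabricate a fresh code (dictionaries saturated)")


def _perturb_name(rng: np.random.Generator, name: str) -> str:
    """Replace at least half of the name tokens with synthetic gibberish."""
    tokens = name.split()
    k = max(1, math.ceil(len(tokens) / 2))
    positions = rng.choice(len(tokens), size=k, replace=False)
    out = list(tokens)
    for pos in positions:
        out[int(pos)] = f"zq{rng.integers(0, 10**6)}x"
    return " ".join(out)


def _pick_revocab(
    rng: np.random.Generator,
    row: DefinitionRow,
    dictionaries: DictionarySet,
    reference_keys: frozenset[tuple[str, str]],
    used_keys: set[tuple[str, str]],
) -> VocabularyId | None:
    """A different vocabulary under which the row's code is verifiably absent."""
    options = []
    for d in dictionaries:
        v = d.vocabulary
        if v.canonical == row.vocabulary.canonical:
            continue
        key = (v.canonical, row.code)
        if row.code in d.entries or key in reference_keys or key in used_keys:
            continue
        options.append(v)
    if not options:
        fallback = VocabularyId.resolve("UNLISTED-VOCAB")
        key = (fallback.canonical, row.code)
        if key in reference_keys or key in used_keys:
            return None
        return fallback
    options.sort(key=lambda v: v.canonical)
    return options[int(rng.integers(0, len(options)))]


def corrupt(
    reference: PhenotypeDefinition,
    profile: CorruptionProfile,
    dictionaries: DictionarySet,
) -> tuple[PhenotypeDefinition, CorruptionLedger]:
    """Apply the corruption operators row by row; return candidate + ledger.

    The reference must be dictionary-valid (as produced by
    :func:`sample_reference`): renamed rows' similarity is measured against
    the dictionary's canonical name, which for a valid reference is the row's
    own original name.
    """
    rng = np.random.default_rng(profile.seed)
    reference_keys = reference.distinct_codes()
    used_keys: set[tuple[str, str]] = set()
    records: list[RowCorruptionRecord] = []
    rows: list[DefinitionRow] = []

    for i, row in enumerate(reference.rows):
        base = dict(
            reference_index=i,
            original_logic=row.logic.value,
            original_name=row.name,
        )
        if rng.random() < profile.p_drop:
            records.append(RowCorruptionRecord(dropped=True, **base))
            continue

        if rng.random() < profile.p_fabricate_code:
            code = _fabricate_code(rng, row.vocabulary, dictionaries, used_keys)
            new_row = replace(row, code=code)
            records.append(
                RowCorruptionRecord(
                    fabricated=True,
                    final_name=new_row.name,
                    final_logic=new_row.logic.value,
                    **base,
                )
            )
        else:
            renamed = rng.random() < profile.p_rename
            flipped = rng.random() < profile.p_flip_logic
            new_row = row
            similarity = None
            if renamed:
                new_name = _perturb_name(rng, row.name)
                similarity = name_similarity(new_name, row.name)
                new_row = replace(new_row, name=new_name)
            if flipped:
                new_logic = (
                    LogicLabel.EXCLUSION
                    if row.logic is LogicLabel.INCLUSION
                    else LogicLabel.INCLUSION
                )
                new_row = replace(new_row, logic=new_logic)
            revocabbed = False
            if not renamed and not flipped and rng.random() < profile.p_revocab:
                new_vocab = _pick_revocab(rng, row, dictionaries, reference_keys, used_keys)
                if new_vocab is not None:
                    new_row = replace(new_row, vocabulary=new_vocab)
                    revocabbed = True
            records.append(
                RowCorruptionRecord(
                    renamed=renamed,
                    logic_flipped=flipped,
                    revocabbed=revocabbed,
                    final_name=new_row.name,
                    final_logic=new_row.logic.value,
                    name_similarity_to_canonical=similarity,
                    **base,
                )
            )
        used_keys.add(new_row.key())
        rows.append(new_row)

    candidate = PhenotypeDefinition(
        phenotype_name=reference.phenotype_name,
        rows=tuple(rows),
        source="candidate",
        provenance=f"synthetic:{RNG_ALGORITHM}:{profile.seed}",
    )
    return candidate, CorruptionLedger(profile=profile, records=records)


# ---------------------------------------------------------------------------
# Closed-form expectations from the ledger
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpectedMetrics:
    """Metric values the ledger implies for the generated pair (exact)."""

    codes_overlap_pct: float
    logic_overlap_pct: float
    strings_overlap_pct: float
    hallucination_pct: float


def expected_metrics(
    ledger: CorruptionLedger,
    strings_threshold: float = 0.5,
    name_threshold: float = 0.7,
) -> ExpectedMetrics:
    """Derive the exact metric values implied by the ledger.

    Codes overlap: surviving rows with an intact (vocabulary, code) pair over
    candidate rows.  Logic overlap: among intact-code rows, those without a
    logic flip (falling back to label-distribution agreement when no code is
    intact).  Strings overlap: the same greedy name assignment the metric
    uses, run over the ledger-recorded names.  Hallucination: fabricated plus
    re-vocabularied rows plus renames whose similarity fell below the name
    threshold.  All values are exact, not asymptotic — the generator
    guarantees that no injected error can accidentally un-inject itself.
    """
    survivors = [r for r in ledger.records if not r.dropped]
    n_cand = len(survivors)
    if n_cand == 0:
        return ExpectedMetrics(0.0, 0.0, 0.0, 0.0)

    intact = [r for r in survivors if r.code_intact]
    codes = 100.0 * len(intact) / n_cand

    if intact:
        agree = sum(1 for r in intact if not r.logic_flipped)
        logic = 100.0 * agree / len(intact)
    else:
        n_ref = len(ledger.records)
        p_ref = sum(1 for r in ledger.records if r.original_logic == "inclusion") / n_ref
        p_cand = sum(1 for r in survivors if r.final_logic == "inclusion") / n_cand
        tv = abs(p_cand - p_ref)  # two labels: TV equals the one-sided gap
        logic = 100.0 * (1.0 - tv)

    candidate_names = [r.final_name or "" for r in survivors]
    reference_names = [r.original_name for r in ledger.records]
    matches = greedy_name_matches(candidate_names, reference_names)
    hits = sum(1 for m in matches if m.similarity >= strings_threshold)
    strings = 100.0 * hits / n_cand

    bad = sum(
        1
        for r in survivors
        if r.fabricated
        or r.revocabbed
        or (
            r.renamed
            and r.name_similarity_to_canonical is not None
            and r.name_similarity_to_canonical < name_threshold
        )
    )
    hallucination = 100.0 * bad / n_cand

    return ExpectedMetrics(codes, logic, strings, hallucination)
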