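"""Dictionary-based detection of fabricated or misnamed concept codes.

A generated definition row is a *hallucination* when its code does not exist
in the vocabulary it claims (fabricated or malformed), or when the code exists
but is paired with a name that does not match the terminology's canonical
name.  Real LLM failures show both modes: entirely invented identifiers, and
real-looking codes such as an allergy-history code re-labelled with a related
but wrong concept name.

Validation consults only the dictionary of the vocabulary the row itself
claims; rescuing a code by looking it up in a different vocabulary is the job
of cross-vocabulary mapping, not of validation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .defmodel import (
    DefinitionRow,
    DictionarySet,
    MalformedCodeError,
    ParameterError,
    PhenotypeDefinition,
    normalize_code,
)
from .metrics import name_similarity

#: Verdict statuses, in the order the checks run.
VALID = "valid"
UNKNOWN_VOCABULARY = "unknown-vocabulary"
MALFORMED_CODE = "malformed-code"
UNKNOWN_CODE = "unknown-code"
NAME_MISMATCH = "name-mismatch"

#: Statuses counted as hallucinations.
HALLUCINATION_STATUSES = frozenset(
    {UNKNOWN_VOCABULARY, MALFORMED_CODE, UNKNOWN_CODE, NAME_MISMATCH}
)


@dataclass(frozen=True)
class ValidationVerdict:
    """Outcome of validating one row against the vocabulary dictionaries."""

    row_index: int
    status: str
    dictionary_name: str | None = None
    name_similarity: float | None = None

    @property
    def is_hallucination(self) -> bool:
        return self.status in HALLUCINATION_STATUSES


def validate_row(
    row: DefinitionRow,
    dictionaries: DictionarySet,
    name_threshold: float = 0.7,
    row_index: int = 0,
) -> ValidationVerdict:
    """Validate one definition row; the first failed check decides the status.

    Checks, in order: is the claimed vocabulary recognized and covered by a
    dictionary; does the normalized code match the vocabulary's shape pattern;
    is the code present in the dictionary; is the claimed name similar enough
    (token-set Jaccard >= ``name_threshold``) to the dictionary's canonical
    name.  A row passing all four is valid.
    """
    if not (0.0 < name_threshold <= 1.0):
        raise ParameterError(f"name_threshold must be in (0, 1], got {name_threshold}")

    dictionary = dictionaries.get(row.vocabulary)
    if not row.vocabulary.recognized or dictionary is None:
        return ValidationVerdict(row_index, UNKNOWN_VOCABULARY)

    try:
        code = normalize_code(row.vocabulary, row.code)
    except MalformedCodeError:
        return ValidationVerdict(row_index, MALFORMED_CODE)
    if not dictionary.matches_shape(code):
        return ValidationVerdict(row_index, MALFORMED_CODE)

    canonical_name = dictionary.entries.get(code)
    if canonical_name is None:
        return ValidationVerdict(row_index, UNKNOWN_CODE)

    similarity = name_similarity(row.name, canonical_name)
    status = VALID if similarity >= name_threshold else NAME_MISMATCH
    return ValidationVerdict(
        row_index, status, dictionary_name=canonical_name, name_similarity=similarity
    )


def validate_definition(
    defn: PhenotypeDefinition,
    dictionaries: DictionarySet,
    name_threshold: float = 0.7,
) -> list[ValidationVerdict]:
    """Verdict for every row of a definition, in row order."""
    return [
        validate_row(row, dictionaries, name_threshold, row_index=i)
        for i, row in enumerate(defn.rows)
    ]


def hallucination_rate(
    defn: PhenotypeDefinition,
    dictionaries: DictionarySet,
    name_threshold: float = 0.7,
) -> float:
    """Percent of rows that are hallucinations; 0 for an empty definition."""
    if not defn.rows:
        return 0.0
    verdicts = validate_definition(defn, dictionaries, name_threshold)
    bad = sum(1 for v in verdicts if v.is_hallucination)
    return 100.0 * bad / len(verdicts)
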