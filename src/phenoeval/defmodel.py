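"""Core domain model for structured computational phenotype definitions.

A phenotype definition is a flat, ordered list of concept rows.  Each row
carries an inclusion/exclusion logic label, the vocabulary the code is drawn
from (SNOMED CT, ICD-10, ICD-10-CM, ...), the concept code itself, the concept
name, and a code-count requirement ("1" = exactly once, "1+" = at least once).
Definitions of this shape are what professional phenotype libraries such as
PheKB and the OHDSI phenotype library reduce to after curation, and what a
language model is asked to emit when prompted for a phenotype.

Everything downstream (overlap metrics, hallucination checks, cross-vocabulary
mapping) compares definitions on *normalized* ``(vocabulary, code)`` pairs, so
the normalization rules live here and are shared by every module.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PhenoEvalError(Exception):
    """Base class for all errors raised by this package."""


class MalformedCodeError(PhenoEvalError):
    """A concept code is empty after normalization."""


class SchemaError(PhenoEvalError):
    """A definition table is missing a mandatory column."""


class RowParseError(PhenoEvalError):
    """A table row could not be parsed; carries the 0-based row index."""

    def __init__(self, index: int, message: str):
        super().__init__(f"row {index}: {message}")
        self.index = index


class ParameterError(PhenoEvalError):
    """A parameter (threshold, probability, name) is out of its domain."""


class CapacityError(PhenoEvalError):
    """A sampling request exceeds what the dictionaries can supply."""


class DictionaryLoadError(PhenoEvalError):
    """A vocabulary file contains conflicting duplicate codes."""


# ---------------------------------------------------------------------------
# Logic labels and code counts
# ---------------------------------------------------------------------------

class LogicLabel(str, enum.Enum):
    """Role a code plays in the phenotype: qualifies or disqualifies a patient."""

    INCLUSION = "inclusion"
    EXCLUSION = "exclusion"

    @classmethod
    def parse(cls, token: str) -> "LogicLabel":
        t = token.strip().lower()
        if t == "inclusion":
            return cls.INCLUSION
        if t == "exclusion":
            return cls.EXCLUSION
        raise ValueError(f"not a logic label: {token!r}")

    def render(self) -> str:
        return self.value.capitalize()


class CodeCount(str, enum.Enum):
    """Occurrence requirement for a code: exactly once ("1") or at least once ("1+").

    Parsed and reported but deliberately excluded from all comparison metrics;
    no overlap measure consumes it.
    """

    EXACTLY_ONCE = "1"
    AT_LEAST_ONCE = "1+"

    @classmethod
    def parse(cls, token: str) -> "CodeCount":
        # "1 +" occurs in curated tables; whitespace inside the token is noise.
        t = re.sub(r"\s+", "", token)
        if t == "1":
            return cls.EXACTLY_ONCE
        if t == "1+":
            return cls.AT_LEAST_ONCE
        raise ValueError(f"not a code count: {token!r}")

    def render(self) -> str:
        return self.value


# ---------------------------------------------------------------------------
# Vocabulary identifiers
# ---------------------------------------------------------------------------

def _squash(token: str) -> str:
    """Collapse case, whitespace, hyphens and underscores for alias matching."""
    return re.sub(r"[\s_\-.]+", "", token.strip().lower())


#: Alias table: squashed alias -> canonical vocabulary name.  User-extensible
#: through :func:`register_vocabulary_alias`.  Both spellings seen in the wild
#: ("ICD10" / "ICD-10", "SNOMED CT" / "SNOMED") resolve to one canonical id.
_VOCAB_ALIASES: dict[str, str] = {
    "snomed": "SNOMED",
    "snomedct": "SNOMED",
    "icd10": "ICD-10",
    "icd10cm": "ICD-10-CM",
    "icd9": "ICD-9",
    "icd9cm": "ICD-9-CM",
    "cpt": "CPT",
    "cpt4": "CPT",
    "hcpcs": "HCPCS",
    "loinc": "LOINC",
    "rxnorm": "RxNorm",
}

#: Vocabularies whose codes are rendered with or without a period depending on
#: the source ("Z91.010" vs "Z91010"); normalization strips the period.
ICD_FAMILY: frozenset[str] = frozenset({"ICD-9", "ICD-9-CM", "ICD-10", "ICD-10-CM"})

#: Default code-shape patterns applied to *normalized* codes, one regular
#: expression per canonical vocabulary.  Editable configuration: dictionaries
#: may be loaded with any pattern, and entries here can be overridden.
DEFAULT_CODE_PATTERNS: dict[str, str] = {
    "SNOMED": r"\d{6,18}",
    "ICD-10": r"[A-Z]\d{2}[0-9A-Z]{0,4}",
    "ICD-10-CM": r"[A-Z]\d[0-9A-Z]{1,5}",
    "ICD-9": r"[0-9EV]\d{2,4}",
    "ICD-9-CM": r"[0-9EV]\d{2,4}",
    "CPT": r"\d{4}[0-9A-Z]",
    "HCPCS": r"[A-Z]\d{4}",
    "LOINC": r"\d{1,7}-?\d",
    "RxNorm": r"\d{1,8}",
}


def register_vocabulary_alias(alias: str, canonical: str) -> None:
    """Extend the alias table so that ``alias`` resolves to ``canonical``."""
    if not alias.strip():
        raise ParameterError("alias must be non-empty")
    _VOCAB_ALIASES[_squash(alias)] = canonical


@dataclass(frozen=True)
class VocabularyId:
    """A clinical terminology identifier.

    ``recognized`` is False when the token did not resolve through the alias
    table; such tokens are preserved verbatim so that diagnostics can report
    exactly what the model emitted.
    """

    canonical: str
    recognized: bool = True

    @classmethod
    def resolve(cls, token: str) -> "VocabularyId":
        canonical = _VOCAB_ALIASES.get(_squash(token))
        if canonical is None:
            return cls(canonical=token.strip(), recognized=False)
        return cls(canonical=canonical)

    @property
    def is_icd_family(self) -> bool:
        return self.canonical in ICD_FAMILY

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


# ---------------------------------------------------------------------------
# Code normalization
# ---------------------------------------------------------------------------

def normalize_code(vocabulary: VocabularyId, code: str) -> str:
    """Canonicalize a concept code for comparison.

    Uppercases, strips surrounding whitespace, and for the ICD family removes
    the period so that dotted ("Z91.010") and undotted ("Z91010") renderings of
    the same code compare equal.  Idempotent.

    Raises
    ------
    MalformedCodeError
        If the code is empty after normalization.
    """
    out = code.strip().upper()
    if vocabulary.is_icd_family:
        out = out.replace(".", "")
    if not out:
        raise MalformedCodeError(f"code {code!r} is empty after normalization")
    return out


# ---------------------------------------------------------------------------
# Rows and definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DefinitionRow:
    """One concept criterion of a phenotype definition."""

    logic: LogicLabel
    vocabulary: VocabularyId
    code: str
    name: str
    count: CodeCount

    def __post_init__(self) -> None:
        if not self.code.strip():
            raise MalformedCodeError("row code must be non-empty")
        if not self.name.strip():
            raise ParameterError("row name must be non-empty")

    def key(self) -> tuple[str, str]:
        """Normalized ``(vocabulary, code)`` identity used by all code metrics."""
        return (self.vocabulary.canonical, normalize_code(self.vocabulary, self.code))


@dataclass(frozen=True)
class PhenotypeDefinition:
    """A named, ordered collection of definition rows.

    ``source`` distinguishes professionally curated references from model
    candidates; a candidate may legitimately be empty (a model may return no
    table at all), a reference may not.
    """

    phenotype_name: str
    rows: tuple[DefinitionRow, ...]
    source: str = "reference"  # "reference" | "candidate"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.source not in ("reference", "candidate"):
            raise ParameterError(f"source must be reference|candidate, got {self.source!r}")
        object.__setattr__(self, "rows", tuple(self.rows))
        if self.source == "reference" and not self.rows:
            raise ParameterError("a reference definition must have at least one row")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[DefinitionRow]:
        return iter(self.rows)

    def distinct_codes(self) -> frozenset[tuple[str, str]]:
        """Set of normalized (vocabulary, code) pairs; duplicates collapsed."""
        return frozenset(r.key() for r in self.rows)

    def deduped_rows(self) -> tuple[DefinitionRow, ...]:
        """Rows after de-duplication by (vocabulary, code), first occurrence kept.

        Logic and strings metrics operate on this view so a model repeating a
        row cannot inflate or deflate a score.
        """
        seen: set[tuple[str, str]] = set()
        out: list[DefinitionRow] = []
        for r in self.rows:
            k = r.key()
            if k not in seen:
                seen.add(k)
                out.append(r)
        return tuple(out)

    def with_rows(self, rows: Iterable[DefinitionRow]) -> "PhenotypeDefinition":
        return replace(self, rows=tuple(rows))


def distinct_codes(defn: PhenotypeDefinition) -> frozenset[tuple[str, str]]:
    """Module-level convenience alias for :meth:`PhenotypeDefinition.distinct_codes`."""
    return defn.distinct_codes()


# ---------------------------------------------------------------------------
# Vocabulary dictionaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VocabularyDictionary:
    """Per-vocabulary lookup from normalized code to its canonical concept name.

    Carries the code-shape pattern used for format validation: a code that does
    not even match the vocabulary's shape is malformed regardless of lookup.
    """

    vocabulary: VocabularyId
    entries: Mapping[str, str]
    code_pattern: str = ""

    def __post_init__(self) -> None:
        pattern = self.code_pattern or DEFAULT_CODE_PATTERNS.get(
            self.vocabulary.canonical, r".+"
        )
        object.__setattr__(self, "code_pattern", pattern)
        object.__setattr__(self, "entries", dict(self.entries))
        object.__setattr__(self, "_regex", re.compile(rf"^(?:{pattern})$"))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return self.lookup(code) is not None

    def lookup(self, code: str) -> str | None:
        """Canonical name for ``code`` (normalized before lookup), or None."""
        try:
            return self.entries.get(normalize_code(self.vocabulary, code))
        except MalformedCodeError:
            return None

    def matches_shape(self, normalized_code: str) -> bool:
        return bool(self._regex.fullmatch(normalized_code))


class DictionarySet:
    """Dictionaries for several vocabularies, keyed by canonical vocabulary name."""

    def __init__(self, dictionaries: Iterable[VocabularyDictionary] = ()):
        self._by_vocab: dict[str, VocabularyDictionary] = {}
        for d in dictionaries:
            self.add(d)

    def add(self, dictionary: VocabularyDictionary) -> None:
        self._by_vocab[dictionary.vocabulary.canonical] = dictionary

    def get(self, vocabulary: VocabularyId) -> VocabularyDictionary | None:
        return self._by_vocab.get(vocabulary.canonical)

    def __iter__(self) -> Iterator[VocabularyDictionary]:
        return iter(self._by_vocab.values())

    def __len__(self) -> int:
        return len(self._by_vocab)

    def __contains__(self, key: tuple[str, str]) -> bool:
        """Membership of a normalized (vocabulary, code) pair in any dictionary."""
        vocab, code = key
        d = self._by_vocab.get(vocab)
        return d is not None and code in d.entries
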