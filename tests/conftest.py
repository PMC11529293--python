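"""Shared fixtures and hypothesis strategies for the test suite."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from phenoeval.defmodel import (
    CodeCount,
    DefinitionRow,
    DictionarySet,
    LogicLabel,
    PhenotypeDefinition,
    VocabularyDictionary,
    VocabularyId,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    database=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.filter_too_much,
        # fixtures used inside @given are read-only reference data
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# The six-row angina reference used throughout (curated corpus excerpt)
# ---------------------------------------------------------------------------

ANGINA_ROWS = [
    ("194823009", "Acute coronary insufficiency", "1+"),
    ("791000119109", "Angina associated with type 2 diabetes mellitus", "1"),
    ("61490001", "Angina, class I", "1+"),
    ("41334000", "Angina, class II", "1"),
    ("85284003", "Angina, class III", "1+"),
    ("89323001", "Angina, class IV", "1+"),
]

SNOMED = VocabularyId.resolve("SNOMED")
ICD10CM = VocabularyId.resolve("ICD-10-CM")
ICD10 = VocabularyId.resolve("ICD-10")


@pytest.fixture
def angina_reference() -> PhenotypeDefinition:
    rows = tuple(
        DefinitionRow(LogicLabel.INCLUSION, SNOMED, code, name, CodeCount.parse(count))
        for code, name, count in ANGINA_ROWS
    )
    return PhenotypeDefinition("angina", rows, source="reference")


@pytest.fixture
def snomed_dictionary() -> VocabularyDictionary:
    return VocabularyDictionary(SNOMED, {code: name for code, name, _ in ANGINA_ROWS})


@pytest.fixture
def angina_dictionaries(snomed_dictionary) -> DictionarySet:
    return DictionarySet([snomed_dictionary])


@pytest.fixture
def peanut_dictionaries() -> DictionarySet:
    """ICD-10-CM fixture holding the real peanut-allergy entry, synthetic scope."""
    return DictionarySet(
        [VocabularyDictionary(ICD10CM, {"Z91010": "Allergy to peanuts"})]
    )


@pytest.fixture
def angina_csv() -> str:
    lines = ["Logic,Vocabulary,Concept code,Concept name,Code count"]
    for code, name, count in ANGINA_ROWS:
        cell = f'"{name}"' if "," in name else name
        lines.append(f"Inclusion,SNOMED,{code},{cell},{count}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Hypothesis strategies
# ---------------------------------------------------------------------------

# Cells must survive every dialect round-trip: no pipes, tabs, commas, or
# runs of spaces (those are the dialect delimiters themselves).
_word = st.text(alphabet="abcdefghijklmnopqrstuvwxyz0123456789", min_size=1, max_size=8)
safe_names = st.lists(_word, min_size=1, max_size=4).map(" ".join)
safe_codes = st.text(
    alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789", min_size=1, max_size=10
)
vocabularies = st.sampled_from(["SNOMED", "ICD-10", "ICD-10-CM", "CPT"]).map(
    VocabularyId.resolve
)


@st.composite
def definition_rows(draw, codes: st.SearchStrategy[str] = safe_codes):
    return DefinitionRow(
        logic=draw(st.sampled_from(list(LogicLabel))),
        vocabulary=draw(vocabularies),
        code=draw(codes),
        name=draw(safe_names),
        count=draw(st.sampled_from(list(CodeCount))),
    )


@st.composite
def definitions(
    draw,
    min_rows: int = 0,
    max_rows: int = 8,
    source: str = "candidate",
    codes: st.SearchStrategy[str] = safe_codes,
):
    rows = draw(st.lists(definition_rows(codes), min_size=min_rows, max_size=max_rows))
    return PhenotypeDefinition("generated", tuple(rows), source=source)


#: Small shared code pool so random pairs actually overlap sometimes.
pooled_codes = st.sampled_from([f"C{i}" for i in range(10)])
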