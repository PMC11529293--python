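"""Cross-vocabulary code mapping and mapped-overlap comparison.

Phenotype definitions in the wild mix coding systems: a curated definition may
use SNOMED CT while a model emits ICD-10-CM.  A crossmap — a finite relation
of (source vocabulary, source code) -> (target vocabulary, target code) links,
such as an extract of OMOP concept relationships or a UMLS crosswalk —
lets codes from different systems be compared in a unified space.

Mapping is single-hop by design: a code's image is whatever the relation links
it to directly, with no transitive closure, which keeps the semantics
predictable and auditable.  The mapped overlap counts a candidate code as
matched when its identity, or any of its single-hop images, coincides with a
reference code's identity or any of its images ("any-match"); mapping can
therefore only add match routes, never remove one, so mapped overlap dominates
plain codes overlap on every input.
"""

from __future__ import annotations

from typing import Iterable

from .defmodel import PhenotypeDefinition, VocabularyId, normalize_code
from .metrics import codes_overlap

Link = tuple[str, str, str, str]  # (source vocab, source code, target vocab, target code)


class CrossMap:
    """A finite, set-semantic relation between codes of different vocabularies.

    Codes are stored normalized; duplicate links collapse.  Queries never
    fail — an unlinked code simply has an empty image.
    """

    def __init__(self, links: Iterable[Link] = ()):
        self._links: set[Link] = set()
        self._forward: dict[tuple[str, str], set[tuple[str, str]]] = {}
        self._reverse: dict[tuple[str, str], set[tuple[str, str]]] = {}
        for link in links:
            self.add(*link)

    def add(self, source_vocab: str, source_code: str, target_vocab: str, target_code: str) -> None:
        sv = VocabularyId.resolve(source_vocab)
        tv = VocabularyId.resolve(target_vocab)
        sc = normalize_code(sv, source_code)
        tc = normalize_code(tv, target_code)
        link = (sv.canonical, sc, tv.canonical, tc)
        if link in self._links:
            return
        self._links.add(link)
        self._forward.setdefault((sv.canonical, sc), set()).add((tv.canonical, tc))
        self._reverse.setdefault((tv.canonical, tc), set()).add((sv.canonical, sc))

    def __len__(self) -> int:
        return len(self._links)

    def __iter__(self):
        return iter(sorted(self._links))

    def image(self, vocab: str, code: str) -> set[tuple[str, str]]:
        """All (vocab, code) pairs linked to the given pair, both directions."""
        key = (vocab, code)
        return set(self._forward.get(key, ())) | set(self._reverse.get(key, ()))

    def lookup(
        self, vocab: str, code: str, target_vocab: str
    ) -> set[str]:
        """Target-vocabulary codes linked to (vocab, code); possibly empty."""
        return {c for v, c in self.image(vocab, code) if v == target_vocab}


def map_code(
    vocab: VocabularyId, code: str, target: VocabularyId, cm: CrossMap
) -> set[str]:
    """Single-hop image of a code in the target vocabulary.

    When source and target vocabularies coincide, the code itself is included
    (identity mapping), so mapping within one system is total.
    """
    normalized = normalize_code(vocab, code)
    out = cm.lookup(vocab.canonical, normalized, target.canonical)
    if vocab.canonical == target.canonical:
        out = out | {normalized}
    return out


def _match_space(keys: frozenset[tuple[str, str]], cm: CrossMap) -> dict[tuple[str, str], set[tuple[str, str]]]:
    """Each key's identity plus its single-hop images."""
    return {k: {k} | cm.image(*k) for k in keys}


def mapped_codes_overlap(
    candidate: PhenotypeDefinition,
    reference: PhenotypeDefinition,
    cm: CrossMap,
) -> float:
    """Codes overlap computed in the crossmap-unified code space.

    A candidate distinct code is matched when its identity-or-image set
    intersects any reference code's identity-or-image set.  The denominator is
    the candidate distinct-code count, as for the plain codes overlap; with an
    empty crossmap the two metrics coincide exactly.
    """
    cand = candidate.distinct_codes()
    if not cand:
        return 0.0
    if len(cm) == 0:
        return codes_overlap(candidate, reference)
    cand_space = _match_space(cand, cm)
    ref_space = _match_space(reference.distinct_codes(), cm)
    ref_union: set[tuple[str, str]] = set()
    for s in ref_space.values():
        ref_union |= s
    matched = sum(1 for s in cand_space.values() if s & ref_union)
    return 100.0 * matched / len(cand)
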