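"""Comparison metrics between a candidate and a reference phenotype definition.

Three per-phenotype percentages quantify how well a candidate definition (for
example, one extracted from a large language model) agrees with a reference
definition (a professionally curated one, or another model's output):

* **codes overlap** — share of the candidate's distinct ``(vocabulary, code)``
  pairs that also occur in the reference.  The candidate's distinct-code count
  is the denominator: the metric reads as the precision of the emitted codes.
* **logic overlap** — among code-matched row pairs, the share whose
  inclusion/exclusion labels agree.  When no codes match at all, the metric
  falls back to agreement between the two label distributions (the complement
  of their total-variation distance), so logical competence remains measurable
  even when every code differs.
* **strings overlap** — share of candidate rows whose concept name can be
  matched one-to-one to a reference name with token-set Jaccard similarity at
  or above a threshold (default 0.5).

All three use the candidate distinct-code/row count as denominator for
uniform interpretability, return 0 for an empty candidate (with a diagnostic,
so aggregation stays total), and operate on rows de-duplicated by
``(vocabulary, code)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .defmodel import (
    DictionarySet,
    ParameterError,
    PhenotypeDefinition,
)

EMPTY_CANDIDATE = "empty-candidate"
NO_CODE_MATCHES = "no-code-matches:distribution-fallback"

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def _tokens(text: str) -> frozenset[str]:
    """Case-folded, punctuation-stripped word tokens of a concept name."""
    return frozenset(t for t in _TOKEN_RE.split(text.casefold()) if t)


def name_similarity(a: str, b: str) -> float:
    """Token-set Jaccard similarity between two concept names, in [0, 1].

    Symmetric; equals 1 iff the token sets are equal; defined as 0 when both
    names tokenize to nothing.
    """
    ta, tb = _tokens(a), _tokens(b)
    if not ta and not tb:
        return 0.0
    return len(ta & tb) / len(ta | tb)


@dataclass(frozen=True)
class RowMatch:
    """One-to-one pairing of a candidate row with a reference row."""

    candidate_index: int
    reference_index: int
    basis: str  # "code" | "mapped-code" | "name"
    similarity: float


def greedy_name_matches(
    candidate_names: list[str], reference_names: list[str]
) -> list[RowMatch]:
    """Greedy one-to-one assignment of candidate to reference names.

    Pairs are taken in descending similarity order, ties broken by
    (candidate index, reference index) ascending; each side is used at most
    once.  Deterministic for given inputs.

    Similarity-1.0 pairs are exactly the pairs with equal non-empty token
    sets, and token-set equality is transitive, so they can be assigned by
    hashing (candidates in index order take references in index order within
    each equal-token class) without changing the outcome; only the leftovers
    need the quadratic similarity sweep.
    """
    cand_tokens = [_tokens(n) for n in candidate_names]
    ref_tokens = [_tokens(n) for n in reference_names]
    used_c: set[int] = set()
    used_r: set[int] = set()
    matches: list[RowMatch] = []

    by_tokens: dict[frozenset[str], list[int]] = {}
    for ri in range(len(ref_tokens) - 1, -1, -1):
        by_tokens.setdefault(ref_tokens[ri], []).append(ri)
    for ci, ts in enumerate(cand_tokens):
        if not ts:
            continue  # empty-vs-empty similarity is defined as 0, not 1
        bucket = by_tokens.get(ts)
        if bucket:
            ri = bucket.pop()
            used_c.add(ci)
            used_r.add(ri)
            matches.append(RowMatch(ci, ri, basis="name", similarity=1.0))

    def jaccard(a: frozenset[str], b: frozenset[str]) -> float:
        if not a and not b:
            return 0.0
        return len(a & b) / len(a | b)

    scored = [
        (jaccard(cand_tokens[ci], ref_tokens[ri]), ci, ri)
        for ci in range(len(cand_tokens))
        if ci not in used_c
        for ri in range(len(ref_tokens))
        if ri not in used_r
    ]
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    for sim, ci, ri in scored:
        if ci in used_c or ri in used_r:
            continue
        used_c.add(ci)
        used_r.add(ri)
        matches.append(RowMatch(ci, ri, basis="name", similarity=sim))
    return matches


# ---------------------------------------------------------------------------
# The three overlap metrics
# ---------------------------------------------------------------------------

def codes_overlap(candidate: PhenotypeDefinition, reference: PhenotypeDefinition) -> float:
    """Percent of candidate distinct codes present in the reference.

    ``100 * |candidate ∩ reference| / |candidate|`` over normalized
    (vocabulary, code) pairs; 0 for an empty candidate.
    """
    cand = candidate.distinct_codes()
    if not cand:
        return 0.0
    return 100.0 * len(cand & reference.distinct_codes()) / len(cand)


def logic_overlap(
    candidate: PhenotypeDefinition,
    reference: PhenotypeDefinition,
    *,
    fallback: bool = True,
) -> float:
    """Percent agreement of inclusion/exclusion labels.

    Primary definition: over code-matched row pairs (candidate row paired with
    the first reference row bearing the same normalized (vocabulary, code)),
    the fraction whose logic labels agree.  If no codes match and ``fallback``
    is enabled, agreement between the two label distributions is reported
    instead: ``100 * (1 - TV)`` where TV is the total-variation distance
    between the candidate's and reference's inclusion/exclusion proportions.
    """
    cand_rows = candidate.deduped_rows()
    if not cand_rows:
        return 0.0
    ref_rows = reference.deduped_rows()
    ref_by_key = {}
    for r in ref_rows:
        ref_by_key.setdefault(r.key(), r)

    paired = [(c, ref_by_key[c.key()]) for c in cand_rows if c.key() in ref_by_key]
    if paired:
        agree = sum(1 for c, r in paired if c.logic == r.logic)
        return 100.0 * agree / len(paired)
    if not fallback or not ref_rows:
        return 0.0

    def proportions(rows):
        n = len(rows)
        inc = sum(1 for r in rows if r.logic.value == "inclusion")
        return {"inclusion": inc / n, "exclusion": (n - inc) / n}

    pc, pr = proportions(cand_rows), proportions(ref_rows)
    tv = 0.5 * sum(abs(pc[k] - pr[k]) for k in ("inclusion", "exclusion"))
    return 100.0 * (1.0 - tv)


def strings_overlap(
    candidate: PhenotypeDefinition,
    reference: PhenotypeDefinition,
    threshold: float = 0.5,
) -> float:
    """Percent of candidate rows whose name matches a reference name.

    Candidate names are assigned one-to-one to reference names greedily in
    descending token-set Jaccard order; a candidate row overlaps when its
    assigned similarity is at or above ``threshold``.  The denominator is the
    candidate row count (after de-duplication by code).
    """
    if not (0.0 < threshold <= 1.0):
        raise ParameterError(f"strings threshold must be in (0, 1], got {threshold}")
    cand_rows = candidate.deduped_rows()
    if not cand_rows:
        return 0.0
    ref_rows = reference.deduped_rows()
    matches = greedy_name_matches(
        [r.name for r in cand_rows], [r.name for r in ref_rows]
    )
    hits = sum(1 for m in matches if m.similarity >= threshold)
    return 100.0 * hits / len(cand_rows)


# ---------------------------------------------------------------------------
# Per-phenotype reports and collection-level aggregation
# ---------------------------------------------------------------------------

#: Canonical metric ordering used by reports and writers.
METRIC_FIELDS: tuple[str, ...] = (
    "codes_overlap_pct",
    "logic_overlap_pct",
    "strings_overlap_pct",
    "hallucination_pct",
    "mapped_codes_overlap_pct",
)


@dataclass(frozen=True)
class MetricReport:
    """All metric percentages for one phenotype pair; absent metrics are None."""

    phenotype_name: str
    codes_overlap_pct: float | None = None
    logic_overlap_pct: float | None = None
    strings_overlap_pct: float | None = None
    hallucination_pct: float | None = None
    mapped_codes_overlap_pct: float | None = None
    diagnostics: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in METRIC_FIELDS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ParameterError(f"{name}={v} outside [0, 100]")
        object.__setattr__(self, "diagnostics", tuple(self.diagnostics))

    def present_metrics(self) -> dict[str, float]:
        return {
            name: getattr(self, name)
            for name in METRIC_FIELDS
            if getattr(self, name) is not None
        }


@dataclass(frozen=True)
class ReportDocument:
    """Per-phenotype metric reports plus avg/min/max aggregates per metric."""

    reports: tuple[MetricReport, ...]
    aggregates: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "reports", tuple(self.reports))
        for name, agg in self.aggregates.items():
            if not agg["min"] <= agg["average"] <= agg["max"]:
                raise ParameterError(f"aggregate ordering violated for {name}: {agg}")


def aggregate(reports: list[MetricReport]) -> ReportDocument:
    """Average / minimum / maximum of each metric over a phenotype collection.

    Metrics absent from a given report are excluded pairwise, so a collection
    where only some phenotypes had a crossmap still aggregates cleanly.
    """
    if not reports:
        raise ParameterError("cannot aggregate an empty report list")
    aggregates: dict[str, dict[str, float]] = {}
    for name in METRIC_FIELDS:
        values = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if values:
            aggregates[name] = {
                "average": sum(values) / len(values),
                "min": min(values),
                "max": max(values),
            }
    return ReportDocument(reports=tuple(reports), aggregates=aggregates)


# ---------------------------------------------------------------------------
# One-call evaluation of a phenotype pair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalConfig:
    """Tunable evaluation parameters, shared across a whole run."""

    strings_threshold: float = 0.5
    name_threshold: float = 0.7
    logic_fallback: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.strings_threshold <= 1.0):
            raise ParameterError("strings_threshold must be in (0, 1]")
        if not (0.0 < self.name_threshold <= 1.0):
            raise ParameterError("name_threshold must be in (0, 1]")


def evaluate_pair(
    candidate: PhenotypeDefinition,
    reference: PhenotypeDefinition,
    dictionaries: DictionarySet | None = None,
    crossmap=None,
    config: EvalConfig | None = None,
) -> MetricReport:
    """Compute every applicable metric for one candidate/reference pair.

    Hallucination rate requires ``dictionaries``; mapped codes overlap
    requires ``crossmap``.  The same machinery serves both comparison
    scenarios — the reference slot may hold a human-curated definition or
    another model's candidate.
    """
    cfg = config or EvalConfig()
    diagnostics: list[str] = []
    if not candidate.rows:
        diagnostics.append(EMPTY_CANDIDATE)

    codes = codes_overlap(candidate, reference)
    logic = logic_overlap(candidate, reference, fallback=cfg.logic_fallback)
    strings = strings_overlap(candidate, reference, cfg.strings_threshold)

    cand_keys = candidate.distinct_codes()
    if candidate.rows and cand_keys and not (cand_keys & reference.distinct_codes()):
        if cfg.logic_fallback:
            diagnostics.append(NO_CODE_MATCHES)

    hallucination = None
    if dictionaries is not None:
        from .hallucination import hallucination_rate  # local import: avoids cycle

        hallucination = hallucination_rate(
            candidate, dictionaries, name_threshold=cfg.name_threshold
        )

    mapped = None
    if crossmap is not None:
        from .mapping import mapped_codes_overlap  # local import: avoids cycle

        mapped = mapped_codes_overlap(candidate, reference, crossmap)

    return MetricReport(
        phenotype_name=candidate.phenotype_name or reference.phenotype_name,
        codes_overlap_pct=codes,
        logic_overlap_pct=logic,
        strings_overlap_pct=strings,
        hallucination_pct=hallucination,
        mapped_codes_overlap_pct=mapped,
        diagnostics=tuple(diagnostics),
    )
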