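"""Prompt construction and the pluggable response-provider contract.

The elicitation prompt asks a language model for a computational phenotype as
a five-column table (logic, vocabulary, code identifier, code name, code
count) and is rendered from a fixed template with the phenotype name
substituted verbatim.  Where responses come from is abstracted behind a tiny
provider contract — text in, text out, with a declared failure channel — so a
batch run can use live models, canned files, or synthetic responses
interchangeably.  No retry, temperature, or seeding policy is implemented for
live providers; reproducibility is delegated to canned-response fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol, runtime_checkable

from .defmodel import ParameterError, PhenotypeDefinition
from .io_formats import ParseDiagnostics, parse_llm_table

#: Elicitation template; the placeholder is replaced verbatim, unescaped.
PROMPT_TEMPLATE = (
    "Provide a computational phenotype for < INSERT_PHENOTYPE > with codes "
    "needed and their name, and logical conditions as well as how many codes "
    "are needed. In the following tabular format: Logic (inclusion or "
    "exclusion), code vocabulary, code identifier, code name, and code count."
)

_PLACEHOLDER = "< INSERT_PHENOTYPE >"


@dataclass(frozen=True)
class PromptRecord:
    """A fully rendered prompt for one phenotype."""

    phenotype_name: str
    text: str


def build_prompt(phenotype_name: str) -> PromptRecord:
    """Render the elicitation prompt for a phenotype name.

    The name is substituted verbatim (punctuation unescaped); distinct names
    yield distinct prompts.
    """
    if not phenotype_name.strip():
        raise ParameterError("phenotype name must be non-empty")
    return PromptRecord(
        phenotype_name=phenotype_name,
        text=PROMPT_TEMPLATE.replace(_PLACEHOLDER, phenotype_name),
    )


class ProviderError(Exception):
    """A response provider's declared failure channel."""


@runtime_checkable
class ResponseProvider(Protocol):
    """Contract for anything that can answer a prompt with response text."""

    name: str

    def __call__(self, prompt_text: str) -> str: ...  # may raise ProviderError


@dataclass
class CannedProvider:
    """Answers every prompt with one fixed response string (testing aid)."""

    response: str
    name: str = "canned"

    def __call__(self, prompt_text: str) -> str:
        return self.response


@dataclass
class DirectoryProvider:
    """Serves responses from ``<directory>/<slug>.txt`` files, keyed by phenotype.

    The slug is the phenotype name lowercased with non-alphanumerics collapsed
    to single underscores.  A missing file is a declared provider failure.
    """

    directory: Path
    name: str = "directory"

    def __call__(self, prompt_text: str) -> str:
        raise ProviderError(
            "DirectoryProvider needs the phenotype name; use respond_to(name)"
        )

    def respond_to(self, phenotype_name: str) -> str:
        path = Path(self.directory) / f"{slugify(phenotype_name)}.txt"
        if not path.exists():
            raise ProviderError(f"no canned response at {path}")
        return path.read_text()


def slugify(name: str) -> str:
    out = "".join(c.lower() if c.isalnum() else "_" for c in name.strip())
    while "__" in out:
        out = out.replace("__", "_")
    return out.strip("_") or "phenotype"


@dataclass
class AcquisitionResult:
    """Outcome of one acquisition: parsed candidate, raw audit copy, failure."""

    prompt: PromptRecord
    definition: PhenotypeDefinition
    raw_response: str | None
    diagnostics: ParseDiagnostics
    failure: str | None = None

    @property
    def failed(self) -> bool:
        return self.failure is not None


def acquire_candidate(
    prompt: PromptRecord,
    provider: ResponseProvider | Callable[[str], str],
) -> AcquisitionResult:
    """Obtain and parse one candidate definition from a provider.

    The raw response is kept alongside the parsed definition for audit; the
    candidate's provenance records the provider's identity.  A provider
    failure is captured as a result, never an exception, so one bad phenotype
    cannot sink a batch run.
    """
    provider_name = getattr(provider, "name", provider.__class__.__name__)
    try:
        if isinstance(provider, DirectoryProvider):
            raw = provider.respond_to(prompt.phenotype_name)
        else:
            raw = provider(prompt.text)
    except ProviderError as exc:
        empty = PhenotypeDefinition(
            phenotype_name=prompt.phenotype_name,
            rows=(),
            source="candidate",
            provenance=provider_name,
        )
        return AcquisitionResult(
            prompt=prompt,
            definition=empty,
            raw_response=None,
            diagnostics=ParseDiagnostics(no_table=True, notes=[f"provider failure: {exc}"]),
            failure=str(exc),
        )
    result = parse_llm_table(
        raw, phenotype_name=prompt.phenotype_name, provenance=provider_name
    )
    return AcquisitionResult(
        prompt=prompt,
        definition=result.definition,
        raw_response=raw,
        diagnostics=result.diagnostics,
    )
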