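"""Ontology-term and taxon-name resolution through pluggable providers.

The annotation workflow needs two lookup services: anatomy terms (for
labeling segments) and taxonomic names (for labeling the whole image).  Both
are modeled as small provider interfaces so the same search and retrieval
code runs against an offline OBO file, a recorded JSON fixture of a term web
service, or any future adapter.  The package ships a mini Plant Ontology
subset and a short taxon list so everything works with no network connection.

Terms are identified by CURIEs of the form PREFIX:digits, e.g. PO:0009066
for *anther*.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

from .errors import (
    MalformedCurieError,
    ProviderUnavailableError,
    TermNotFoundError,
)

_CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*:\d+$")
_QUOTED_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


@dataclass(frozen=True)
class OntologyTerm:
    """A resolved ontology term: CURIE, preferred name, definition, synonyms."""

    term_id: str
    name: str
    definition: str | None = None
    synonyms: tuple[str, ...] = ()
    ontology: str = ""

    def __post_init__(self):
        if not _CURIE_RE.match(self.term_id):
            raise MalformedCurieError(
                f"term id {self.term_id!r} is not a PREFIX:digits CURIE"
            )
        if not self.name:
            raise ValueError("term name must be nonempty")
        object.__setattr__(self, "synonyms", tuple(self.synonyms))
        if not self.ontology:
            object.__setattr__(self, "ontology", self.term_id.split(":")[0])


@dataclass(frozen=True)
class TaxonRecord:
    """A scientific name, optionally with an external namebank identifier."""

    name: str
    namebank_id: str | None = None
    source: str = "local-list"

    def __post_init__(self):
        if not self.name:
            raise ValueError("taxon name must be nonempty")


@runtime_checkable
class TermProvider(Protocol):
    """Anything that can enumerate terms and resolve a CURIE to a term."""

    def get(self, term_id: str) -> OntologyTerm: ...

    def terms(self) -> Iterable[OntologyTerm]: ...


@runtime_checkable
class TaxonProvider(Protocol):
    def taxa(self) -> Iterable[TaxonRecord]: ...


# ---------------------------------------------------------------------------
# Providers
# ---------------------------------------------------------------------------


def _strip_quotes(value: str) -> str:
    m = _QUOTED_RE.search(value)
    return m.group(1).replace('\\"', '"') if m else value


class OboTermProvider:
    """Terms read from a flat OBO file ([Term] stanzas; obsolete excluded)."""

    def __init__(self, path: str | Path):
        import obonet  # deferred: not needed by other providers

        path = Path(path)
        if not path.exists():
            raise ProviderUnavailableError(f"OBO file not found: {path}")
        try:
            graph = obonet.read_obo(str(path), ignore_obsolete=True)
        except Exception as exc:  # malformed file
            raise ProviderUnavailableError(f"cannot parse OBO file {path}: {exc}")
        self._terms: dict[str, OntologyTerm] = {}
        for term_id, data in graph.nodes(data=True):
            name = data.get("name")
            if not name or not _CURIE_RE.match(term_id):
                continue
            definition = data.get("def")
            synonyms = tuple(_strip_quotes(s) for s in data.get("synonym", []))
            self._terms[term_id] = OntologyTerm(
                term_id=term_id,
                name=name,
                definition=_strip_quotes(definition) if definition else None,
                synonyms=synonyms,
            )

    def get(self, term_id: str) -> OntologyTerm:
        try:
            return self._terms[term_id]
        except KeyError:
            raise TermNotFoundError(f"term {term_id} not found in ontology")

    def terms(self) -> Iterable[OntologyTerm]:
        return list(self._terms.values())


class JsonTermProvider:
    """Terms from a recorded JSON document, mimicking a term web service.

    The schema is this package's own fixture format (a list of objects with
    ``id``, ``name``, ``definition`` and ``synonyms`` keys); it exists so the
    provider contract can be exercised against a second, structurally
    different source.
    """

    def __init__(self, source: str | Path | dict):
        if isinstance(source, (str, Path)):
            path = Path(source)
            if not path.exists():
                raise ProviderUnavailableError(f"JSON fixture not found: {path}")
            source = json.loads(path.read_text())
        try:
            records = source["terms"]
        except (TypeError, KeyError):
            raise ProviderUnavailableError("JSON term document lacks a 'terms' list")
        self._terms = {
            rec["id"]: OntologyTerm(
                term_id=rec["id"],
                name=rec["name"],
                definition=rec.get("definition"),
                synonyms=tuple(rec.get("synonyms", ())),
            )
            for rec in records
        }

    def get(self, term_id: str) -> OntologyTerm:
        try:
            return self._terms[term_id]
        except KeyError:
            raise TermNotFoundError(f"term {term_id} not found in ontology")

    def terms(self) -> Iterable[OntologyTerm]:
        return list(self._terms.values())


class ListTaxonProvider:
    """Taxon names from a plain-text list (one name per line, optional id).

    Stands in for a taxonomic name-resolution service; lines are
    ``name<TAB>identifier`` with ``#`` comments ignored.
    """

    def __init__(self, path: str | Path, source_name: str = "local-list"):
        path = Path(path)
        if not path.exists():
            raise ProviderUnavailableError(f"taxon list not found: {path}")
        self._taxa: list[TaxonRecord] = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, ident = line.partition("\t")
            self._taxa.append(
                TaxonRecord(name.strip(), ident.strip() or None, source_name)
            )

    def taxa(self) -> Iterable[TaxonRecord]:
        return list(self._taxa)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def get_term(provider: TermProvider, term_id: str) -> OntologyTerm:
    """Resolve a CURIE to its full term record (name, definition, synonyms)."""
    if not _CURIE_RE.match(term_id):
        raise MalformedCurieError(
            f"term id {term_id!r} is not a PREFIX:digits CURIE"
        )
    return provider.get(term_id)


def search_terms(provider: TermProvider, prefix: str, limit: int = 10) -> list[OntologyTerm]:
    """Autocomplete: terms whose name or a synonym starts with ``prefix``.

    Matching is case-insensitive.  Results are ordered by (name length,
    name, id), except that an exact name match always comes first.  At most
    ``limit`` entries are returned; no match yields an empty list, which is
    distinct from a provider error.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    needle = prefix.lower()
    hits = [
        t
        for t in provider.terms()
        if t.name.lower().startswith(needle)
        or any(s.lower().startswith(needle) for s in t.synonyms)
    ]
    hits.sort(key=lambda t: (t.name.lower() != needle, len(t.name), t.name.lower(), t.term_id))
    return hits[:limit]


def search_taxa(provider: TaxonProvider, query: str, limit: int | None = None) -> list[TaxonRecord]:
    """Case-insensitive substring search over the provider's name list."""
    if not query:
        raise ValueError("taxon query must be nonempty")
    needle = query.lower()
    hits = [t for t in provider.taxa() if needle in t.name.lower()]
    hits.sort(key=lambda t: (len(t.name), t.name))
    return hits[:limit] if limit is not None else hits


# ---------------------------------------------------------------------------
# Packaged offline fixtures
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(resources.files("segont").joinpath("data", name))  # type: ignore[arg-type]


def mini_plant_ontology() -> OboTermProvider:
    """The packaged mini Plant Ontology subset (floral + vegetative anatomy)."""
    return OboTermProvider(_data_path("mini_plant_ontology.obo"))


def mini_term_service() -> JsonTermProvider:
    """The same subset served from the recorded JSON fixture."""
    return JsonTermProvider(_data_path("po_service_fixture.json"))


def mini_taxon_list() -> ListTaxonProvider:
    """The packaged taxon name list."""
    return ListTaxonProvider(_data_path("taxa.txt"))
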