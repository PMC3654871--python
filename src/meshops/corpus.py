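"""Annotated article corpus and entity definitions.

The corpus format is JSON-lines, one article per line::

    {"article_id": "a1", "year": 1999, "terms": ["T1", "T2"]}

The on-disk term list is the raw curator-assigned annotation.  Propagation
to ancestor terms — an article annotated with a term counts as annotated
with every ancestor of that term — is a method step applied at load time;
raw terms are retained so a corpus can be written back losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import IntegrityError, ParseError
from .tree import TermTree

__all__ = [
    "Article",
    "Corpus",
    "CorpusLoadReport",
    "Entity",
    "EntitySet",
    "load_corpus",
    "write_corpus",
    "load_entities",
    "write_entities",
    "bibliography",
    "filter_by_year",
]


@dataclass
class Article:
    article_id: str
    year: int
    terms: frozenset[str]       # ancestor-closed annotation
    raw_terms: tuple[str, ...]  # curator-assigned annotation, file order


@dataclass
class CorpusLoadReport:
    n_articles: int = 0
    unknown_terms: set[str] = field(default_factory=set)  # annotations absent from the tree


@dataclass
class Corpus:
    """Dated articles with propagated annotations and a per-term index."""

    articles: list[Article]
    term_index: dict[str, set[str]]
    report: CorpusLoadReport = field(default_factory=CorpusLoadReport)

    @property
    def n_articles(self) -> int:
        return len(self.articles)

    def article_ids(self) -> set[str]:
        return {a.article_id for a in self.articles}


@dataclass(frozen=True)
class Entity:
    entity_id: str
    entity_class: str  # "drug" or "disease"
    defining_term: str


@dataclass
class EntitySet:
    entities: list[Entity]

    def __iter__(self):
        return iter(self.entities)

    def __len__(self) -> int:
        return len(self.entities)

    def of_class(self, entity_class: str) -> list[Entity]:
        return [e for e in self.entities if e.entity_class == entity_class]

    def get(self, entity_id: str) -> Entity:
        for e in self.entities:
            if e.entity_id == entity_id:
                return e
        raise KeyError(f"unknown entity: {entity_id!r}")


def _index(articles: list[Article]) -> dict[str, set[str]]:
    idx: dict[str, set[str]] = {}
    for art in articles:
        for t in art.terms:
            idx.setdefault(t, set()).add(art.article_id)
    return idx


def load_corpus(path: str | Path, tree: TermTree) -> Corpus:
    """Read a JSON-lines corpus and propagate annotations through the tree.

    Duplicate article ids raise :class:`IntegrityError`.  Annotations absent
    from the tree are legal (they stand in for supplementary concepts that
    sit outside the hierarchy): they are kept but contribute no ancestors,
    and are recorded in the load report.
    """
    articles: list[Article] = []
    seen: set[str] = set()
    unknown: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                article_id = str(obj["article_id"])
                year = int(obj["year"])
                raw_terms = tuple(str(t) for t in obj["terms"])
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if year <= 0 or year > 9999:
                raise ParseError(f"{path}: line {lineno}: invalid year {year}")
            if article_id in seen:
                raise IntegrityError(f"{path}: duplicate article_id {article_id!r}")
            seen.add(article_id)
            unknown.update(t for t in raw_terms if t not in tree)
            closed = frozenset(tree.propagate(set(raw_terms)))
            articles.append(
                Article(article_id=article_id, year=year, terms=closed, raw_terms=raw_terms)
            )
    report = CorpusLoadReport(n_articles=len(articles), unknown_terms=unknown)
    return Corpus(articles=articles, term_index=_index(articles), report=report)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write the corpus back as JSON-lines using the raw (pre-propagation) terms."""
    with open(path, "w", encoding="utf-8") as fh:
        for art in corpus.articles:
            fh.write(
                json.dumps(
                    {
                        "article_id": art.article_id,
                        "year": art.year,
                        "terms": list(art.raw_terms),
                    }
                )
                + "\n"
            )


def load_entities(path: str | Path, tree: TermTree | None = None) -> EntitySet:
    """Read the entity TSV (``entity_id  class  defining_term``, header required)."""
    entities: list[Entity] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["entity_id", "class", "defining_term"]:
            raise ParseError(f"{path}: line 1: expected header 'entity_id\\tclass\\tdefining_term'")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            entity_id, entity_class, defining_term = parts
            if entity_class not in ("drug", "disease"):
                raise ParseError(f"{path}: line {lineno}: unknown class {entity_class!r}")
            if entity_id in seen:
                raise IntegrityError(f"{path}: duplicate entity_id {entity_id!r}")
            if tree is not None and defining_term not in tree:
                raise IntegrityError(
                    f"{path}: line {lineno}: defining_term {defining_term!r} not in tree"
                )
            seen.add(entity_id)
            entities.append(Entity(entity_id, entity_class, defining_term))
    return EntitySet(entities)


def write_entities(entities: EntitySet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity_id\tclass\tdefining_term\n")
        for e in entities:
            fh.write(f"{e.entity_id}\t{e.entity_class}\t{e.defining_term}\n")


def bibliography(corpus: Corpus, entity: Entity) -> set[str]:
    """All article ids indexed under the entity's defining term.

    No year filtering happens here; temporal cuts belong to validation.
    An unindexed defining term yields the empty set.
    """
    return set(corpus.term_index.get(entity.defining_term, set()))


def filter_by_year(corpus: Corpus, year_max: int) -> Corpus:
    """Restrict the corpus to articles published in or before ``year_max``."""
    kept = [a for a in corpus.articles if a.year <= year_max]
    return Corpus(articles=kept, term_index=_index(kept),
                  report=CorpusLoadReport(n_articles=len(kept),
                                          unknown_terms=set(corpus.report.unknown_terms)))
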