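"""Controlled-vocabulary tree with dot-delimited tree numbers.

A vocabulary term may occupy several positions in the hierarchy; each
position is addressed by a tree number such as ``C04.557.337``.  Parenthood
is defined positionally: the parent position of a tree number is obtained by
dropping its final dot-delimited segment.  A term's ancestors are the union,
over all of its tree numbers, of the terms owning every proper prefix
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParseError

__all__ = ["TermTree", "TreeLoadReport", "load_tree", "ancestors"]


@dataclass
class TreeLoadReport:
    """Bookkeeping emitted by :func:`load_tree`.

    dangling_prefixes are prefix positions encountered while walking up a
    tree number for which no term owns the position; they break the ancestor
    chain silently (the walk continues past them).
    """

    n_terms: int = 0
    n_tree_numbers: int = 0
    dangling_prefixes: set[str] = field(default_factory=set)


@dataclass
class TermTree:
    """Vocabulary terms, their tree numbers, and the ancestor closure.

    Attributes
    ----------
    entries:
        term-id -> set of tree numbers owned by the term.
    closure:
        term-id -> set of strict ancestor term-ids (the term itself is
        excluded).  Transitively closed and acyclic by construction.
    report:
        Load bookkeeping (dangling prefixes etc.).
    """

    entries: dict[str, set[str]]
    closure: dict[str, set[str]]
    report: TreeLoadReport = field(default_factory=TreeLoadReport)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.entries

    def ancestors(self, term_id: str) -> set[str]:
        """Strict ancestors of ``term_id``; raises ``KeyError`` if unknown."""
        if term_id not in self.closure:
            raise KeyError(f"unknown term: {term_id!r}")
        return set(self.closure[term_id])

    def propagate(self, terms: set[str]) -> set[str]:
        """Close a term set under the ancestor relation.

        Terms absent from the tree are kept as-is and contribute no
        ancestors.  Idempotent.
        """
        out = set(terms)
        for t in terms:
            anc = self.closure.get(t)
            if anc:
                out |= anc
        return out


def _compute_closure(entries: dict[str, set[str]]) -> tuple[dict[str, set[str]], set[str]]:
    """Build the transitive ancestor closure from tree-number prefixes.

    Returns (closure, dangling prefix positions).  Because a prefix position
    always has strictly fewer segments than the child position, the relation
    is acyclic and the prefix walk itself yields the full closure.
    """
    owner: dict[str, set[str]] = {}
    for term, numbers in entries.items():
        for num in numbers:
            owner.setdefault(num, set()).add(term)

    closure: dict[str, set[str]] = {t: set() for t in entries}
    dangling: set[str] = set()
    for term, numbers in entries.items():
        anc = closure[term]
        for num in numbers:
            segments = num.split(".")
            for cut in range(len(segments) - 1, 0, -1):
                prefix = ".".join(segments[:cut])
                owners = owner.get(prefix)
                if owners:
                    anc.update(o for o in owners if o != term)
                else:
                    dangling.add(prefix)
    return closure, dangling


def load_tree(path: str | Path) -> TermTree:
    """Read a two-column TSV (``term_id<TAB>tree_number``) into a TermTree.

    A term may appear on multiple lines (one per tree position).  Prefix
    positions owned by no term are skipped silently but recorded in the load
    report.  A line with the wrong column count raises :class:`ParseError`
    naming the line number.
    """
    entries: dict[str, set[str]] = {}
    n_numbers = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            term, number = parts
            entries.setdefault(term, set()).add(number)
            n_numbers += 1

    closure, dangling = _compute_closure(entries)
    report = TreeLoadReport(
        n_terms=len(entries), n_tree_numbers=n_numbers, dangling_prefixes=dangling
    )
    return TermTree(entries=entries, closure=closure, report=report)


def ancestors(tree: TermTree, term_id: str) -> set[str]:
    """Module-level convenience wrapper over :meth:`TermTree.ancestors`."""
    return tree.ancestors(term_id)
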