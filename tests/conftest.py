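"""Shared fixtures: tiny hand-built vocabularies, corpora and profiles."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest

from meshops import Profile, load_corpus, load_entities, load_tree


def write_tree(path, rows):
    with open(path, "w", encoding="utf-8") as fh:
        for term, number in rows:
            fh.write(f"{term}\t{number}\n")
    return path


def write_corpus_file(path, articles):
    with open(path, "w", encoding="utf-8") as fh:
        for art in articles:
            fh.write(json.dumps(art) + "\n")
    return path


def write_entities_file(path, rows):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity_id\tclass\tdefining_term\n")
        for eid, cls, term in rows:
            fh.write(f"{eid}\t{cls}\t{term}\n")
    return path


@pytest.fixture
def chain_tree(tmp_path):
    """Three-term chain X > Y > Z."""
    return load_tree(
        write_tree(tmp_path / "tree.tsv", [("X", "A01"), ("Y", "A01.200"), ("Z", "A01.200.300")])
    )


@pytest.fixture
def chain_corpus(tmp_path, chain_tree):
    """Three articles annotated {Z}, {Y}, {X}: counts 3/2/1 after closure."""
    path = write_corpus_file(
        tmp_path / "corpus.jsonl",
        [
            {"article_id": "a1", "year": 2001, "terms": ["Z"]},
            {"article_id": "a2", "year": 2002, "terms": ["Y"]},
            {"article_id": "a3", "year": 2003, "terms": ["X"]},
        ],
    )
    return load_corpus(path, chain_tree)


def make_profile(entity_id, rows, n_articles, background_kind="universal"):
    """Hand-build a Profile from (term, count, fraction, p, weight) tuples."""
    df = pd.DataFrame(rows, columns=["term_id", "count", "fraction", "p_value", "weight"])
    df = df.sort_values(["p_value", "term_id"], kind="mergesort", ignore_index=True)
    return Profile(
        entity_id=entity_id, n_articles=n_articles, entries=df, background_kind=background_kind
    )


def random_profile(rng: np.random.Generator, entity_id: str, vocab: list[str],
                   n_terms: int | None = None) -> Profile:
    """Random but internally consistent profile over a subset of vocab."""
    if n_terms is None:
        n_terms = int(rng.integers(2, max(3, len(vocab) // 2)))
    terms = sorted(rng.choice(vocab, size=n_terms, replace=False))
    n = int(rng.integers(n_terms, 4 * n_terms))
    rows = []
    for t in terms:
        k = int(rng.integers(1, n + 1))
        p = float(rng.uniform(1e-12, 1.0))
        w = float(rng.uniform(0.0, 3.0))
        rows.append((t, k, k / n, p, w))
    return make_profile(entity_id, rows, n)
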