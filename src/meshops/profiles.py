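"""Per-entity term over-representation profiles.

A profile summarizes an entity's bibliography (the articles indexed under
its defining term) as a vector of tuples, one per distinct term observed in
the bibliography: the term count ``k``, the fraction ``f = k/n`` of the
``n`` bibliography articles carrying the term, a one-sided hypergeometric
enrichment p-value against a background article set, and a tf-idf weight.

The enrichment p-value for a term seen ``k`` times in a bibliography of
size ``n``, against a background of ``N`` articles of which ``K`` carry the
term, is the upper tail ``P(X >= k)`` of the hypergeometric distribution —
equivalently the one-sided Fisher exact test on the 2x2 contingency table.
Only over-representation is scored; depletion is not of interest here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .corpus import Corpus, Entity, EntitySet, bibliography
from .errors import ConfigurationError, ProfileError

__all__ = [
    "Background",
    "Profile",
    "P_FLOOR",
    "background_counts",
    "hypergeom_upper_tail",
    "hypergeom_upper_tail_grid",
    "build_profile",
    "build_profiles",
    "annotation_level",
    "write_profiles",
    "read_profiles",
]

# p-values are clamped here before any downstream logarithm: at literature
# scale upper tails underflow double precision and log(0) must never occur.
P_FLOOR = 1e-300


@dataclass
class Background:
    """Term counts over a background article set.

    kind is "universal" (all corpus articles) or "class-specific" (only
    articles linked to at least one entity of one class).
    """

    term_counts: dict[str, int]
    n_total: int
    kind: str = "universal"


@dataclass
class Profile:
    """Over-representation profile for one entity.

    entries columns: term_id, count, fraction, p_value, weight; rows sorted
    by ascending p_value then term_id.  Every term observed at least once in
    the bibliography is present — no significance cutoff is applied, since
    downstream similarity metrics need the full vectors.
    """

    entity_id: str
    n_articles: int
    entries: pd.DataFrame
    background_kind: str = "universal"

    def term_set(self) -> set[str]:
        return set(self.entries["term_id"])

    def as_dict(self) -> dict[str, tuple[int, float, float, float]]:
        """term_id -> (count, fraction, p_value, weight) for metric computation."""
        cached = getattr(self, "_dict_cache", None)
        if cached is None:
            e = self.entries
            cached = {
                t: (int(k), float(f), float(p), float(w))
                for t, k, f, p, w in zip(
                    e["term_id"], e["count"], e["fraction"], e["p_value"], e["weight"]
                )
            }
            object.__setattr__(self, "_dict_cache", cached)
        return cached


def background_counts(
    corpus: Corpus, subset: set[str] | None = None, kind: str = "universal"
) -> Background:
    """Count per-term article totals over the corpus or an article-id subset."""
    if subset is None:
        n_total = corpus.n_articles
        counts = {t: len(ids) for t, ids in corpus.term_index.items()}
    else:
        ids_all = corpus.article_ids()
        if not subset <= ids_all:
            raise ConfigurationError("background subset contains unknown article ids")
        n_total = len(subset)
        counts = {}
        for t, ids in corpus.term_index.items():
            c = len(ids & subset)
            if c:
                counts[t] = c
    if n_total == 0:
        raise ConfigurationError("empty background")
    return Background(term_counts=counts, n_total=n_total, kind=kind)


def class_background(corpus: Corpus, entities: EntitySet, entity_class: str) -> Background:
    """Class-specific background: articles indexed under >=1 entity of the class."""
    subset: set[str] = set()
    for e in entities.of_class(entity_class):
        subset |= corpus.term_index.get(e.defining_term, set())
    return background_counts(corpus, subset=subset, kind="class-specific")


def _log_binom(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _log_pmf(js: np.ndarray, n: int, K: int, N: int) -> np.ndarray:
    """log P(X = j) for X ~ Hypergeometric(N total, K marked, n drawn)."""
    return _log_binom(K, js) + _log_binom(N - K, n - js) - _log_binom(N, n)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail ``P(X >= k)`` for X ~ Hypergeometric(N total, K marked, n drawn).

    Summed in log space for stability; the result is clamped to
    ``[P_FLOOR, 1]`` so downstream logarithms are always finite.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"invalid hypergeometric margins k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    hi = min(n, K)
    js = np.arange(k, hi + 1)
    logp = logsumexp(_log_pmf(js, n, K, N))
    return float(min(1.0, max(P_FLOOR, np.exp(logp))))


def hypergeom_upper_tail_grid(n: int, K: int, N: int) -> np.ndarray:
    """Upper tails for every k = 0 .. min(n, K) at once.

    Same log-space pmf basis as :func:`hypergeom_upper_tail`, accumulated
    from the top with logaddexp so each entry is the tail sum.  Used where
    many counts share the same margins.
    """
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric margins n={n} K={K} N={N}")
    hi = min(n, K)
    logp = _log_pmf(np.arange(hi + 1), n, K, N)
    tail = np.logaddexp.accumulate(logp[::-1])[::-1]
    out = np.minimum(1.0, np.maximum(P_FLOOR, np.exp(tail)))
    out[0] = 1.0
    return out


def _upper_tail_vector(ks: np.ndarray, n: int, Ks: np.ndarray, N: int) -> np.ndarray:
    """Vectorized upper tails for many terms sharing n and N.

    Same log-space summation as :func:`hypergeom_upper_tail`, evaluated per
    term; used by profile construction.
    """
    out = np.empty(len(ks))
    for i, (k, K) in enumerate(zip(ks, Ks)):
        out[i] = hypergeom_upper_tail(int(k), n, int(K), N)
    return out


def build_profile(corpus: Corpus, entity: Entity, background: Background) -> Profile:
    """Build the over-representation profile of one entity.

    Every term appearing in the bibliography gets a row.  The tf-idf weight
    is ``f * ln(N / K)`` with K the background article count of the term
    (bibliography-relative term frequency times background-relative inverse
    document frequency).  The bibliography's own articles stay inside the
    background counts — no leave-self-out.
    """
    bib = bibliography(corpus, entity)
    if not bib:
        raise ProfileError(f"entity {entity.entity_id!r} has an empty bibliography")
    n = len(bib)
    N = background.n_total
    counts: dict[str, int] = {}
    for art in corpus.articles:
        if art.article_id in bib:
            for t in art.terms:
                counts[t] = counts.get(t, 0) + 1

    terms = sorted(counts)
    ks = np.array([counts[t] for t in terms], dtype=int)
    Ks = np.array([background.term_counts.get(t, 0) for t in terms], dtype=int)
    if np.any(Ks < ks):
        raise ConfigurationError(
            f"entity {entity.entity_id!r}: bibliography term count exceeds background count "
            "(bibliography not contained in background?)"
        )
    ps = _upper_tail_vector(ks, n, Ks, N)
    fs = ks / n
    with np.errstate(divide="ignore"):
        idf = np.log(N / np.maximum(Ks, 1))
    ws = fs * idf

    df = pd.DataFrame(
        {"term_id": terms, "count": ks, "fraction": fs, "p_value": ps, "weight": ws}
    ).sort_values(["p_value", "term_id"], kind="mergesort", ignore_index=True)
    return Profile(
        entity_id=entity.entity_id, n_articles=n, entries=df, background_kind=background.kind
    )


def build_profiles(
    corpus: Corpus, entities: EntitySet | list[Entity], background: Background
) -> tuple[dict[str, Profile], list[str]]:
    """Build profiles for many entities; returns (profiles, skipped entity ids).

    Entities with empty bibliographies are skipped and reported, matching
    the pipeline convention of skip-and-report.
    """
    profiles: dict[str, Profile] = {}
    skipped: list[str] = []
    for e in entities:
        try:
            profiles[e.entity_id] = build_profile(corpus, e, background)
        except ProfileError:
            skipped.append(e.entity_id)
    return profiles, skipped


def annotation_level(profile: Profile) -> int:
    """Number of distinct terms in the profile — the bias covariate."""
    return len(profile.entries)


def write_profiles(profiles: dict[str, Profile] | list[Profile], path: str | Path) -> None:
    """Write profiles as a long TSV, deterministic row order."""
    if isinstance(profiles, dict):
        profiles = [profiles[k] for k in sorted(profiles)]
    frames = []
    for p in profiles:
        df = p.entries.copy()
        df.insert(0, "entity_id", p.entity_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["entity_id", "term_id", "count", "fraction", "p_value", "weight"]
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_profiles(path: str | Path, background_kind: str = "universal") -> dict[str, Profile]:
    """Read profiles written by :func:`write_profiles`.

    The bibliography size n is recovered from the defining-term row
    invariant f = k/n (max count/fraction ratio is exact for the row with
    fraction 1; any row reproduces it up to rounding)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, Profile] = {}
    for eid, sub in df.groupby("entity_id", sort=True):
        sub = sub.drop(columns=["entity_id"]).reset_index(drop=True)
        n = int(round((sub["count"] / sub["fraction"]).iloc[0]))
        out[str(eid)] = Profile(
            entity_id=str(eid), n_articles=n, entries=sub, background_kind=background_kind
        )
    return out
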