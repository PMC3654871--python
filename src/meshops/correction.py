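"""Empirical-significance correction for literature-annotation bias.

Heavily annotated entities receive systematically more extreme raw
similarity scores regardless of genuine relatedness.  The correction
replaces a pair's raw score by its empirical significance conditional on
both entities' annotation levels: among all pairs formed between the drug's
annotation-level peers and the disease's annotation-level peers, the
fraction whose raw score is strictly more extreme than the query pair's.

Peers are the same-class entities within +/- half_width percentile (default
5, i.e. a 10%-of-the-class window) of the query entity's annotation-level
percentile.  Percentiles use mid-ranks, so tied levels share a percentile;
windows are truncated at 0 and 100 without widening.  The query pair stays
in its own pool and add-one smoothing is applied, so corrected values lie
in (0, 1]; smaller means more unexpectedly similar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import CorrectionError
from .profiles import Profile, annotation_level
from .similarity import ScoreMatrix

__all__ = [
    "AnnotationIndex",
    "CorrectedMatrix",
    "annotation_index",
    "peer_set",
    "corrected_score",
    "corrected_matrix",
]

DEFAULT_HALF_WIDTH = 5.0


@dataclass
class AnnotationIndex:
    """Annotation levels and their mid-rank percentiles for one entity class."""

    levels: dict[str, int]
    percentile: dict[str, float]

    @classmethod
    def from_levels(cls, levels: dict[str, int]) -> "AnnotationIndex":
        ids = sorted(levels)
        vals = np.array([levels[i] for i in ids], dtype=float)
        # mid-rank percentile in (0, 100): ties share a value, and the
        # percentile is non-decreasing in the level
        ranks = rankdata(vals, method="average")
        pct = 100.0 * (ranks - 0.5) / len(ids)
        return cls(levels=dict(levels), percentile={i: float(p) for i, p in zip(ids, pct)})

    @classmethod
    def from_profiles(cls, profiles: dict[str, Profile] | list[Profile]) -> "AnnotationIndex":
        if isinstance(profiles, dict):
            profiles = list(profiles.values())
        return cls.from_levels({p.entity_id: annotation_level(p) for p in profiles})


def annotation_index(profiles: dict[str, Profile] | list[Profile]) -> AnnotationIndex:
    return AnnotationIndex.from_profiles(profiles)


def peer_set(index: AnnotationIndex, entity: str, half_width: float = DEFAULT_HALF_WIDTH) -> set[str]:
    """Same-class entities whose percentile lies within +/- half_width of the query's.

    The window is truncated at [0, 100] (no wrap-around, no widening); the
    query entity always belongs to its own peer set.
    """
    if entity not in index.percentile:
        raise KeyError(f"unknown entity: {entity!r}")
    if not (0.0 < half_width <= 50.0):
        raise ValueError("half_width must be in (0, 50]")
    p = index.percentile[entity]
    lo = max(0.0, p - half_width)
    hi = min(100.0, p + half_width)
    return {e for e, q in index.percentile.items() if lo <= q <= hi}


def _more_extreme_count(pool: np.ndarray, x: float, higher_is_similar: bool) -> int:
    if higher_is_similar:
        return int(np.sum(pool > x))
    return int(np.sum(pool < x))


def corrected_score(
    scores: ScoreMatrix,
    index_drugs: AnnotationIndex,
    index_diseases: AnnotationIndex,
    drug: str,
    disease: str,
    half_width: float = DEFAULT_HALF_WIDTH,
) -> float:
    """Empirical significance of one pair against its annotation-level peers.

    Returns (1 + #{pool scores strictly more extreme}) / (1 + pool size);
    "more extreme" follows the metric's polarity, on the magnitude for
    signed metrics.
    """
    dpeers = sorted(peer_set(index_drugs, drug, half_width))
    speers = sorted(peer_set(index_diseases, disease, half_width))
    di = [scores._drug_pos[d] for d in dpeers if d in scores._drug_pos]
    sj = [scores._disease_pos[s] for s in speers if s in scores._disease_pos]
    if not di or not sj:
        raise CorrectionError("empty peer score pool")
    oriented = scores.metric.oriented(scores.values)
    pool = oriented[np.ix_(di, sj)].ravel()
    x = float(scores.metric.oriented(np.array([scores.value(drug, disease)]))[0])
    more = _more_extreme_count(pool, x, True)
    return (1 + more) / (1 + pool.size)


@dataclass
class CorrectedMatrix:
    """Corrected (empirical-significance) scores on the same axes as the source."""

    drugs: list[str]
    diseases: list[str]
    metric_id: str
    values: np.ndarray  # in (0, 1]; smaller = more unexpectedly similar
    window_half_width: float
    n_pool: np.ndarray  # peer-pair pool size per cell


def corrected_matrix(
    scores: ScoreMatrix,
    index_drugs: AnnotationIndex,
    index_diseases: AnnotationIndex,
    half_width: float = DEFAULT_HALF_WIDTH,
) -> CorrectedMatrix:
    """Elementwise empirical significance over the whole matrix.

    Peer sets are cached per entity and pools per (drug-window,
    disease-window) pair; counting uses a sorted pool with binary search, so
    the result is exactly the double-loop count.
    """
    oriented = scores.metric.oriented(scores.values)
    n_drugs, n_diseases = oriented.shape

    drug_peer_idx: list[tuple[int, ...]] = []
    for d in scores.drugs:
        peers = peer_set(index_drugs, d, half_width)
        drug_peer_idx.append(
            tuple(sorted(scores._drug_pos[p] for p in peers if p in scores._drug_pos))
        )
    disease_peer_idx: list[tuple[int, ...]] = []
    for s in scores.diseases:
        peers = peer_set(index_diseases, s, half_width)
        disease_peer_idx.append(
            tuple(sorted(scores._disease_pos[p] for p in peers if p in scores._disease_pos))
        )

    pools: dict[tuple[tuple[int, ...], tuple[int, ...]], np.ndarray] = {}
    values = np.empty_like(oriented)
    n_pool = np.empty(oriented.shape, dtype=int)
    for i in range(n_drugs):
        di = drug_peer_idx[i]
        for j in range(n_diseases):
            sj = disease_peer_idx[j]
            key = (di, sj)
            pool = pools.get(key)
            if pool is None:
                pool = np.sort(oriented[np.ix_(di, sj)], axis=None)
                pools[key] = pool
            x = oriented[i, j]
            more = pool.size - int(np.searchsorted(pool, x, side="right"))
            values[i, j] = (1 + more) / (1 + pool.size)
            n_pool[i, j] = pool.size
    return CorrectedMatrix(
        drugs=list(scores.drugs),
        diseases=list(scores.diseases),
        metric_id=scores.metric.metric_id,
        values=values,
        window_half_width=half_width,
        n_pool=n_pool,
    )
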