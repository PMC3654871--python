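"""Label construction and ROC evaluation for candidate drug-disease pairs.

Two labelings are supported.  The temporal split treats pairs first
co-mentioned in an article after a cutoff year as positives, pairs already
co-mentioned at or before the cutoff as excluded (they were not novel), and
everything else as negative.  The reference-collection labeling takes a
curated pair list as positives, again excluding pre-cutoff co-occurrences.
AUC uses the rank-sum (Mann-Whitney) formulation with average ranks for
ties — the counting baselines are integer-valued and hence tie-heavy, so
tie handling materially affects their AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .corpus import Corpus, EntitySet
from .correction import AnnotationIndex, DEFAULT_HALF_WIDTH, annotation_index, corrected_matrix
from .errors import EvaluationError, LabelingError
from .profiles import Profile
from .similarity import METRICS, MetricSpec, ScoreMatrix, score_matrix

__all__ = [
    "LabelSet",
    "cooccurring_pairs",
    "temporal_labels",
    "reference_labels",
    "roc_auc",
    "metric_panel_auc",
    "annotation_correlation",
]

POSITIVE = "positive"
NEGATIVE = "negative"
EXCLUDED = "excluded"


@dataclass
class LabelSet:
    """Per-pair {positive, negative, excluded} assignment over a full grid."""

    labels: dict[tuple[str, str], str]
    provenance: str  # "future-cooccurrence" or "reference-collection"

    def counts(self) -> dict[str, int]:
        out = {POSITIVE: 0, NEGATIVE: 0, EXCLUDED: 0}
        for v in self.labels.values():
            out[v] += 1
        return out


def cooccurring_pairs(
    corpus: Corpus, entities: EntitySet, year_max: int | None = None
) -> set[tuple[str, str]]:
    """All (drug, disease) pairs co-mentioned by some article up to year_max.

    Co-occurrence is read off the propagated term sets: an article indexed
    under a descendant of a defining term counts as mentioning the entity,
    consistent with how bibliographies are formed.
    """
    drug_by_term: dict[str, list[str]] = {}
    for e in entities.of_class("drug"):
        drug_by_term.setdefault(e.defining_term, []).append(e.entity_id)
    disease_by_term: dict[str, list[str]] = {}
    for e in entities.of_class("disease"):
        disease_by_term.setdefault(e.defining_term, []).append(e.entity_id)

    pairs: set[tuple[str, str]] = set()
    for art in corpus.articles:
        if year_max is not None and art.year > year_max:
            continue
        drugs = [d for t in art.terms if t in drug_by_term for d in drug_by_term[t]]
        if not drugs:
            continue
        diseases = [s for t in art.terms if t in disease_by_term for s in disease_by_term[t]]
        for d in drugs:
            for s in diseases:
                pairs.add((d, s))
    return pairs


def _full_grid(entities: EntitySet) -> list[tuple[str, str]]:
    drugs = [e.entity_id for e in entities.of_class("drug")]
    diseases = [e.entity_id for e in entities.of_class("disease")]
    return [(d, s) for d in drugs for s in diseases]


def temporal_labels(corpus: Corpus, entities: EntitySet, cutoff_year: int) -> LabelSet:
    """Label the drug x disease grid by first-co-occurrence time."""
    if not any(a.year > cutoff_year for a in corpus.articles):
        raise LabelingError(f"no article after cutoff year {cutoff_year}")
    before = cooccurring_pairs(corpus, entities, year_max=cutoff_year)
    ever = cooccurring_pairs(corpus, entities, year_max=None)
    labels: dict[tuple[str, str], str] = {}
    for pair in _full_grid(entities):
        if pair in before:
            labels[pair] = EXCLUDED
        elif pair in ever:
            labels[pair] = POSITIVE
        else:
            labels[pair] = NEGATIVE
    return LabelSet(labels=labels, provenance="future-cooccurrence")


def read_reference_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV of (drug_id, disease_id); a header row is auto-detected."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LabelingError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and parts[0].lower() in ("drug_id", "drug"):
                continue
            pairs.append((parts[0], parts[1]))
    return pairs


def reference_labels(
    pairs_file: str | Path, entities: EntitySet, corpus: Corpus, cutoff_year: int
) -> tuple[LabelSet, list[tuple[str, str]]]:
    """Label the grid from a curated pair list; returns (labels, unresolvable rows).

    Listed pairs whose ids resolve become positives; pairs co-occurring at
    or before the cutoff are excluded even when listed (they were not
    novel); everything else is negative.
    """
    listed = read_reference_pairs(pairs_file)
    drugs = {e.entity_id for e in entities.of_class("drug")}
    diseases = {e.entity_id for e in entities.of_class("disease")}
    resolvable = [(d, s) for d, s in listed if d in drugs and s in diseases]
    skipped = [(d, s) for d, s in listed if not (d in drugs and s in diseases)]
    if not resolvable:
        raise LabelingError(f"{pairs_file}: no resolvable reference pairs")
    before = cooccurring_pairs(corpus, entities, year_max=cutoff_year)
    positives = set(resolvable)
    labels: dict[tuple[str, str], str] = {}
    for pair in _full_grid(entities):
        if pair in before:
            labels[pair] = EXCLUDED
        elif pair in positives:
            labels[pair] = POSITIVE
        else:
            labels[pair] = NEGATIVE
    return LabelSet(labels=labels, provenance="reference-collection"), skipped


def roc_auc(scores: ScoreMatrix, labels: LabelSet, polarity: str | None = None) -> float:
    """AUC by the rank-sum formulation, average ranks for ties.

    Scores are first oriented so "more similar" is numerically higher,
    following the metric's registered polarity (overridable via
    ``polarity``); excluded pairs never enter the computation.
    """
    metric = scores.metric
    if polarity is not None:
        metric = MetricSpec(metric.metric_id, polarity, metric.domain, metric.use_magnitude)
    oriented = metric.oriented(scores.values)
    ys, xs = [], []
    for i, d in enumerate(scores.drugs):
        for j, s in enumerate(scores.diseases):
            lab = labels.labels[(d, s)]
            if lab == EXCLUDED:
                continue
            ys.append(1 if lab == POSITIVE else 0)
            xs.append(oriented[i, j])
    y = np.array(ys)
    x = np.array(xs, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("need at least one positive and one negative pair")
    ranks = rankdata(x, method="average")
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def metric_panel_auc(
    drug_profiles: dict[str, Profile] | list[Profile],
    disease_profiles: dict[str, Profile] | list[Profile],
    labels: LabelSet,
    metrics: list[MetricSpec | str] | None = None,
    with_correction: bool = False,
    correction_base: str = "l2_logp_overlap",
    half_width: float = DEFAULT_HALF_WIDTH,
) -> pd.DataFrame:
    """One AUC row per metric; optionally adds the corrected variant of one metric.

    Columns: metric_id, auc (registry polarity), auc_auto_oriented
    (max(auc, 1-auc)), n_pos, n_neg, n_excluded.
    """
    if metrics is None:
        metrics = list(METRICS.values())
    counts = labels.counts()
    rows = []
    cached: dict[str, ScoreMatrix] = {}
    for m in metrics:
        spec = METRICS[m] if isinstance(m, str) else m
        sm = score_matrix(spec, drug_profiles, disease_profiles)
        cached[spec.metric_id] = sm
        auc = roc_auc(sm, labels)
        rows.append((spec.metric_id, auc, max(auc, 1 - auc),
                     counts[POSITIVE], counts[NEGATIVE], counts[EXCLUDED]))
    if with_correction:
        base = cached.get(correction_base) or score_matrix(
            correction_base, drug_profiles, disease_profiles
        )
        cm = corrected_matrix(
            base,
            annotation_index(drug_profiles),
            annotation_index(disease_profiles),
            half_width,
        )
        # corrected values are empirical p-values: smaller = more similar
        corr_sm = ScoreMatrix(
            drugs=cm.drugs,
            diseases=cm.diseases,
            metric=MetricSpec(f"corrected_{correction_base}", "lower-is-similar", "all-terms"),
            values=cm.values,
        )
        auc = roc_auc(corr_sm, labels)
        rows.append((corr_sm.metric.metric_id, auc, max(auc, 1 - auc),
                     counts[POSITIVE], counts[NEGATIVE], counts[EXCLUDED]))
    return pd.DataFrame(
        rows, columns=["metric_id", "auc", "auc_auto_oriented", "n_pos", "n_neg", "n_excluded"]
    )


def annotation_correlation(
    scores: ScoreMatrix,
    index: AnnotationIndex,
    axis: str,
    labels: LabelSet | None = None,
) -> float:
    """Pearson correlation between pair scores and one side's annotation level.

    ``axis`` selects whether each pair contributes its drug's or its
    disease's annotation level.  When a label set is given, excluded pairs
    are dropped.  Raises on zero variance (correlation undefined).
    """
    if axis not in ("drug", "disease"):
        raise ValueError("axis must be 'drug' or 'disease'")
    xs, ls = [], []
    for i, d in enumerate(scores.drugs):
        for j, s in enumerate(scores.diseases):
            if labels is not None and labels.labels[(d, s)] == EXCLUDED:
                continue
            xs.append(scores.values[i, j])
            ls.append(index.levels[d if axis == "drug" else s])
    x = np.array(xs, dtype=float)
    lv = np.array(ls, dtype=float)
    if np.std(x) == 0.0 or np.std(lv) == 0.0:
        raise EvaluationError("correlation undefined: zero variance")
    return float(np.corrcoef(x, lv)[0, 1])
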