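"""Temporal and reference labeling, ROC AUC, and correlation auditing."""

import numpy as np
import pytest

from meshops import (
    AnnotationIndex,
    METRICS,
    ScoreMatrix,
    annotation_correlation,
    cooccurring_pairs,
    load_corpus,
    load_entities,
    load_tree,
    metric_panel_auc,
    reference_labels,
    roc_auc,
    temporal_labels,
)
from meshops.errors import EvaluationError, LabelingError
from meshops.similarity import MetricSpec
from meshops.validation import EXCLUDED, LabelSet, NEGATIVE, POSITIVE

from conftest import write_corpus_file, write_entities_file, write_tree


def pair_counting_auc(scores, labels01):
    """Independent oracle: (#concordant + 0.5 #tied) / (#pos * #neg)."""
    pos = [s for s, y in zip(scores, labels01) if y == 1]
    neg = [s for s, y in zip(scores, labels01) if y == 0]
    conc = sum(1 for p in pos for n in neg if p > n)
    ties = sum(1 for p in pos for n in neg if p == n)
    return (conc + 0.5 * ties) / (len(pos) * len(neg))


@pytest.fixture
def labeled_world(tmp_path):
    """3 drugs x 4 diseases; 3 pre-cutoff pairs, 2 novel pairs, 7 never paired."""
    terms = [("CD%d" % i, "A%02d" % i) for i in range(1, 4)] + [
        ("SD%d" % j, "B%02d" % j) for j in range(1, 5)
    ]
    tree = load_tree(write_tree(tmp_path / "t.tsv", terms))
    articles = [
        # pre-cutoff co-occurrences: (D1,S1), (D1,S2), (D2,S3)
        {"article_id": "p1", "year": 2004, "terms": ["CD1", "SD1"]},
        {"article_id": "p2", "year": 2005, "terms": ["CD1", "SD2"]},
        {"article_id": "p3", "year": 2006, "terms": ["CD2", "SD3"]},
        # (D1,S1) also recurs after the cutoff: exclusion must win
        {"article_id": "p4", "year": 2009, "terms": ["CD1", "SD1"]},
        # novel pairs: (D2,S1), (D3,S4) first co-occur after the cutoff
        {"article_id": "f1", "year": 2008, "terms": ["CD2", "SD1"]},
        {"article_id": "f2", "year": 2010, "terms": ["CD3", "SD4"]},
    ]
    corpus = load_corpus(write_corpus_file(tmp_path / "c.jsonl", articles), tree)
    ents = load_entities(
        write_entities_file(
            tmp_path / "e.tsv",
            [(f"D{i}", "drug", f"CD{i}") for i in range(1, 4)]
            + [(f"S{j}", "disease", f"SD{j}") for j in range(1, 5)],
        ),
        tree,
    )
    return tree, corpus, ents


class TestCooccurrence:
    def test_simple_pair_detected(self, labeled_world):
        _, corpus, ents = labeled_world
        pairs = cooccurring_pairs(corpus, ents, year_max=2007)
        assert ("D1", "S1") in pairs
        assert pairs == {("D1", "S1"), ("D1", "S2"), ("D2", "S3")}

    def test_no_coannotation_empty(self, tmp_path, labeled_world):
        tree, _, ents = labeled_world
        corpus = load_corpus(
            write_corpus_file(
                tmp_path / "c2.jsonl",
                [{"article_id": "x", "year": 2000, "terms": ["CD1"]}],
            ),
            tree,
        )
        assert cooccurring_pairs(corpus, ents) == set()

    def test_all_years_when_unbounded(self, labeled_world):
        _, corpus, ents = labeled_world
        assert len(cooccurring_pairs(corpus, ents, year_max=None)) == 5


class TestTemporalLabels:
    def test_three_way_partition(self, labeled_world):
        _, corpus, ents = labeled_world
        labels = temporal_labels(corpus, ents, 2007)
        counts = labels.counts()
        assert counts == {POSITIVE: 2, NEGATIVE: 7, EXCLUDED: 3}
        assert len(labels.labels) == 12  # every grid pair labeled exactly once

    def test_precutoff_dominates(self, labeled_world):
        _, corpus, ents = labeled_world
        labels = temporal_labels(corpus, ents, 2007)
        assert labels.labels[("D1", "S1")] == EXCLUDED  # seen 2004 and 2009
        assert labels.labels[("D2", "S1")] == POSITIVE  # first seen 2008

    def test_requires_post_cutoff_articles(self, labeled_world):
        _, corpus, ents = labeled_world
        with pytest.raises(LabelingError):
            temporal_labels(corpus, ents, 2050)


class TestReferenceLabels:
    def write_pairs(self, path, rows, header=True):
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write("drug_id\tdisease_id\n")
            for d, s in rows:
                fh.write(f"{d}\t{s}\n")
        return path

    def test_positives_exclusion_and_skips(self, tmp_path, labeled_world):
        _, corpus, ents = labeled_world
        path = self.write_pairs(
            tmp_path / "ref.tsv",
            [("D2", "S1"), ("D3", "S2"), ("D1", "S1"), ("DX", "S9")],
        )
        labels, skipped = reference_labels(path, ents, corpus, 2007)
        assert skipped == [("DX", "S9")]
        assert labels.labels[("D2", "S1")] == POSITIVE
        assert labels.labels[("D3", "S2")] == POSITIVE
        assert labels.labels[("D1", "S1")] == EXCLUDED  # pre-cutoff co-occurrence wins
        assert labels.labels[("D3", "S4")] == NEGATIVE  # not listed here

    def test_empty_reference_fatal(self, tmp_path, labeled_world):
        _, corpus, ents = labeled_world
        path = self.write_pairs(tmp_path / "ref.tsv", [])
        with pytest.raises(LabelingError):
            reference_labels(path, ents, corpus, 2007)


def matrix_with_labels(scores, labels01, metric="term_overlap"):
    n = len(scores)
    drugs = [f"D{i}" for i in range(n)]
    sm = ScoreMatrix(drugs, ["S0"], METRICS[metric], np.array(scores).reshape(n, 1))
    labels = LabelSet(
        {(d, "S0"): (POSITIVE if y == 1 else NEGATIVE) for d, y in zip(drugs, labels01)},
        "reference-collection",
    )
    return sm, labels


class TestRocAuc:
    def test_perfect_separation(self):
        sm, labels = matrix_with_labels([5, 4, 1, 0], [1, 1, 0, 0])
        assert roc_auc(sm, labels) == 1.0

    def test_all_ties_half(self):
        sm, labels = matrix_with_labels([2, 2, 2, 2], [1, 0, 1, 0])
        assert roc_auc(sm, labels) == 0.5

    def test_known_value_three_quarters(self):
        sm, labels = matrix_with_labels([3, 1, 2, 0], [1, 1, 0, 0])
        assert roc_auc(sm, labels) == 0.75

    def test_needs_both_classes(self):
        sm, labels = matrix_with_labels([1, 2], [1, 1])
        with pytest.raises(EvaluationError):
            roc_auc(sm, labels)

    def test_polarity_reversal_complements(self):
        sm, labels = matrix_with_labels([3, 1, 2, 0], [1, 1, 0, 0])
        auc = roc_auc(sm, labels)
        assert roc_auc(sm, labels, polarity="lower-is-similar") == pytest.approx(1 - auc)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=40)
        ys = rng.integers(0, 2, size=40)
        ys[0], ys[1] = 1, 0
        sm, labels = matrix_with_labels(scores, ys)
        sm2, _ = matrix_with_labels(np.exp(3 * scores), ys)
        assert roc_auc(sm, labels) == pytest.approx(roc_auc(sm2, labels))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 500))
        scores = rng.integers(0, 8, size=n).astype(float)  # tie-heavy
        ys = rng.integers(0, 2, size=n)
        ys[0], ys[1] = 1, 0
        sm, labels = matrix_with_labels(scores, ys)
        assert roc_auc(sm, labels) == pytest.approx(pair_counting_auc(scores, ys), abs=1e-12)

    def test_excluded_pairs_ignored(self):
        sm, labels = matrix_with_labels([9, 3, 1, 2, 0], [1, 1, 1, 0, 0])
        labels.labels[("D0", "S0")] = EXCLUDED  # drop the top positive
        assert roc_auc(sm, labels) == pair_counting_auc([3, 1, 2, 0], [1, 1, 0, 0])


class TestPanelAndCorrelation:
    def test_panel_reduces_to_roc_auc(self, labeled_world):
        from meshops import background_counts, build_profiles, filter_by_year, score_matrix

        _, corpus, ents = labeled_world
        pre = filter_by_year(corpus, 2007)
        bg = background_counts(pre)
        dp, _ = build_profiles(pre, ents.of_class("drug"), bg)
        sp, _ = build_profiles(pre, ents.of_class("disease"), bg)
        labels = temporal_labels(corpus, ents, 2007)
        panel = metric_panel_auc(dp, sp, labels, ["term_overlap", "n_disease_terms"],
                                 with_correction=True)
        assert list(panel.metric_id) == ["term_overlap", "n_disease_terms",
                                         "corrected_l2_logp_overlap"]
        direct = roc_auc(score_matrix("term_overlap", dp, sp), labels)
        assert panel.auc.iloc[0] == pytest.approx(direct)
        assert (panel.auc_auto_oriented >= 0.5 - 1e-12).all()
        assert (panel.auc_auto_oriented >= panel.auc - 1e-12).all()

    def test_constant_shift_leaves_auc_unchanged(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=30)
        ys = rng.integers(0, 2, size=30)
        ys[0], ys[1] = 1, 0
        sm, labels = matrix_with_labels(scores, ys)
        sm2, _ = matrix_with_labels(scores + 100.0, ys)
        assert roc_auc(sm, labels) == pytest.approx(roc_auc(sm2, labels))

    def test_correlation_matches_direct_formula(self):
        rng = np.random.default_rng(13)
        drugs = [f"D{i}" for i in range(15)]
        diseases = [f"S{j}" for j in range(12)]
        lv = {s: int(v) for s, v in zip(diseases, rng.integers(1, 500, size=12))}
        idx = AnnotationIndex.from_levels(lv)
        values = rng.normal(size=(15, 12)) + np.array([lv[s] for s in diseases]) / 100.0
        sm = ScoreMatrix(drugs, diseases, METRICS["term_overlap"], values)
        r = annotation_correlation(sm, idx, "disease")
        x = values.ravel()
        y = np.tile([lv[s] for s in diseases], 15).astype(float)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_perfect_linear_dependence(self):
        drugs = ["D0", "D1"]
        diseases = ["S0", "S1", "S2"]
        lv = {"S0": 3, "S1": 8, "S2": 21}
        idx = AnnotationIndex.from_levels(lv)
        values = np.tile([3.0, 8.0, 21.0], (2, 1))
        sm = ScoreMatrix(drugs, diseases, METRICS["term_overlap"], values)
        assert annotation_correlation(sm, idx, "disease") == pytest.approx(1.0)

    def test_constant_scores_undefined(self):
        idx = AnnotationIndex.from_levels({"S0": 1, "S1": 5})
        sm = ScoreMatrix(["D0"], ["S0", "S1"], METRICS["term_overlap"],
                         np.array([[2.0, 2.0]]))
        with pytest.raises(EvaluationError):
            annotation_correlation(sm, idx, "disease")
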