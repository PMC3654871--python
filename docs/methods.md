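# Methods

## The model

An annotated corpus is a set of dated articles, each carrying a
curator-assigned set of terms from a hierarchical controlled vocabulary.
Hierarchy positions are dot-delimited tree numbers; the parent of a
position is the position minus its final segment, and a term's ancestors
are the union of the owners of every proper prefix over all of its
positions. At load time every article's term set is closed under the
ancestor relation — an article about a specific disease is also an article
about its parent disease categories — and raw terms are retained so the
corpus round-trips. Terms absent from the tree (stand-ins for
supplementary concepts that live outside the hierarchy) are legal
annotations that simply contribute no ancestors.

An entity (drug or disease) is identified with one defining term; its
bibliography is every article indexed under that term post-propagation.
The entity's profile lists, for each term observed in the bibliography of
size n: the count k, the fraction f = k/n, the enrichment p-value, and a
tf-idf weight. The p-value is the one-sided hypergeometric upper tail
P(X ≥ k) with population N (the background article count), K marked (the
background articles carrying the term) and n drawn — identical to the
one-sided Fisher exact test on the 2×2 table (a tested invariant). Two
backgrounds are supported: universal (all articles) and class-specific
(articles linked to at least one entity of the class); cross-class profile
comparison requires the universal background, and mixing background kinds
is a configuration error.

Numerical choices for the profile:

- Tail sums are accumulated in log space (gammaln-based log-pmf +
  logsumexp), so extreme enrichment never underflows to a hard zero
  prematurely; the result is clamped to [1e-300, 1] so downstream
  logarithms are always finite.
- The tf-idf weight is w = f · ln(N/K): bibliography-relative term
  frequency times background-relative inverse document frequency. The
  weight definition is a documented design choice — only the cosine over
  these weights is canonical, not the weight formula itself.
- The bibliography's own articles remain inside the background counts (no
  leave-self-out); every observed term is kept (no significance cutoff),
  since the similarity formulas need complete vectors;
  rows are ordered by ascending p then term id, making outputs
  deterministic.

## The similarity panel

Fifteen pairwise scores plus one variant, computed from the drug profile C
and disease profile D. Sums "over all terms" range over the union of terms
present in either profile; a term absent from a profile contributes
p = 1, f = 0, k = 0, w = 0; log is natural (a fixed base change rescales
every metric without moving any rank or AUC).

| id | definition | polarity |
|---|---|---|
| cosine_tfidf | cos(w_C, w_D) | higher-is-similar |
| cosine_p | cos(p_C, p_D) | higher-is-similar |
| cosine_fraction | cos(f_C, f_D) | higher-is-similar |
| sum_log_combined_p | Σ log(p_C + p_D − p_C·p_D) | higher-is-similar |
| sum_diff_log_p | Σ (log p_C − log p_D) | lower-is-similar, scored as magnitude |
| l2_logp_overlap | √Σ_{C∩D} (log p_C − log p_D)² | higher-is-similar |
| l2_fraction_overlap | √Σ_{C∩D} (f_C − f_D)² | higher-is-similar |
| l2_logp_all | √Σ (log p_C − log p_D)² | lower-is-similar |
| l2_p_all | √Σ (p_C − p_D)² | lower-is-similar |
| l2_fraction_all | √Σ (f_C − f_D)² | lower-is-similar |
| l2_freq_all | √Σ (k_C − k_D)² | lower-is-similar |
| term_coverage | \|C ∪ D\| | higher-is-similar |
| term_overlap | \|C ∩ D\| | higher-is-similar |
| n_drug_terms | \|C\| | higher-is-similar |
| n_disease_terms | \|D\| | higher-is-similar |
| total_terms | \|C\| + \|D\| | higher-is-similar |

Design notes:

- The polarity registry orients scores for ROC evaluation and for "more
  extreme" in the correction. The overlap-restricted L2 "distances" grow
  with the size of the intersection and behave as similarities, hence their
  higher-is-similar polarity; the full-union L2 forms are genuine
  distances. The signed log-p difference sum only encodes which side is
  globally more significant, so it is oriented by |Σ|. The validation
  module also reports an auto-oriented AUC (max of AUC, 1−AUC) so a
  mis-registered polarity is visible rather than silent.
- Empty intersection: the overlap-only metrics return 0, the
  minimum-evidence value under their polarity — no shared term, no
  similarity evidence.
- n_drug_terms and n_disease_terms use one profile only; they are the
  annotation-level baselines any useful similarity metric must beat.
  total_terms (|C|+|D|) is kept alongside term_coverage (|C∪D|) because
  both readings of a "total number of terms" baseline occur in practice.
- Summing over the union is the operative definition: for most formulas
  the absent-term conventions make it equal to summing over the whole
  vocabulary, but for cosine_p they do not (absent-absent terms would
  contribute 1·1), so the union definition is normative here.

## Annotation-bias correction

Annotation level x = the number of distinct terms in an entity's profile.
Within each class, entities get mid-rank percentiles of their levels
(ties share a percentile); an entity's peers are all same-class entities
within ±half_width percentile (default 5, i.e. a 10 %-of-class window),
truncated at [0, 100] without widening — the conservative reading of a
percentile window at the boundary. The corrected score of a pair is

(1 + #{peer-pair scores strictly more extreme than the pair's}) / (1 + pool size)

where the pool is every drug-peer × disease-peer raw score (the query pair
included — it is its own peer) and "more extreme" follows the metric's
polarity. Add-one smoothing keeps the value in (0, 1], standard
empirical-p practice; strictness matches a "score greater than x_s"
counting rule. Within fixed peer sets the corrected value is
non-increasing in raw extremeness, under an i.i.d. null it is approximately
uniform, and the implementation (sorted pools + binary search, cached per
window pair) is exactly equal to the naive double-loop count — all three
are tested.

Pools are not filtered by prior co-publication; exclusion of known pairs
happens only in validation labeling, keeping the correction a pure
conditional-significance transform.

## Validation

Co-occurrence is read off the propagated term sets (an article indexed
under a descendant of a disease term mentions the disease), consistent
with bibliography construction. The temporal split labels every
drug × disease pair: first co-occurrence at or before the cutoff year →
excluded (not novel), first co-occurrence after it → positive, never
co-occurring → negative. Reference-collection labeling takes a curated
pair list as positives, with pre-cutoff co-occurrence still excluding a
pair even when listed — "novel" takes precedence — and unresolvable rows
reported, not fatal. AUC is the rank-sum (Mann-Whitney) statistic with
average ranks for ties; the counting baselines are integer-valued and
tie-heavy, and any other tie convention biases their AUC. Profiles used
for prediction are built on the pre-cutoff corpus only (`filter_by_year`);
labels use the full corpus.

## The synthetic world

The generator emits the package's own on-disk formats with planted ground
truth. Defaults (frozen; chosen once as a small but realistic world):
300 terms in a depth-4 random tree, 40 topics of 8 terms, 60 drugs and
50 diseases with 2 topics each, log-normal(μ=2, σ=1) publication counts
floored at 1 (median ≈ 7 articles, heavy right tail — sample skewness > 1
is a tested property), 6 terms per article with 10 % uniform noise
replacement, link rate 0.35 among topic-sharing pairs, cutoff year 2007
with articles drawn from the preceding 12 years, and 70 % of
link-evidencing articles dated after the cutoff.

Mechanics worth knowing:

- Defining terms are tree leaves withheld from topic and noise
  vocabularies, so drug–disease co-annotation occurs exactly for planted
  links (a tested property) and ancestor propagation cannot leak one
  entity's defining term into another's articles.
- Links are planted at the topic level: a linked pair's profile similarity
  emerges from sampling shared topic terms, not from copying terms, so the
  signal the metrics detect is not tautological.
- A link is declared "future" (all its co-annotated articles post-cutoff →
  a temporal positive) or "historical" (all pre-cutoff → an excluded pair)
  as a whole, with probability future_fraction.
- With bias_strength b, a topic-sharing pair links with probability
  link_rate · (u_c · u_d)^b where u are publication-count mid-rank
  percentiles in (0, 1]; b = 0 makes links independent of output volume.

Two frozen scenarios drive the end-to-end checks. "unbiased"
(bias_strength 0, seed 20070): similarity must beat both count baselines —
seed-averaged AUC margin ≈ 0.09 in the shipped world. "biased" (600 terms,
120 drugs × 100 diseases, σ = 1.3, link_rate 0.6, bias_strength 6, seed
20076): annotation level alone predicts future links (baseline AUC ≈ 0.83
and 0.93), raw similarity correlates with annotation level (r ≈ 0.55 on
both axes), and the corrected scores do not (|r| < 0.1). The biased
scenario's parameters were calibrated once to realize that confound and
then frozen.

What a green synthetic run does not establish: real vocabularies are far
larger and deeper, real indexing density varies by era and journal, topics
drift over time, publication counts grow rather than sit static, and real
co-publication has causes other than shared topics. The synthetic world
validates the machinery and the qualitative phenomena (bias, its removal,
content beating popularity), not absolute AUC levels on real literature.

## Degenerate inputs and edge behavior

- Empty bibliography → profile error; pipeline stages skip-and-report the
  entity and validation drops its pairs.
- Unknown terms in a corpus are kept, reported, and propagation-inert;
  dangling tree-number prefixes are skipped and reported.
- Zero-variance score or level vectors make the Pearson audit undefined →
  explicit error rather than NaN.
- A 1×1 score matrix corrects to (1+0)/(1+1) = 0.5: one pair, its own
  peer.
- AUC requires at least one positive and one negative non-excluded pair.

## Known limitations

- Vocabulary qualifiers/subheadings are not modeled; a term is atomic.
- The correction is purely empirical; no parametric approximation of the
  conditional score distribution is offered, so very narrow windows on
  small classes give coarse (grid-valued) corrected scores.
- Profile construction iterates the corpus per entity; fine at the tested
  scales (thousands of articles, hundreds of entities), not tuned for
  tens of millions of articles.
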