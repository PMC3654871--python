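"""Pairwise profile similarity metrics and drug x disease score matrices.

The panel covers cosine similarities (over tf-idf weights, p-values and
term fractions), log-p combination sums, Euclidean (L2) distances over
several per-term measures — restricted to the overlapping terms or taken
over all terms — and four counting measures (term coverage, term overlap
and the per-profile term counts, the latter two serving as single-profile
baselines).

Conventions: sums "over all terms" range over the union of terms present in
either profile; a term absent from a profile contributes p = 1, fraction =
0, count = 0 and weight = 0.  "log" is the natural logarithm throughout (a
fixed base change rescales metrics without affecting ranks or AUC).
p-values are floored (see :data:`meshops.profiles.P_FLOOR`) before logs.

Each metric carries a declared polarity: whether a larger value is read as
"more similar".  The L2-over-overlap distances grow with the size of the
term intersection, so they are registered higher-is-similar; the full-union
L2 distances are genuine distances and are lower-is-similar.  The signed
sum of log-p differences is scored by magnitude (use_magnitude), since its
sign only encodes which profile is more significant overall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .profiles import P_FLOOR, Profile

__all__ = [
    "MetricSpec",
    "METRICS",
    "ScoreMatrix",
    "score_pair",
    "score_matrix",
    "write_scores",
    "read_scores",
]

HIGHER = "higher-is-similar"
LOWER = "lower-is-similar"


@dataclass(frozen=True)
class MetricSpec:
    metric_id: str
    polarity: str  # HIGHER or LOWER
    domain: str  # "all-terms", "overlap-only", or "single-profile"
    use_magnitude: bool = False  # orient by |value| (signed metrics only)

    def oriented(self, values: np.ndarray) -> np.ndarray:
        """Map raw values so that larger always means more similar."""
        v = np.abs(values) if self.use_magnitude else np.asarray(values, dtype=float)
        return v if self.polarity == HIGHER else -v


METRICS: dict[str, MetricSpec] = {
    m.metric_id: m
    for m in [
        MetricSpec("cosine_tfidf", HIGHER, "all-terms"),
        MetricSpec("cosine_p", HIGHER, "all-terms"),
        MetricSpec("cosine_fraction", HIGHER, "all-terms"),
        MetricSpec("sum_log_combined_p", HIGHER, "all-terms"),
        MetricSpec("sum_diff_log_p", LOWER, "all-terms", use_magnitude=True),
        MetricSpec("l2_logp_overlap", HIGHER, "overlap-only"),
        MetricSpec("l2_fraction_overlap", HIGHER, "overlap-only"),
        MetricSpec("l2_logp_all", LOWER, "all-terms"),
        MetricSpec("l2_p_all", LOWER, "all-terms"),
        MetricSpec("l2_fraction_all", LOWER, "all-terms"),
        MetricSpec("l2_freq_all", LOWER, "all-terms"),
        MetricSpec("term_coverage", HIGHER, "all-terms"),
        MetricSpec("term_overlap", HIGHER, "overlap-only"),
        MetricSpec("n_drug_terms", HIGHER, "single-profile"),
        MetricSpec("n_disease_terms", HIGHER, "single-profile"),
        # |C| + |D|: the sum of the two per-profile counts, kept alongside
        # term_coverage (|C u D|) since both readings of "total terms" occur.
        MetricSpec("total_terms", HIGHER, "single-profile"),
    ]
}


@dataclass
class ScoreMatrix:
    """Dense drugs x diseases matrix of one metric's raw values."""

    drugs: list[str]
    diseases: list[str]
    metric: MetricSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.drugs), len(self.diseases)):
            raise ValueError("score matrix shape does not match axis lengths")
        self._drug_pos = {d: i for i, d in enumerate(self.drugs)}
        self._disease_pos = {d: j for j, d in enumerate(self.diseases)}

    def value(self, drug: str, disease: str) -> float:
        return float(self.values[self._drug_pos[drug], self._disease_pos[disease]])


def _aligned(cp: Profile, dp: Profile):
    """Align the two profiles on the union of their term sets.

    Returns arrays (counts, fractions, floored p-values, weights) per side
    plus the boolean intersection mask, in sorted union-term order.
    """
    c = cp.as_dict()
    d = dp.as_dict()
    union = sorted(set(c) | set(d))
    m = len(union)
    cc = np.zeros(m)
    cf = np.zeros(m)
    cpv = np.ones(m)
    cw = np.zeros(m)
    dc = np.zeros(m)
    df_ = np.zeros(m)
    dpv = np.ones(m)
    dw = np.zeros(m)
    both = np.zeros(m, dtype=bool)
    for i, t in enumerate(union):
        tc = c.get(t)
        td = d.get(t)
        if tc is not None:
            cc[i], cf[i], cpv[i], cw[i] = tc
        if td is not None:
            dc[i], df_[i], dpv[i], dw[i] = td
        both[i] = tc is not None and td is not None
    cpv = np.clip(cpv, P_FLOOR, 1.0)
    dpv = np.clip(dpv, P_FLOOR, 1.0)
    return cc, cf, cpv, cw, dc, df_, dpv, dw, both


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na = np.sqrt(np.sum(a * a))
    nb = np.sqrt(np.sum(b * b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.sum(a * b) / (na * nb))


def score_pair(metric: MetricSpec | str, drug_profile: Profile, disease_profile: Profile) -> float:
    """Raw metric value for one (drug profile, disease profile) pair."""
    if isinstance(metric, str):
        metric = METRICS[metric]
    if drug_profile.background_kind != disease_profile.background_kind:
        raise ConfigurationError("profiles were built against different background kinds")

    mid = metric.metric_id
    # counting measures do not need alignment
    if mid in ("term_coverage", "term_overlap", "n_drug_terms", "n_disease_terms", "total_terms"):
        C = drug_profile.term_set()
        D = disease_profile.term_set()
        if mid == "term_coverage":
            return float(len(C | D))
        if mid == "term_overlap":
            return float(len(C & D))
        if mid == "n_drug_terms":
            return float(len(C))
        if mid == "n_disease_terms":
            return float(len(D))
        return float(len(C) + len(D))

    cc, cf, cpv, cw, dc, df_, dpv, dw, both = _aligned(drug_profile, disease_profile)
    if mid == "cosine_tfidf":
        return _cosine(cw, dw)
    if mid == "cosine_p":
        return _cosine(cpv, dpv)
    if mid == "cosine_fraction":
        return _cosine(cf, df_)
    if mid == "sum_log_combined_p":
        comb = cpv + dpv - cpv * dpv
        return float(np.sum(np.log(np.clip(comb, P_FLOOR, 1.0))))
    if mid == "sum_diff_log_p":
        return float(np.sum(np.log(cpv) - np.log(dpv)))
    if mid == "l2_logp_overlap":
        diff = (np.log(cpv) - np.log(dpv))[both]
        return float(np.sqrt(np.sum(diff * diff)))
    if mid == "l2_fraction_overlap":
        diff = (cf - df_)[both]
        return float(np.sqrt(np.sum(diff * diff)))
    if mid == "l2_logp_all":
        diff = np.log(cpv) - np.log(dpv)
        return float(np.sqrt(np.sum(diff * diff)))
    if mid == "l2_p_all":
        diff = cpv - dpv
        return float(np.sqrt(np.sum(diff * diff)))
    if mid == "l2_fraction_all":
        diff = cf - df_
        return float(np.sqrt(np.sum(diff * diff)))
    if mid == "l2_freq_all":
        diff = cc - dc
        return float(np.sqrt(np.sum(diff * diff)))
    raise KeyError(f"unknown metric: {mid!r}")


def score_matrix(
    metric: MetricSpec | str,
    drug_profiles: list[Profile] | dict[str, Profile],
    disease_profiles: list[Profile] | dict[str, Profile],
) -> ScoreMatrix:
    """Elementwise :func:`score_pair` over every drug/disease combination."""
    if isinstance(metric, str):
        metric = METRICS[metric]
    if isinstance(drug_profiles, dict):
        drug_profiles = [drug_profiles[k] for k in sorted(drug_profiles)]
    if isinstance(disease_profiles, dict):
        disease_profiles = [disease_profiles[k] for k in sorted(disease_profiles)]
    if not drug_profiles or not disease_profiles:
        raise ConfigurationError("need at least one profile per side")
    values = np.empty((len(drug_profiles), len(disease_profiles)))
    for i, cp in enumerate(drug_profiles):
        for j, dp in enumerate(disease_profiles):
            values[i, j] = score_pair(metric, cp, dp)
    return ScoreMatrix(
        drugs=[p.entity_id for p in drug_profiles],
        diseases=[p.entity_id for p in disease_profiles],
        metric=metric,
        values=values,
    )


def write_scores(matrices: list[ScoreMatrix] | ScoreMatrix, path: str | Path) -> None:
    """Long-format TSV: drug_id, disease_id, metric_id, score."""
    if isinstance(matrices, ScoreMatrix):
        matrices = [matrices]
    rows = []
    for sm in matrices:
        for i, drug in enumerate(sm.drugs):
            for j, disease in enumerate(sm.diseases):
                rows.append((drug, disease, sm.metric.metric_id, sm.values[i, j]))
    pd.DataFrame(rows, columns=["drug_id", "disease_id", "metric_id", "score"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_scores(path: str | Path) -> list[ScoreMatrix]:
    """Inverse of :func:`write_scores`; axis order is first-appearance order."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for mid in df["metric_id"].unique():
        sub = df[df["metric_id"] == mid]
        drugs = list(dict.fromkeys(sub["drug_id"]))
        diseases = list(dict.fromkeys(sub["disease_id"]))
        values = (
            sub.pivot(index="drug_id", columns="disease_id", values="score")
            .reindex(index=drugs, columns=diseases)
            .to_numpy()
        )
        out.append(ScoreMatrix(drugs=drugs, diseases=diseases, metric=METRICS[mid], values=values))
    return out
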