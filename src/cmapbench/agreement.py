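"""Reproducibility statistics.

Spearman rank correlation and a modified (ternary) Jaccard index over
DE profiles; within-dataset replicate agreement with the max-by-condition
summary; cross-dataset agreement over harmonized condition pairs; and the
two sample-level measures: the "in-replicate" limiting correlation
(min of per-replicate maxima) and the "cross-replicate" best-case
correlation (max over cross pairs).

The ternary Jaccard treats two thresholded profiles A, B in {-1, 0, +1} as
signed DE gene lists:

    J_T(A, B) = #{i : A_i = B_i != 0} / #{i : A_i != 0 or B_i != 0}

i.e. genes DE in both AND changed in the same direction, over genes DE in
either.  When neither profile has any DE gene the index is defined as 0
(not 1): two empty hit lists carry no evidence of agreement.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import DEProfile, TernaryVector, count_de_genes, ternarize
from .synth import ConditionKey, ExpressionMatrix

__all__ = [
    "PairComparison",
    "AgreementRecord",
    "HarmonizedPair",
    "spearman_correlation",
    "ternary_jaccard",
    "within_dataset_agreement",
    "cross_dataset_agreement",
    "harmonize",
    "in_replicate_sample_agreement",
    "cross_replicate_sample_agreement",
    "attach_sample_agreements",
]


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Ties receive average ranks.  Returns NaN (a flagged missing value) when
    either vector is constant, since rank correlation is undefined there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))


def ternary_jaccard(a: TernaryVector, b: TernaryVector) -> float:
    """Modified Jaccard index for ternary DE vectors; see module docstring."""
    av = a.values
    bv = b.values
    if not av.index.equals(bv.index):
        raise ValueError("ternary vectors must share an identical gene index")
    x = av.to_numpy()
    y = bv.to_numpy()
    num = int(np.count_nonzero((x == y) & (x != 0)))
    den = int(np.count_nonzero((x != 0) | (y != 0)))
    return num / den if den else 0.0


@dataclass
class PairComparison:
    """One unordered replicate-pair comparison within a condition."""

    replicate_a: str
    replicate_b: str
    value: float
    lesser_de_count: int
    in_replicate_sample_agreement: float = math.nan
    cross_replicate_sample_agreement: float = math.nan


@dataclass
class AgreementRecord:
    """Per-condition reproducibility summary over replicate-pair comparisons."""

    condition: ConditionKey
    metric: str
    pairs: list[PairComparison] = field(default_factory=list)

    @property
    def all_pairwise_values(self) -> list[float]:
        return [p.value for p in self.pairs]

    @property
    def valid_pairs(self) -> list[PairComparison]:
        return [p for p in self.pairs if not math.isnan(p.value)]

    @property
    def max_pair(self) -> PairComparison | None:
        """The best-case pair; the condition's summary statistic comes from it."""
        valid = self.valid_pairs
        return max(valid, key=lambda p: p.value) if valid else None

    @property
    def max_value(self) -> float:
        best = self.max_pair
        return best.value if best is not None else math.nan

    @property
    def lesser_de_count(self) -> int | None:
        best = self.max_pair
        return best.lesser_de_count if best is not None else None


@dataclass(eq=False)
class HarmonizedPair:
    """A condition's pair of profiles from two corpora on a shared gene index."""

    condition: ConditionKey
    condition_b: ConditionKey
    profile_a: DEProfile
    profile_b: DEProfile
    shared_gene_index: pd.Index


def _pair_metric(p: DEProfile, q: DEProfile, metric: str) -> float:
    if metric == "spearman":
        return spearman_correlation(p.values.to_numpy(), q.values.to_numpy())
    if metric == "ternary_jaccard":
        return ternary_jaccard(ternarize(p), ternarize(q))
    raise ValueError(f"unknown metric {metric!r}")


def within_dataset_agreement(
    profiles: list[DEProfile],
    metric: str = "spearman",
    cell_lines: set[str] | None = None,
    duration_h: float | None = None,
) -> list[AgreementRecord]:
    """All unordered replicate-pair similarities, grouped by condition.

    Optional filters restrict to given cell lines and a single treatment
    duration before grouping.  Conditions with a single profile instance
    (no replicates) are dropped.  Each pair also records the lesser of the
    two profiles' DE gene counts (the "limiting profile" representative).
    """
    eligible = [
        p
        for p in profiles
        if (cell_lines is None or p.condition.cell_line in cell_lines)
        and (duration_h is None or p.condition.duration_h == duration_h)
    ]
    by_condition: dict[ConditionKey, list[DEProfile]] = {}
    for p in eligible:
        by_condition.setdefault(p.condition, []).append(p)

    records: list[AgreementRecord] = []
    for cond in sorted(by_condition, key=str):
        group = sorted(by_condition[cond], key=lambda p: p.replicate_id)
        if len(group) < 2:
            continue
        de_counts = {p.replicate_id: count_de_genes(ternarize(p)) for p in group}
        rec = AgreementRecord(condition=cond, metric=metric)
        for p, q in itertools.combinations(group, 2):
            rec.pairs.append(
                PairComparison(
                    replicate_a=p.replicate_id,
                    replicate_b=q.replicate_id,
                    value=_pair_metric(p, q, metric),
                    lesser_de_count=min(de_counts[p.replicate_id], de_counts[q.replicate_id]),
                )
            )
        records.append(rec)
    return records


def harmonize(
    corpus_a: list[DEProfile],
    corpus_b: list[DEProfile],
    conc_tolerance: float = 0.0,
) -> tuple[list[HarmonizedPair], list[ConditionKey]]:
    """Match conditions across two corpora and fix a shared gene index per pair.

    With ``conc_tolerance`` 0 all four key fields must match exactly.  With a
    positive tolerance, compound, cell line and duration must match and the
    concentrations must satisfy |c_a - c_b| / c_a < tolerance (corpus A's
    concentration is the reference denominator).  Returns the matched pairs
    and the list of corpus-A conditions left unmatched.
    """
    pairs: list[HarmonizedPair] = []
    unmatched: list[ConditionKey] = []
    b_sorted = sorted(corpus_b, key=lambda p: (str(p.condition), p.replicate_id))
    for pa in sorted(corpus_a, key=lambda p: (str(p.condition), p.replicate_id)):
        ka = pa.condition
        hit = False
        for pb in b_sorted:
            kb = pb.condition
            if (ka.compound, ka.cell_line, ka.duration_h) != (
                kb.compound,
                kb.cell_line,
                kb.duration_h,
            ):
                continue
            if conc_tolerance == 0.0:
                if ka.concentration_uM != kb.concentration_uM:
                    continue
            elif abs(ka.concentration_uM - kb.concentration_uM) / ka.concentration_uM >= conc_tolerance:
                continue
            shared = pa.values.index.intersection(pb.values.index)
            pairs.append(
                HarmonizedPair(
                    condition=ka,
                    condition_b=kb,
                    profile_a=pa,
                    profile_b=pb,
                    shared_gene_index=shared,
                )
            )
            hit = True
        if not hit:
            unmatched.append(ka)
    return pairs, unmatched


def cross_dataset_agreement(
    pairs: list[HarmonizedPair],
    metric: str = "spearman",
    universe: str = "all",
    landmark_ids: pd.Index | None = None,
    min_shared_genes: int = 10,
) -> list[AgreementRecord]:
    """One agreement value per harmonized condition pair on the shared index.

    ``universe='landmark'`` further restricts the shared index to landmark
    genes.  Pairs whose usable index is shorter than ``min_shared_genes``
    are skipped (rank correlation on very short vectors is uninformative).
    """
    records: list[AgreementRecord] = []
    for hp in pairs:
        idx = hp.shared_gene_index
        if universe == "landmark":
            if landmark_ids is None:
                raise ValueError("landmark universe requires landmark_ids")
            idx = idx.intersection(landmark_ids)
        if len(idx) < min_shared_genes:
            continue
        pa = hp.profile_a.restricted(idx)
        pb = hp.profile_b.restricted(idx)
        tern_a = ternarize(pa)
        tern_b = ternarize(pb)
        value = _pair_metric(pa, pb, metric)
        rec = AgreementRecord(condition=hp.condition, metric=metric)
        rec.pairs.append(
            PairComparison(
                replicate_a=hp.profile_a.replicate_id,
                replicate_b=hp.profile_b.replicate_id,
                value=value,
                lesser_de_count=min(count_de_genes(tern_a), count_de_genes(tern_b)),
            )
        )
        records.append(rec)
    return records


def _max_pairwise_within(mat: pd.DataFrame) -> float:
    cols = list(mat.columns)
    best = -np.inf
    for i, j in itertools.combinations(range(len(cols)), 2):
        r = spearman_correlation(mat.iloc[:, i].to_numpy(), mat.iloc[:, j].to_numpy())
        if not math.isnan(r):
            best = max(best, r)
    return best if best != -np.inf else math.nan


def in_replicate_sample_agreement(rep1: pd.DataFrame, rep2: pd.DataFrame) -> float:
    """Limiting correlation of constituent-sample expression.

    For each replicate group (genes x samples), the maximum pairwise rank
    correlation among its constituent samples is computed; the pair's
    representative value is the smaller of the two maxima — the noisier
    replicate caps the agreement the DE pair can reach.  A replicate with
    fewer than two samples yields NaN.
    """
    if rep1.shape[1] < 2 or rep2.shape[1] < 2:
        return math.nan
    return min(_max_pairwise_within(rep1), _max_pairwise_within(rep2))


def cross_replicate_sample_agreement(rep1: pd.DataFrame, rep2: pd.DataFrame) -> float:
    """Best-case correlation between one replicate's samples and the other's."""
    if rep1.shape[1] < 1 or rep2.shape[1] < 1:
        return math.nan
    best = -np.inf
    for i in range(rep1.shape[1]):
        x = rep1.iloc[:, i].to_numpy()
        for j in range(rep2.shape[1]):
            r = spearman_correlation(x, rep2.iloc[:, j].to_numpy())
            if not math.isnan(r):
                best = max(best, r)
    return best if best != -np.inf else math.nan


def attach_sample_agreements(
    records: list[AgreementRecord], expr: ExpressionMatrix
) -> None:
    """Fill each pair's sample-level agreements from the expression matrix.

    Replicate labels on the DE profiles refer to treatment replicate groups
    in ``expr``; the constituent samples of each group (treatment samples)
    are compared in place.
    """
    meta = expr.sample_meta
    cache: dict[str, pd.DataFrame] = {}

    def slice_of(rep_group: str) -> pd.DataFrame:
        if rep_group not in cache:
            ids = meta.index[
                (meta["replicate_group"] == rep_group) & (meta["role"] == "treatment")
            ]
            cache[rep_group] = expr.values[ids]
        return cache[rep_group]

    for rec in records:
        for pair in rec.pairs:
            s1 = slice_of(pair.replicate_a)
            s2 = slice_of(pair.replicate_b)
            pair.in_replicate_sample_agreement = in_replicate_sample_agreement(s1, s2)
            pair.cross_replicate_sample_agreement = cross_replicate_sample_agreement(s1, s2)
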