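"""Signature-query engine and retrieval benchmark.

Scores up/down gene-list signatures against a corpus of DE profiles with a
two-sided Kolmogorov-Smirnov running-sum enrichment statistic (the classic
connectivity-map scoring family), aggregates profile scores per compound,
ranks compounds against a shared compound universe, and computes the
benchmark metrics: retrieval rank, inverse rank, top-decile success, median
rank, and the rank-product / 75th-percentile meta-rankings used to combine
multiple query signatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .de import DEProfile
from .signatures import Signature

__all__ = [
    "ConnectivityScore",
    "RetrievalResult",
    "rank_genes",
    "CorpusIndex",
    "enrichment_score",
    "connectivity_score",
    "query_corpus",
    "success_at_decile",
    "median_rank",
    "meta_rank_product",
    "meta_rank_percentile",
]


@dataclass
class ConnectivityScore:
    """Signed similarity in [-1, 1]; positive mimics the query, negative reverses it.

    The combined value is (es_up - es_down) / 2, zeroed when the two
    enrichment scores share a sign (an internally inconsistent match).
    """

    value: float
    es_up: float
    es_down: float


@dataclass
class RetrievalResult:
    """A query's ranked compound list and where the target compound landed."""

    query_id: str
    target_compound: str
    ranked_compounds: list[tuple[str, float]]
    rank_of_target: int | None
    inverse_rank_of_target: int | None
    corpus_compound_count: int
    cell_line_filter: str | None = None

    @property
    def target_in_universe(self) -> bool:
        return self.rank_of_target is not None


def rank_genes(profile: DEProfile) -> pd.Index:
    """Profile's genes ordered by descending DE value; ties lexicographic."""
    df = pd.DataFrame({"v": profile.values.to_numpy(), "g": profile.values.index.astype(str)})
    df = df.sort_values(["v", "g"], ascending=[False, True], kind="stable")
    return pd.Index(df["g"].tolist())


def _es_from_positions(positions: np.ndarray, n: int) -> float:
    """KS running-sum extreme from the 0-based ranks of the list members."""
    m = positions.size
    steps = np.full(n, -1.0 / (n - m))
    steps[positions] = 1.0 / m
    running = np.cumsum(steps)
    hi = float(running.max())
    lo = float(running.min())
    return hi if hi >= -lo else lo


def enrichment_score(gene_list: Sequence[str], ranked_profile) -> float:
    """Two-sided KS running-sum statistic of a gene list against a ranked profile.

    Walking down the ranked profile, the running sum rises by 1/|list| at
    list members and falls by 1/(N - |list|) elsewhere; the score is the
    signed extreme deviation (positive if the maximum dominates, negative
    if the minimum does).  List members concentrated at the top push the
    score toward +1; at the bottom, toward -1.
    """
    if len(gene_list) == 0:
        raise ValueError("gene list is empty")
    order = pd.Index(ranked_profile)
    n = len(order)
    if len(set(gene_list)) != len(gene_list):
        raise ValueError("gene list contains duplicates")
    positions = order.get_indexer(pd.Index(gene_list))
    if (positions < 0).any():
        missing = [g for g, p in zip(gene_list, positions) if p < 0][:5]
        raise ValueError(f"gene list not contained in profile universe (e.g. {missing})")
    if len(gene_list) >= n:
        raise ValueError("gene list must be a strict subset of the profile universe")
    return _es_from_positions(positions, n)


def _combine(es_up: float, es_down: float) -> float:
    return 0.0 if es_up * es_down > 0 else (es_up - es_down) / 2.0


def connectivity_score(sig: Signature, profile: DEProfile) -> ConnectivityScore:
    """Combined enrichment of a signature's up and down lists in one profile."""
    order = rank_genes(profile)
    es_up = enrichment_score(sig.up_genes, order)
    es_down = enrichment_score(sig.down_genes, order)
    return ConnectivityScore(value=_combine(es_up, es_down), es_up=es_up, es_down=es_down)


class CorpusIndex:
    """Pre-ranked corpus for batch querying: one gene ordering per profile."""

    def __init__(self, corpus: Sequence[DEProfile]):
        self.profiles = list(corpus)
        self.orders = [rank_genes(p) for p in self.profiles]

    def score(self, sig: Signature, i: int) -> float:
        order = self.orders[i]
        up = order.get_indexer(pd.Index(sig.up_genes))
        down = order.get_indexer(pd.Index(sig.down_genes))
        if (up < 0).any() or (down < 0).any():
            raise ValueError("signature genes not contained in profile universe")
        n = len(order)
        return _combine(_es_from_positions(up, n), _es_from_positions(down, n))


def query_corpus(
    sig: Signature,
    corpus: Sequence[DEProfile],
    cell_line_filter: str | None = None,
    compound_universe: set[str] | None = None,
    aggregate: str = "max",
    target_compound: str | None = None,
    query_id: str = "",
    index: "CorpusIndex | None" = None,
) -> RetrievalResult:
    """Score a signature against every corpus profile and rank compounds.

    Profiles failing the cell-line filter or outside the compound universe
    are ignored.  A compound's score aggregates over its profiles (max by
    default, median by option); compounds sort by descending score with
    lexicographic tie-break, and ranks run 1..K over the K universe
    compounds actually present.  A target compound absent from the ranked
    universe yields an explicit not-in-universe result (rank None).
    """
    if aggregate not in ("max", "median"):
        raise ValueError("aggregate must be 'max' or 'median'")
    if target_compound is None:
        if sig.source_condition is None:
            raise ValueError("target_compound required when signature has no source condition")
        target_compound = sig.source_condition.compound

    if index is None:
        index = CorpusIndex(corpus)
    elif index.profiles is not list(corpus) and len(index.profiles) != len(corpus):
        raise ValueError("corpus index does not match corpus")
    scores_by_compound: dict[str, list[float]] = {}
    for i, prof in enumerate(index.profiles):
        if cell_line_filter is not None and prof.condition.cell_line != cell_line_filter:
            continue
        compound = prof.condition.compound
        if compound_universe is not None and compound not in compound_universe:
            continue
        scores_by_compound.setdefault(compound, []).append(index.score(sig, i))
    if not scores_by_compound:
        raise ValueError("no corpus profiles left after filtering")

    agg = max if aggregate == "max" else lambda v: float(np.median(v))
    compound_scores = {c: float(agg(v)) for c, v in scores_by_compound.items()}
    ranked = sorted(compound_scores.items(), key=lambda kv: (-kv[1], kv[0]))
    k = len(ranked)
    rank = None
    for i, (compound, _) in enumerate(ranked, start=1):
        if compound == target_compound:
            rank = i
            break
    inverse = (k + 1 - rank) if rank is not None else None
    return RetrievalResult(
        query_id=query_id,
        target_compound=target_compound,
        ranked_compounds=ranked,
        rank_of_target=rank,
        inverse_rank_of_target=inverse,
        corpus_compound_count=k,
        cell_line_filter=cell_line_filter,
    )


def success_at_decile(result: RetrievalResult) -> bool:
    """True iff the target ranks in the top 10% of the ranked universe.

    The cutoff is ceil(0.1 * K) for a K-compound universe, so it adapts to
    the corpus size rather than assuming any particular scale.
    """
    if result.rank_of_target is None:
        return False
    cutoff = math.ceil(0.1 * result.corpus_compound_count)
    return result.rank_of_target <= cutoff


def median_rank(results: Sequence[RetrievalResult]) -> float:
    """Median target rank over queries (mean of middle two for even counts)."""
    ranks = [r.rank_of_target for r in results if r.rank_of_target is not None]
    if not ranks:
        raise ValueError("no ranked results")
    return float(np.median(ranks))


def _check_rank_lists(rank_lists: Sequence[Mapping[str, float]]) -> list[str]:
    if not rank_lists:
        raise ValueError("rank_lists is empty")
    compounds = sorted(rank_lists[0])
    for i, lst in enumerate(rank_lists):
        for c in compounds:
            if c not in lst:
                raise ValueError(f"compound {c!r} missing from rank list {i}")
        if len(lst) != len(compounds):
            extra = sorted(set(lst) - set(compounds))
            raise ValueError(f"compound {extra[0]!r} missing from rank list 0")
    return compounds


def meta_rank_product(rank_lists: Sequence[Mapping[str, float]]) -> list[str]:
    """Compounds ordered by the geometric mean of their ranks across lists.

    Every compound appears in every list, so ordering by the raw rank
    product is equivalent to ordering by the geometric mean and keeps
    genuinely tied products exactly tied (integer ranks stay exact).
    """
    compounds = _check_rank_lists(rank_lists)
    product = {c: float(np.prod([lst[c] for lst in rank_lists])) for c in compounds}
    return sorted(compounds, key=lambda c: (product[c], c))


def meta_rank_percentile(
    rank_lists: Sequence[Mapping[str, float]], percentile: float = 75.0
) -> list[str]:
    """Compounds ordered by a percentile (default 75th) of their ranks.

    Uses linear interpolation between order statistics; ties fall back to
    lexicographic compound order.
    """
    compounds = _check_rank_lists(rank_lists)
    stat = {
        c: float(np.percentile([lst[c] for lst in rank_lists], percentile))
        for c in compounds
    }
    return sorted(compounds, key=lambda c: (stat[c], c))
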