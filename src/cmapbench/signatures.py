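"""Query-signature generation.

Four thresholding procedures turn a DE profile into paired up/down gene
lists: a fixed cutoff, a hybrid cutoff with top-150 truncation, and top-k
selections over either all genes or the landmark subset.  Query engines of
the connectivity-map family restrict list sizes to 10-150 genes per
direction; conditions outside the bounds yield a Disqualification value
rather than an exception so batch runs can report them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import DEProfile
from .synth import ConditionKey

__all__ = [
    "Signature",
    "Disqualification",
    "MIN_LIST",
    "MAX_LIST",
    "fixed_cutoff_signature",
    "hybrid_threshold_signature",
    "top_k_signature",
    "restrict_to_universe",
]

MIN_LIST = 10
MAX_LIST = 150


@dataclass(eq=False)
class Signature:
    """Ordered up/down gene lists plus the method that produced them."""

    up_genes: list[str]
    down_genes: list[str]
    method: str
    source_condition: ConditionKey | None = None
    gene_universe: str = "all"

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down gene lists must be disjoint")
        if len(set(self.up_genes)) != len(self.up_genes) or len(
            set(self.down_genes)
        ) != len(self.down_genes):
            raise ValueError("gene lists must not contain duplicates")

    @property
    def query_eligible(self) -> bool:
        return (
            MIN_LIST <= len(self.up_genes) <= MAX_LIST
            and MIN_LIST <= len(self.down_genes) <= MAX_LIST
        )


@dataclass
class Disqualification:
    """A condition excluded from querying, with the rule that excluded it."""

    condition: ConditionKey | None
    reason: str
    method: str = ""


def _ordered_by_magnitude(values: pd.Series) -> list[str]:
    """Gene ids sorted by descending |value|; ties broken lexicographically."""
    df = pd.DataFrame({"mag": values.abs(), "gene": values.index.astype(str)})
    df = df.sort_values(["mag", "gene"], ascending=[False, True], kind="stable")
    return df["gene"].tolist()


def fixed_cutoff_signature(
    profile: DEProfile, cutoff: float = 1.0
) -> Signature | Disqualification:
    """Up = genes >= +cutoff, down = genes <= -cutoff; 10-150 genes per side.

    Lists are ordered by descending magnitude of change.  Either list
    falling below 10 or above 150 genes disqualifies the condition.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    v = profile.values
    up = v[v >= cutoff]
    down = v[v <= -cutoff]
    for name, lst in (("up", up), ("down", down)):
        if len(lst) < MIN_LIST:
            return Disqualification(profile.condition, f"{name}<{MIN_LIST}", "fixed_cutoff")
        if len(lst) > MAX_LIST:
            return Disqualification(profile.condition, f"{name}>{MAX_LIST}", "fixed_cutoff")
    return Signature(
        up_genes=_ordered_by_magnitude(up),
        down_genes=_ordered_by_magnitude(down),
        method="fixed_cutoff",
        source_condition=profile.condition,
    )


def hybrid_threshold_signature(profile: DEProfile) -> Signature | Disqualification:
    """Cutoff at +-1.0, but lists over 150 genes truncate to the 150 largest.

    Lists under 10 genes still disqualify the condition.
    """
    v = profile.values
    up = v[v >= 1.0]
    down = v[v <= -1.0]
    for name, lst in (("up", up), ("down", down)):
        if len(lst) < MIN_LIST:
            return Disqualification(profile.condition, f"{name}<{MIN_LIST}", "hybrid")
    return Signature(
        up_genes=_ordered_by_magnitude(up)[:MAX_LIST],
        down_genes=_ordered_by_magnitude(down)[:MAX_LIST],
        method="hybrid",
        source_condition=profile.condition,
    )


def top_k_signature(
    profile: DEProfile,
    k_per_direction: int,
    universe: str = "all",
    landmark_ids: pd.Index | None = None,
) -> Signature | Disqualification:
    """The k most-positive and k most-negative genes, per direction.

    k=50 over the landmark universe is the "Top-100" procedure; k=10 and
    k=150 over all genes are "Top-20" and "Top-300".  Genes with value
    exactly 0 never enter either list; profiles with fewer than k strictly
    signed genes in the chosen universe are disqualified.
    """
    if k_per_direction < 1:
        raise ValueError("k_per_direction must be >= 1")
    if universe not in ("all", "landmark"):
        raise ValueError("universe must be 'all' or 'landmark'")
    v = profile.values
    if universe == "landmark":
        if landmark_ids is None:
            raise ValueError("landmark universe requires landmark_ids")
        v = v.loc[v.index.intersection(landmark_ids)]
    pos = v[v > 0]
    neg = v[v < 0]
    method = f"top{2 * k_per_direction}"
    if len(pos) < k_per_direction:
        return Disqualification(
            profile.condition, f"<{k_per_direction} positive genes in {universe}", method
        )
    if len(neg) < k_per_direction:
        return Disqualification(
            profile.condition, f"<{k_per_direction} negative genes in {universe}", method
        )
    return Signature(
        up_genes=_ordered_by_magnitude(pos)[:k_per_direction],
        down_genes=_ordered_by_magnitude(neg)[:k_per_direction],
        method=method,
        source_condition=profile.condition,
        gene_universe=universe,
    )


def restrict_to_universe(profile: DEProfile, gene_set) -> DEProfile:
    """Restrict a profile to a gene universe (e.g. shared or landmark genes).

    Preserves the profile's gene order; errors on an empty intersection.
    """
    gene_index = pd.Index(gene_set)
    if len(gene_index) == 0:
        raise ValueError("gene_set must be nonempty")
    return profile.restricted(gene_index)
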