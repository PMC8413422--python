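"""Differential-expression engine.

Turns probe-level or sample-level expression into gene-level DE profiles:
probe-to-gene collapsing (max-magnitude rule), plate-matched fold-change
computation under the 2-20 equal-group-size constraint, moderated z-scores,
de-standardization, and ternarization at the conventional cutoffs
(|log2FC| >= 1.0, |de-standardized z| >= 2.0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synth import ConditionKey, ExpressionMatrix, substream

__all__ = [
    "DEProfile",
    "TernaryVector",
    "ProbeMap",
    "Exclusion",
    "collapse_probes",
    "select_representative_profiles",
    "compute_fc_profiles",
    "compute_mzs_profiles",
    "destandardize_mzs",
    "ternarize",
    "count_de_genes",
    "FC_CUTOFF",
    "MZS_CUTOFF",
]

FC_CUTOFF = 1.0  # |log2 fold-change| at or beyond which a gene counts as DE
MZS_CUTOFF = 2.0  # |z * sqrt(n)| cutoff for de-standardized moderated z-scores


@dataclass(eq=False)
class DEProfile:
    """One gene-indexed differential-expression vector for a condition instance.

    ``kind`` is "FC" (log2 fold-change) or "MZS" (moderated z-score);
    ``n_contributing_replicates`` is the sample-group size behind the profile
    and is the n used when de-standardizing MZS values.
    """

    condition: ConditionKey
    kind: str
    values: pd.Series
    n_contributing_replicates: int
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("FC", "MZS"):
            raise ValueError(f"kind must be 'FC' or 'MZS', got {self.kind!r}")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("DE profile values must be finite")
        if self.n_contributing_replicates < 1:
            raise ValueError("n_contributing_replicates must be >= 1")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def restricted(self, gene_ids: pd.Index) -> "DEProfile":
        common = self.values.index.intersection(gene_ids)
        if len(common) == 0:
            raise ValueError("gene restriction leaves an empty profile")
        return DEProfile(
            condition=self.condition,
            kind=self.kind,
            values=self.values.loc[common],
            n_contributing_replicates=self.n_contributing_replicates,
            replicate_id=self.replicate_id,
        )


@dataclass(eq=False)
class TernaryVector:
    """Gene-indexed values in {-1, 0, +1}: under-expressed / unchanged / over-expressed."""

    values: pd.Series
    source_kind: str
    thresholds_used: tuple[float, float]

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (-1, 0, 1)).all():
            raise TypeError("ternary values must be in {-1, 0, +1}")


ProbeMap = Mapping[str, frozenset]
"""probe_id -> set of gene_ids; probes hitting more than one gene are dropped."""


@dataclass
class Exclusion:
    """Machine-readable record of a condition/group skipped by a processing rule."""

    condition: str
    reason: str


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: Mapping[str, Iterable]) -> pd.DataFrame:
    """Collapse a probe x profile matrix to gene x profile.

    Probes mapping to more than one gene are removed outright.  Where several
    probes map to one gene, each profile (column) independently keeps the
    value of largest absolute magnitude, sign preserved.
    """
    if not probe_map:
        raise ValueError("probe map is empty")
    single = {p: next(iter(gs)) for p, gs in probe_map.items() if len(set(gs)) == 1}
    keep = [p for p in probe_matrix.index if p in single]
    if not keep:
        return pd.DataFrame(
            index=pd.Index([], name="gene_id"), columns=probe_matrix.columns, dtype=float
        )
    sub = probe_matrix.loc[keep]
    gene_of = pd.Series([single[p] for p in keep], index=sub.index)
    # per gene, per column: row index of the max-|value| probe
    winners = sub.abs().groupby(gene_of).idxmax()
    out = {}
    for col in sub.columns:
        out[col] = sub[col].to_numpy()[sub.index.get_indexer(winners[col])]
    collapsed = pd.DataFrame(out, index=winners.index)
    collapsed.index.name = "gene_id"
    return collapsed.sort_index()


def select_representative_profiles(
    profiles: Sequence[DEProfile], seed: int
) -> list[DEProfile]:
    """Keep exactly one profile per distinct condition, chosen uniformly at random.

    Mirrors the duplicate-condition handling used when building a query
    corpus: duplicate profiles of the same condition are collapsed to a
    single random representative.  Deterministic under the seed.
    """
    by_condition: dict[ConditionKey, list[DEProfile]] = {}
    for p in profiles:
        by_condition.setdefault(p.condition, []).append(p)
    out: list[DEProfile] = []
    for cond in sorted(by_condition, key=str):
        group = sorted(by_condition[cond], key=lambda p: p.replicate_id)
        rng = substream(seed, "representative", str(cond))
        out.append(group[int(rng.integers(len(group)))])
    return out


def _matched_control_group(
    meta: pd.DataFrame, plate_pool: str
) -> tuple[str, pd.Index] | None:
    """Largest control group sharing the plate pool; ties broken lexicographically."""
    ctl = meta[(meta["role"] == "control") & (meta["plate_pool"] == plate_pool)]
    if ctl.empty:
        return None
    sizes = ctl.groupby("replicate_group").size()
    best = sizes.sort_index().sort_values(kind="stable", ascending=False).index[0]
    return best, ctl.index[ctl["replicate_group"] == best]


def _subsample(ids: pd.Index, n: int, rng: np.random.Generator) -> pd.Index:
    if len(ids) <= n:
        return ids
    pick = rng.choice(len(ids), size=n, replace=False)
    return ids[np.sort(pick)]


def compute_fc_profiles(
    expr: ExpressionMatrix,
    group_bounds: tuple[int, int] = (2, 20),
    seed: int = 0,
) -> tuple[list[DEProfile], list[Exclusion]]:
    """Plate-matched log2 fold-change profiles, one per treatment replicate group.

    For each treatment group the largest control group from the same plate
    pool is used; both groups are randomly subsampled (seeded) to a common
    size within ``group_bounds`` so they contribute equal sample numbers.
    Groups that cannot reach the minimum are skipped and reported.
    """
    lo, hi = group_bounds
    meta = expr.sample_meta
    profiles: list[DEProfile] = []
    exclusions: list[Exclusion] = []
    treat = meta[meta["role"] == "treatment"]
    for rep_group, rows in treat.groupby("replicate_group", sort=True):
        cond = expr.condition_of(rep_group)
        plate = rows["plate_pool"].iloc[0]
        matched = _matched_control_group(meta, plate)
        if matched is None:
            exclusions.append(Exclusion(str(cond), f"no plate-matched control ({rep_group})"))
            continue
        _, ctl_ids = matched
        n = min(len(rows), len(ctl_ids), hi)
        if n < lo:
            exclusions.append(
                Exclusion(str(cond), f"group size {n} below minimum {lo} ({rep_group})")
            )
            continue
        rng = substream(seed, "fc-subsample", rep_group)
        t_ids = _subsample(rows.index, n, rng)
        c_ids = _subsample(ctl_ids, n, rng)
        fc = expr.values[t_ids].mean(axis=1) - expr.values[c_ids].mean(axis=1)
        profiles.append(
            DEProfile(
                condition=cond,
                kind="FC",
                values=fc,
                n_contributing_replicates=n,
                replicate_id=rep_group,
            )
        )
    return profiles, exclusions


def compute_mzs_profiles(
    expr: ExpressionMatrix,
    group_bounds: tuple[int, int] = (2, 20),
    seed: int = 0,
    var_floor: float = 1e-3,
) -> tuple[list[DEProfile], list[Exclusion]]:
    """Moderated z-score profiles from sample-level expression.

    z_g = (mean treatment - mean control) / sqrt((s2_t + s2_c) / n + floor),
    with a small variance floor guarding near-constant genes.  Group matching,
    size constraints and subsampling are identical to :func:`compute_fc_profiles`.
    The recorded ``n_contributing_replicates`` is the per-group sample size
    used, which later drives de-standardization (z * sqrt(n)).
    """
    lo, hi = group_bounds
    meta = expr.sample_meta
    profiles: list[DEProfile] = []
    exclusions: list[Exclusion] = []
    treat = meta[meta["role"] == "treatment"]
    for rep_group, rows in treat.groupby("replicate_group", sort=True):
        cond = expr.condition_of(rep_group)
        plate = rows["plate_pool"].iloc[0]
        matched = _matched_control_group(meta, plate)
        if matched is None:
            exclusions.append(Exclusion(str(cond), f"no plate-matched control ({rep_group})"))
            continue
        _, ctl_ids = matched
        n = min(len(rows), len(ctl_ids), hi)
        if n < lo:
            exclusions.append(
                Exclusion(str(cond), f"group size {n} below minimum {lo} ({rep_group})")
            )
            continue
        rng = substream(seed, "fc-subsample", rep_group)  # same draws as the FC path
        t_ids = _subsample(rows.index, n, rng)
        c_ids = _subsample(ctl_ids, n, rng)
        t = expr.values[t_ids].to_numpy()
        c = expr.values[c_ids].to_numpy()
        diff = t.mean(axis=1) - c.mean(axis=1)
        se = np.sqrt((t.var(axis=1, ddof=1) + c.var(axis=1, ddof=1)) / n + var_floor)
        z = pd.Series(diff / se, index=expr.gene_ids)
        profiles.append(
            DEProfile(
                condition=cond,
                kind="MZS",
                values=z,
                n_contributing_replicates=n,
                replicate_id=rep_group,
            )
        )
    return profiles, exclusions


def destandardize_mzs(profile: DEProfile) -> pd.Series:
    """Multiply moderated z-scores by sqrt(n contributing replicates)."""
    if profile.kind != "MZS":
        raise TypeError(f"destandardize_mzs requires kind='MZS', got {profile.kind!r}")
    return profile.values * np.sqrt(profile.n_contributing_replicates)


def ternarize(profile: DEProfile) -> TernaryVector:
    """Threshold a DE profile into {-1, 0, +1}.

    FC profiles use +-1.0 cutoffs directly; MZS profiles are de-standardized
    first and then cut at +-2.0.  Values exactly at a cutoff count as DE.
    """
    if profile.kind == "FC":
        vals, cut = profile.values, FC_CUTOFF
    else:
        vals, cut = destandardize_mzs(profile), MZS_CUTOFF
    arr = vals.to_numpy()
    tern = np.where(arr >= cut, 1, np.where(arr <= -cut, -1, 0))
    return TernaryVector(
        values=pd.Series(tern, index=vals.index),
        source_kind=profile.kind,
        thresholds_used=(-cut, cut),
    )


def count_de_genes(t: TernaryVector) -> int:
    """Number of differentially expressed (nonzero) genes."""
    return int(np.count_nonzero(t.values.to_numpy()))
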