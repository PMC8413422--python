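"""Synthetic perturbation-corpus generator.

Produces paired "platform A / platform B" gene-expression compendia with
planted ground truth so that every downstream stage (differential expression,
signature generation, query retrieval, agreement statistics, regression) can
be benchmarked against a known answer.

The generative model, per treatment sample on platform P:

    x_gs = baseline_g + plate(s) + f(d) * resp(c, l) * theta^P_g(c, l)
           + eps_gs + eta_gs

where ``f(d) = d^h / (EC50^h + d^h)`` is a Hill saturation in the compound
concentration d, ``resp`` is a per-(compound, cell line) responsiveness in
[0, 1], ``theta^P`` is the platform's sparse effect vector, ``eps`` is
per-sample expression noise and ``eta`` is platform-specific distortion
(treatment samples only).  Control samples carry only baseline, plate offset
and noise.  Plate offsets are gene-independent scalars shared by a treatment
replicate group and its plate-matched control group, so they cancel exactly
in within-plate differential expression.

Platform B effect vectors are constructed as

    theta^B = rho * z1 + sqrt(1 - rho^2) * z2

with z1 = theta^A and z2 an independent draw from the same sparse
distribution, so the expected Pearson correlation between the two platforms'
effect vectors equals the requested concordance rho.  All random draws flow
through keyed substreams of a single corpus seed, so z2 and every noise draw
are invariant to rho: regenerating the corpus on a grid of rho values varies
only the planted concordance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConditionKey",
    "CorpusSpec",
    "GroundTruth",
    "ExpressionMatrix",
    "generate_ground_truth",
    "dose_scaling",
    "simulate_corpus",
    "substream",
]


def substream(seed: int, *key: object) -> np.random.Generator:
    """Deterministic, independent RNG substream keyed by strings/numbers.

    A single corpus seed expands into named substreams (one per stage and per
    condition), so components can be regenerated independently and draws for
    one entity never shift when an unrelated parameter changes.
    """
    tag = zlib.crc32("/".join(str(k) for k in key).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


@dataclass(frozen=True, order=True)
class ConditionKey:
    """Experimental unit of identity: compound x concentration x cell line x duration."""

    compound: str
    concentration_uM: float
    cell_line: str
    duration_h: float

    def __str__(self) -> str:  # "10 uM metformin in MCF7 for 6 h" style
        return (
            f"{self.concentration_uM:g} uM {self.compound} in "
            f"{self.cell_line} for {self.duration_h:g} h"
        )


class SpecValidationError(ValueError):
    """Raised when a CorpusSpec field violates its invariant."""


@dataclass
class CorpusSpec:
    """Parameters of a synthetic two-platform perturbation corpus.

    Defaults describe a small but fully featured compendium: 20 compounds in
    two cell lines at four log-spaced concentrations spanning typical EC50s,
    three replicate profiles per condition, and mid-level noise relative to
    an effect scale of 2 (log2 units).
    """

    n_genes: int = 1000
    n_landmark: int = 100
    compounds: Sequence[str] = field(
        default_factory=lambda: [f"cpd{i:02d}" for i in range(20)]
    )
    concentrations: Sequence[float] = field(
        default_factory=lambda: [0.1, 1.0, 10.0, 100.0]
    )
    cell_lines: Sequence[str] = field(default_factory=lambda: ["MCF7", "PC3"])
    duration_h: float = 6.0
    n_replicate_profiles: int = 3
    n_samples_per_group: int = 4
    sample_noise_sd: float = 0.5
    platform_noise_sd: float = 0.25
    plate_effect_sd: float = 0.3
    concordance_rho: float = 0.8
    frac_de_genes: float = 0.15
    effect_scale: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise SpecValidationError("n_genes must be positive")
        if not (0 < self.n_landmark <= self.n_genes):
            raise SpecValidationError("n_landmark must be in (0, n_genes]")
        if not self.compounds:
            raise SpecValidationError("compounds must be non-empty")
        if len(set(self.compounds)) != len(self.compounds):
            raise SpecValidationError("compounds must be unique")
        if not self.concentrations or any(c <= 0 for c in self.concentrations):
            raise SpecValidationError("concentrations must be positive")
        if not self.cell_lines:
            raise SpecValidationError("cell_lines must be non-empty")
        if self.duration_h <= 0:
            raise SpecValidationError("duration_h must be positive")
        if self.n_replicate_profiles < 1:
            raise SpecValidationError("n_replicate_profiles must be >= 1")
        if not (2 <= self.n_samples_per_group <= 20):
            raise SpecValidationError("n_samples_per_group must be within [2, 20]")
        for name in ("sample_noise_sd", "platform_noise_sd", "plate_effect_sd"):
            if getattr(self, name) < 0:
                raise SpecValidationError(f"{name} must be nonnegative")
        if not (0.0 <= self.concordance_rho <= 1.0):
            raise SpecValidationError("concordance_rho must be in [0, 1]")
        if not (0.0 < self.frac_de_genes <= 1.0):
            raise SpecValidationError("frac_de_genes must be in (0, 1]")
        if self.effect_scale <= 0:
            raise SpecValidationError("effect_scale must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        width = len(str(self.n_genes))
        return pd.Index([f"G{i:0{width}d}" for i in range(self.n_genes)], name="gene_id")

    @property
    def landmark_ids(self) -> pd.Index:
        return self.gene_ids[: self.n_landmark]

    def with_(self, **kw) -> "CorpusSpec":
        return replace(self, **kw)


@dataclass(eq=False)
class GroundTruth:
    """Planted parameters of a corpus: what the analysis should recover."""

    effect_vectors: Mapping[tuple[str, str], pd.Series]
    platformB_effect_vectors: Mapping[tuple[str, str], pd.Series]
    ec50: Mapping[str, float]
    hill_coeff: Mapping[str, float]
    responsiveness: dict[tuple[str, str], float]
    baseline: pd.Series

    def effect_for(self, platform: str, compound: str, cell_line: str) -> pd.Series:
        if platform == "A":
            return self.effect_vectors[(compound, cell_line)]
        if platform == "B":
            return self.platformB_effect_vectors[(compound, cell_line)]
        raise ValueError(f"unknown platform {platform!r}; expected 'A' or 'B'")

    def to_frame(self) -> pd.DataFrame:
        """Ground-truth effect vectors as a tidy table (for TSV export)."""
        rows = []
        for (compound, cell), theta in self.effect_vectors.items():
            theta_b = self.platformB_effect_vectors[(compound, cell)]
            df = pd.DataFrame(
                {
                    "compound": compound,
                    "cell_line": cell,
                    "gene_id": theta.index,
                    "effect_A": theta.values,
                    "effect_B": theta_b.values,
                }
            )
            df["ec50_uM"] = self.ec50[compound]
            df["hill_coeff"] = self.hill_coeff[compound]
            df["responsiveness"] = self.responsiveness[(compound, cell)]
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


@dataclass(eq=False)
class ExpressionMatrix:
    """A gene x sample log2 expression matrix with complete sample metadata.

    ``sample_meta`` is indexed by sample id with columns: compound,
    concentration_uM, cell_line, duration_h, role (treatment|control),
    plate_pool, replicate_group.  Control rows carry empty compound and
    NaN concentration.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    landmark_ids: pd.Index

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.values.columns.equals(self.sample_meta.index):
            raise ValueError("sample_meta index must match matrix columns")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def condition_of(self, replicate_group: str) -> ConditionKey:
        rows = self.sample_meta[self.sample_meta["replicate_group"] == replicate_group]
        r = rows.iloc[0]
        return ConditionKey(
            r["compound"], float(r["concentration_uM"]), r["cell_line"], float(r["duration_h"])
        )


def _sparse_effect(rng: np.random.Generator, spec: CorpusSpec) -> np.ndarray:
    """Sparse effect draw: Bernoulli(frac_de) support, N(0, effect_scale) magnitudes."""
    mask = rng.random(spec.n_genes) < spec.frac_de_genes
    vals = rng.normal(0.0, spec.effect_scale, size=spec.n_genes)
    return np.where(mask, vals, 0.0)


def generate_ground_truth(spec: CorpusSpec) -> GroundTruth:
    """Draw planted effect vectors, dose-response and responsiveness parameters.

    Platform B vectors are ``rho * z1 + sqrt(1 - rho^2) * z2`` with z2 an
    independent same-scale sparse draw, so corr(theta_A, theta_B) has
    expectation ``spec.concordance_rho``.  Substreams are keyed by compound
    and cell line only — never by rho — so a rho sweep with a fixed seed
    reuses identical z1, z2 draws.
    """
    spec.validate()
    genes = spec.gene_ids
    rho = spec.concordance_rho
    effect_a: dict[tuple[str, str], pd.Series] = {}
    effect_b: dict[tuple[str, str], pd.Series] = {}
    responsiveness: dict[tuple[str, str], float] = {}
    ec50: dict[str, float] = {}
    hill: dict[str, float] = {}

    lo, hi = min(spec.concentrations), max(spec.concentrations)
    for compound in spec.compounds:
        rng_c = substream(spec.seed, "truth", "compound", compound)
        if lo == hi:
            ec50[compound] = float(lo)
        else:
            ec50[compound] = float(
                10 ** rng_c.uniform(np.log10(lo), np.log10(hi))
            )
        hill[compound] = float(rng_c.uniform(1.0, 2.0))
        for cell in spec.cell_lines:
            rng_e = substream(spec.seed, "truth", "effect", compound, cell)
            z1 = _sparse_effect(rng_e, spec)
            z2 = _sparse_effect(rng_e, spec)
            theta_b = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * z2
            effect_a[(compound, cell)] = pd.Series(z1, index=genes)
            effect_b[(compound, cell)] = pd.Series(theta_b, index=genes)
            rng_r = substream(spec.seed, "truth", "resp", compound, cell)
            responsiveness[(compound, cell)] = float(rng_r.uniform(0.3, 1.0))

    rng_b = substream(spec.seed, "truth", "baseline")
    baseline = pd.Series(rng_b.uniform(4.0, 12.0, size=spec.n_genes), index=genes)
    return GroundTruth(
        effect_vectors=effect_a,
        platformB_effect_vectors=effect_b,
        ec50=ec50,
        hill_coeff=hill,
        responsiveness=responsiveness,
        baseline=baseline,
    )


def dose_scaling(concentration: float, ec50: float, hill_coeff: float) -> float:
    """Hill saturation fraction ``d^h / (EC50^h + d^h)`` in [0, 1].

    Strictly increasing in concentration; equals 0.5 at the EC50.
    Computed on the log scale for numerical stability at extreme doses.
    """
    if concentration <= 0 or ec50 <= 0 or hill_coeff <= 0:
        raise ValueError("concentration, ec50 and hill_coeff must all be positive")
    # d^h / (ec50^h + d^h) = 1 / (1 + (ec50/d)^h)
    log_ratio = hill_coeff * (np.log(ec50) - np.log(concentration))
    return float(1.0 / (1.0 + np.exp(log_ratio)))


def simulate_corpus(truth: GroundTruth, spec: CorpusSpec, platform: str) -> ExpressionMatrix:
    """Simulate one platform's expression matrix from planted ground truth.

    Every condition (compound x concentration x cell line) receives
    ``n_replicate_profiles`` replicate groups; each group has its own plate
    pool holding ``n_samples_per_group`` treatment and as many plate-matched
    control samples.
    """
    if platform not in ("A", "B"):
        raise ValueError(f"platform must be 'A' or 'B', got {platform!r}")
    spec.validate()
    genes = spec.gene_ids
    baseline = truth.baseline.to_numpy()

    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[dict] = []

    for compound in spec.compounds:
        theta_by_cell = {
            cell: truth.effect_for(platform, compound, cell).to_numpy()
            for cell in spec.cell_lines
        }
        for cell in spec.cell_lines:
            for conc in spec.concentrations:
                frac = dose_scaling(conc, truth.ec50[compound], truth.hill_coeff[compound])
                signal = frac * truth.responsiveness[(compound, cell)] * theta_by_cell[cell]
                for rep in range(spec.n_replicate_profiles):
                    tag = f"{compound}_{cell}_{conc:g}_r{rep}"
                    plate = f"PL_{platform}_{tag}"
                    rep_group = f"RG_{platform}_{tag}"
                    ctl_group = f"CG_{platform}_{tag}"
                    rng = substream(spec.seed, "corpus", platform, tag)
                    plate_offset = rng.normal(0.0, spec.plate_effect_sd)
                    n = spec.n_samples_per_group
                    noise_t = rng.normal(0.0, spec.sample_noise_sd, size=(spec.n_genes, n))
                    noise_c = rng.normal(0.0, spec.sample_noise_sd, size=(spec.n_genes, n))
                    distort = (
                        rng.normal(0.0, spec.platform_noise_sd, size=(spec.n_genes, n))
                        if spec.platform_noise_sd > 0
                        else 0.0
                    )
                    treat = baseline[:, None] + plate_offset + signal[:, None] + noise_t + distort
                    ctrl = baseline[:, None] + plate_offset + noise_c
                    for i in range(n):
                        sample_ids.append(f"{platform}_{tag}_T{i}")
                        columns.append(treat[:, i])
                        meta_rows.append(
                            dict(
                                compound=compound,
                                concentration_uM=conc,
                                cell_line=cell,
                                duration_h=spec.duration_h,
                                role="treatment",
                                plate_pool=plate,
                                replicate_group=rep_group,
                            )
                        )
                    for i in range(n):
                        sample_ids.append(f"{platform}_{tag}_C{i}")
                        columns.append(ctrl[:, i])
                        meta_rows.append(
                            dict(
                                compound="",
                                concentration_uM=np.nan,
                                cell_line=cell,
                                duration_h=spec.duration_h,
                                role="control",
                                plate_pool=plate,
                                replicate_group=ctl_group,
                            )
                        )

    values = pd.DataFrame(
        np.column_stack(columns), index=genes, columns=pd.Index(sample_ids, name="sample_id")
    )
    meta = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    return ExpressionMatrix(values=values, sample_meta=meta, landmark_ids=spec.landmark_ids)
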