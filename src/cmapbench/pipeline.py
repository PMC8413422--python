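"""End-to-end orchestration.

One reproducible run ties the stages together in the order the analysis
proceeds: simulate a two-platform corpus, compute DE profiles, generate
query signatures, compute within- and cross-dataset agreement, run the
retrieval benchmark, and fit the explanatory models.  Every intermediate is
persisted as text (GCT / GRP / TSV / JSON) and the whole run is a pure
function of (config, seed): re-running reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .agreement import (
    attach_sample_agreements,
    cross_dataset_agreement,
    harmonize,
    within_dataset_agreement,
)
from .de import compute_fc_profiles, compute_mzs_profiles, select_representative_profiles
from .modeling import (
    build_regression_input,
    de_count_vs_dose,
    dose_trend,
    standardized_linear_fit,
)
from .retrieval import CorpusIndex, median_rank, query_corpus, success_at_decile
from .signatures import Disqualification, hybrid_threshold_signature
from .synth import CorpusSpec, generate_ground_truth, simulate_corpus

__all__ = ["RunConfig", "RunReport", "run_pipeline", "STAGES", "config_hash"]

log = logging.getLogger("cmapbench")

STAGES = ["simulate", "de", "signatures", "agree", "retrieve", "model"]

FLOAT_FMT = "%.6g"


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    corpus: CorpusSpec = field(default_factory=CorpusSpec)
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    fc_cutoff: float = 1.0
    mzs_cutoff: float = 2.0
    min_list: int = 10
    max_list: int = 150
    aggregate: str = "max"
    direction: str = "mimic"
    constrain_cell_line: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}")
        # stages must form a prefix-closed chain: each stage needs its predecessors
        enabled = [s for s in STAGES if s in self.stages]
        if enabled != STAGES[: len(enabled)]:
            raise ConfigError(
                f"stages must be a prefix of {STAGES} (each stage needs its predecessors)"
            )
        if self.aggregate not in ("max", "median"):
            raise ConfigError("aggregate must be 'max' or 'median'")
        if self.direction not in ("mimic", "reverse"):
            raise ConfigError("direction must be 'mimic' or 'reverse'")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        corpus_doc = dict(doc.get("corpus") or {})
        if "corpus" in doc:
            corpus_known = {f.name for f in dataclasses.fields(CorpusSpec)}
            bad = set(corpus_doc) - corpus_known
            if bad:
                raise ConfigError(f"unknown corpus keys: {sorted(bad)}")
            doc["corpus"] = CorpusSpec(**corpus_doc)
        cfg = cls(**doc)
        # the run seed drives the corpus too, unless the corpus block pins its own
        if "seed" not in corpus_doc:
            cfg.corpus = cfg.corpus.with_(seed=cfg.seed)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["corpus"]["compounds"] = list(d["corpus"]["compounds"])
        d["corpus"]["concentrations"] = list(d["corpus"]["concentrations"])
        d["corpus"]["cell_lines"] = list(d["corpus"]["cell_lines"])
        return d


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Counts and summary statistics of one pipeline run."""

    config_hash: str
    seed: int
    software_version: str
    stage_counts: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)


def _write_exclusions(exclusions, path: Path) -> None:
    df = pd.DataFrame(
        [dict(condition=e.condition, reason=e.reason) for e in exclusions],
        columns=["condition", "reason"],
    )
    df.to_csv(path, sep="\t", index=False)


def _records_to_tables(records) -> tuple[pd.DataFrame, pd.DataFrame]:
    pair_rows, cond_rows = [], []
    for rec in records:
        for p in rec.pairs:
            pair_rows.append(
                dict(
                    condition=str(rec.condition),
                    metric=rec.metric,
                    replicate_a=p.replicate_a,
                    replicate_b=p.replicate_b,
                    value=p.value,
                    lesser_de_count=p.lesser_de_count,
                    in_replicate=p.in_replicate_sample_agreement,
                    cross_replicate=p.cross_replicate_sample_agreement,
                )
            )
        cond_rows.append(
            dict(
                condition=str(rec.condition),
                metric=rec.metric,
                n_pairs=len(rec.pairs),
                max_value=rec.max_value,
                lesser_de_count=rec.lesser_de_count,
            )
        )
    cols_p = [
        "condition", "metric", "replicate_a", "replicate_b", "value",
        "lesser_de_count", "in_replicate", "cross_replicate",
    ]
    cols_c = ["condition", "metric", "n_pairs", "max_value", "lesser_de_count"]
    return (
        pd.DataFrame(pair_rows, columns=cols_p),
        pd.DataFrame(cond_rows, columns=cols_c),
    )


def run_pipeline(config: RunConfig, outdir) -> RunReport:
    """Execute the enabled stages in order, persisting every intermediate."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report = RunReport(
        config_hash=config_hash(config),
        seed=config.seed,
        software_version=__import__("cmapbench").__version__,
    )
    (outdir / "config.json").write_text(
        json.dumps(config.to_dict(), sort_keys=True, indent=2) + "\n"
    )

    spec = config.corpus
    enabled = [s for s in STAGES if s in config.stages]

    # ---- simulate ------------------------------------------------------
    truth = generate_ground_truth(spec)
    expr = {}
    if "simulate" in enabled:
        for platform in ("A", "B"):
            expr[platform] = simulate_corpus(truth, spec, platform)
            cio.write_gct(expr[platform].values, outdir / f"expression_{platform}.gct")
            cio.write_sample_meta(
                expr[platform].sample_meta, outdir / f"sample_meta_{platform}.tsv"
            )
        cio.write_grp(spec.landmark_ids, outdir / "landmark_genes.grp", "landmark gene ids")
        truth.to_frame().to_csv(
            outdir / "ground_truth.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        report.stage_counts["simulate"] = {
            "n_samples_per_platform": int(expr["A"].values.shape[1]),
            "n_genes": spec.n_genes,
        }
        log.info("stage=simulate event=done samples=%d", expr["A"].values.shape[1])

    # ---- de ------------------------------------------------------------
    fc = {}
    if "de" in enabled:
        for platform in ("A", "B"):
            profiles, excl = compute_fc_profiles(expr[platform], seed=config.seed)
            fc[platform] = profiles
            mat, meta = cio.profiles_to_frame(profiles)
            mat.to_csv(outdir / f"de_fc_{platform}.tsv", sep="\t", float_format=FLOAT_FMT)
            meta.to_csv(outdir / f"de_fc_{platform}_meta.tsv", sep="\t")
            _write_exclusions(excl, outdir / f"de_fc_{platform}_exclusions.tsv")
        mzs_a, mzs_excl = compute_mzs_profiles(expr["A"], seed=config.seed)
        mat, meta = cio.profiles_to_frame(mzs_a)
        mat.to_csv(outdir / "de_mzs_A.tsv", sep="\t", float_format=FLOAT_FMT)
        meta.to_csv(outdir / "de_mzs_A_meta.tsv", sep="\t")
        _write_exclusions(mzs_excl, outdir / "de_mzs_A_exclusions.tsv")
        report.stage_counts["de"] = {
            "fc_profiles_A": len(fc["A"]),
            "fc_profiles_B": len(fc["B"]),
            "mzs_profiles_A": len(mzs_a),
        }
        log.info("stage=de event=done fc_A=%d fc_B=%d", len(fc["A"]), len(fc["B"]))

    # ---- signatures ----------------------------------------------------
    sigs = []
    disqualified: list[Disqualification] = []
    if "signatures" in enabled:
        # one query per (compound, cell line): the highest-concentration profile
        top_dose = max(spec.concentrations)
        rep_profiles = select_representative_profiles(
            [p for p in fc["A"] if p.condition.concentration_uM == top_dose],
            seed=config.seed,
        )
        manifest_rows = []
        sig_dir = outdir / "signatures"
        sig_dir.mkdir(exist_ok=True)
        for prof in rep_profiles:
            res = hybrid_threshold_signature(prof)
            cond = prof.condition
            stem = sig_dir / f"{cond.compound}_{cond.cell_line}"
            if isinstance(res, Disqualification):
                disqualified.append(res)
                manifest_rows.append(
                    dict(
                        condition=str(cond), method="hybrid", n_up=0, n_down=0,
                        disqualified=res.reason,
                    )
                )
                continue
            sigs.append(res)
            cio.write_signature_grp(res, stem)
            manifest_rows.append(
                dict(
                    condition=str(cond), method="hybrid",
                    n_up=len(res.up_genes), n_down=len(res.down_genes), disqualified="",
                )
            )
        pd.DataFrame(
            manifest_rows,
            columns=["condition", "method", "n_up", "n_down", "disqualified"],
        ).to_csv(outdir / "signature_manifest.tsv", sep="\t", index=False)
        report.stage_counts["signatures"] = {
            "eligible": len(sigs),
            "disqualified": len(disqualified),
        }
        log.info("stage=signatures event=done eligible=%d", len(sigs))

    # ---- agree ---------------------------------------------------------
    within_records = []
    cross_records = []
    if "agree" in enabled:
        within_records = within_dataset_agreement(fc["A"], metric="spearman")
        attach_sample_agreements(within_records, expr["A"])
        pairs_df, cond_df = _records_to_tables(within_records)
        pairs_df.to_csv(
            outdir / "within_agreement_pairs.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        cond_df.to_csv(
            outdir / "within_agreement_conditions.tsv", sep="\t", index=False,
            float_format=FLOAT_FMT,
        )
        rep_a = select_representative_profiles(fc["A"], seed=config.seed)
        rep_b = select_representative_profiles(fc["B"], seed=config.seed)
        hpairs, unmatched = harmonize(rep_a, rep_b, conc_tolerance=0.0)
        cross_records = cross_dataset_agreement(hpairs, metric="spearman")
        cross_land = cross_dataset_agreement(
            hpairs, metric="spearman", universe="landmark", landmark_ids=spec.landmark_ids
        )
        cross_df, _ = _records_to_tables(cross_records)
        cross_df.to_csv(
            outdir / "cross_agreement.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        cross_land_df, _ = _records_to_tables(cross_land)
        cross_land_df.to_csv(
            outdir / "cross_agreement_landmark.tsv", sep="\t", index=False,
            float_format=FLOAT_FMT,
        )
        pd.DataFrame({"unmatched_condition": [str(c) for c in unmatched]}).to_csv(
            outdir / "harmonization_unmatched.tsv", sep="\t", index=False
        )
        mean_cross = (
            float(np.mean([r.max_value for r in cross_records])) if cross_records else math.nan
        )
        report.stage_counts["agree"] = {
            "within_conditions": len(within_records),
            "cross_pairs": len(cross_records),
            "unmatched": len(unmatched),
        }
        report.summaries["agreement"] = {
            "mean_within_max_spearman": float(
                np.mean([r.max_value for r in within_records])
            )
            if within_records
            else math.nan,
            "mean_cross_spearman": mean_cross,
        }
        log.info(
            "stage=agree event=done within=%d cross=%d",
            len(within_records), len(cross_records),
        )

    # ---- retrieve ------------------------------------------------------
    results = []
    if "retrieve" in enabled:
        corpus = select_representative_profiles(fc["B"], seed=config.seed)
        index = CorpusIndex(corpus)
        shared = {p.condition.compound for p in fc["A"]} & {
            p.condition.compound for p in corpus
        }
        rows = []
        for sig in sigs:
            if config.direction == "reverse":
                sig = dataclasses.replace(
                    sig, up_genes=sig.down_genes, down_genes=sig.up_genes
                )
            cond = sig.source_condition
            res = query_corpus(
                sig,
                corpus,
                cell_line_filter=cond.cell_line if config.constrain_cell_line else None,
                compound_universe=shared,
                aggregate=config.aggregate,
                query_id=f"{cond.compound}|{cond.cell_line}",
                index=index,
            )
            results.append(res)
            rows.append(
                dict(
                    query_id=res.query_id,
                    target_compound=res.target_compound,
                    rank_of_target=res.rank_of_target,
                    inverse_rank_of_target=res.inverse_rank_of_target,
                    corpus_compound_count=res.corpus_compound_count,
                    top_decile=success_at_decile(res),
                )
            )
        res_df = pd.DataFrame(
            rows,
            columns=[
                "query_id", "target_compound", "rank_of_target",
                "inverse_rank_of_target", "corpus_compound_count", "top_decile",
            ],
        )
        res_df.to_csv(outdir / "retrieval_results.tsv", sep="\t", index=False)
        ranked_rows = [
            dict(query_id=res.query_id, compound=c, score=s, rank=i + 1)
            for res in results
            for i, (c, s) in enumerate(res.ranked_compounds)
        ]
        pd.DataFrame(
            ranked_rows, columns=["query_id", "compound", "score", "rank"]
        ).to_csv(outdir / "retrieval_rankings.tsv", sep="\t", index=False,
                 float_format=FLOAT_FMT)
        if results:
            frac = float(np.mean([success_at_decile(r) for r in results]))
            report.summaries["retrieval"] = {
                "n_queries": len(results),
                "top_decile_fraction": frac,
                "median_rank": median_rank(results),
                "rank1_fraction": float(
                    np.mean([r.rank_of_target == 1 for r in results])
                ),
            }
        report.stage_counts["retrieve"] = {"n_queries": len(results)}
        log.info("stage=retrieve event=done queries=%d", len(results))

    # ---- model ---------------------------------------------------------
    if "model" in enabled:
        table, excluded = build_regression_input(within_records)
        table.to_csv(
            outdir / "regression_input.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        fit_doc: dict = {"n_excluded": excluded}
        if len(table) >= 10:
            try:
                fit = standardized_linear_fit(table)
                fit_doc.update(
                    standardized_coefficients=fit.standardized_coefficients.round(6).to_dict(),
                    adjusted_r_squared=round(fit.adjusted_r_squared, 6),
                    f_statistic=round(fit.f_statistic, 4),
                    f_dof=list(fit.f_dof),
                    n_used=fit.n_used,
                )
            except ValueError as exc:
                fit_doc["error"] = str(exc)
        else:
            fit_doc["error"] = "too few complete conditions"
        (outdir / "regression_fit.json").write_text(
            json.dumps(fit_doc, sort_keys=True, indent=2) + "\n"
        )
        trends, ineligible = dose_trend(within_records)
        pd.DataFrame(
            [
                dict(
                    compound=t.compound, cell_line=t.cell_line, n_pairs=t.n_pairs,
                    trend_statistic=t.trend_statistic, trend_p_value=t.trend_p_value,
                )
                for t in trends
            ],
            columns=["compound", "cell_line", "n_pairs", "trend_statistic", "trend_p_value"],
        ).to_csv(outdir / "dose_trends.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        pd.DataFrame({"ineligible": ineligible}).to_csv(
            outdir / "dose_trend_ineligible.tsv", sep="\t", index=False
        )
        de_count_vs_dose(fc["A"]).to_csv(
            outdir / "de_count_vs_dose.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        report.stage_counts["model"] = {
            "regression_rows": len(table),
            "dose_trend_groups": len(trends),
        }
        if trends:
            report.summaries["dose_trend"] = {
                "mean_trend_statistic": float(np.mean([t.trend_statistic for t in trends])),
            }
        if "standardized_coefficients" in fit_doc:
            report.summaries["regression"] = {
                "coefficients": fit_doc["standardized_coefficients"],
                "adjusted_r_squared": fit_doc["adjusted_r_squared"],
            }
        log.info("stage=model event=done rows=%d trends=%d", len(table), len(trends))

    (outdir / "report.json").write_text(report.to_json() + "\n")
    return report
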