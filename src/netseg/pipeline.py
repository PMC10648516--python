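"""End-to-end orchestration: simulate -> denoise -> netbuild -> segregate
-> analyze, from a single JSON-serializable configuration.

Every stage writes plain TSV/JSON artifacts so intermediate results can be
inspected (and stages rerun) without the toolkit. One master seed governs
both the simulation streams and the permutation stream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .denoise import DenoiseResult, denoise_subject
from .errors import ConfigurationError
from .inference import (
    DEFAULT_COVARIATES,
    ModelResult,
    PermutationResult,
    block_permutation_test,
    fit_interaction_mixed,
    fit_ols,
)
from .netbuild import ConnectivityMatrix, correlation_matrix, zero_negatives
from .partition import SystemPartition, default_partition
from .segmetrics import block_matrix, mean_interactions, system_segregation
from .synth import (
    CohortSpec,
    EffectSpec,
    SubjectRecord,
    build_generating_covariance,
    cohort_to_frame,
    generate_cohort,
    generate_subject_timeseries,
    subject_seed_sequences,
)

logger = logging.getLogger(__name__)

# Exit codes for the command-line front end.
EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_QC = 3
EXIT_INFERENCE = 4


@dataclass(frozen=True)
class DenoiseParams:
    tr: float = 3.0                      # seconds
    fd_threshold: float = 0.3            # mm
    band: tuple[float, float] = (0.009, 0.08)  # Hz
    min_frames: int = 100
    n_select: int = 100


@dataclass(frozen=True)
class AnalysisParams:
    models: tuple[str, ...] = ("global", "system-type", "interaction-type", "blocks")
    n_perm: int = 1000
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    alpha: float = 0.05


_VALID_MODELS = {"global", "system-type", "interaction-type", "blocks"}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated, JSON-round-trippable configuration of a full run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    effects: EffectSpec = field(default_factory=EffectSpec)
    denoise: DenoiseParams = field(default_factory=DenoiseParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.analysis.models) - _VALID_MODELS
        if bad:
            raise ConfigurationError(f"unknown analysis models: {sorted(bad)}")
        d = self.denoise
        if not (0 < d.band[0] < d.band[1] < 0.5 / d.tr):
            raise ConfigurationError("band infeasible for TR")
        if d.n_select > d.min_frames:
            raise ConfigurationError("n_select cannot exceed min_frames")

    def to_json(self) -> str:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {
                    ("|".join(k) if isinstance(k, tuple) else k): convert(v)
                    for k, v in obj.items()
                }
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            return obj
        return json.dumps(convert(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        effects_raw = raw.get("effects", {})
        if "between_z_overrides" in effects_raw:
            effects_raw["between_z_overrides"] = {
                tuple(k.split("|")): v
                for k, v in effects_raw["between_z_overrides"].items()
            }
        for key in ("cdr_between_systems",):
            if key in effects_raw:
                effects_raw[key] = tuple(effects_raw[key])
        cohort_raw = raw.get("cohort", {})
        for key, val in list(cohort_raw.items()):
            if isinstance(val, list):
                cohort_raw[key] = tuple(val)
        den_raw = raw.get("denoise", {})
        if "band" in den_raw:
            den_raw["band"] = tuple(den_raw["band"])
        ana_raw = raw.get("analysis", {})
        for key in ("models", "covariates"):
            if key in ana_raw:
                ana_raw[key] = tuple(ana_raw[key])
        return cls(
            cohort=CohortSpec(**cohort_raw),
            effects=EffectSpec(**effects_raw),
            denoise=DenoiseParams(**den_raw),
            analysis=AnalysisParams(**ana_raw),
            seed=int(raw.get("seed", 0)),
            out_dir=raw.get("out_dir"),
        )


@dataclass
class SubjectArtifacts:
    """In-memory results for one subject that survived quality control."""

    record: SubjectRecord
    matrix: ConnectivityMatrix
    denoise: DenoiseResult


@dataclass
class RunReport:
    """Machine-readable summary of a full pipeline run."""

    n_simulated: int
    n_excluded: int
    n_analyzed: int
    segregation: pd.DataFrame
    qc: pd.DataFrame
    model_results: dict[str, ModelResult]
    permutation_results: dict[str, PermutationResult]
    version: str
    seed: int

    def to_json(self) -> str:
        def model_dict(m: ModelResult) -> dict:
            return {
                "terms": m.terms,
                "beta": m.coefficients,
                "ci95": {k: list(v) for k, v in m.ci95.items()},
                "t": m.t_values,
                "partial_r": m.partial_r,
                "p": m.p_values,
                "df": m.df,
                "r2": m.r2,
                "adj_r2": m.adj_r2,
                "marginal_r2": m.marginal_r2,
                "conditional_r2": m.conditional_r2,
                "n_obs": m.n_obs,
            }
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "counts": {
                    "simulated": self.n_simulated,
                    "qc_excluded": self.n_excluded,
                    "analyzed": self.n_analyzed,
                },
                "models": {k: model_dict(m) for k, m in self.model_results.items()},
                "permutation": {
                    k: {
                        "n_perm": p.n_perm,
                        "seed": p.seed,
                        "beta": p.observed_beta,
                        "p": p.perm_p,
                        "fdr_significant": p.fdr_significant,
                    }
                    for k, p in self.permutation_results.items()
                },
            },
            indent=2,
        )


def simulate_and_denoise(
    config: PipelineConfig,
    partition: SystemPartition,
) -> tuple[list[SubjectArtifacts], pd.DataFrame]:
    """Stages 1-3: cohort, time series, denoising and network construction.

    Returns the per-subject artifacts of retained subjects plus a QC table
    covering everyone.
    """
    cohort = generate_cohort(config.cohort, config.seed)
    # Independent per-subject noise streams, distinct from the cohort draw.
    ts_streams = subject_seed_sequences(config.seed + 1, len(cohort))
    d = config.denoise
    artifacts: list[SubjectArtifacts] = []
    qc_rows = []
    for subject, stream in zip(cohort, ts_streams):
        cov = build_generating_covariance(subject, partition, config.effects)
        data, motion, tissue, _ = generate_subject_timeseries(
            subject, cov, subject.n_frames, d.tr, config.effects, stream
        )
        res = denoise_subject(
            data, motion, d.tr,
            tissue_surrogates=tissue,
            fd_threshold=d.fd_threshold,
            band=d.band,
            min_frames=d.min_frames,
            n_select=d.n_select,
        )
        qc_rows.append(
            {
                "subject_id": subject.subject_id,
                "clean_frames": res.verdict.clean_frames,
                "pct_loss": res.pct_frames_lost,
                "verdict": "retained" if res.verdict.retained else "excluded",
                "reason": res.verdict.reason,
                "mean_fd_pre": res.mean_fd_pre,
                "mean_fd_post": res.mean_fd_post,
                "cdr": subject.cdr,
                "age": subject.age,
            }
        )
        if res.ts is None:
            logger.info("QC excluded %s (%d clean frames)",
                        subject.subject_id, res.verdict.clean_frames)
            continue
        subject.mean_fd_post = res.mean_fd_post
        m = zero_negatives(
            correlation_matrix(res.ts.data, node_ids=partition.node_ids)
        )
        artifacts.append(SubjectArtifacts(record=subject, matrix=m, denoise=res))
    return artifacts, pd.DataFrame(qc_rows)


def segregation_table(
    artifacts: list[SubjectArtifacts], partition: SystemPartition
) -> pd.DataFrame:
    """Per-subject segregation outcomes merged with covariates."""
    rows = []
    for art in artifacts:
        res = system_segregation(art.matrix, partition)
        mean_w, mean_b = mean_interactions(art.matrix, partition)
        s = art.record
        rows.append(
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "cdr": s.cdr,
                "gender": s.gender,
                "education": s.education,
                "mean_fd_post": s.mean_fd_post,
                "global_segregation": res.global_segregation,
                "assoc_segregation": res.assoc_segregation,
                "sensorimotor_segregation": res.sensorimotor_segregation,
                "mean_within": mean_w,
                "mean_between": mean_b,
            }
        )
    return pd.DataFrame(rows)


def block_table(
    artifacts: list[SubjectArtifacts], partition: SystemPartition
) -> pd.DataFrame:
    """Subjects x blocks table of block-mean connectivity (unique blocks)."""
    rows = []
    index = []
    for art in artifacts:
        bm = block_matrix(art.matrix, partition)
        long = bm.to_long()
        rows.append(long["mean_z"].to_numpy())
        index.append(art.record.subject_id)
    cols = [f"{a}__{b}" for a, b in zip(long["system_a"], long["system_b"])]
    table = pd.DataFrame(rows, index=index, columns=cols)
    undefined = table.columns[table.isna().any()]
    if len(undefined):
        # structurally undefined blocks (e.g. a 1-node system's within block)
        # cannot be tested; they are dropped here but stay NaN in block TSVs
        logger.warning("dropping undefined blocks from testing: %s",
                       list(undefined))
        table = table.drop(columns=undefined)
    return table


def _long_table(seg: pd.DataFrame, value_cols: dict[str, str],
                condition: str) -> pd.DataFrame:
    pieces = []
    for level, col in value_cols.items():
        part = seg[["subject_id", "age", "cdr", "gender", "education",
                    "mean_fd_post"]].copy()
        part[condition] = level
        part["value"] = seg[col].to_numpy()
        pieces.append(part)
    return pd.concat(pieces, ignore_index=True)


def analyze(
    seg: pd.DataFrame,
    blocks: pd.DataFrame | None,
    params: AnalysisParams,
    seed: int,
) -> tuple[dict[str, ModelResult], dict[str, PermutationResult]]:
    """Stage 5: regression, mixed-model and permutation inference."""
    if len(seg) < 25:
        raise ConfigurationError(
            f"only {len(seg)} analyzable subjects; need >= 25 for the "
            "covariate-controlled models"
        )
    covs = list(params.covariates)
    models: dict[str, ModelResult] = {}
    perms: dict[str, PermutationResult] = {}

    if "global" in params.models:
        models["global_segregation"] = fit_ols(
            seg, "global_segregation", focal=["age", "cdr"], covariates=covs
        )

    if "system-type" in params.models:
        models["assoc_segregation"] = fit_ols(
            seg, "assoc_segregation", focal=["age", "cdr"], covariates=covs
        )
        models["sensorimotor_segregation"] = fit_ols(
            seg, "sensorimotor_segregation", focal=["age", "cdr"], covariates=covs
        )
        long = _long_table(
            seg,
            {"sensorimotor": "sensorimotor_segregation",
             "association": "assoc_segregation"},
            condition="system_type",
        )
        models["mixed_age_x_system_type"] = fit_interaction_mixed(
            long, "value", "system_type", focal=["age", "cdr"], covariates=covs
        )
        models["mixed_three_way_system_type"] = fit_interaction_mixed(
            long, "value", "system_type", focal=["age", "cdr"],
            covariates=covs, three_way=True,
        )

    if "interaction-type" in params.models:
        models["mean_within"] = fit_ols(
            seg, "mean_within", focal=["age", "cdr"], covariates=covs
        )
        models["mean_between"] = fit_ols(
            seg, "mean_between", focal=["age", "cdr"], covariates=covs
        )
        long = _long_table(
            seg,
            {"between": "mean_between", "within": "mean_within"},
            condition="interaction_type",
        )
        models["mixed_age_x_interaction_type"] = fit_interaction_mixed(
            long, "value", "interaction_type", focal=["age", "cdr"],
            covariates=covs,
        )

    if "blocks" in params.models and blocks is not None:
        aligned = seg.set_index("subject_id").loc[blocks.index].reset_index()
        for focal, alternate in (("cdr", "age"), ("age", "cdr")):
            perms[focal] = block_permutation_test(
                blocks,
                aligned,
                focal=focal,
                covariates=[alternate] + covs,
                n_perm=params.n_perm,
                seed=seed + (11 if focal == "cdr" else 13),
                alpha=params.alpha,
            )
    return models, perms


def run_pipeline(config: PipelineConfig,
                 partition: SystemPartition | None = None,
                 write: bool | None = None) -> RunReport:
    """Run all stages; optionally write artifacts under ``config.out_dir``."""
    partition = partition or default_partition()
    if write is None:
        write = config.out_dir is not None

    logger.info("stage=simulate n=%d seed=%d", config.cohort.size, config.seed)
    artifacts, qc = simulate_and_denoise(config, partition)
    n_total = len(qc)
    n_kept = len(artifacts)
    logger.info("stage=qc retained=%d excluded=%d", n_kept, n_total - n_kept)

    seg = segregation_table(artifacts, partition)
    blocks = (
        block_table(artifacts, partition)
        if "blocks" in config.analysis.models and artifacts else None
    )

    logger.info("stage=analyze models=%s", ",".join(config.analysis.models))
    models, perms = analyze(seg, blocks, config.analysis, config.seed)

    report = RunReport(
        n_simulated=n_total,
        n_excluded=n_total - n_kept,
        n_analyzed=n_kept,
        segregation=seg,
        qc=qc,
        model_results=models,
        permutation_results=perms,
        version=__version__,
        seed=config.seed,
    )
    if write:
        out = Path(config.out_dir or ".")
        out.mkdir(parents=True, exist_ok=True)
        partition.to_tsv(out / "partition.tsv")
        qc.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        seg.to_csv(out / "segregation.tsv", sep="\t", index=False)
        if blocks is not None:
            blocks.to_csv(out / "blocks.tsv", sep="\t", index_label="subject_id")
        (out / "report.json").write_text(report.to_json())
        (out / "config.json").write_text(config.to_json())
    return report


def write_simulation(config: PipelineConfig, out_dir: str | Path,
                     partition: SystemPartition | None = None) -> None:
    """Write raw simulated data (covariates, per-subject time series and
    motion traces, partition, ground truth) as plain TSV/JSON files."""
    from .synth import ground_truth_for

    partition = partition or default_partition()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.cohort, config.seed)
    ts_streams = subject_seed_sequences(config.seed + 1, len(cohort))
    for subject, stream in zip(cohort, ts_streams):
        cov = build_generating_covariance(subject, partition, config.effects)
        data, motion, tissue, _ = generate_subject_timeseries(
            subject, cov, subject.n_frames, config.denoise.tr,
            config.effects, stream,
        )
        pd.DataFrame(data, columns=list(partition.node_ids)).to_csv(
            out / f"{subject.subject_id}_timeseries.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            motion,
            columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
        ).to_csv(out / f"{subject.subject_id}_motion.tsv", sep="\t", index=False)
        pd.DataFrame(tissue, columns=["white_matter", "csf"]).to_csv(
            out / f"{subject.subject_id}_tissue.tsv", sep="\t", index=False
        )
    cohort_to_frame(cohort).to_csv(out / "covariates.tsv", sep="\t", index=False)
    partition.to_tsv(out / "partition.tsv")
    gt = ground_truth_for(cohort, partition, config.effects)
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "expected_global": gt.expected_global,
                "expected_assoc": gt.expected_assoc,
                "expected_sensorimotor": gt.expected_sensorimotor,
                "spike_rate": gt.spike_rate,
                "slopes": {
                    "age_slope_within_assoc": config.effects.age_slope_within_assoc,
                    "cdr_slope_between": config.effects.cdr_slope_between,
                    "cdr_slope_within": config.effects.cdr_slope_within,
                },
            },
            indent=2,
        )
    )
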