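"""End-to-end orchestration: QC -> kernels -> CV -> fit -> evaluation.

`run_pipeline` wires the whole analysis for one (model, scheme) pair on a
validated :class:`~hybridnorm.io.DatasetBundle`; everything is deterministic
given the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .crossval import SCHEMES, run_scheme
from .enviro import OmegaKernel, align_to_planting, build_W, omega as build_omega
from .evaluation import EvalSummary, evaluate
from .io import DatasetBundle, qc_filter
from .kernels import Kernel, grm
from .model import (
    MODEL_IDS,
    SamplerConfig,
    VariancePartition,
    build_terms,
    fit,
    variance_partition,
)

__all__ = ["PipelineConfig", "PipelineReport", "prepare_kernels", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Knobs of one pipeline run (all deterministic given ``seed``)."""

    seed: int = 0
    k: int = 5
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    qc: bool = True
    center_grm: bool = True
    rescale_kernels: bool = True
    standardize_ecs: bool = True
    n_days: int = 131
    weather_completeness: float = 0.9
    fisher_z: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sampler = SamplerConfig(**d.pop("sampler", {}))
        return cls(sampler=sampler, **d)


@dataclass
class PipelineReport:
    """Everything one run produces."""

    model_id: str
    scheme: str
    evaluation: EvalSummary
    partition: VariancePartition
    predictions: pd.DataFrame
    qc_removed: pd.DataFrame
    config: PipelineConfig

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "summary": self.evaluation.to_frame(),
            "per_env": self.evaluation.per_env,
            "partition": pd.DataFrame(
                [self.partition.percentages], index=[self.model_id]
            ),
            "predictions": self.predictions,
        }


def prepare_kernels(
    bundle: DatasetBundle, config: PipelineConfig | None = None
) -> tuple[dict[str, Kernel], OmegaKernel]:
    """Build the parental GRMs and the environmental kinship for a bundle."""
    config = config or PipelineConfig()
    hybrids = bundle.hybrids
    kernels = {
        "G_P1": grm(bundle.markers.subset(hybrids.parent1_ids),
                    center=config.center_grm, level="parent1"),
        "G_P2": grm(bundle.markers.subset(hybrids.parent2_ids),
                    center=config.center_grm, level="parent2"),
    }
    grids = {
        e: align_to_planting(
            bundle.weather[e], bundle.planting[e], n_days=config.n_days,
            completeness_threshold=config.weather_completeness, env_id=e,
        )
        for e in bundle.env_ids
    }
    W = build_W(grids, standardize=config.standardize_ecs)
    return kernels, build_omega(W)


def run_pipeline(
    bundle: DatasetBundle,
    model_id: str,
    scheme: str,
    config: PipelineConfig | None = None,
) -> PipelineReport:
    """QC the phenotypes, build kernels, cross-validate, and evaluate.

    Emits per-environment correlations, the weighted average with its 95%
    CI, the full-data variance partition, and the cell-level prediction
    table.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}; expected one of {MODEL_IDS}")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    config = config or PipelineConfig()

    if config.qc:
        pheno, removed = qc_filter(bundle.pheno)
        if len(removed):
            warnings.warn(f"QC removed {len(removed)} records")
        bundle = DatasetBundle(
            bundle.markers, bundle.hybrids, pheno, bundle.weather, bundle.planting
        )
    else:
        removed = bundle.pheno.df.iloc[0:0]

    kernels, om = prepare_kernels(bundle, config)

    sampler = SamplerConfig(
        n_iter=config.sampler.n_iter, burn_in=config.sampler.burn_in,
        thin=config.sampler.thin, prior_df=config.sampler.prior_df,
        prior_var_share=config.sampler.prior_var_share, seed=config.seed,
    )
    preds = run_scheme(
        model_id, scheme, bundle, kernels, omega=om, k=config.k,
        seed=config.seed, sampler=sampler, rescale=config.rescale_kernels,
    )
    summary = evaluate(preds, model_id=model_id, scheme=scheme,
                       fisher_z=config.fisher_z)

    spec = build_terms(model_id, bundle, kernels, omega=om,
                       rescale=config.rescale_kernels)
    full_fit = fit(spec, bundle.pheno.y, sampler)
    partition = variance_partition(full_fit)

    return PipelineReport(
        model_id=model_id,
        scheme=scheme,
        evaluation=summary,
        partition=partition,
        predictions=preds,
        qc_removed=removed,
        config=config,
    )
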