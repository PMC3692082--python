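"""End-to-end orchestration: expression -> sites -> channels -> SVM scores.

The two-step architecture: first, every available scoring channel is
combined with the per-sample miRNA concentrations into per-gene channel
scores (Fermi-Dirac occupancy sums for the energy channels, weighted sums
for the count/regression channels); second, the rank-normalized channel
scores are integrated by a trained SVM into the per-gene target
probability (the ComiR score), one column per sample (set mode) or per
miRNA (single-miRNA mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .aggregate import ChannelScoreMatrix, FermiDiracParams, build_channel_matrix
from .expression import (
    ConcentrationVector,
    FilterPolicy,
    apply_filter,
    expand_modes,
    log_to_linear,
    resolve_ids,
    to_concentrations,
)
from .io import Channel, ExpressionTable, SiteScoreTable, TargetSequence
from .sites import (
    DEFAULT_ENERGY_MODEL,
    DEFAULT_SEED,
    EnergyModel,
    SeedDefinition,
    compute_channel_sites,
)
from .svm import ComirResult, TrainedModel, features_from_block, predict_matrix, train_model
from .synth import FixtureBundle, FixtureSpec, generate_fixture

__all__ = [
    "PipelineConfig",
    "prepare_vectors",
    "compute_site_tables",
    "score_genes",
    "run",
    "train_on_bundle",
    "default_model",
]

#: Channels computable from sequence alone, used when nothing is imported.
BUILTIN_CHANNELS = (Channel.MIRANDA_ENERGY, Channel.TARGETSCAN_SEED)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of a prediction run, with the documented defaults."""

    log_base: float = 2.0
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    fd_params: FermiDiracParams = field(default_factory=FermiDiracParams)
    seed_def: SeedDefinition = field(default_factory=lambda: DEFAULT_SEED)
    energy_model: EnergyModel = field(default_factory=lambda: DEFAULT_ENERGY_MODEL)


def prepare_vectors(
    expression: ExpressionTable,
    config: PipelineConfig = PipelineConfig(),
    *,
    alias_map: Mapping[str, str] | None = None,
    known_ids: Iterable[str] | None = None,
) -> list[tuple[str, ConcentrationVector]]:
    """Preprocess an expression table into labeled concentration vectors."""
    table = expression
    if table.is_log_input:
        table = log_to_linear(table, config.log_base)
    if known_ids is not None:
        table = resolve_ids(table, alias_map, known_ids)
    vectors = [apply_filter(v, config.filter_policy) for v in to_concentrations(table)]
    return expand_modes(vectors, config.filter_policy)


def compute_site_tables(
    targets: list[TargetSequence],
    mirna_sequences: Mapping[str, str],
    config: PipelineConfig = PipelineConfig(),
    imported: Mapping[Channel, SiteScoreTable] | None = None,
    channels: Iterable[Channel] | None = None,
) -> dict[Channel, SiteScoreTable]:
    """Site tables for the requested channels (built-in scan or imported)."""
    imported = dict(imported or {})
    if channels is None:
        channels = list(BUILTIN_CHANNELS) + [
            c for c in imported if c not in BUILTIN_CHANNELS
        ]
    return {
        Channel(ch): compute_channel_sites(
            targets,
            mirna_sequences,
            ch,
            imported.get(Channel(ch)),
            seed_def=config.seed_def,
            energy_model=config.energy_model,
        )
        for ch in channels
    }


def score_genes(
    targets: list[TargetSequence],
    mirna_sequences: Mapping[str, str],
    expression: ExpressionTable,
    config: PipelineConfig = PipelineConfig(),
    imported: Mapping[Channel, SiteScoreTable] | None = None,
    channels: Iterable[Channel] | None = None,
    **prepare_kwargs,
) -> ChannelScoreMatrix:
    """First pipeline step: per-gene, per-channel expression-combined scores."""
    labeled = prepare_vectors(expression, config, **prepare_kwargs)
    tables = compute_site_tables(targets, mirna_sequences, config, imported, channels)
    gene_ids = [t.gene_id for t in targets]
    return build_channel_matrix(tables, labeled, gene_ids, config.fd_params)


def run(
    targets: list[TargetSequence],
    mirna_sequences: Mapping[str, str],
    expression: ExpressionTable,
    model: TrainedModel,
    config: PipelineConfig = PipelineConfig(),
    imported: Mapping[Channel, SiteScoreTable] | None = None,
    **prepare_kwargs,
) -> ComirResult:
    """Full prediction run: returns per-gene probabilities per label."""
    matrix = score_genes(
        targets,
        mirna_sequences,
        expression,
        config,
        imported,
        channels=[Channel(c) for c in model.channels],
        **prepare_kwargs,
    )
    return predict_matrix(model, matrix)


def train_on_bundle(
    bundle: FixtureBundle,
    *,
    seed: int = 0,
    config: PipelineConfig = PipelineConfig(),
    channels: Iterable[Channel] | None = None,
    train_label: str | None = None,
    **svm_kwargs,
) -> TrainedModel:
    """Train the integration SVM on a labeled synthetic bundle.

    Features are the rank-normalized channel scores of one sample (the
    first by default); labels are the bundle's target/decoy classes.  The
    same routine applies to any user-supplied labeled gene set.
    """
    imported = {
        Channel.PITA_DDG: bundle.pita_sites,
        Channel.MIRSVR: bundle.mirsvr_sites,
    }
    matrix = score_genes(
        bundle.targets,
        bundle.mirna_sequences,
        bundle.expression,
        config,
        imported=imported,
        channels=channels,
    )
    label = train_label if train_label is not None else matrix.labels[0]
    features = features_from_block(matrix.block(label))
    labels = bundle.labels.reindex(features.index)
    return train_model(features, labels, seed=seed, **svm_kwargs)


def default_model(
    seed: int = 0,
    channels: Iterable[Channel] | None = None,
    spec: FixtureSpec | None = None,
    **svm_kwargs,
) -> TrainedModel:
    """The default integration model, trained on the default synthetic bundle.

    No pre-trained model is shipped; this trains deterministically (given
    ``seed``) on the standard synthetic study, and is clearly synthetic —
    retrain on your own labeled target/non-target genes for real analyses.
    """
    if spec is None:
        spec = FixtureSpec(seed=seed)
    bundle = generate_fixture(spec)
    return train_on_bundle(bundle, seed=seed, channels=channels, **svm_kwargs)
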