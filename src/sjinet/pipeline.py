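"""End-to-end orchestration: proteomes -> hits -> signals -> SJI network -> OGs.

The stages are pure functions over explicit intermediates, so a run can be
resumed from a precomputed hit table (the expensive stage) — the bootstrap
analysis relies on this to re-cluster thousands of plots without realigning
anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .align import (
    DEFAULT_MAX_RATIO,
    K_PROKARYOTE,
    ScoringConfig,
    SimilarityHit,
    all_hits,
)
from .ogdetect import THRESHOLD_PERMISSIVE, OrthologGroup, detect_ogs, og_partition
from .records import Proteomes
from .signals import SeedPlot, SpectralConfig, detect_signals
from .sji import SignalSet, build_network, signal_sets_from_plots


@dataclass
class PipelineConfig:
    """All knobs of a full run, with the prokaryote-mode defaults."""

    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    k_per_species: int = K_PROKARYOTE
    max_ratio: float = DEFAULT_MAX_RATIO
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    threshold: float = THRESHOLD_PERMISSIVE
    louvain_seed: int = 17
    max_depth: int = 50


@dataclass
class PipelineResult:
    hits: dict[str, list[SimilarityHit]]
    plots: dict[str, SeedPlot]
    signal_sets: dict[str, SignalSet]
    network: nx.Graph
    ogs: list[OrthologGroup]

    @property
    def partition(self) -> dict[str, str]:
        return og_partition(self.ogs)

    @property
    def dc(self) -> dict[str, float]:
        return {v: og.dc[v] for og in self.ogs for v in og.members}


def run_from_hits(
    hits: Mapping[str, list[SimilarityHit]],
    seed_ids: Iterable[str],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Signals -> SJI network -> OGs from an existing hit table.

    ``seed_ids`` lists every protein that should appear in the network (seeds
    without hits become isolated nodes and eventually singleton OGs).
    """
    config = config or PipelineConfig()
    plots = {
        sid: detect_signals(sid, list(hits.get(sid, ())), config.spectral)
        for sid in sorted(seed_ids)
    }
    signal_sets = signal_sets_from_plots(plots.values())
    network = build_network(signal_sets)
    ogs = detect_ogs(
        network,
        signal_sets,
        threshold=config.threshold,
        max_depth=config.max_depth,
        louvain_seed=config.louvain_seed,
    )
    return PipelineResult(dict(hits), plots, signal_sets, network, ogs)


def run_pipeline(
    proteomes: Proteomes,
    config: PipelineConfig | None = None,
    hits: Mapping[str, list[SimilarityHit]] | None = None,
) -> PipelineResult:
    """Full run; pass precomputed ``hits`` to skip the alignment stage."""
    config = config or PipelineConfig()
    if hits is None:
        hits = all_hits(
            proteomes,
            k_per_species=config.k_per_species,
            max_ratio=config.max_ratio,
            cfg=config.scoring,
        )
    seed_ids = [r.protein_id for recs in proteomes.values() for r in recs]
    return run_from_hits(hits, seed_ids, config)


def drop_proteins(
    hits: Mapping[str, list[SimilarityHit]],
    seed_ids: Iterable[str],
    removed: set[str],
) -> tuple[dict[str, list[SimilarityHit]], list[str]]:
    """Remove proteins from a hit table, both as seeds and as targets."""
    kept = [sid for sid in seed_ids if sid not in removed]
    filtered = {
        sid: [h for h in hits.get(sid, ()) if h.target_id not in removed] for sid in kept
    }
    return filtered, kept
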