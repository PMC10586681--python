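"""End-to-end orchestration: corpus -> network -> modules -> profiles -> tests."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .community import ConsensusResult, Partition, consensus_cluster
from .cooccurrence import SignedNetwork, build_network
from .datatypes import Corpus, MergeMap, PipelineConfig
from .inference import (
    ContingencyResult,
    RankTestResult,
    chi_square_independence,
    emotion_group_tests,
    intensity_by_module_table,
    misuse_by_module_table,
)
from .preprocess import preprocess_corpus
from .profiling import ModuleProfile, assign_participants, module_summary

logger = logging.getLogger("coopnet")

__all__ = ["PipelineResult", "run_pipeline", "run_inference"]


@dataclass
class PipelineResult:
    corpus: Corpus
    retained_labels: list[str]
    preprocess_report: dict
    network: SignedNetwork
    consensus: ConsensusResult
    partition: Partition
    assignments: dict[str, int | None]
    profiles: list[ModuleProfile]
    misuse_test: ContingencyResult | None
    intensity_tests: dict[str, ContingencyResult] = field(default_factory=dict)
    emotion_tests: dict[str, RankTestResult] = field(default_factory=dict)


def run_inference(
    corpus: Corpus,
    assignments: dict[str, int | None],
    retained_labels: list[str],
    config: PipelineConfig,
) -> tuple[ContingencyResult | None, dict, dict]:
    """Module-membership tests: misuse-type and intensity chi-squares
    plus per-label Kruskal-Wallis/Dunn comparisons across modules."""
    misuse = None
    table = misuse_by_module_table(corpus, assignments, config)
    if table.size and table.to_numpy().sum() > 0:
        try:
            misuse = chi_square_independence(table)
        except ValueError:
            logger.warning("misuse-by-module table degenerate; test skipped")
    intensity_tests = {}
    for kind in ("substance", "behavior"):
        t = intensity_by_module_table(corpus, assignments, config, kind=kind)
        if t.size and t.to_numpy().sum() > 0:
            try:
                intensity_tests[kind] = chi_square_independence(t)
            except ValueError:
                logger.warning("intensity table for %s degenerate; skipped", kind)
    emotion = emotion_group_tests(
        corpus, assignments, retained_labels, config, grouping="module"
    )
    return misuse, intensity_tests, emotion


def run_pipeline(
    corpus: Corpus,
    config: PipelineConfig | None = None,
    merge_map: MergeMap | None = None,
) -> PipelineResult:
    """Run preprocessing, network construction, consensus clustering,
    profiling and inference in the fixed order."""
    config = config or PipelineConfig()
    config.validate()
    logger.info(
        "pipeline start: config=%s seed=%d n=%d",
        config.config_hash(),
        config.random_seed,
        corpus.n_participants,
    )
    corpus, retained_labels, report = preprocess_corpus(corpus, config, merge_map)
    network = build_network(corpus)
    consensus = consensus_cluster(
        network,
        runs=config.consensus_runs,
        threshold=config.consensus_threshold,
        seed=config.random_seed,
        max_iter=config.consensus_max_iter,
    )
    partition = consensus.final_partition
    assignments = assign_participants(corpus, partition)
    profiles = module_summary(
        corpus, partition, assignments, config, retained_labels=retained_labels
    )
    misuse, intensity_tests, emotion = run_inference(
        corpus, assignments, retained_labels, config
    )
    logger.info(
        "pipeline done: %d tokens, %d modules, Q=%.4f, converged=%s",
        network.n_nodes,
        partition.n_modules,
        consensus.modularity,
        consensus.converged,
    )
    return PipelineResult(
        corpus=corpus,
        retained_labels=retained_labels,
        preprocess_report=report,
        network=network,
        consensus=consensus,
        partition=partition,
        assignments=assignments,
        profiles=profiles,
        misuse_test=misuse,
        intensity_tests=intensity_tests,
        emotion_tests=emotion,
    )
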