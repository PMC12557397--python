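"""End-to-end workflow: preprocess -> similarity -> cluster -> score -> dcTMD.

:func:`analyze_ensemble` is the in-memory entry point used from Python;
:func:`run_pipeline` is its file-based counterpart driven by a
:class:`RunConfig` (what the CLI executes), writing every artifact with a
config-hash provenance stamp so a run is reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import io as psio
from .cluster import (Partition, group_small_clusters, leiden_cpm,
                      select_gamma, write_partition)
from .dctmd import pathwise_free_energy
from .features import TrajectoryEnsemble, read_ensemble
from .measures import SimilarityMatrix, distance_matrix, to_similarity
from .preprocess import PreprocessConfig, apply_preprocessing
from .score import score_partitions

__all__ = ["RunConfig", "AnalysisResult", "analyze_ensemble", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (serializable)."""

    input_path: str
    input_format: str = "hdf5"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    measure: str = "euclidean"
    procrustes_stride: int = 5
    gamma_rule: str = "Q2"
    seed: int = 0
    small_cluster_threshold: int = 5
    works_path: str | None = None
    temperature: float | None = None
    dctmd_min_cluster_size: int = 100
    output_dir: str = "."

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        pc = d["preprocess"]["pca_components"]
        d["preprocess"]["pca_components"] = list(pc) if pc is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        pp = dict(d.pop("preprocess", {}))
        if pp.get("pca_components") is not None:
            pp["pca_components"] = tuple(pp["pca_components"])
        return cls(preprocess=PreprocessConfig(**pp), **d)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class AnalysisResult:
    similarity: SimilarityMatrix
    partition: Partition
    gamma: float
    scores: dict[str, float] | None = None


def analyze_ensemble(ensemble: TrajectoryEnsemble,
                     measure: str = "euclidean",
                     preprocess: PreprocessConfig | None = None,
                     gamma_rule: str = "Q2",
                     seed: int = 0,
                     small_cluster_threshold: int = 5,
                     procrustes_stride: int = 5,
                     restarts: int = 10) -> AnalysisResult:
    """Similarity -> Leiden/CPM -> '?'-grouping (-> NMI if labels exist)."""
    preprocess = preprocess or PreprocessConfig()
    prepped, _ = apply_preprocessing(ensemble, preprocess)
    kwargs = {"stride": procrustes_stride} if measure == "procrustes" else {}
    dm = distance_matrix(prepped, measure, preprocessing=preprocess.fingerprint(),
                         **kwargs)
    sim = to_similarity(dm)
    gamma = select_gamma(sim, gamma_rule)
    part = leiden_cpm(sim, gamma, seed=seed, restarts=restarts)
    part = group_small_clusters(part, small_cluster_threshold)
    scores = None
    if ensemble.labels is not None:
        scores = score_partitions(part.assignment.tolist(), ensemble.labels)
    return AnalysisResult(similarity=sim, partition=part, gamma=gamma, scores=scores)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """File-based pipeline run; returns the paths and summary numbers."""
    os.makedirs(config.output_dir, exist_ok=True)
    chash = config.hash()
    with open(os.path.join(config.output_dir, "resolved_config.json"), "w") as f:
        json.dump({"config_hash": chash, **config.to_dict()}, f, indent=2, sort_keys=True)

    t0 = time.perf_counter()
    ensemble = read_ensemble(config.input_path, config.input_format)
    logger.info("stage=load n=%d M=%d (%.2fs)", len(ensemble), ensemble.n_contacts,
                time.perf_counter() - t0)

    result = analyze_ensemble(
        ensemble, measure=config.measure, preprocess=config.preprocess,
        gamma_rule=config.gamma_rule, seed=config.seed,
        small_cluster_threshold=config.small_cluster_threshold,
        procrustes_stride=config.procrustes_stride)
    logger.info("stage=cluster gamma=%.4f clusters=%d objective=%.4f",
                result.gamma, result.partition.cluster_ids().size,
                result.partition.objective)

    sim_path = os.path.join(config.output_dir, "similarity.csv")
    psio.write_matrix(result.similarity, sim_path, extra_meta={"config_hash": chash})
    part_path = os.path.join(config.output_dir, "partition.tsv")
    write_partition(result.partition, part_path, gamma_rule=config.gamma_rule)

    from .cluster import block_order
    order = block_order(result.similarity, result.partition)
    np.savetxt(os.path.join(config.output_dir, "block_order.txt"), order, fmt="%d")

    outputs: dict[str, Any] = {
        "config_hash": chash,
        "similarity": sim_path,
        "partition": part_path,
        "gamma": result.gamma,
        "n_clusters": int(result.partition.cluster_ids().size),
    }
    if result.scores is not None:
        outputs["scores"] = result.scores
        with open(os.path.join(config.output_dir, "scores.json"), "w") as f:
            json.dump(result.scores, f, indent=2)

    if config.works_path:
        works = psio.read_work_ensemble(config.works_path, config.temperature)
        profiles = pathwise_free_energy(works, result.partition,
                                        min_cluster_size=config.dctmd_min_cluster_size)
        profile_paths = {}
        for cid, prof in profiles.items():
            p = os.path.join(config.output_dir, f"free_energy_cluster{cid}.tsv")
            psio.write_profile(prof, p, extra_meta={"config_hash": chash})
            profile_paths[cid] = p
        outputs["free_energy_profiles"] = profile_paths
    return outputs
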