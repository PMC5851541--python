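"""End-to-end orchestration of the five-stage clustering pipeline.

read/dichotomize/filter -> concordance -> ARI similarity -> patient
communities (walktrap) -> per-community aggregation -> centralities,
z-scores, bridge flags, symptom clusters. Outputs are plain CSV/JSON plus
GraphML per community, and are byte-reproducible given the same config
(stage timings go to the log, never into outputs).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import aggregation, characterization, graph_community, similarity, symptom_data
from .concordance import unique_entry_matrix
from .errors import ConcordnetError, ConfigurationError

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "characterize_cohort"]

log = logging.getLogger("concordnet")


@dataclass
class PipelineConfig:
    input_path: str
    output_dir: str
    id_column: str = "patient_id"
    missing: str = "error"  # or "zero"
    walktrap_steps: int = 4
    bridge_threshold: float = 2.0
    min_community_size: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.walktrap_steps < 1:
            raise ConfigurationError("walktrap_steps must be >= 1")
        if self.bridge_threshold <= 0:
            raise ConfigurationError("bridge_threshold must be positive")
        if self.min_community_size < 1:
            raise ConfigurationError("min_community_size must be >= 1")
        if self.missing not in ("error", "zero"):
            raise ConfigurationError(f"unknown missing policy {self.missing!r}")


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML mapping of the same field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a YAML mapping")
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"bad config key in {path}: {exc}") from exc


class _Stage:
    """Context manager logging a stage's wall time at INFO."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            log.info("stage %s: done in %.2fs", self.name, dt)
        else:
            log.error("stage %s: failed after %.2fs: %s", self.name, dt, exc)
        return False


def _wrap_stage(name):
    """Re-raise pipeline errors with the failing stage named."""
    class _ctx(_Stage):
        def __exit__(self, exc_type, exc, tb):
            super().__exit__(exc_type, exc, tb)
            if exc is not None and isinstance(exc, ConcordnetError):
                exc.args = (f"[stage: {name}] {exc.args[0] if exc.args else ''}",)
            return False
    return _ctx(name)


def characterize_cohort(table, partition, config: PipelineConfig, outdir: Path):
    """Aggregation + characterization + symptom clusters for a clustered cohort.

    Shared by ``run_pipeline`` and the ``characterize`` CLI subcommand (which
    starts from precomputed community assignments). Only communities with at
    least ``min_community_size`` patients are aggregated, characterized and
    compared. Returns (networks, profiles, cluster solutions).
    """
    with _wrap_stage("aggregate"):
        nets = aggregation.aggregate_cohort(table, partition)
        sizes = partition.sizes()
        nets = {
            c: net
            for c, net in nets.items()
            if sizes[c] >= config.min_community_size
        }
        for c, net in nets.items():
            g = net.to_graph()
            graph_community.write_graphml(g, outdir / f"community_{c}_network.graphml")
            graph_community.write_edgelist(g, outdir / f"community_{c}_edges.csv")
            net.counts_to_csv(outdir / f"community_{c}_counts.csv")

    with _wrap_stage("characterize"):
        ordered = [nets[c] for c in sorted(nets)]
        profiles = characterization.characterize_communities(
            ordered, threshold=config.bridge_threshold
        )
        characterization.centrality_table(profiles).to_csv(
            outdir / "centrality.csv", index=False
        )

    with _wrap_stage("symptom_clusters"):
        solutions = {
            c: characterization.detect_symptom_clusters(
                nets[c], steps=config.walktrap_steps, seed=config.seed
            )
            for c in sorted(nets)
        }
        rows = []
        for c in sorted(solutions):
            sol = solutions[c]
            for s, lab in zip(sol.symptom_labels, sol.labels):
                rows.append(f"{c},{s},{int(lab)}")
        (outdir / "clusters.csv").write_text(
            "community_id,symptom,cluster_label\n" + "\n".join(rows) + "\n"
        )
    return nets, profiles, solutions


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full concordance network clustering pipeline.

    Returns the run summary (also written to ``summary.json``): cohort and
    community sizes with percentages relative to the post-filter count, the
    patient partition's modularity, and per reported community its symptom
    clusters' modularity and flagged bridge / highly-central symptoms.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _wrap_stage("read"):
        table = symptom_data.read_symptom_table(
            config.input_path, id_column=config.id_column, missing=config.missing
        )
        table = symptom_data.dichotomize(table)
        log.info("read %d patients x %d symptoms", table.n, table.k)

    with _wrap_stage("filter"):
        n_input = table.n
        table, removed = symptom_data.filter_zero_patients(table)
        log.info("removed %d zero-symptom patients, %d remain", len(removed), table.n)

    with _wrap_stage("similarity"):
        vectors = unique_entry_matrix(table.values)
        sim = similarity.build_similarity_matrix(vectors, table.patient_ids)
        sim.to_csv(outdir / "similarity.csv")

    with _wrap_stage("communities"):
        graph = graph_community.similarity_to_graph(sim)
        partition = graph_community.walktrap_communities(
            graph, steps=config.walktrap_steps, seed=config.seed
        )
        log.info(
            "%d communities, modularity %.4f",
            partition.n_communities,
            partition.modularity,
        )
        lines = [
            f"{pid},{int(lab)}" for pid, lab in zip(table.patient_ids, partition.labels)
        ]
        (outdir / "communities.csv").write_text(
            "patient_id,community\n" + "\n".join(lines) + "\n"
        )

    nets, profiles, solutions = characterize_cohort(table, partition, config, outdir)

    sizes = partition.sizes()
    profiles_by_id = {p.community_id: p for p in profiles}
    community_rows = []
    for c in range(partition.n_communities):
        row = {
            "community_id": int(c),
            "n_patients": int(sizes[c]),
            "percent": round(100.0 * sizes[c] / table.n, 1),
            "reported": bool(sizes[c] >= config.min_community_size),
        }
        if c in solutions:
            row.update(
                {
                    "symptom_cluster_modularity": solutions[c].modularity,
                    "n_symptom_clusters": solutions[c].n_clusters,
                    "bridge_symptoms": profiles_by_id[c].bridge_symptoms(),
                    "highly_central_symptoms": profiles_by_id[c].highly_central_symptoms(),
                }
            )
        community_rows.append(row)
    summary = {
        "n_input_patients": n_input,
        "n_removed_zero_symptom": len(removed),
        "removed_patient_ids": list(removed),
        "n_patients": table.n,
        "n_symptoms": table.k,
        "n_communities": int(partition.n_communities),
        "patient_partition_modularity": partition.modularity,
        "min_community_size": config.min_community_size,
        "communities": community_rows,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
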