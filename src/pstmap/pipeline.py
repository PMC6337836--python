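"""End-to-end orchestration: translate, map, merge, cluster, qualify, export.

Every intermediate is a plain-text file in the dialects the stage modules
define, so the stages can also be run (and re-run) independently; no stage
mutates its inputs, and a given config, input set and seed reproduce every
output bit for bit.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .annotate import (
    QualifiedCluster,
    clusters_to_gff3,
    parse_gff3,
    qualify_clusters,
    write_cluster_table,
)
from .clusterer import Cluster, ClusterParams, cluster_hits, write_clusters
from .sixframe import read_fasta, six_frame_translate
from .tagmap import Hit, MapParams, map_psts, read_psts, write_hits

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    ``pst_paths`` may hold several PST files (e.g. one per sample); their hit
    lists are merged before clustering when ``merge`` is on, the behaviour
    used to pool samples of one strain and avoid polymorphism artifacts.
    """

    genome_fasta: str
    annotation_gff3: Optional[str]
    pst_paths: Sequence[str]
    out_dir: str
    map_params: MapParams = field(default_factory=MapParams)
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    ignore_strand: bool = False
    merge: bool = True


@dataclass
class PipelineResult:
    n_segments: int
    hits: List[Hit]
    clusters: List[Cluster]
    qualified: Optional[List[QualifiedCluster]]
    artifacts: Dict[str, str]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute translate -> map (per PST file) -> merge -> cluster -> qualify.

    Writes ``hits.tsv``, ``clusters.tsv`` and, when an annotation is given,
    ``qualified.tsv`` and ``clusters.gff3`` under ``out_dir``; logs parameter
    values and per-stage counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, str] = {}

    logger.info("map params: %s", config.map_params)
    logger.info("cluster params: %s", config.cluster_params)

    contigs = read_fasta(config.genome_fasta)
    segments = [s for c in contigs for s in six_frame_translate(c)]
    logger.info("translated %d contig(s) into %d segment(s)", len(contigs), len(segments))

    all_hits: List[Hit] = []
    for pst_path in config.pst_paths:
        psts = read_psts(pst_path)
        hits = map_psts(psts, segments, config.map_params)
        logger.info("%s: %d PST(s) -> %d hit(s)", pst_path, len(psts), len(hits))
        if not config.merge:
            per_file = out / f"hits_{Path(pst_path).stem}.tsv"
            write_hits(hits, per_file)
            artifacts[f"hits:{Path(pst_path).stem}"] = str(per_file)
        all_hits.extend(hits)
    all_hits.sort(key=lambda h: (h.contig_id, h.start, h.end, h.strand, h.spectrum_id))

    hits_path = out / "hits.tsv"
    write_hits(all_hits, hits_path)
    artifacts["hits"] = str(hits_path)

    clusters = cluster_hits(all_hits, config.cluster_params)
    logger.info("%d hit(s) -> %d cluster(s)", len(all_hits), len(clusters))
    clusters_path = out / "clusters.tsv"
    write_clusters(clusters, clusters_path)
    artifacts["clusters"] = str(clusters_path)

    qualified: Optional[List[QualifiedCluster]] = None
    if config.annotation_gff3 is not None:
        annotation = parse_gff3(config.annotation_gff3)
        qualified = qualify_clusters(clusters, annotation, all_hits, config.ignore_strand)
        tallies = Counter(
            (q.annotation_label, q.confidence_label, q.consistency_label) for q in qualified
        )
        categories = Counter(q.category for q in qualified)
        logger.info("label tallies: %s", dict(tallies))
        logger.info("category tallies: %s", dict(categories))
        qualified_path = out / "qualified.tsv"
        write_cluster_table(qualified, qualified_path)
        artifacts["qualified"] = str(qualified_path)
        gff_path = out / "clusters.gff3"
        clusters_to_gff3(qualified, gff_path)
        artifacts["gff3"] = str(gff_path)

    return PipelineResult(
        n_segments=len(segments),
        hits=all_hits,
        clusters=clusters,
        qualified=qualified,
        artifacts=artifacts,
    )
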