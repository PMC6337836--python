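"""Single-linkage clustering of genomic hits into candidate coding regions.

Nearby hits on the same contig and strand are chained whenever the gap
between a hit and the running end of the current chain is at most ``maxdist``
nucleotides; chains short on evidence (fewer than ``minhit`` hits or
``minpep`` distinct peptides) are discarded.  Hits in different reading
frames on the same strand do co-cluster, because exons change frame across
introns and a cluster is meant to span a whole gene's evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from .tagmap import Hit, normalize_il

__all__ = ["ClusterParams", "Cluster", "cluster_hits", "write_clusters"]


@dataclass(frozen=True)
class ClusterParams:
    """Clustering thresholds; defaults are the workflow's optimised settings."""

    maxdist: int = 5000
    minhit: int = 3
    minpep: int = 2
    strand_aware: bool = True
    count_tags: bool = False  # count distinct tags instead of distinct peptides

    def __post_init__(self) -> None:
        if self.maxdist < 0:
            raise ValueError("maxdist must be >= 0")
        if self.minhit < 1 or self.minpep < 1:
            raise ValueError("minhit and minpep must be >= 1")


@dataclass
class Cluster:
    cluster_id: str
    contig_id: str
    strand: str
    start: int
    end: int
    hits: List[Hit]

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    @property
    def n_peptides(self) -> int:
        return len({normalize_il(h.peptide) for h in self.hits})

    @property
    def n_spectra(self) -> int:
        return len({h.spectrum_id for h in self.hits})


def _distinct_evidence(hits: Sequence[Hit], count_tags: bool) -> int:
    if count_tags:
        return len({normalize_il(h.tag) for h in hits})
    return len({normalize_il(h.peptide) for h in hits})


def cluster_hits(hits: Iterable[Hit], params: ClusterParams = ClusterParams()) -> List[Cluster]:
    """Chain hits into clusters per (contig, strand) and filter by evidence.

    Hits sorted by start join the current chain iff
    ``hit.start - max(end so far) <= maxdist``; this equals the transitive
    closure of the pairwise gap relation.  Surviving chains are numbered
    deterministically by contig then span start.
    """
    groups: Dict[Tuple[str, str], List[Hit]] = {}
    for h in hits:
        key = (h.contig_id, h.strand if params.strand_aware else ".")
        groups.setdefault(key, []).append(h)

    chains: List[Tuple[str, str, List[Hit]]] = []
    for (contig, strand), members in groups.items():
        members.sort(key=lambda h: (h.start, h.end, h.spectrum_id))
        current: List[Hit] = []
        max_end = -1
        for h in members:
            if current and h.start - max_end > params.maxdist:
                chains.append((contig, strand, current))
                current = []
                max_end = -1
            current.append(h)
            max_end = max(max_end, h.end)
        if current:
            chains.append((contig, strand, current))

    kept = [
        (contig, strand, members)
        for contig, strand, members in chains
        if len(members) >= params.minhit
        and _distinct_evidence(members, params.count_tags) >= params.minpep
    ]
    kept.sort(key=lambda c: (c[0], min(h.start for h in c[2])))
    clusters = []
    for i, (contig, strand, members) in enumerate(kept, start=1):
        clusters.append(
            Cluster(
                cluster_id=str(i),
                contig_id=contig,
                strand=strand,
                start=min(h.start for h in members),
                end=max(h.end for h in members),
                hits=members,
            )
        )
    return clusters


def write_clusters(clusters: Iterable[Cluster], path) -> None:
    """Write the cluster table as TSV with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("#cluster_id\tcontig\tstrand\tfrom\tto\ttot_hit\tn_peptides\tn_spectra\n")
        for c in clusters:
            fh.write(
                f"{c.cluster_id}\t{c.contig_id}\t{c.strand}\t{c.start + 1}\t{c.end}\t"
                f"{c.n_hits}\t{c.n_peptides}\t{c.n_spectra}\n"
            )
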