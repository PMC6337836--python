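"""Qualify clusters against an existing GFF3 annotation and export GFF3.

Each cluster receives four labels:

* ``ANNOTATED`` / ``UNANNOTATED`` — at least one hit fully included in an
  annotated CDS, or none;
* ``DUBIOUS`` / ``POSSIBLE`` / ``SURE`` — a confidence grade from the number
  of *typical* spectra (spectra all of whose genome-wide hits fall inside the
  cluster) and distinct peptides: DUBIOUS with 0-1 typical spectra, POSSIBLE
  with >= 2 typical spectra but < 3 peptides, SURE with >= 2 typical spectra
  and >= 3 peptides;
* ``OK`` / ``CHECK`` — all hits CDS-included, or at least one that is not;
* ``IN`` / ``OUT`` / ``CROSS`` — the cluster span contained in, disjoint
  from, or straddling annotated mRNA intervals.

"Included in a CDS" means full containment of the hit interval in a single
CDS feature on the same contig and strand.  Partial overlaps count toward the
per-peptide ``cds_cross`` tally instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import gffutils
from intervaltree import IntervalTree

from .clusterer import Cluster
from .tagmap import Hit, normalize_il

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeAnnotation",
    "QualifiedCluster",
    "parse_gff3",
    "count_typical_spectra",
    "categorize_cluster",
    "qualify_cluster",
    "qualify_clusters",
    "write_cluster_table",
    "clusters_to_gff3",
]

_KNOWN_TYPES = {"gene", "mRNA", "CDS"}


@dataclass
class GenomeAnnotation:
    """mRNA and CDS intervals per contig/strand, 0-based half-open.

    ``mrnas``: (contig, strand, start, end, mrna_id)
    ``cds``:   (contig, strand, start, end, parent_mrna_id or None)
    """

    mrnas: List[Tuple[str, str, int, int, str]] = field(default_factory=list)
    cds: List[Tuple[str, str, int, int, Optional[str]]] = field(default_factory=list)
    mrna_parents: Dict[str, Optional[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._mrna_trees: Dict[Tuple[str, str], IntervalTree] = {}
        self._cds_trees: Dict[Tuple[str, str], IntervalTree] = {}
        for contig, strand, start, end, mrna_id in self.mrnas:
            self._mrna_trees.setdefault((contig, strand), IntervalTree()).addi(
                start, end, mrna_id
            )
        for contig, strand, start, end, parent in self.cds:
            self._cds_trees.setdefault((contig, strand), IntervalTree()).addi(
                start, end, parent
            )

    def _strands(self, strand: str, ignore_strand: bool) -> Tuple[str, ...]:
        return ("+", "-") if ignore_strand else (strand,)

    def mrnas_overlapping(
        self, contig: str, strand: str, start: int, end: int, ignore_strand: bool = False
    ) -> List[Tuple[int, int, str]]:
        out = []
        for s in self._strands(strand, ignore_strand):
            tree = self._mrna_trees.get((contig, s))
            if tree is not None:
                out.extend((iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end))
        return out

    def cds_overlapping(
        self, contig: str, strand: str, start: int, end: int, ignore_strand: bool = False
    ) -> List[Tuple[int, int, Optional[str]]]:
        out = []
        for s in self._strands(strand, ignore_strand):
            tree = self._cds_trees.get((contig, s))
            if tree is not None:
                out.extend((iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end))
        return out

    def hit_in_cds(self, hit: Hit, ignore_strand: bool = False) -> bool:
        """True iff the hit interval is fully inside a single CDS feature."""
        return any(
            b <= hit.start and hit.end <= e
            for b, e, _ in self.cds_overlapping(
                hit.contig_id, hit.strand, hit.start, hit.end, ignore_strand
            )
        )

    def hit_overlaps_cds(self, hit: Hit, ignore_strand: bool = False) -> bool:
        return bool(
            self.cds_overlapping(hit.contig_id, hit.strand, hit.start, hit.end, ignore_strand)
        )


def parse_gff3(path) -> GenomeAnnotation:
    """Read gene/mRNA/CDS features from a GFF3 file.

    File coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention.  Unknown feature types are ignored with a
    log line; a CDS whose Parent cannot be resolved is kept as an orphan.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    mrna_ids: Set[str] = set()
    mrnas: List[Tuple[str, str, int, int, str]] = []
    cds: List[Tuple[str, str, int, int, Optional[str]]] = []
    mrna_parents: Dict[str, Optional[str]] = {}
    skipped: Dict[str, int] = {}
    for feat in db.all_features():
        if feat.featuretype == "mRNA":
            mrnas.append((feat.seqid, feat.strand, feat.start - 1, feat.end, feat.id))
            mrna_ids.add(feat.id)
            parents = feat.attributes.get("Parent", [])
            mrna_parents[feat.id] = parents[0] if parents else None
        elif feat.featuretype not in _KNOWN_TYPES:
            skipped[feat.featuretype] = skipped.get(feat.featuretype, 0) + 1
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent", [])
        parent = parents[0] if parents else None
        if parent is not None and parent not in mrna_ids:
            logger.warning("CDS %s has unresolvable Parent %r; kept as orphan", feat.id, parent)
            parent = None
        elif parent is None:
            logger.warning("CDS %s has no Parent; kept as orphan", feat.id)
        cds.append((feat.seqid, feat.strand, feat.start - 1, feat.end, parent))
    for ftype, n in skipped.items():
        logger.info("ignored %d feature(s) of type %s", n, ftype)
    return GenomeAnnotation(mrnas=mrnas, cds=cds, mrna_parents=mrna_parents)


@dataclass
class QualifiedCluster:
    cluster: Cluster
    annotation_label: str
    confidence_label: str
    consistency_label: str
    category: str
    tot_hit: int
    hit_in: int
    cds_in: int
    cds_cross: int
    n_typical_spectra: int


def count_typical_spectra(cluster: Cluster, all_hits: Sequence[Hit]) -> int:
    """Spectra specific to this cluster.

    A spectrum is *typical* for a cluster when every one of its hits,
    genome-wide (including hits that ended up in no cluster), belongs to the
    cluster's member set.
    """
    members = set(cluster.hits)
    by_spectrum: Dict[str, List[Hit]] = {}
    for h in all_hits:
        by_spectrum.setdefault(h.spectrum_id, []).append(h)
    cluster_spectra = {h.spectrum_id for h in cluster.hits}
    return sum(
        1
        for sid in cluster_spectra
        if all(h in members for h in by_spectrum.get(sid, []))
    )


def categorize_cluster(
    cluster: Cluster, annotation: GenomeAnnotation, ignore_strand: bool = False
) -> str:
    """IN if the span is contained in some mRNA, OUT if it overlaps none,
    CROSS otherwise.  Containment in any single mRNA suffices (isoforms
    share exons)."""
    overlapping = annotation.mrnas_overlapping(
        cluster.contig_id, cluster.strand, cluster.start, cluster.end, ignore_strand
    )
    if not overlapping:
        return "OUT"
    if any(b <= cluster.start and cluster.end <= e for b, e, _ in overlapping):
        return "IN"
    return "CROSS"


def qualify_cluster(
    cluster: Cluster,
    annotation: GenomeAnnotation,
    all_hits: Sequence[Hit],
    ignore_strand: bool = False,
) -> QualifiedCluster:
    """Assign all four labels plus the per-CDS overlap counts to a cluster."""
    in_flags = [annotation.hit_in_cds(h, ignore_strand) for h in cluster.hits]
    hit_in = sum(in_flags)
    tot_hit = len(cluster.hits)

    by_pep: Dict[str, List[Hit]] = {}
    for h in cluster.hits:
        by_pep.setdefault(normalize_il(h.peptide), []).append(h)
    cds_in = cds_cross = 0
    for hits in by_pep.values():
        if any(annotation.hit_in_cds(h, ignore_strand) for h in hits):
            cds_in += 1
        elif any(annotation.hit_overlaps_cds(h, ignore_strand) for h in hits):
            cds_cross += 1

    typical = count_typical_spectra(cluster, all_hits)
    n_pep = cluster.n_peptides
    if typical <= 1:
        confidence = "DUBIOUS"
    elif n_pep < 3:
        confidence = "POSSIBLE"
    else:
        confidence = "SURE"

    return QualifiedCluster(
        cluster=cluster,
        annotation_label="ANNOTATED" if hit_in >= 1 else "UNANNOTATED",
        confidence_label=confidence,
        consistency_label="OK" if hit_in == tot_hit else "CHECK",
        category=categorize_cluster(cluster, annotation, ignore_strand),
        tot_hit=tot_hit,
        hit_in=hit_in,
        cds_in=cds_in,
        cds_cross=cds_cross,
        n_typical_spectra=typical,
    )


def qualify_clusters(
    clusters: Iterable[Cluster],
    annotation: GenomeAnnotation,
    all_hits: Sequence[Hit],
    ignore_strand: bool = False,
) -> List[QualifiedCluster]:
    return [qualify_cluster(c, annotation, all_hits, ignore_strand) for c in clusters]


def write_cluster_table(qualified: Iterable[QualifiedCluster], path) -> None:
    """Tabular qualification report, 1-based inclusive coordinates."""
    cols = (
        "#cluster_id\tcontig\tstrand\tfrom\tto\ttot_hit\thit_in\tcds_in\tcds_cross\t"
        "n_peptides\tn_spectra\ttypical_spectra\tannotation\tconfidence\tconsistency\tcategory"
    )
    with open(path, "w") as fh:
        fh.write(cols + "\n")
        for q in qualified:
            c = q.cluster
            fh.write(
                f"{c.cluster_id}\t{c.contig_id}\t{c.strand}\t{c.start + 1}\t{c.end}\t"
                f"{q.tot_hit}\t{q.hit_in}\t{q.cds_in}\t{q.cds_cross}\t"
                f"{c.n_peptides}\t{c.n_spectra}\t{q.n_typical_spectra}\t"
                f"{q.annotation_label}\t{q.confidence_label}\t{q.consistency_label}\t"
                f"{q.category}\n"
            )


def clusters_to_gff3(qualified: Iterable[QualifiedCluster], path) -> None:
    """Write clusters as viewer-loadable GFF3.

    One ``match`` feature per cluster carrying the labels and counts, with
    one ``match_part`` child per member hit carrying spectrum, tag, peptide
    and modification count.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for q in qualified:
            c = q.cluster
            attrs = (
                f"ID=cluster_{c.cluster_id};annotation={q.annotation_label};"
                f"confidence={q.confidence_label};consistency={q.consistency_label};"
                f"category={q.category};tot_hit={q.tot_hit};hit_in={q.hit_in};"
                f"cds_in={q.cds_in};cds_cross={q.cds_cross};"
                f"typical_spectra={q.n_typical_spectra};"
                f"spectra={','.join(sorted({h.spectrum_id for h in c.hits}))}"
            )
            fh.write(
                f"{c.contig_id}\tpstmap\tmatch\t{c.start + 1}\t{c.end}\t.\t"
                f"{c.strand}\t.\t{attrs}\n"
            )
            for i, h in enumerate(c.hits, start=1):
                part_attrs = (
                    f"ID=cluster_{c.cluster_id}.part{i};Parent=cluster_{c.cluster_id};"
                    f"spectrum={h.spectrum_id};tag={h.tag};peptide={h.peptide};"
                    f"frame={h.frame};n_mods={h.n_mods_used}"
                )
                fh.write(
                    f"{h.contig_id}\tpstmap\tmatch_part\t{h.start + 1}\t{h.end}\t.\t"
                    f"{h.strand}\t.\t{part_attrs}\n"
                )
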