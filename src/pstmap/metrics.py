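"""Sensitivity/selectivity evaluation against an expected protein set.

Sensitivity is the fraction of expected proteins that the workflow recovered
(``true_pos / nref``); selectivity is the fraction of recovered proteins that
were expected (``true_pos / nfound``).  Proteins can be matched either in
hit space (at least ``min_valid_hits`` hits contained in the protein's
genomic intervals) or in cluster space (an IN or CROSS cluster overlapping
the protein's mRNA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .annotate import GenomeAnnotation, QualifiedCluster
from .tagmap import Hit

__all__ = [
    "EvalResult",
    "evaluate",
    "match_proteins_by_hits",
    "match_proteins_by_clusters",
    "protein_index_from_annotation",
    "write_eval_report",
]

#: protein id -> list of (contig, strand, start, end) genomic intervals
ProteinIndex = Dict[str, List[Tuple[str, str, int, int]]]


@dataclass(frozen=True)
class EvalResult:
    true_pos: int
    nref: int
    nfound: int

    @property
    def sensitivity(self) -> float:
        return self.true_pos / self.nref

    @property
    def selectivity(self) -> float:
        return self.true_pos / self.nfound if self.nfound else 0.0


def evaluate(found: Set[str], expected: Set[str]) -> EvalResult:
    """Compare the recovered protein set with the expected one."""
    if not expected:
        raise ValueError("expected protein set is empty")
    return EvalResult(
        true_pos=len(found & expected), nref=len(expected), nfound=len(found)
    )


def _index_trees(protein_index: ProteinIndex) -> Dict[Tuple[str, str], IntervalTree]:
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for pid, intervals in protein_index.items():
        for contig, strand, start, end in intervals:
            trees.setdefault((contig, strand), IntervalTree()).addi(start, end, pid)
    return trees


def match_proteins_by_hits(
    hits: Iterable[Hit], protein_index: ProteinIndex, min_valid_hits: int = 2
) -> Set[str]:
    """Proteins matched by at least ``min_valid_hits`` hits.

    A hit counts for a protein when its interval is fully contained in one
    of the protein's genomic intervals on the same contig and strand.
    """
    trees = _index_trees(protein_index)
    counts: Dict[str, int] = {}
    for h in hits:
        tree = trees.get((h.contig_id, h.strand))
        if tree is None:
            continue
        for iv in tree.overlap(h.start, h.end):
            if iv.begin <= h.start and h.end <= iv.end:
                counts[iv.data] = counts.get(iv.data, 0) + 1
    return {pid for pid, n in counts.items() if n >= min_valid_hits}


def match_proteins_by_clusters(
    qualified: Iterable[QualifiedCluster], protein_index: ProteinIndex
) -> Set[str]:
    """Proteins whose genomic intervals overlap an IN or CROSS cluster."""
    trees = _index_trees(protein_index)
    matched: Set[str] = set()
    for q in qualified:
        if q.category not in ("IN", "CROSS"):
            continue
        c = q.cluster
        tree = trees.get((c.contig_id, c.strand))
        if tree is None:
            continue
        matched.update(iv.data for iv in tree.overlap(c.start, c.end))
    return matched


def protein_index_from_annotation(annotation: GenomeAnnotation) -> ProteinIndex:
    """mRNA spans keyed by the parent gene id (or the mRNA id if orphan)."""
    index: ProteinIndex = {}
    for contig, strand, start, end, mrna_id in annotation.mrnas:
        key = annotation.mrna_parents.get(mrna_id) or mrna_id
        index.setdefault(key, []).append((contig, strand, start, end))
    return index


def write_eval_report(result: EvalResult, path, percent: bool = False) -> None:
    scale, fmt = (100.0, "{:.1f}") if percent else (1.0, "{:.4f}")
    with open(path, "w") as fh:
        fh.write("#true_pos\tnref\tnfound\tsensitivity\tselectivity\n")
        fh.write(
            f"{result.true_pos}\t{result.nref}\t{result.nfound}\t"
            f"{fmt.format(result.sensitivity * scale)}\t"
            f"{fmt.format(result.selectivity * scale)}\n"
        )
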