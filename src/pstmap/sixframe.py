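"""Six-frame translation of genomic sequence into stop-free segments.

Every contig is translated in the three forward and three reverse-complement
frames.  Translations are split at stop codons and at codons containing N, so
each emitted segment is a contiguous stop-free stretch of one frame together
with an exact residue-to-genome coordinate map.  All internal coordinates are
0-based half-open on the forward strand; GFF3's 1-based inclusive convention
appears only at file boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "Contig",
    "TranslatedSegment",
    "read_fasta",
    "reverse_complement",
    "six_frame_translate",
    "segment_to_genomic",
    "write_segments",
    "read_segments",
]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class Contig:
    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"contig {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class TranslatedSegment:
    """A stop-free translated stretch of one reading frame.

    ``genomic_start`` is the leftmost forward-strand base covered by the
    segment; for reverse-strand segments the first residue therefore sits at
    the *right* end of the genomic interval.
    """

    contig_id: str
    strand: str
    frame: int
    aa_seq: str
    genomic_start: int
    contig_length: int


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_fasta(path) -> List[Contig]:
    """Read a (multi-)FASTA of contigs.

    Sequences are upper-cased; characters outside {A,C,G,T,N} are replaced by
    N with a warning.  Duplicate ids and empty files are rejected.
    """
    contigs: List[Contig] = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate contig id {record.id!r} in {path}")
        seen.add(record.id)
        seq = str(record.seq).upper()
        bad = sum(1 for ch in seq if ch not in _VALID)
        if bad:
            logger.warning(
                "contig %s: %d non-ACGTN character(s) replaced by N", record.id, bad
            )
            seq = "".join(ch if ch in _VALID else "N" for ch in seq)
        contigs.append(Contig(record.id, seq))
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return contigs


def _codon_map(code_table: int) -> Dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[code_table]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def six_frame_translate(contig: Contig, code_table: int = 1) -> List[TranslatedSegment]:
    """Translate ``contig`` in all six frames into stop-free segments.

    Stop codons and codons containing N break segments (they are never
    translated to a placeholder residue).  Empty segments are dropped.
    Reverse-strand frames are translated from the reverse complement with
    coordinates reported on the forward strand.
    """
    codons = _codon_map(code_table)
    length = len(contig.seq)
    segments: List[TranslatedSegment] = []
    for strand in "+-":
        seq = contig.seq if strand == "+" else reverse_complement(contig.seq)
        for frame in range(3):
            residues: List[str] = []
            seg_start = -1  # strand-local position of first codon base
            for pos in range(frame, length - 2, 3):
                aa = codons.get(seq[pos : pos + 3])
                if aa is None or aa == "*":
                    if residues:
                        segments.append(
                            _make_segment(contig, strand, frame, residues, seg_start, length)
                        )
                        residues = []
                    continue
                if not residues:
                    seg_start = pos
                residues.append(aa)
            if residues:
                segments.append(
                    _make_segment(contig, strand, frame, residues, seg_start, length)
                )
    return segments


def _make_segment(
    contig: Contig,
    strand: str,
    frame: int,
    residues: List[str],
    local_start: int,
    length: int,
) -> TranslatedSegment:
    n_bases = 3 * len(residues)
    if strand == "+":
        genomic_start = local_start
    else:
        genomic_start = length - (local_start + n_bases)
    return TranslatedSegment(
        contig_id=contig.id,
        strand=strand,
        frame=frame,
        aa_seq="".join(residues),
        genomic_start=genomic_start,
        contig_length=length,
    )


def write_segments(segments: List[TranslatedSegment], path) -> None:
    """Write translated segments as TSV (start is 1-based in the file)."""
    with open(path, "w") as fh:
        fh.write("#contig\tstrand\tframe\tstart\tcontig_length\taa_seq\n")
        for s in segments:
            fh.write(
                f"{s.contig_id}\t{s.strand}\t{s.frame}\t{s.genomic_start + 1}\t"
                f"{s.contig_length}\t{s.aa_seq}\n"
            )


def read_segments(path) -> List[TranslatedSegment]:
    segments: List[TranslatedSegment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            contig, strand, frame, start, length, aa = parts
            segments.append(
                TranslatedSegment(contig, strand, int(frame), aa, int(start) - 1, int(length))
            )
    return segments


def segment_to_genomic(
    segment: TranslatedSegment, aa_from: int, aa_to: int
) -> Tuple[str, str, Tuple[int, int]]:
    """Forward-strand base interval covered by residues ``[aa_from, aa_to)``.

    Always 0-based half-open, with length ``3 * (aa_to - aa_from)``.
    """
    n = len(segment.aa_seq)
    if not (0 <= aa_from < aa_to <= n):
        raise ValueError(f"residue range [{aa_from}, {aa_to}) outside segment of length {n}")
    if segment.strand == "+":
        start = segment.genomic_start + 3 * aa_from
        end = segment.genomic_start + 3 * aa_to
    else:
        start = segment.genomic_start + 3 * (n - aa_to)
        end = segment.genomic_start + 3 * (n - aa_from)
    return segment.contig_id, segment.strand, (start, end)
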