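"""Synthetic proteogenomes and PST sets with ground truth.

The simulator builds a genome of multi-exon protein-coding genes whose
feature lengths follow log-normal samplers centred on the medians of the
test organism's genome (coding exon 137 nt, intron 531 nt, intergenic
2529 nt, about seven introns per gene, hence a median gene around 4.8 kb).
Genes alternate strands so that both strands are exercised and same-strand
neighbours are separated by roughly a gene plus two spacers, the regime the
default clustering distance is designed for.

PSTs are derived the way the real workflow observes them: each protein is
digested with trypsin, a tag window is cut from sampled peptides, and the
flanking masses are computed from the residues on either side of the window
(optionally perturbed by Gaussian mass error).  Only peptides lying strictly
inside a single exon are sampled, because a tag mapper working on six-frame
translations cannot recover splice-junction peptides or peptides whose
tryptic context is interrupted by an intron.  Decoy PSTs (random tags with
uniform random flank masses) model unmatchable spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from Bio.Data import CodonTable

from .masscalc import MassConstants, sum_residue_masses, tryptic_digest
from .sixframe import Contig, reverse_complement
from .tagmap import PST

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "SynthGene",
    "GroundTruthRecord",
    "SimResult",
    "sample_length",
    "synth_genome",
    "synth_psts",
    "simulate",
    "expected_genes",
    "gene_index",
    "derive_proteins",
    "write_genome_fasta",
    "write_proteins_fasta",
    "write_annotation_gff3",
    "write_ground_truth",
    "read_ground_truth",
]

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def _non_stop_codons() -> List[str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    return sorted(table.forward_table)


_CODONS = _non_stop_codons()
_CODON_TO_AA = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)


@dataclass(frozen=True)
class SynthConfig:
    """Simulation parameters; length defaults are the test genome's medians."""

    n_genes: int = 50
    contig_id: str = "contig_1"
    exon_cds_median: float = 137.0  # nt of coding sequence per exon
    intron_median: float = 531.0
    intergenic_median: float = 2529.0
    #: Genes on the same strand are kept at least this far apart so that
    #: distinct genes produce distinct clusters at the default clustering
    #: distance; sampled spacers are padded only when the constraint binds.
    min_same_strand_separation: int = 5001
    mean_introns_per_gene: float = 7.0
    length_sigma: float = 0.5  # log-space spread of all length samplers
    psts_per_peptide: int = 2
    tag_len: int = 5
    min_peptide_len: int = 7  # shorter tryptic peptides fall below the MS scan range
    flank_mass_error_sd: float = 0.0
    decoy_fraction: float = 0.0
    decoy_flank_range: float = 1200.0
    missed_cleavages: int = 0
    proline_rule: bool = True
    mass_constants: MassConstants = field(default_factory=MassConstants)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 3 <= self.tag_len <= 5:
            raise ValueError("tag_len must be in [3, 5]")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise ValueError("decoy_fraction must be in [0, 1]")
        if min(self.exon_cds_median, self.intron_median, self.intergenic_median) < 3:
            raise ValueError("length medians must be >= 3 nt")
        if self.flank_mass_error_sd < 0:
            raise ValueError("flank_mass_error_sd must be >= 0")
        if self.psts_per_peptide < 1:
            raise ValueError("psts_per_peptide must be >= 1")


@dataclass
class SynthGene:
    """A simulated gene with its protein and residue-to-genome map."""

    gene_id: str
    mrna_id: str
    contig_id: str
    strand: str
    start: int
    end: int
    exons: List[Tuple[int, int]]  # genome order, 0-based half-open
    protein: str
    genomic_positions: List[int]  # genomic base of each coding nt, transcription order

    def residue_span(self, aa_from: int, aa_to: int) -> Tuple[int, int]:
        """Forward-strand genomic span covered by residues [aa_from, aa_to)."""
        positions = self.genomic_positions[3 * aa_from : 3 * aa_to]
        return min(positions), max(positions) + 1

    def exon_aa_ranges(self) -> List[Tuple[int, int]]:
        """Residue index range fully encoded by each exon (transcription order)."""
        ranges = []
        cum = 0
        order = self.exons if self.strand == "+" else list(reversed(self.exons))
        for start, end in order:
            length = end - start
            ranges.append((cum // 3, (cum + length) // 3))
            cum += length
        return ranges


@dataclass(frozen=True)
class GroundTruthRecord:
    spectrum_id: str
    gene_id: str
    peptide: str
    contig_id: str
    strand: str
    start: int
    end: int
    is_decoy: bool


@dataclass
class SimResult:
    config: SynthConfig
    contigs: List[Contig]
    genes: List[SynthGene]
    psts: List[PST]
    truth: List[GroundTruthRecord]


def sample_length(
    rng: np.random.Generator,
    median: float,
    sigma: float,
    minimum: int = 1,
    multiple_of: int = 1,
) -> int:
    """Log-normal length sampler parameterised by its median.

    Right-skewed and strictly positive like real genomic feature lengths;
    rounded to ``multiple_of`` and floored at ``minimum``.
    """
    value = float(np.exp(rng.normal(np.log(median), sigma)))
    value = multiple_of * round(value / multiple_of)
    return max(minimum, int(value))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def synth_genome(config: SynthConfig, rng: np.random.Generator | None = None):
    """Build one contig of alternating-strand multi-exon genes.

    Returns ``(contigs, genes)``; every gene's CDS pieces are multiples of
    three, concatenate without internal stop codons, and translate to the
    recorded protein.  Deterministic under the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    parts: List[str] = []
    genes: List[SynthGene] = []
    pos = 0
    last_end = {"+": None, "-": None}
    for gi in range(config.n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        spacer = sample_length(rng, config.intergenic_median, config.length_sigma, minimum=100)
        prev = last_end[strand]
        if prev is not None:
            spacer = max(spacer, prev + config.min_same_strand_separation - pos)
        parts.append(_random_dna(rng, spacer))
        pos += spacer

        n_exons = 1 + int(rng.poisson(config.mean_introns_per_gene))
        exon_lens = [
            sample_length(rng, config.exon_cds_median, config.length_sigma, 9, multiple_of=3)
            for _ in range(n_exons)
        ]
        intron_lens = [
            sample_length(rng, config.intron_median, config.length_sigma, minimum=20)
            for _ in range(n_exons - 1)
        ]
        total_codons = sum(exon_lens) // 3
        codons = ["ATG"] + list(rng.choice(_CODONS, size=total_codons - 1))
        cds_nt = "".join(codons)
        protein = "".join(_CODON_TO_AA[cds_nt[i : i + 3]] for i in range(0, len(cds_nt), 3))

        gene_pieces: List[str] = []
        local_exons: List[Tuple[int, int]] = []  # gene-local, transcription orientation
        offset = 0
        consumed = 0
        for k, elen in enumerate(exon_lens):
            gene_pieces.append(cds_nt[consumed : consumed + elen])
            local_exons.append((offset, offset + elen))
            consumed += elen
            offset += elen
            if k < n_exons - 1:
                gene_pieces.append(_random_dna(rng, intron_lens[k]))
                offset += intron_lens[k]
        gene_seq = "".join(gene_pieces)
        glen = len(gene_seq)

        genomic_gene_seq = gene_seq if strand == "+" else reverse_complement(gene_seq)
        parts.append(genomic_gene_seq)

        if strand == "+":
            exons = [(pos + a, pos + b) for a, b in local_exons]
            genomic_positions = [pos + a + i for a, b in local_exons for i in range(b - a)]
        else:
            exons = sorted((pos + glen - b, pos + glen - a) for a, b in local_exons)
            genomic_positions = [
                pos + glen - 1 - (a + i) for a, b in local_exons for i in range(b - a)
            ]
        genes.append(
            SynthGene(
                gene_id=f"gene_{gi + 1:03d}",
                mrna_id=f"mrna_{gi + 1:03d}",
                contig_id=config.contig_id,
                strand=strand,
                start=pos,
                end=pos + glen,
                exons=exons,
                protein=protein,
                genomic_positions=genomic_positions,
            )
        )
        pos += glen
        last_end[strand] = pos
    tail = sample_length(rng, config.intergenic_median, config.length_sigma, minimum=100)
    parts.append(_random_dna(rng, tail))
    contig = Contig(config.contig_id, "".join(parts))
    return [contig], genes


def _mappable_peptides(gene: SynthGene, config: SynthConfig) -> List[Tuple[str, int, int]]:
    """Tryptic peptides the six-frame mapper can recover exactly.

    A peptide qualifies when it lies strictly inside one exon with at least
    one flanking residue of the same exon on each side, so its tryptic
    context (preceding K/R, following non-P residue) is intact in genomic
    frame and its genomic interval is contiguous.
    """
    ranges = gene.exon_aa_ranges()
    out = []
    min_len = max(config.tag_len, config.min_peptide_len)
    for pep, i, j in tryptic_digest(
        gene.protein, config.missed_cleavages, config.proline_rule
    ):
        if len(pep) < min_len:
            continue
        if any(a < i and j < b for a, b in ranges):
            out.append((pep, i, j))
    return out


def synth_psts(
    genes: Sequence[SynthGene],
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> Tuple[List[PST], List[GroundTruthRecord]]:
    """Generate PSTs with ground truth from simulated genes.

    Each eligible peptide contributes up to ``psts_per_peptide`` PSTs at
    distinct tag windows; flank masses follow the configured offsets plus
    Gaussian error.  Decoys (random tag, uniform flank masses) are appended
    so that they make up ``decoy_fraction`` of the final set.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    consts = config.mass_constants
    psts: List[PST] = []
    truth: List[GroundTruthRecord] = []
    sid = 0
    n_skipped = 0
    for gene in genes:
        n_total = len(tryptic_digest(gene.protein, config.missed_cleavages, config.proline_rule))
        eligible = _mappable_peptides(gene, config)
        n_skipped += n_total - len(eligible)
        for pep, i, j in eligible:
            n_windows = len(pep) - config.tag_len + 1
            k = min(config.psts_per_peptide, n_windows)
            for w in sorted(rng.choice(n_windows, size=k, replace=False)):
                w = int(w)
                tag = pep[w : w + config.tag_len]
                mn = sum_residue_masses(pep[:w]) + consts.n_flank_offset
                mc = sum_residue_masses(pep[w + config.tag_len :]) + consts.c_flank_offset
                if config.flank_mass_error_sd > 0:
                    mn += rng.normal(0.0, config.flank_mass_error_sd)
                    mc += rng.normal(0.0, config.flank_mass_error_sd)
                sid += 1
                spectrum_id = f"spec{sid:06d}"
                start, end = gene.residue_span(i, j)
                psts.append(PST(spectrum_id, tag, mn, mc))
                truth.append(
                    GroundTruthRecord(
                        spectrum_id=spectrum_id,
                        gene_id=gene.gene_id,
                        peptide=pep,
                        contig_id=gene.contig_id,
                        strand=gene.strand,
                        start=start,
                        end=end,
                        is_decoy=False,
                    )
                )
    if n_skipped:
        logger.debug("skipped %d peptide(s) too short or not exon-interior", n_skipped)

    n_true = len(psts)
    if config.decoy_fraction >= 1.0:
        n_decoys = max(n_true, 1)
        psts, truth = [], []
    elif config.decoy_fraction > 0:
        n_decoys = round(n_true * config.decoy_fraction / (1.0 - config.decoy_fraction))
    else:
        n_decoys = 0
    for _ in range(n_decoys):
        sid += 1
        spectrum_id = f"decoy{sid:06d}"
        tag = "".join(rng.choice(list(_RESIDUES), size=config.tag_len))
        mn = consts.n_flank_offset + float(rng.uniform(0.0, config.decoy_flank_range))
        mc = consts.c_flank_offset + float(rng.uniform(0.0, config.decoy_flank_range))
        psts.append(PST(spectrum_id, tag, mn, mc))
        truth.append(
            GroundTruthRecord(spectrum_id, "-", tag, "-", ".", 0, 0, is_decoy=True)
        )
    return psts, truth


def simulate(config: SynthConfig) -> SimResult:
    """Run the full simulation: genome, genes, PSTs, ground truth."""
    rng = np.random.default_rng(config.seed)
    contigs, genes = synth_genome(config, rng)
    psts, truth = synth_psts(genes, config, rng)
    return SimResult(config=config, contigs=contigs, genes=genes, psts=psts, truth=truth)


def expected_genes(
    truth: Sequence[GroundTruthRecord], min_hits: int = 3, min_peptides: int = 2
) -> Set[str]:
    """Genes whose emitted (non-decoy) PSTs meet the cluster evidence bar."""
    by_gene: Dict[str, List[GroundTruthRecord]] = {}
    for rec in truth:
        if not rec.is_decoy:
            by_gene.setdefault(rec.gene_id, []).append(rec)
    return {
        gid
        for gid, recs in by_gene.items()
        if len(recs) >= min_hits and len({r.peptide for r in recs}) >= min_peptides
    }


def gene_index(genes: Sequence[SynthGene]) -> Dict[str, List[Tuple[str, str, int, int]]]:
    """Protein index (gene span per gene) for the metrics module."""
    return {g.gene_id: [(g.contig_id, g.strand, g.start, g.end)] for g in genes}


# ---------------------------------------------------------------------------
# File output / self-consistency helpers
# ---------------------------------------------------------------------------


def write_genome_fasta(contigs: Sequence[Contig], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i : i + width] + "\n")


def write_proteins_fasta(genes: Sequence[SynthGene], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.protein), width):
                fh.write(g.protein[i : i + width] + "\n")


def write_annotation_gff3(genes: Sequence[SynthGene], path) -> None:
    """Write gene/mRNA/CDS features (1-based inclusive, genome order)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig_id}\tpstmap-sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.contig_id}\tpstmap-sim\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.mrna_id};Parent={g.gene_id}\n"
            )
            order = g.exons if g.strand == "+" else list(reversed(g.exons))
            cum = 0
            records = []
            for k, (start, end) in enumerate(order, start=1):
                phase = (3 - cum % 3) % 3
                records.append((start, end, k, phase))
                cum += end - start
            for start, end, k, phase in sorted(records):
                fh.write(
                    f"{g.contig_id}\tpstmap-sim\tCDS\t{start + 1}\t{end}\t.\t"
                    f"{g.strand}\t{phase}\tID={g.mrna_id}.cds{k};Parent={g.mrna_id}\n"
                )


def write_ground_truth(truth: Sequence[GroundTruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#spectrum_id\tgene_id\tpeptide\tcontig\tstrand\tstart\tend\tis_decoy\n")
        for r in truth:
            fh.write(
                f"{r.spectrum_id}\t{r.gene_id}\t{r.peptide}\t{r.contig_id}\t{r.strand}\t"
                f"{r.start + 1}\t{r.end}\t{int(r.is_decoy)}\n"
            )


def read_ground_truth(path) -> List[GroundTruthRecord]:
    records: List[GroundTruthRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise ValueError(f"{path}:{lineno}: expected 8 columns, got {len(parts)}")
            sid, gid, pep, contig, strand, start, end, decoy = parts
            records.append(
                GroundTruthRecord(
                    sid, gid, pep, contig, strand, int(start) - 1, int(end), bool(int(decoy))
                )
            )
    return records


def derive_proteins(contigs: Sequence[Contig], gff3_path) -> Dict[str, str]:
    """Re-derive each mRNA's protein from genome FASTA + GFF3 annotation.

    CDS pieces of each mRNA are concatenated in transcription order
    (reverse-complemented for the minus strand) and translated; used to
    check that emitted annotation, genome and proteins agree.
    """
    from .annotate import parse_gff3

    ann = parse_gff3(gff3_path)
    seqs = {c.id: c.seq for c in contigs}
    by_parent: Dict[str, List[Tuple[str, str, int, int]]] = {}
    for contig, strand, start, end, parent in ann.cds:
        if parent is not None:
            by_parent.setdefault(parent, []).append((contig, strand, start, end))
    proteins: Dict[str, str] = {}
    for mrna_id, pieces in by_parent.items():
        pieces.sort(key=lambda p: p[2])
        strand = pieces[0][1]
        nt = "".join(seqs[contig][start:end] for contig, _, start, end in pieces)
        if strand == "-":
            nt = reverse_complement(nt)
        proteins[mrna_id] = "".join(
            _CODON_TO_AA[nt[i : i + 3]] for i in range(0, len(nt) - 2, 3)
        )
    return proteins
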