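# Methods

## The problem

Gene predictors miss and mangle genes, especially in lineages with few close
relatives to borrow models from. Shotgun proteomics offers direct evidence of
translation, but matching spectra against a predicted protein database can
only confirm the predictions it is given. `pstmap` instead takes *peptide
sequence tags* (PSTs) — short stretches of sequence read de novo from MS/MS
spectra — straight to the genome: it searches all six reading frames, checks
each candidate site against the tag's flanking fragment-ion masses, and
aggregates the verified placements into candidate coding regions that can be
compared with, and used to correct, an existing annotation.

## Data model

A PST is a tag of 3–5 residues plus two masses: `mn`, the N-terminal fragment
ion flanking the tag, and `mc`, the C-terminal one. The defaults interpret
them as singly protonated b and y ions:

    mn = sum(prefix residue masses) + proton
    mc = sum(suffix residue masses) + water + proton

where *prefix*/*suffix* are the peptide residues before/after the tag. Both
offsets live in `MassConstants` and are configurable, because de novo engines
differ in whether they report proton- or hydrogen-referenced ion masses; the
b/y convention is the natural one for tags cut from CID ladders. All masses
are monoisotopic — the reference dipeptide values ("DD" = 230.05 Da,
"ET" = 230.09 Da) match monoisotopic sums, not average ones — and the residue
table is frozen in `masscalc` at six decimals. Modifications are mass shifts
on one residue type; the defaults are fixed-ish carbamidomethyl-C
(+57.021464 Da) and variable oxidation-M (+15.994915 Da), stored at full
precision ("+57"/"+16" are nominal labels only).

## Mapping with flank verification

The genome is translated in all six frames (`sixframe`); translations are cut
at stop codons and at codons containing N, so every segment is a stop-free
stretch with an exact residue→genome coordinate map. Codons with N are
segment breakers rather than X residues: translating through ambiguity would
invite spurious tag matches. Internally all coordinates are 0-based half-open
on the forward strand; the 1-based inclusive convention of GFF3/TSV exists
only at file boundaries.

For each PST (`tagmap`), every segment position where the tag matches — with
I and L interchangeable, since they are exact isobars — seeds a verification:
walk left from the tag accumulating residue masses and collect every
boundary `b` that (i) is a valid tryptic N-terminus (segment start, or
preceded by K/R and not starting with P when the proline rule is on) and
(ii) explains `mn` within the absolute tolerance, optionally spending
modifications on eligible prefix residues; symmetrically walk right for
`mc`, requiring K/R (with a legal cleavage) or the segment end. A boundary
pair becomes a hit if the total modifications spent stay within `max_mods`
and the inferred peptide holds at most `missed_cleavages` internal cleavage
sites. Segment ends count as cleavage boundaries because a stop codon
truncates the frame mid-peptide.

All verifying boundary pairs at a position are reported (the clusterer
tolerates them); only exact duplicates — same spectrum, same genomic
interval — are collapsed, keeping the variant with fewer modifications.
The hit interval covers the whole inferred peptide, not just the tag, so
clusters reflect the true extent of peptide evidence. Only I/L is expanded
during matching; K/Q and other near-isobars are left to the mass tolerance.

## Clustering and qualification

Hits on one contig and strand are chained single-linkage (`clusterer`):
sorted by start, a hit joins the current chain when the gap to the chain's
running maximum end is at most `maxdist` (5000 nt by default — large enough
to bridge introns, which is also why hits in *different frames* on the same
strand deliberately co-cluster, while opposite strands never do). Chains
with fewer than `minhit` hits (3) or `minpep` distinct I/L-normalised
peptides (2) are discarded. Gap ≤ maxdist joins; maxdist + 1 splits.

Each cluster is then compared with the annotation (`annotate`):

* **ANNOTATED / UNANNOTATED** — at least one hit fully contained in a single
  CDS feature (same contig and strand), or none.
* **DUBIOUS / POSSIBLE / SURE** — from the number of *typical spectra*
  (spectra whose every genome-wide hit falls inside the cluster) and
  distinct peptides: ≤ 1 typical spectrum is DUBIOUS; ≥ 2 typical spectra
  with < 3 peptides is POSSIBLE; ≥ 2 with ≥ 3 peptides is SURE. Typicality
  is evaluated genome-wide, not per contig.
* **OK / CHECK** — all hits CDS-contained, or at least one that is not.
* **IN / OUT / CROSS** — the cluster span contained in at least one mRNA
  (isoforms share exons, so any single mRNA suffices), overlapping none, or
  straddling. Same-strand mRNAs only, unless `ignore_strand` is set for
  annotations with unreliable strands.

Per-peptide CDS tallies accompany the labels: a peptide counts `cds_in` when
any of its hits is CDS-contained, otherwise `cds_cross` when any hit
partially overlaps a CDS.

Evaluation (`metrics`) follows the standard protocol: with an expected
protein set of size `nref` and a found set of size `nfound`,
sensitivity = true_pos/nref and selectivity = true_pos/nfound. Proteins can
be matched in hit space (≥ `min_valid_hits` hits contained in the protein's
intervals, default 2) or in cluster space (an IN or CROSS cluster
overlapping the protein's mRNA).

## The simulator

`synthdata` builds genomes whose feature lengths follow log-normal samplers
(σ = 0.5 in log space — strictly positive and right-skewed like real feature
lengths) centred on the test organism's medians: coding exon 137 nt, intron
531 nt, intergenic spacer 2529 nt, with 1 + Poisson(7) exons per gene, which
makes the median gene ≈ 4.8 kb; whole-gene and exon-count statistics emerge
from these rather than being sampled directly. CDS pieces are multiples of
three (≥ 9 nt), codons are drawn uniformly from the 61 non-stop codons with
an ATG start, and genes alternate strands. Placement additionally keeps
same-strand neighbours ≥ 5001 nt apart (sampled spacers are padded only when
the constraint binds): with the median spacer below the clustering distance,
densely detected same-strand neighbours would otherwise routinely co-cluster,
and the simulator's job is to produce scenes where one gene maps to one
cluster.

PSTs are emitted the way the workflow can observe them: proteins are
digested with trypsin, and each peptide that (a) is at least 7 residues long
— shorter tryptic peptides fall below the instrument acquisition window —
and (b) lies strictly inside a single exon with one same-exon residue of
margin on each side, contributes up to `psts_per_peptide` (default 2,
emulating redundant spectral sampling) tag windows with flank masses
computed from the configured offsets plus Gaussian error
(`flank_mass_error_sd`, default 0 = the clean reference condition). The
margin condition exists because a six-frame mapper cannot recover
splice-junction peptides, nor peptides whose tryptic context (the preceding
K/R, the following non-P residue) is interrupted by an intron; such peptides
are real but invisible to this method, so emitting them would conflate
generator and method limitations. Decoy PSTs — random tags with flank masses
drawn uniformly over the plausible range — model unmatchable spectra and make
up `decoy_fraction` of the emitted set.

What the simulator does **not** emulate: splice-site dinucleotides, codon
usage and GC bias (composition is uniform), spectral noise structure or
engine-specific tag error profiles, UTRs (mRNA equals the gene span),
overlapping genes, paralogy and repeats. Passing tests therefore show that
the pipeline's logic is correct and self-consistent under realistic length
statistics, not that real spectra of a real genome would reach the same
sensitivity.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `tolerance` | 0.5 | Da | absolute flank-mass tolerance for ion-trap fragment masses |
| `max_mods` | 1 | count | one modification per inferred peptide |
| `missed_cleavages` | 1 | count | matches full-trypsin searches with one missed cleavage |
| `il_equivalent` | on | — | I/L are exact isobars; tags cannot distinguish them |
| `proline_rule` | on | — | trypsin rarely cleaves K/R–P |
| `maxdist` | 5000 | nt | covers ≈ 99.6% of introns while limiting gene merging |
| `minhit` / `minpep` | 3 / 2 | count | evidence floor that maximised IN clusters |
| `min_valid_hits` | 2 | count | hits needed before a protein counts as matched |
| `tag_len` (simulator) | 5 | residues | the tag length that optimised selectivity |
| `flank_mass_error_sd` | 0 | Da | clean reference condition; raise to stress the tolerance |
| `decoy_fraction` | 0 | — | fraction of emitted PSTs that are decoys |

## Numerical and degenerate-input choices

* Residue masses at six decimals; flank comparisons are plain absolute
  differences, so tolerance semantics are exact and order-independent.
* Leftward/rightward extension stops once the accumulated mass exceeds the
  target plus tolerance plus the largest spendable modification delta, which
  bounds work per tag occurrence.
* Equal-start hits are ordered by end, then spectrum id; cluster ids are
  assigned after filtering, by contig then span start — output is therefore
  byte-stable for a given input.
* Empty inputs are well-defined: no hits → no clusters; an empty annotation
  qualifies every cluster OUT/UNANNOTATED/CHECK; an empty cluster list still
  writes a valid GFF3 header. Contigs shorter than one codon translate to
  nothing, without error.
* A spectrum's hits are compared by full identity (interval, strand, frame,
  peptide) when computing typicality.

## Known limitations

At 0.5 Da tolerance, residue masses form a near-integer lattice with many
coincidences (K ≈ Q at 0.036 Da; GG ≈ N at 0.025 Da; GA ≈ Q; VVK ≈ GLR at
0.03 Da…), so a tag plus verified flanks occasionally places a peptide at an
unrelated locus: on clean 50-gene simulations this produces about one
false placement per ~1500 PSTs. When such a placement lands inside another
gene it is absorbed harmlessly; when it lands intergenic near a true cluster
it can stretch that cluster past its mRNA and turn an IN into a CROSS — on
the order of one affected cluster per 50 genes. This is intrinsic to
mass-tolerant flank verification, and it is exactly what the CHECK
consistency label is for: the affected cluster is flagged for curation, the
same workflow position the method's real-data results occupy (where the best
achieved category distribution was 90% IN, not 100%). Tightening the
tolerance would suppress these at the cost of sensitivity on noisier
spectra.

Other limitations: no splice-aware mapping (junction peptides are invisible
by design; clustering, not translation, bridges introns), no FDR model for
hits, no support for semi-tryptic peptides or N-terminal protein
modifications, and protein inference is interval overlap, not parsimony.

## Problem sizes

The test suite and the reproduction script run entirely on simulated data:
50-gene genomes (~0.4 Mb, ~1500–2000 PSTs) for end-to-end checks, 2-gene
genomes (≤ 20 kb) for exhaustive oracle comparisons, and 1000 random hit
configurations for the clustering oracle. These sizes keep every oracle
brute-forceable while exercising both strands, multi-exon genes, decoys and
mass noise.
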