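# pstmap

Proteogenomic mapping of de novo **peptide sequence tags** (PSTs) onto
genomic sequence — for annotating genomes where predicted gene models are
incomplete or wrong, using shotgun MS/MS evidence directly instead of a
predicted-protein database.

A PST is a short (3–5 residue) sequence read de novo from an MS/MS spectrum
together with the masses of the fragment ions flanking it. `pstmap` locates
each tag on the six-frame translation of the genome and keeps a placement
only when *both* flank masses are explained by the surrounding residues
under tryptic constraints: with tag prefix/suffix residue sets *P*/*S*,
N-flank offset δ_n (proton) and C-flank offset δ_c (water + proton),

    |m_n − (Σ_{r∈P} m_r + Σ mods + δ_n)| ≤ τ   and   |m_c − (Σ_{r∈S} m_r + Σ mods + δ_c)| ≤ τ

with τ = 0.5 Da and at most one modification (carbamidomethyl-C +57,
oxidation-M +16) by default. Verified placements (*hits*) on one contig and
strand are chained into *clusters* whenever consecutive hits are ≤ 5000 nt
apart; clusters with ≥ 3 hits and ≥ 2 distinct peptides are kept, compared
with an existing GFF3 annotation, labelled
(ANNOTATED/UNANNOTATED × DUBIOUS/POSSIBLE/SURE × OK/CHECK, plus
IN/OUT/CROSS relative to mRNA features), and exported as viewer-loadable
GFF3. Recovery is scored as sensitivity = true_pos/nref and
selectivity = true_pos/nfound against an expected protein set.

The package also ships a synthetic proteogenome simulator (multi-exon genes
on both strands with realistic feature-length statistics, PSTs with
configurable mass error and decoys, full ground truth) so the entire
pipeline is testable at desk scale. See `docs/methods.md` for the model,
parameter rationale, and limitations.

## Worked example

```sh
pstmap simulate --outdir demo --n-genes 8 --seed 42
pstmap run --genome demo/genome.fasta --annotation demo/annotation.gff3 \
           --psts demo/psts.tsv --outdir demo/out
```

```
INFO pstmap: simulated 8 genes, 326 PSTs into demo
INFO pstmap.pipeline: label tallies: {('ANNOTATED', 'SURE', 'OK'): 8}
INFO pstmap.pipeline: category tallies: {'IN': 8}
INFO pstmap: pipeline done: 6478 segments, 327 hits, 8 clusters
```

All 326 clean PSTs map (one maps twice — a genuine repeated placement), and
the hits chain into exactly one cluster per simulated gene. The
qualification table (`demo/out/qualified.tsv`) begins:

```
#cluster_id  contig    strand  from   to     tot_hit  hit_in  cds_in  cds_cross  n_peptides  n_spectra  typical_spectra  annotation  confidence  consistency  category
1            contig_1  +       2967   9872   48       48      24      0          24          48         48               ANNOTATED   SURE        OK           IN
2            contig_1  -       11940  19433  62       62      31      0          31          62         62               ANNOTATED   SURE        OK           IN
```

Cluster 1 spans 2967–9872 on the forward strand: 48 hits, all inside
annotated CDS (`hit_in = tot_hit`, hence OK), 24 distinct peptides, 48
spectra specific to the cluster (typical), and the span is contained in an
mRNA (IN) — a confidently re-detected gene. Comparing against the
simulator's ground truth:

```sh
pstmap evaluate demo/out/hits.tsv --annotation demo/annotation.gff3 \
                --truth demo/truth.tsv -o demo/eval.tsv
# INFO pstmap: sensitivity 1.000 selectivity 1.000 (true_pos=8 nref=8 nfound=8)
```

Every gene with enough emitted evidence (≥ 3 hits, ≥ 2 peptides) is
recovered by an IN or CROSS cluster, and every recovered protein was
expected. `demo/out/clusters.gff3` holds the same clusters as `match` /
`match_part` features loadable in a genome viewer next to the annotation.

Stages can equally be run separately (`translate`, `map`, `cluster`,
`qualify`, `togff`) on each other's TSV outputs, or from the library API
(`pstmap.run_pipeline`).

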