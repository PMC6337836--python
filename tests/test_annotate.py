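import gffutils
import numpy as np
import pytest

from pstmap.annotate import (
    GenomeAnnotation,
    categorize_cluster,
    clusters_to_gff3,
    count_typical_spectra,
    parse_gff3,
    qualify_cluster,
    qualify_clusters,
    write_cluster_table,
)
from pstmap.clusterer import ClusterParams, cluster_hits
from pstmap.synthdata import write_annotation_gff3
from pstmap.tagmap import Hit

from _oracles import brute_typical

# one mRNA on c1:+ spanning [1000, 11000) with two CDS pieces
ANN = GenomeAnnotation(
    mrnas=[("c1", "+", 1000, 11000, "m1")],
    cds=[("c1", "+", 1000, 2000, "m1"), ("c1", "+", 8000, 9000, "m1")],
)


def mk_hit(sid, start, end, pep, strand="+", contig="c1"):
    return Hit(sid, pep[:3], contig, strand, 0, pep, start, end, 0)


def _qualify(members, extras=()):
    clusters = cluster_hits(members, ClusterParams(minhit=1, minpep=1))
    assert len(clusters) == 1
    return qualify_cluster(clusters[0], ANN, list(members) + list(extras))


IN_CDS = [(1100, 1130), (1300, 1330), (1600, 1630)]
OUT_CDS = [(3000, 3030), (3500, 3530), (4000, 4030)]  # inside mRNA, outside CDS


@pytest.mark.parametrize(
    "annotated,confidence,consistency",
    [
        (a, c, k)
        for a in ("ANNOTATED", "UNANNOTATED")
        for c in ("DUBIOUS", "POSSIBLE", "SURE")
        for k in (("OK", "CHECK") if a == "ANNOTATED" else ("CHECK",))
    ],
)
def test_label_truth_table(annotated, confidence, consistency):
    """Every constructible label combination is assigned per the rules.

    (UNANNOTATED/OK is impossible by definition: with no CDS-included hit,
    not all hits can be CDS-included.)
    """
    base = IN_CDS if annotated == "ANNOTATED" else OUT_CDS
    n_spectra = {"DUBIOUS": 1, "POSSIBLE": 2, "SURE": 3}[confidence]
    n_peptides = {"DUBIOUS": 1, "POSSIBLE": 2, "SURE": 3}[confidence]
    members = [
        mk_hit(f"s{i}", *base[i], pep=f"PEPT{chr(65 + i)}K")
        for i in range(max(n_spectra, n_peptides))
    ]
    if consistency == "CHECK" and annotated == "ANNOTATED":
        # extra hit outside any CDS, sharing an existing spectrum and peptide
        members.append(mk_hit("s0", 3200, 3230, "PEPTAK"))
    q = _qualify(members)
    assert q.annotation_label == annotated
    assert q.confidence_label == confidence
    assert q.consistency_label == consistency


def test_dubious_when_spectra_shared_with_other_locus():
    """Spectra that also hit outside the cluster are not typical."""
    members = [mk_hit(f"s{i}", *IN_CDS[i], pep=f"PEPT{chr(65 + i)}K") for i in range(3)]
    extras = [mk_hit(f"s{i}", 50000 + i * 100, 50030 + i * 100, "XXXXK") for i in range(3)]
    q = _qualify(members, extras)
    assert q.n_typical_spectra == 0
    assert q.confidence_label == "DUBIOUS"
    assert q.annotation_label == "ANNOTATED"


@pytest.mark.parametrize(
    "span,expected",
    [
        ((1200, 1800), "IN"),  # inside the mRNA
        ((20000, 20500), "OUT"),  # disjoint from every mRNA
        ((10500, 12000), "CROSS"),  # straddles the mRNA end
    ],
)
def test_cluster_categories(span, expected):
    members = [
        mk_hit("s1", span[0], span[0] + 30, "AAAAK"),
        mk_hit("s2", span[1] - 30, span[1], "CCCCK"),
    ]
    clusters = cluster_hits(members, ClusterParams(minhit=1, minpep=1))
    assert categorize_cluster(clusters[0], ANN) == expected


def test_category_is_strand_aware_by_default():
    members = [
        mk_hit("s1", 1200, 1230, "AAAAK", strand="-"),
        mk_hit("s2", 1400, 1430, "CCCCK", strand="-"),
    ]
    cluster = cluster_hits(members, ClusterParams(minhit=1, minpep=1))[0]
    assert categorize_cluster(cluster, ANN) == "OUT"
    assert categorize_cluster(cluster, ANN, ignore_strand=True) == "IN"


def test_empty_annotation_gives_out_unannotated():
    empty = GenomeAnnotation()
    members = [mk_hit("s1", 1100, 1130, "AAAAK"), mk_hit("s2", 1300, 1330, "CCCCK")]
    cluster = cluster_hits(members, ClusterParams(minhit=1, minpep=1))[0]
    q = qualify_cluster(cluster, empty, members)
    assert (q.category, q.annotation_label, q.consistency_label) == (
        "OUT",
        "UNANNOTATED",
        "CHECK",
    )


def test_peptide_cds_in_and_cross_counts():
    members = [
        mk_hit("s1", 1100, 1130, "AAAAK"),  # fully inside CDS 1
        mk_hit("s2", 1950, 2040, "CCCCK"),  # straddles the CDS 1 end
        mk_hit("s3", 3000, 3030, "DDDDK"),  # no CDS overlap at all
    ]
    q = _qualify(members)
    assert (q.cds_in, q.cds_cross) == (1, 1)
    assert (q.hit_in, q.tot_hit) == (1, 3)
    assert q.consistency_label == "CHECK"


def test_typical_spectra_rules_and_oracle(small_hits):
    members = [mk_hit("s1", 1100, 1130, "AAAAK"), mk_hit("s2", 1300, 1330, "CCCCK")]
    cluster = cluster_hits(members, ClusterParams(minhit=1, minpep=1))[0]
    # spectrum with all hits in the cluster is typical; a shared one is not
    shared = [mk_hit("s2", 90000, 90030, "EEEEK")]
    assert count_typical_spectra(cluster, members) == 2
    assert count_typical_spectra(cluster, members + shared) == 1
    # randomized comparison against the exhaustive per-spectrum oracle
    clusters = cluster_hits(small_hits)
    for c in clusters:
        assert count_typical_spectra(c, small_hits) == brute_typical(c.hits, small_hits)


def test_label_families_are_total(small_hits, small_annotation):
    """Every cluster gets exactly one label per family, plus invariants."""
    clusters = cluster_hits(small_hits)
    for q in qualify_clusters(clusters, small_annotation, small_hits):
        assert q.annotation_label in ("ANNOTATED", "UNANNOTATED")
        assert q.confidence_label in ("DUBIOUS", "POSSIBLE", "SURE")
        assert q.consistency_label in ("OK", "CHECK")
        assert q.category in ("IN", "OUT", "CROSS")
        assert q.hit_in <= q.tot_hit
        assert (q.annotation_label == "ANNOTATED") == (q.hit_in >= 1)
        assert (q.consistency_label == "OK") == (q.hit_in == q.tot_hit)
        if q.annotation_label == "UNANNOTATED":
            assert q.consistency_label == "CHECK"


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------


def test_parse_minimal_gff3(tmp_path):
    p = tmp_path / "mini.gff3"
    p.write_text(
        "##gff-version 3\n"
        "c1\tsrc\tgene\t101\t500\t.\t+\t.\tID=g1\n"
        "c1\tsrc\tmRNA\t101\t500\t.\t+\t.\tID=m1;Parent=g1\n"
        "c1\tsrc\tCDS\t151\t300\t.\t+\t0\tID=cds1;Parent=m1\n"
    )
    ann = parse_gff3(p)
    assert ann.mrnas == [("c1", "+", 100, 500, "m1")]
    assert ann.cds == [("c1", "+", 150, 300, "m1")]
    assert ann.mrna_parents == {"m1": "g1"}


def test_annotation_round_trip(small_sim, tmp_path):
    p1 = tmp_path / "a.gff3"
    write_annotation_gff3(small_sim.genes, p1)
    ann = parse_gff3(p1)
    for g in small_sim.genes:
        assert (g.contig_id, g.strand, g.start, g.end, g.mrna_id) in ann.mrnas
        for exon in g.exons:
            assert (g.contig_id, g.strand, exon[0], exon[1], g.mrna_id) in ann.cds


def test_cluster_gff3_round_trip(tmp_path, small_hits, small_annotation):
    clusters = cluster_hits(small_hits)
    qualified = qualify_clusters(clusters, small_annotation, small_hits)
    path = tmp_path / "clusters.gff3"
    clusters_to_gff3(qualified, path)
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True)
    matches = list(db.features_of_type("match"))
    parts = list(db.features_of_type("match_part"))
    assert len(matches) == len(qualified)
    assert len(parts) == sum(q.tot_hit for q in qualified)
    by_id = {f.attributes["ID"][0]: f for f in matches}
    for q in qualified:
        f = by_id[f"cluster_{q.cluster.cluster_id}"]
        assert (f.start - 1, f.end) == (q.cluster.start, q.cluster.end)
        assert f.strand == q.cluster.strand
        assert f.attributes["annotation"][0] == q.annotation_label
        assert f.attributes["confidence"][0] == q.confidence_label
        assert f.attributes["consistency"][0] == q.consistency_label
        assert f.attributes["category"][0] == q.category
        assert int(f.attributes["tot_hit"][0]) == q.tot_hit
    for f in parts:
        parent = by_id[f.attributes["Parent"][0]]
        assert parent.start <= f.start and f.end <= parent.end


def test_empty_cluster_list_yields_valid_gff3(tmp_path):
    path = tmp_path / "empty.gff3"
    clusters_to_gff3([], path)
    assert path.read_text() == "##gff-version 3\n"


def test_cluster_table_columns(tmp_path, small_hits, small_annotation):
    clusters = cluster_hits(small_hits)
    qualified = qualify_clusters(clusters, small_annotation, small_hits)
    path = tmp_path / "qualified.tsv"
    write_cluster_table(qualified, path)
    lines = path.read_text().strip().split("\n")
    assert len(lines) == len(qualified) + 1
    header = lines[0].lstrip("#").split("\t")
    assert header[:5] == ["cluster_id", "contig", "strand", "from", "to"]
    row = dict(zip(header, lines[1].split("\t")))
    assert row["annotation"] in ("ANNOTATED", "UNANNOTATED")
    assert int(row["tot_hit"]) >= int(row["hit_in"])
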