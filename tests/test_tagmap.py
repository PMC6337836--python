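import numpy as np
import pytest

from pstmap.masscalc import MONOISOTOPIC, MassConstants, OXIDATION
from pstmap.sixframe import TranslatedSegment, six_frame_translate
from pstmap.synthdata import SynthConfig, simulate
from pstmap.tagmap import (
    PST,
    Hit,
    MapParams,
    find_tag,
    map_psts,
    read_hits,
    read_psts,
    verify_flanks,
    write_hits,
    write_psts,
)

from _oracles import oracle_map

N_OFF = MassConstants().n_flank_offset
C_OFF = MassConstants().c_flank_offset


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def test_pst_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    residues = sorted(MONOISOTOPIC)
    psts = [
        PST(
            f"s{i}",
            "".join(rng.choice(residues, size=int(rng.integers(3, 6)))),
            float(rng.uniform(1, 1500)),
            float(rng.uniform(19, 1500)),
        )
        for i in range(100)
    ]
    path = tmp_path / "psts.tsv"
    write_psts(psts, path)
    assert read_psts(path) == psts


def test_pst_parse_errors(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("#spectrum_id\ttag\tmn\tmc\ns1\tAAA\t1.0\n")
    with pytest.raises(ValueError, match=":2"):
        read_psts(p)
    p.write_text("s1\tAA\t1.0\t19.0\n")
    with pytest.raises(ValueError, match="length"):
        read_psts(p)
    with pytest.raises(ValueError):
        PST("s", "AAAAAA", 1.0, 19.0)


def test_hits_round_trip(tmp_path):
    hits = [
        Hit("s1", "FSQ", "c1", "+", 0, "LFSQK", 12, 27, 0),
        Hit("s2", "AIA", "c1", "-", 2, "KALAK", 100, 115, 1),
    ]
    path = tmp_path / "hits.tsv"
    write_hits(hits, path)
    assert read_hits(path) == hits


# ---------------------------------------------------------------------------
# tag finding
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "tag,segment,il,expected",
    [
        ("FSQ", "RLFSQK", True, [2]),
        ("AIA", "KALAK", True, [1]),
        ("AIA", "KALAK", False, []),
        ("WWW", "RLFSQK", True, []),
        ("AAA", "AAAAA", True, [0, 1, 2]),
    ],
)
def test_find_tag(tag, segment, il, expected):
    assert find_tag(tag, segment, il_equivalent=il) == expected


# ---------------------------------------------------------------------------
# flank verification
# ---------------------------------------------------------------------------


def _m(seq):
    return sum(MONOISOTOPIC[ch] for ch in seq)


def test_verify_flanks_clean_placement():
    """Exact flank masses recover the tryptic peptide around the tag."""
    pst = PST("s", "FSQ", _m("L") + N_OFF, _m("K") + C_OFF)
    out = verify_flanks("RLFSQKA", 2, pst, MapParams())
    assert out == [("LFSQK", 1, 0)]


def test_verify_flanks_respects_tolerance():
    pst = PST("s", "FSQ", _m("L") + N_OFF + 0.6, _m("K") + C_OFF)
    assert verify_flanks("RLFSQKA", 2, pst, MapParams()) == []
    # within tolerance it still verifies
    pst = PST("s", "FSQ", _m("L") + N_OFF + 0.4, _m("K") + C_OFF)
    assert verify_flanks("RLFSQKA", 2, pst, MapParams()) == [("LFSQK", 1, 0)]


def test_verify_flanks_with_oxidized_methionine():
    """An unexplained +16 on the prefix is absorbed by one M oxidation."""
    pst = PST("s", "FSQ", _m("M") + OXIDATION.delta + N_OFF, _m("K") + C_OFF)
    out = verify_flanks("RMFSQKA", 2, pst, MapParams())
    assert out == [("MFSQK", 1, 1)]
    # but not when modifications are disallowed
    assert verify_flanks("RMFSQKA", 2, pst, MapParams(max_mods=0)) == []


def test_verify_flanks_requires_tryptic_boundaries():
    # prefix L is not preceded by K/R and is not the segment start
    pst = PST("s", "FSQ", _m("L") + N_OFF, _m("K") + C_OFF)
    assert verify_flanks("GLFSQKA", 2, pst, MapParams()) == []
    # segment start qualifies as a boundary
    pst2 = PST("s", "FSQ", _m("L") + N_OFF, _m("K") + C_OFF)
    assert verify_flanks("LFSQKA", 1, pst2, MapParams()) == [("LFSQK", 0, 0)]


def test_verify_flanks_caps_missed_cleavages():
    # peptide would contain two internal K
    seg = "RKAKAFSQKA"
    pst = PST("s", "FSQ", _m("KAKA") + N_OFF, _m("K") + C_OFF)
    assert verify_flanks(seg, 5, pst, MapParams(missed_cleavages=2)) == [
        ("KAKAFSQK", 1, 0)
    ]
    assert verify_flanks(seg, 5, pst, MapParams(missed_cleavages=1)) == []


# ---------------------------------------------------------------------------
# genome-wide mapping
# ---------------------------------------------------------------------------


def _noisy_sim(seed, **kw):
    cfg = SynthConfig(
        n_genes=2,
        seed=seed,
        mean_introns_per_gene=3.0,
        intergenic_median=800.0,
        min_same_strand_separation=0,
        flank_mass_error_sd=0.3,
        decoy_fraction=0.25,
        psts_per_peptide=1,
        **kw,
    )
    sim = simulate(cfg)
    segments = [s for c in sim.contigs for s in six_frame_translate(c)]
    return sim, segments


def _keys(hits):
    return {(h.spectrum_id, h.contig_id, h.strand, h.start, h.end) for h in hits}


def test_map_matches_exhaustive_oracle_small():
    sim, segments = _noisy_sim(5)
    params = MapParams()
    assert _keys(map_psts(sim.psts, segments, params)) == oracle_map(
        sim.psts, segments, params
    )


def test_absent_tag_contributes_no_hits(small_segments):
    pst = PST("s", "WWWWW", 500.0, 500.0)
    assert map_psts([pst], small_segments) == []


def test_monotonicity_in_tolerance_and_mods():
    """Enlarging tolerance or the modification budget never removes hits."""
    sim, segments = _noisy_sim(6)
    base = _keys(map_psts(sim.psts, segments, MapParams(tolerance=0.25, max_mods=0)))
    wider = _keys(map_psts(sim.psts, segments, MapParams(tolerance=0.5, max_mods=0)))
    moddy = _keys(map_psts(sim.psts, segments, MapParams(tolerance=0.5, max_mods=1)))
    assert base <= wider <= moddy


def test_il_substitution_leaves_hits_invariant():
    sim, segments = _noisy_sim(7)
    swapped = [
        TranslatedSegment(
            s.contig_id,
            s.strand,
            s.frame,
            s.aa_seq.replace("I", "L"),
            s.genomic_start,
            s.contig_length,
        )
        for s in segments
    ]
    assert _keys(map_psts(sim.psts, segments)) == _keys(map_psts(sim.psts, swapped))


def test_duplicate_placements_collapse_to_fewest_mods(small_sim, small_segments):
    hits = map_psts(small_sim.psts, small_segments)
    seen = {}
    for h in hits:
        key = (h.spectrum_id, h.contig_id, h.strand, h.start, h.end)
        assert key not in seen, "duplicate placement emitted"
        seen[key] = h


def test_output_order_is_deterministic(small_sim, small_segments):
    a = map_psts(small_sim.psts, small_segments)
    b = map_psts(list(reversed(small_sim.psts)), small_segments)
    assert a == b
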