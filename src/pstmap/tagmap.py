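"""Place peptide sequence tags on translated segments with flank verification.

A PST is a 3-5 residue tag read de novo from an MS/MS spectrum together with
the masses of the fragment ions flanking it (mn on the N side, mc on the C
side).  A placement is a *hit* only when the tag matches the translated frame
and both flank masses are explained, within an absolute tolerance, by the
residues surrounding the match under tryptic constraints:

* the inferred peptide must start at a tryptic N-terminus (segment start, or
  preceded by K/R honouring the proline rule) whose residue-mass sum plus the
  N-flank offset reproduces ``mn``;
* it must end at a tryptic C-terminus (K/R followed by a legal cleavage, or
  segment end) reproducing ``mc`` symmetrically;
* internal missed cleavages and total modifications are capped.

Flank offsets default to the singly charged b/y ion convention (proton, and
water + proton) and are configurable through :class:`MassConstants`.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from .masscalc import (
    DEFAULT_MODIFICATIONS,
    MONOISOTOPIC,
    MassConstants,
    Modification,
)
from .sixframe import TranslatedSegment, segment_to_genomic

__all__ = [
    "PST",
    "MapParams",
    "Hit",
    "normalize_il",
    "read_psts",
    "write_psts",
    "read_hits",
    "write_hits",
    "find_tag",
    "verify_flanks",
    "map_psts",
]

MIN_TAG_LEN = 3
MAX_TAG_LEN = 5


@dataclass(frozen=True)
class PST:
    """A peptide sequence tag: spectrum id, 3-5 residue tag, two flank masses."""

    spectrum_id: str
    tag: str
    mn: float
    mc: float

    def __post_init__(self) -> None:
        if not MIN_TAG_LEN <= len(self.tag) <= MAX_TAG_LEN:
            raise ValueError(
                f"tag {self.tag!r} has length {len(self.tag)}; "
                f"expected {MIN_TAG_LEN}-{MAX_TAG_LEN}"
            )
        for ch in self.tag:
            if ch not in MONOISOTOPIC:
                raise ValueError(f"tag {self.tag!r} contains unknown residue {ch!r}")
        if self.mn < 0 or self.mc < 0:
            raise ValueError(f"negative flank mass on spectrum {self.spectrum_id}")


@dataclass(frozen=True)
class MapParams:
    """Mapping parameters; defaults are the workflow's optimised settings."""

    tolerance: float = 0.5
    max_mods: int = 1
    il_equivalent: bool = True
    missed_cleavages: int = 1
    proline_rule: bool = True
    mass_constants: MassConstants = field(default_factory=MassConstants)
    modifications: Tuple[Modification, ...] = DEFAULT_MODIFICATIONS

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_mods < 0:
            raise ValueError("max_mods must be >= 0")


@dataclass(frozen=True)
class Hit:
    """A verified genomic placement of a PST.

    ``start``/``end`` are 0-based half-open forward-strand coordinates of the
    full inferred peptide (not just the tag), so clusters reflect the extent
    of peptide evidence.
    """

    spectrum_id: str
    tag: str
    contig_id: str
    strand: str
    frame: int
    peptide: str
    start: int
    end: int
    n_mods_used: int


def normalize_il(seq: str) -> str:
    """Collapse the I/L isobar: replace every I by L."""
    return seq.replace("I", "L")


# ---------------------------------------------------------------------------
# PST and hit file formats (tab-separated, '#'-prefixed header)
# ---------------------------------------------------------------------------

PST_HEADER = "#spectrum_id\ttag\tmn\tmc"
HIT_HEADER = "#spectrum_id\ttag\tcontig\tstrand\tframe\tpeptide\tstart\tend\tn_mods"


def write_psts(psts: Iterable[PST], path) -> None:
    with open(path, "w") as fh:
        fh.write(PST_HEADER + "\n")
        for p in psts:
            fh.write(f"{p.spectrum_id}\t{p.tag}\t{p.mn!r}\t{p.mc!r}\n")


def read_psts(path) -> List[PST]:
    psts: List[PST] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}"
                )
            spectrum_id, tag, mn_s, mc_s = parts
            try:
                mn, mc = float(mn_s), float(mc_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric flank mass") from exc
            try:
                psts.append(PST(spectrum_id, tag, mn, mc))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return psts


def write_hits(hits: Iterable[Hit], path) -> None:
    """Write hits as TSV with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write(HIT_HEADER + "\n")
        for h in hits:
            fh.write(
                f"{h.spectrum_id}\t{h.tag}\t{h.contig_id}\t{h.strand}\t{h.frame}\t"
                f"{h.peptide}\t{h.start + 1}\t{h.end}\t{h.n_mods_used}\n"
            )


def read_hits(path) -> List[Hit]:
    hits: List[Hit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(parts)}"
                )
            sid, tag, contig, strand, frame, pep, start, end, nmods = parts
            hits.append(
                Hit(
                    spectrum_id=sid,
                    tag=tag,
                    contig_id=contig,
                    strand=strand,
                    frame=int(frame),
                    peptide=pep,
                    start=int(start) - 1,
                    end=int(end),
                    n_mods_used=int(nmods),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Tag location and flank verification
# ---------------------------------------------------------------------------


def find_tag(tag: str, segment, il_equivalent: bool = True) -> List[int]:
    """All residue positions where ``tag`` matches the segment sequence.

    Matching is exact except that I and L are interchangeable when
    ``il_equivalent`` is on.  ``segment`` may be a TranslatedSegment or a
    plain residue string.
    """
    aa = segment.aa_seq if isinstance(segment, TranslatedSegment) else segment
    if il_equivalent:
        aa = normalize_il(aa)
        tag = normalize_il(tag)
    positions: List[int] = []
    pos = aa.find(tag)
    while pos != -1:
        positions.append(pos)
        pos = aa.find(tag, pos + 1)
    return positions


def _feasible_mod_counts(
    needed: float,
    region: str,
    mods: Sequence[Modification],
    max_mods: int,
    tolerance: float,
) -> List[int]:
    """Mod counts k for which some multiset of k mods placeable on ``region``
    has a delta sum within ``tolerance`` of ``needed``."""
    counts = Counter(region)
    out: List[int] = []
    for k in range(max_mods + 1):
        found = False
        for combo in itertools.combinations_with_replacement(mods, k):
            if abs(needed - sum(m.delta for m in combo)) > tolerance:
                continue
            combo_targets = Counter(m.target for m in combo)
            if all(counts[t] >= c for t, c in combo_targets.items()):
                found = True
                break
        if found:
            out.append(k)
    return out


def _n_boundary_ok(aa: str, b: int, proline_rule: bool) -> bool:
    if b == 0:
        return True
    if aa[b - 1] not in "KR":
        return False
    return not (proline_rule and aa[b] == "P")


def _c_boundary_ok(aa: str, e: int, proline_rule: bool) -> bool:
    if e == len(aa):
        return True
    if aa[e - 1] not in "KR":
        return False
    return not (proline_rule and aa[e] == "P")


def _internal_cleavages(aa: str, b: int, e: int, proline_rule: bool) -> int:
    n = 0
    for i in range(b, e - 1):
        if aa[i] in "KR" and not (proline_rule and aa[i + 1] == "P"):
            n += 1
    return n


def verify_flanks(
    segment, tag_pos: int, pst: PST, params: MapParams
) -> List[Tuple[str, int, int]]:
    """Verify both flank masses of ``pst`` at ``tag_pos`` in ``segment``.

    Extends leftward and rightward from the tag to every tryptic boundary
    whose accumulated residue mass (plus the flank offset and optionally
    modification deltas) matches ``mn`` / ``mc`` within tolerance, then
    combines boundary pairs subject to the missed-cleavage and total-mod
    caps.  Returns ``(peptide, peptide_aa_start, n_mods_used)`` triples; on
    duplicate coordinates the variant with fewer modifications wins.
    """
    aa = segment.aa_seq if isinstance(segment, TranslatedSegment) else segment
    t = len(pst.tag)
    mods = params.modifications
    tol = params.tolerance
    max_delta = max((m.delta for m in mods), default=0.0)
    slack = tol + params.max_mods * max(max_delta, 0.0)

    # Candidate peptide starts b with the set of feasible prefix-mod counts.
    n_candidates: List[Tuple[int, List[int]]] = []
    target_n = pst.mn - params.mass_constants.n_flank_offset
    run = 0.0
    b = tag_pos
    while True:
        if _n_boundary_ok(aa, b, params.proline_rule):
            ks = _feasible_mod_counts(target_n - run, aa[b:tag_pos], mods, params.max_mods, tol)
            if ks:
                n_candidates.append((b, ks))
        if b == 0:
            break
        b -= 1
        run += MONOISOTOPIC[aa[b]]
        if run > target_n + slack:
            break

    # Candidate peptide ends e with feasible suffix-mod counts.
    c_candidates: List[Tuple[int, List[int]]] = []
    target_c = pst.mc - params.mass_constants.c_flank_offset
    run = 0.0
    e = tag_pos + t
    while True:
        if _c_boundary_ok(aa, e, params.proline_rule):
            ks = _feasible_mod_counts(
                target_c - run, aa[tag_pos + t : e], mods, params.max_mods, tol
            )
            if ks:
                c_candidates.append((e, ks))
        if e == len(aa):
            break
        run += MONOISOTOPIC[aa[e]]
        e += 1
        if run > target_c + slack:
            break

    best: Dict[Tuple[int, int], int] = {}
    for b, pre_ks in n_candidates:
        for e, suf_ks in c_candidates:
            total = min(
                (kp + ks for kp in pre_ks for ks in suf_ks if kp + ks <= params.max_mods),
                default=None,
            )
            if total is None:
                continue
            if _internal_cleavages(aa, b, e, params.proline_rule) > params.missed_cleavages:
                continue
            key = (b, e)
            if key not in best or total < best[key]:
                best[key] = total
    return [(aa[b:e], b, nm) for (b, e), nm in sorted(best.items())]


# ---------------------------------------------------------------------------
# Genome-wide mapping
# ---------------------------------------------------------------------------


def _tag_index(
    segments: Sequence[TranslatedSegment], lengths: Iterable[int], il_equivalent: bool
) -> Dict[int, Dict[str, List[Tuple[int, int]]]]:
    """Per-tag-length index of every k-mer position over all segments."""
    index: Dict[int, Dict[str, List[Tuple[int, int]]]] = {
        length: defaultdict(list) for length in lengths
    }
    for si, seg in enumerate(segments):
        text = normalize_il(seg.aa_seq) if il_equivalent else seg.aa_seq
        for length, table in index.items():
            for i in range(len(text) - length + 1):
                table[text[i : i + length]].append((si, i))
    return index


def map_psts(
    psts: Sequence[PST],
    segments: Sequence[TranslatedSegment],
    params: MapParams = MapParams(),
) -> List[Hit]:
    """Map every PST against every translated segment.

    The union of verified placements over all tag occurrences, converted to
    forward-strand genomic coordinates.  Placements of the same spectrum on
    the same interval are collapsed (fewest modifications kept); output order
    is deterministic: contig, start, end, strand, spectrum id.
    """
    if not psts:
        return []
    index = _tag_index(segments, {len(p.tag) for p in psts}, params.il_equivalent)
    collapsed: Dict[Tuple[str, str, str, int, int], Hit] = {}
    for pst in psts:
        key_tag = normalize_il(pst.tag) if params.il_equivalent else pst.tag
        for si, pos in index[len(pst.tag)].get(key_tag, ()):
            seg = segments[si]
            for peptide, aa_start, n_mods in verify_flanks(seg, pos, pst, params):
                contig, strand, (gstart, gend) = segment_to_genomic(
                    seg, aa_start, aa_start + len(peptide)
                )
                key = (pst.spectrum_id, contig, strand, gstart, gend)
                hit = Hit(
                    spectrum_id=pst.spectrum_id,
                    tag=pst.tag,
                    contig_id=contig,
                    strand=strand,
                    frame=seg.frame,
                    peptide=peptide,
                    start=gstart,
                    end=gend,
                    n_mods_used=n_mods,
                )
                if key not in collapsed or n_mods < collapsed[key].n_mods_used:
                    collapsed[key] = hit
    return sorted(
        collapsed.values(),
        key=lambda h: (h.contig_id, h.start, h.end, h.strand, h.spectrum_id),
    )
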