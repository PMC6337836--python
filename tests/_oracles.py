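"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and written from first principles:
forward enumeration instead of backward search, O(n^2) closure instead of
sorted chaining, an independently typed residue mass table instead of the
package's.  None of it imports the code paths it checks beyond plain data
types.
"""

from __future__ import annotations

import itertools
from collections import Counter
from typing import Dict, List, Sequence, Set, Tuple

from Bio.Seq import Seq

# Reference monoisotopic residue masses, typed independently from a standard
# table (same source standard as the package's frozen table).
REF_MASSES = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}
REF_WATER = 18.0105646


def ref_peptide_mass(seq: str) -> float:
    """Brute-force table-lookup neutral peptide mass."""
    return sum(REF_MASSES[ch] for ch in seq) + REF_WATER


# ---------------------------------------------------------------------------
# Six-frame translation oracle
# ---------------------------------------------------------------------------


def brute_six_frame(dna: str) -> List[Tuple[str, int, str, int]]:
    """Naive codon-loop six-frame translation.

    Returns (strand, frame, aa_seq, leftmost_forward_base) for every
    stop-free, N-free segment, using Biopython's translation table codon by
    codon.
    """
    out: List[Tuple[str, int, str, int]] = []
    length = len(dna)
    for strand in "+-":
        s = dna if strand == "+" else str(Seq(dna).reverse_complement())
        for frame in range(3):
            run: List[str] = []
            run_start = None
            for pos in range(frame, length - 2, 3):
                codon = s[pos : pos + 3]
                if "N" in codon:
                    aa = None
                else:
                    aa = str(Seq(codon).translate())
                    if aa == "*":
                        aa = None
                if aa is None:
                    if run:
                        out.append(_emit(strand, frame, run, run_start, length))
                        run = []
                    continue
                if not run:
                    run_start = pos
                run.append(aa)
            if run:
                out.append(_emit(strand, frame, run, run_start, length))
    return out


def _emit(strand: str, frame: int, run: List[str], local_start: int, length: int):
    n_bases = 3 * len(run)
    left = local_start if strand == "+" else length - (local_start + n_bases)
    return (strand, frame, "".join(run), left)


# ---------------------------------------------------------------------------
# Exhaustive tag-mapping oracle
# ---------------------------------------------------------------------------


def _norm(seq: str) -> str:
    return seq.replace("I", "L")


def _flank_ok(
    target: float,
    region: str,
    mods,
    n_allowed: int,
    tolerance: float,
) -> Set[int]:
    """All mod counts <= n_allowed explaining target within tolerance."""
    base = sum(REF_MASSES[ch] for ch in region)
    counts = Counter(region)
    ok: Set[int] = set()
    for k in range(n_allowed + 1):
        for combo in itertools.combinations_with_replacement(mods, k):
            need = Counter(m.target for m in combo)
            if any(counts[t] < c for t, c in need.items()):
                continue
            if abs(target - base - sum(m.delta for m in combo)) <= tolerance:
                ok.add(k)
                break
    return ok


def oracle_map(psts, segments, params) -> Set[Tuple[str, str, str, int, int]]:
    """Enumerate every tryptic peptide of every segment, generate all its tag
    windows, and intersect with the PST list under the mass rules.

    Returns the set of (spectrum_id, contig, strand, start, end).
    """
    n_off = params.mass_constants.n_flank_offset
    c_off = params.mass_constants.c_flank_offset
    hits: Set[Tuple[str, str, str, int, int]] = set()
    by_len: Dict[int, list] = {}
    for p in psts:
        by_len.setdefault(len(p.tag), []).append(p)
    for seg in segments:
        aa = seg.aa_seq
        n = len(aa)
        bounds = [0] + [
            i + 1
            for i in range(n - 1)
            if aa[i] in "KR" and not (params.proline_rule and aa[i + 1] == "P")
        ] + [n]
        bounds = sorted(set(bounds))
        nfrag = len(bounds) - 1
        for bi in range(nfrag):
            for bj in range(bi, min(bi + params.missed_cleavages + 1, nfrag)):
                b, e = bounds[bi], bounds[bj + 1]
                pep = aa[b:e]
                pep_norm = _norm(pep) if params.il_equivalent else pep
                for tlen, plist in by_len.items():
                    for w in range(len(pep) - tlen + 1):
                        window = pep_norm[w : w + tlen]
                        for pst in plist:
                            tag = _norm(pst.tag) if params.il_equivalent else pst.tag
                            if window != tag:
                                continue
                            pre_ks = _flank_ok(
                                pst.mn - n_off,
                                pep[:w],
                                params.modifications,
                                params.max_mods,
                                params.tolerance,
                            )
                            if not pre_ks:
                                continue
                            suf_ks = _flank_ok(
                                pst.mc - c_off,
                                pep[w + tlen :],
                                params.modifications,
                                params.max_mods,
                                params.tolerance,
                            )
                            if not any(
                                kp + ks <= params.max_mods
                                for kp in pre_ks
                                for ks in suf_ks
                            ):
                                continue
                            if seg.strand == "+":
                                start = seg.genomic_start + 3 * b
                                end = seg.genomic_start + 3 * e
                            else:
                                start = seg.genomic_start + 3 * (n - e)
                                end = seg.genomic_start + 3 * (n - b)
                            hits.add((pst.spectrum_id, seg.contig_id, seg.strand, start, end))
    return hits


# ---------------------------------------------------------------------------
# Clustering closure oracle
# ---------------------------------------------------------------------------


def closure_clusters(
    hits: Sequence, maxdist: int, minhit: int, minpep: int, strand_aware: bool = True
) -> Set[frozenset]:
    """Union-find transitive closure of the pairwise gap relation.

    Returns the set of surviving clusters as frozensets of member indices.
    """
    n = len(hits)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        for j in range(i + 1, n):
            hi, hj = hits[i], hits[j]
            if hi.contig_id != hj.contig_id:
                continue
            if strand_aware and hi.strand != hj.strand:
                continue
            a, b = (hi, hj) if (hi.start, hi.end) <= (hj.start, hj.end) else (hj, hi)
            if b.start - a.end <= maxdist:
                union(i, j)

    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out: Set[frozenset] = set()
    for members in groups.values():
        if len(members) < minhit:
            continue
        peptides = {_norm(hits[i].peptide) for i in members}
        if len(peptides) < minpep:
            continue
        out.add(frozenset(members))
    return out


# ---------------------------------------------------------------------------
# Typical-spectra oracle
# ---------------------------------------------------------------------------


def brute_typical(cluster_hits: Sequence, all_hits: Sequence) -> int:
    """Per-spectrum exhaustive check of cluster specificity."""
    members = set(cluster_hits)
    n = 0
    for sid in {h.spectrum_id for h in cluster_hits}:
        everywhere = [h for h in all_hits if h.spectrum_id == sid]
        if all(h in members for h in everywhere):
            n += 1
    return n
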