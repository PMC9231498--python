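"""Alignment primitives shared by annotation, calling and dating.

Global affine-gap alignment goes through Bio.Align.PairwiseAligner; fast
infix (glocal) matching of short queries against longer targets — clip
versus LTR, solo-LTR scans — goes through edlib edit distance.
"""

from __future__ import annotations

import edlib
from Bio import Align

from ._seq import revcomp


def global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = global_aligner()


def aligned_blocks(target: str, query: str) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Gapless blocks ((t0,t1),(q0,q1)) of the best global affine alignment."""
    aln = _ALIGNER.align(target, query)[0]
    tb, qb = aln.aligned
    return [((int(t[0]), int(t[1])), (int(q[0]), int(q[1]))) for t, q in zip(tb, qb)]


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatched positions among aligned, ungapped columns.

    The pair is aligned globally with affine gaps; gap columns are excluded
    from both numerator and denominator.  Computed on a canonical ordering
    of the two sequences so the distance is exactly symmetric.
    """
    if not a or not b:
        raise ValueError("p_distance requires non-empty sequences")
    if b < a:
        a, b = b, a
    aligned = 0
    mismatched = 0
    for (t0, t1), (q0, q1) in aligned_blocks(a, b):
        aligned += t1 - t0
        for i in range(t1 - t0):
            if a[t0 + i] != b[q0 + i]:
                mismatched += 1
    if aligned == 0:
        return 1.0
    return mismatched / aligned


def identity_fraction(a: str, b: str) -> float:
    """Matches of the global alignment over the longer sequence length."""
    if not a or not b:
        return 0.0
    matches = 0
    for (t0, t1), (q0, q1) in aligned_blocks(a, b):
        for i in range(t1 - t0):
            if a[t0 + i] == b[q0 + i]:
                matches += 1
    return matches / max(len(a), len(b))


def infix_match(query: str, target: str, both_strands: bool = True):
    """Best infix (glocal) placement of ``query`` inside ``target``.

    Returns ``(identity, matches_equivalent, strand, (start, end))`` where
    identity is 1 - edit_distance/len(query) and matches_equivalent the
    corresponding match count lower bound.  edlib's HW task allows free gaps
    at both target ends, which is the right model for a clipped read tail or
    a solo LTR embedded in a contig.
    """
    if not query or not target:
        return 0.0, 0, "+", (0, 0)
    best = (-1.0, 0, "+", (0, 0))
    strands = [("+", query), ("-", revcomp(query))] if both_strands else [("+", query)]
    for strand, q in strands:
        res = edlib.align(q, target, mode="HW", task="locations")
        ed = res["editDistance"]
        if ed < 0:
            continue
        ident = 1.0 - ed / len(q)
        if ident > best[0]:
            loc = res["locations"][0]
            best = (ident, len(q) - ed, strand, (int(loc[0]), int(loc[1]) + 1))
    return best
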