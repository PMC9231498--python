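"""Structural provirus annotation in an assembly.

Finds candidate proviruses as pairs of similar, same-strand long terminal
repeats (LTRs) at proviral spacing, confirms integration sites through
target site duplications (TSDs), profiles the gag/pro/pol/env coding
regions for premature stops and frameshifts against a template, and
classifies structural completeness (full-length versus defective versus
solo LTR).

The LTR-pair search is a deliberately simple, deterministic k-mer
anchor-and-chain scan followed by alignment verification — adequate at the
scale of a single assembly screen; it does not attempt motif-level scoring.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from ._align import aligned_blocks, identity_fraction, infix_match
from ._seq import revcomp
from .simulate import STOP_CODONS, ProvirusTemplate

__all__ = [
    "GeneProfile",
    "ProvirusAnnotation",
    "find_ltr_pairs",
    "detect_tsd",
    "profile_genes",
    "classify_structure",
    "find_solo_ltrs",
    "annotate_assembly",
    "annotations_to_frame",
    "write_annotations",
]

GENES = ("gag", "pro", "pol", "env")


@dataclass(frozen=True)
class GeneProfile:
    identity: float
    n_stops: int | None
    n_frameshifts: int | None
    detected: bool


@dataclass
class ProvirusAnnotation:
    contig: str
    start: int
    end: int
    ltr5: tuple[int, int] | None
    ltr3: tuple[int, int] | None
    ltr_identity: float | None
    tsd_len: int
    tsd_seq: str
    structure_tokens: tuple[str, ...]
    full_length: bool
    solo: bool = False
    strand: str = "+"
    lineage: str | None = None
    genes: dict[str, GeneProfile] = field(default_factory=dict)

    @property
    def element_interval(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# LTR pair discovery


def find_ltr_pairs(
    contig_seq: str,
    min_ltr_len: int = 100,
    ltr_len_max: int = 1200,
    element_len_range: tuple[int, int] = (4000, 12000),
    min_identity: float = 0.85,
    k: int = 12,
    band: int = 24,
    max_chain_gap: int = 250,
    max_kmer_occupancy: int = 64,
) -> list[tuple[tuple[int, int], tuple[int, int], float]]:
    """Candidate (ltr5, ltr3) interval pairs on one contig.

    Exact k-mers shared at a consistent offset (within ``band``, tolerating
    small indels between the repeats) are chained into candidate repeat
    pairs, whose identity is then verified by global alignment.  Candidates
    are non-overlapping, ordered leftmost-first then longest.
    """
    if min_ltr_len < 50:
        raise ValueError("min_ltr_len must be >= 50")
    if min_identity < 0.7:
        raise ValueError("min_identity must be >= 0.7")
    n = len(contig_seq)
    elem_min, elem_max = element_len_range
    d_min = max(min_ltr_len, elem_min - ltr_len_max)
    d_max = elem_max

    kmers: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        kmers[contig_seq[i : i + k]].append(i)

    hits: list[tuple[int, int]] = []  # (offset d, upstream position i)
    for positions in kmers.values():
        if len(positions) < 2 or len(positions) > max_kmer_occupancy:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                d = positions[bi] - positions[ai]
                if d_min <= d <= d_max:
                    hits.append((d, positions[ai]))
    if not hits:
        return []

    # group by offset (diagonal), then split groups on large positional gaps
    hits.sort()
    groups: list[list[tuple[int, int]]] = []
    for h in hits:
        if groups and h[0] - groups[-1][0][0] <= band:
            groups[-1].append(h)
        else:
            groups.append([h])

    candidates: list[tuple[tuple[int, int], tuple[int, int], float]] = []
    for group in groups:
        group.sort(key=lambda h: h[1])
        chains: list[list[tuple[int, int]]] = [[group[0]]]
        for h in group[1:]:
            if h[1] - chains[-1][-1][1] <= max_chain_gap:
                chains[-1].append(h)
            else:
                chains.append([h])
        for chain in chains:
            i0 = chain[0][1]
            i1 = chain[-1][1] + k
            if i1 - i0 < min_ltr_len or i1 - i0 > ltr_len_max:
                continue
            j0 = min(h[1] + h[0] for h in chain)
            j1 = max(h[1] + h[0] for h in chain) + k
            if j1 > n or j0 < i1:
                continue
            span = j1 - i0
            if not (elem_min <= span <= elem_max):
                continue
            ident = identity_fraction(contig_seq[i0:i1], contig_seq[j0:j1])
            if ident >= min_identity:
                candidates.append(((i0, i1), (j0, j1), ident))

    # deterministic ordering, then greedy non-overlap (leftmost, then longest)
    candidates.sort(key=lambda c: (c[0][0], -(c[1][1] - c[0][0])))
    chosen: list[tuple[tuple[int, int], tuple[int, int], float]] = []
    for cand in candidates:
        s, e = cand[0][0], cand[1][1]
        if all(e <= c[0][0] or s >= c[1][1] for c in chosen):
            chosen.append(cand)
    return chosen


def detect_tsd(
    contig_seq: str, element_interval: tuple[int, int], max_tsd: int = 20
) -> tuple[int, str]:
    """Longest exact duplication flanking the element (0 if none).

    Returns the largest k <= max_tsd such that the k bases immediately 5'
    of the element equal the k bases immediately 3' of it; searches only
    over the flank actually available at contig edges.
    """
    s, e = element_interval
    left = contig_seq[max(0, s - max_tsd) : s]
    right = contig_seq[e : e + max_tsd]
    for k in range(min(len(left), len(right)), 0, -1):
        if left[-k:] == right[:k]:
            return k, left[-k:]
    return 0, ""


# ---------------------------------------------------------------------------
# coding-region profiling


def refine_boundaries_by_tsd(
    contig_seq: str,
    element_interval: tuple[int, int],
    max_tsd: int = 20,
    max_shift: int = 6,
) -> tuple[int, int, int, str]:
    """Resolve repeat-boundary ambiguity by maximising the flanking TSD.

    When a flank base coincides with the homologous base inside the
    element, the repeat pair can slide by a few bases and truncate the
    apparent TSD; trying small boundary shifts and keeping the one with
    the longest exact duplication restores the integration-site geometry.
    Returns (start, end, tsd_len, tsd_seq); ties prefer the unshifted
    boundaries.
    """
    s, e = element_interval
    best = None
    # the detected repeat pair is maximal, so the true element can only be
    # a trim of it: start moves right, end moves left
    for ds in range(0, max_shift + 1):
        for de in range(-max_shift, 1):
            if e + de <= s + ds:
                continue
            k, seq = detect_tsd(contig_seq, (s + ds, e + de), max_tsd)
            key = (-k, abs(ds) + abs(de), ds, de)
            if best is None or key < best[0]:
                best = (key, s + ds, e + de, k, seq)
    return best[1], best[2], best[3], best[4]


def profile_genes(
    element_seq: str,
    template: ProvirusTemplate,
    min_gene_identity: float = 0.4,
) -> dict[str, GeneProfile]:
    """Per-gene identity, premature stops and frameshifts versus a template.

    The element is aligned globally (affine gaps) to the full template.
    Identity per gene counts matched columns over the gene's template
    length; premature stop codons are read in the template frame from
    codons aligned without gaps; each indel of length not divisible by
    three that touches the gene counts as one frameshift.  A gene under
    ``min_gene_identity`` is reported undetected (counts None), not as
    mutation-free.
    """
    tmpl = template.full_seq
    blocks = aligned_blocks(tmpl, element_seq)
    offset = template.ltr_len
    # template position -> aligned query position (-1 where deleted)
    qmap = [-1] * len(tmpl)
    for (t0, t1), (q0, q1) in blocks:
        for i in range(t1 - t0):
            qmap[t0 + i] = q0 + i

    profiles: dict[str, GeneProfile] = {}
    for gene in GENES:
        a, b = template.gene_map[gene]
        a += offset
        b += offset
        matches = sum(
            1
            for t in range(a, b)
            if qmap[t] >= 0 and element_seq[qmap[t]] == tmpl[t]
        )
        identity = matches / (b - a)
        if identity < min_gene_identity:
            profiles[gene] = GeneProfile(identity, None, None, False)
            continue
        # premature stops in template frame, codons aligned without gaps
        n_stops = 0
        for t in range(a, b - 3, 3):  # final codon is the template stop
            q = qmap[t]
            if q >= 0 and qmap[t + 1] == q + 1 and qmap[t + 2] == q + 2:
                codon = element_seq[q : q + 3]
                if codon in STOP_CODONS and tmpl[t : t + 3] not in STOP_CODONS:
                    n_stops += 1
        # frame-disrupting indels from inter-block gaps
        n_fs = 0
        for bi in range(1, len(blocks)):
            (pt0, pt1), (pq0, pq1) = blocks[bi - 1]
            (t0, t1), (q0, q1) = blocks[bi]
            dt = t0 - pt1  # deletion in element relative to template
            dq = q0 - pq1  # insertion in element
            if dt > 0 and dt % 3 and pt1 < b and t0 > a:
                n_fs += 1
            if dq > 0 and dq % 3 and a <= pt1 < b:
                n_fs += 1
        profiles[gene] = GeneProfile(identity, n_stops, n_fs, True)
    return profiles


# ---------------------------------------------------------------------------
# structural classification


def classify_structure(
    contig: str,
    contig_seq: str,
    pair: tuple[tuple[int, int], tuple[int, int], float],
    template: ProvirusTemplate,
    max_tsd: int = 20,
    min_gene_identity: float = 0.4,
    lineage: str | None = None,
    strand: str = "+",
) -> ProvirusAnnotation:
    """Full annotation of one LTR-pair candidate.

    ``strand`` gives the element's orientation relative to the contig (as
    determined from an LTR match against the template library); minus-strand
    elements are reverse-complemented before gene profiling.  full_length is
    true iff both LTRs and all of gag, pro, pol, env are detected.
    """
    (l5s, l5e), (l3s, l3e), ident = pair
    start, end, tsd_len, tsd_seq = refine_boundaries_by_tsd(
        contig_seq, (l5s, l3e), max_tsd
    )
    # the repeat pair slides as a unit: both LTR starts move with the
    # refined element start, both ends with the refined element end
    ds, de = start - l5s, end - l3e
    element = contig_seq[start:end]
    if strand == "-":
        element = revcomp(element)
    genes = profile_genes(element, template, min_gene_identity)
    tokens = ["5LTR"] + [g for g in GENES if genes[g].detected] + ["3LTR"]
    full = all(genes[g].detected for g in GENES)
    return ProvirusAnnotation(
        contig=contig,
        start=start,
        end=end,
        ltr5=(start, l5e + de),
        ltr3=(l3s + ds, end),
        ltr_identity=ident,
        tsd_len=tsd_len,
        tsd_seq=tsd_seq,
        structure_tokens=tuple(tokens),
        full_length=full,
        strand=strand,
        lineage=lineage,
        genes=genes,
    )


def find_solo_ltrs(
    contig_seq: str,
    ltr_seq: str,
    min_identity: float = 0.85,
    exclude: list[tuple[int, int]] | None = None,
    max_hits: int = 64,
) -> list[tuple[int, int, float]]:
    """Lone LTR-like matches to a library LTR outside annotated elements.

    Iterative best-infix search with masking; a hit overlapping an excluded
    (already annotated) interval is masked and not reported.
    """
    exclude = list(exclude or [])
    seq = contig_seq
    hits: list[tuple[int, int, float]] = []
    for _ in range(max_hits):
        ident, _m, _strand, (s, e) = infix_match(ltr_seq, seq)
        if ident < min_identity or e <= s:
            break
        seq = seq[:s] + "N" * (e - s) + seq[e:]
        if any(s < xe and e > xs for xs, xe in exclude):
            continue
        hits.append((s, e, ident))
        exclude.append((s, e))
    hits.sort()
    return hits


def annotate_assembly(
    assembly: dict[str, str],
    templates: dict[str, ProvirusTemplate],
    min_ltr_len: int = 100,
    ltr_len_max: int = 1200,
    element_len_range: tuple[int, int] = (4000, 12000),
    min_identity: float = 0.85,
    max_tsd: int = 20,
    min_gene_identity: float = 0.4,
    with_solo: bool = True,
) -> list[ProvirusAnnotation]:
    """Annotate every contig of an assembly against a set of lineage templates.

    Each LTR-pair candidate is classified against the template whose LTR
    best matches its 5' LTR; solo LTRs are then searched outside annotated
    elements.
    """
    annotations: list[ProvirusAnnotation] = []
    for contig in sorted(assembly):
        seq = assembly[contig]
        pairs = find_ltr_pairs(
            seq,
            min_ltr_len=min_ltr_len,
            ltr_len_max=ltr_len_max,
            element_len_range=element_len_range,
            min_identity=min_identity,
        )
        occupied: list[tuple[int, int]] = []
        for pair in pairs:
            ltr5_seq = seq[pair[0][0] : pair[0][1]]
            best_lineage, best_ident, best_strand = None, -1.0, "+"
            for name, tpl in sorted(templates.items()):
                ident, _, strand, _ = infix_match(ltr5_seq, tpl.ltr)
                if ident > best_ident:
                    best_lineage, best_ident, best_strand = name, ident, strand
            ann = classify_structure(
                contig,
                seq,
                pair,
                templates[best_lineage],
                max_tsd=max_tsd,
                min_gene_identity=min_gene_identity,
                lineage=best_lineage,
                strand=best_strand,
            )
            annotations.append(ann)
            occupied.append((ann.start, ann.end))
        if with_solo:
            for name, tpl in sorted(templates.items()):
                for s, e, ident in find_solo_ltrs(
                    seq, tpl.ltr, min_identity=min_identity, exclude=list(occupied)
                ):
                    tsd_len, tsd_seq = detect_tsd(seq, (s, e), max_tsd)
                    annotations.append(
                        ProvirusAnnotation(
                            contig=contig,
                            start=s,
                            end=e,
                            ltr5=(s, e),
                            ltr3=None,
                            ltr_identity=None,
                            tsd_len=tsd_len,
                            tsd_seq=tsd_seq,
                            structure_tokens=("5LTR",),
                            full_length=False,
                            solo=True,
                            lineage=name,
                        )
                    )
                    occupied.append((s, e))
    annotations.sort(key=lambda a: (a.contig, a.start))
    return annotations


# ---------------------------------------------------------------------------
# tabular output


def annotations_to_frame(annotations: list[ProvirusAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        row = {
            "contig": a.contig,
            "start": a.start,
            "end": a.end,
            "lineage": a.lineage or "",
            "ltr_identity": "" if a.ltr_identity is None else round(a.ltr_identity, 4),
            "tsd_len": a.tsd_len,
            "tsd_seq": a.tsd_seq,
            "strand": a.strand,
            "structure": "-".join(a.structure_tokens),
            "full_length": a.full_length,
            "solo": a.solo,
        }
        for g in GENES:
            prof = a.genes.get(g)
            row[f"{g}_identity"] = "" if prof is None else round(prof.identity, 4)
            row[f"{g}_stops"] = "" if (prof is None or prof.n_stops is None) else prof.n_stops
            row[f"{g}_frameshifts"] = (
                "" if (prof is None or prof.n_frameshifts is None) else prof.n_frameshifts
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_annotations(annotations: list[ProvirusAnnotation], tsv_path, bed_path=None):
    df = annotations_to_frame(annotations)
    df.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for a in annotations:
                name = f"{a.lineage or 'ERV'}|{'solo' if a.solo else 'provirus'}"
                fh.write(
                    f"{a.contig}\t{a.start}\t{a.end}\t{name}\t0\t{a.strand}\n"
                )
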