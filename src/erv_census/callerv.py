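"""Per-individual ERV presence/absence calling from SAM alignments.

Non-reference insertions are called from clusters of discordant read pairs
(host-anchored reads whose mates map to the ERV library) and soft-clipped
reads whose clipped tails match a library LTR.  Reference-locus absences
(chromosomes in the preintegration state) are called from read pairs
spanning the locus at an apparent insert stretched by the element length,
plus reads split/clipped at the element boundaries.  A soft-clip rescue
pass re-counts LTR-matching clips around known cross-sample loci, which
recovers calls in low-coverage individuals.

Support semantics: the ``min_reads`` threshold of a policy counts
discordant read pairs (the discovery signal); soft-clips drive the
stringent per-side CLIP filters, breakpoint/TSD refinement, and rescue.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pysam

from ._align import infix_match
from ._seq import dinucleotide_entropy
from .simulate import LIB_PREFIX

__all__ = [
    "SoftClip",
    "DiscordantPair",
    "AlignmentEvidence",
    "FilterPolicy",
    "InsertionCall",
    "AbsenceCall",
    "RefLocus",
    "extract_evidence",
    "call_nonreference_insertions",
    "call_reference_absences",
    "rescue_softclips",
    "calls_to_frame",
]


@dataclass(frozen=True)
class SoftClip:
    contig: str
    pos: int  # 0-based clip point on the reference
    side: str  # 'left' (clip at read start) | 'right' (clip at read end)
    seq: str
    lineage: str
    read_name: str


@dataclass(frozen=True)
class DiscordantPair:
    contig: str
    anchor_pos: int  # junction-side end of the host-anchored read
    lineage: str
    read_name: str


@dataclass
class AlignmentEvidence:
    softclips: list[SoftClip]
    discordant: list[DiscordantPair]


@dataclass(frozen=True)
class FilterPolicy:
    """Two-tier calling policy.

    stringent: discovery-grade — per-side clip support and a
    support-vs-coverage sanity window on top of the pair threshold.
    relaxed: cross-individual typing — pair support alone.
    """

    mode: str = "stringent"  # 'stringent' | 'relaxed'
    min_reads: int = 5  # discordant-pair support (5 for HC, 2 for LC)
    min_clip_each_side: int = 2
    coverage: float | None = None

    @classmethod
    def hc(cls, mode: str = "stringent", coverage: float | None = 40.0):
        return cls(mode=mode, min_reads=5, min_clip_each_side=2, coverage=coverage)

    @classmethod
    def lc(cls, mode: str = "relaxed", coverage: float | None = 6.0):
        return cls(mode=mode, min_reads=2, min_clip_each_side=2, coverage=coverage)


@dataclass(frozen=True)
class InsertionCall:
    contig: str
    start: int  # breakpoint interval (the TSD when resolvable)
    end: int
    clip5_support: int
    clip3_support: int
    pair_support: int
    lineage: str
    tier: str  # 'stringent' | 'relaxed'
    tsd_len_est: int


@dataclass(frozen=True)
class AbsenceCall:
    locus_id: str
    contig: str
    start: int
    end: int
    spanning_support: int
    split_support: int
    zygosity_hint: str  # 'hom_absent' | 'het'


@dataclass(frozen=True)
class RefLocus:
    locus_id: str
    contig: str
    start: int
    end: int
    lineage: str = ""


# ---------------------------------------------------------------------------
# evidence extraction


def _iter_sam(sam) -> Iterable[pysam.AlignedSegment]:
    if isinstance(sam, (str,)) or hasattr(sam, "__fspath__"):
        with pysam.AlignmentFile(str(sam), "r") as fh:
            yield from fh
    else:
        yield from sam


def library_ltrs(library: dict[str, str]) -> dict[str, str]:
    """Lineage -> LTR sequence from library contig naming conventions.

    Entries named ``<prefix><lineage>_LTR`` are LTRs; if none exist, full
    library entries are used as match targets directly.
    """
    ltrs = {}
    for name, seq in library.items():
        if name.endswith("_LTR"):
            lineage = name[len(LIB_PREFIX) :] if name.startswith(LIB_PREFIX) else name
            ltrs[lineage[: -len("_LTR")]] = seq
    if not ltrs:
        for name, seq in library.items():
            lineage = name[len(LIB_PREFIX) :] if name.startswith(LIB_PREFIX) else name
            ltrs[lineage] = seq
    return ltrs


def _match_clip(
    clip: str, ltrs: dict[str, str], min_identity: float, min_matches: int
) -> str | None:
    best_lineage, best_matches = None, -1
    for lineage in sorted(ltrs):
        ident, matches, _strand, _loc = infix_match(clip, ltrs[lineage])
        if ident >= min_identity and matches >= min_matches and matches > best_matches:
            best_lineage, best_matches = lineage, matches
    return best_lineage


def extract_evidence(
    sam,
    erv_library: dict[str, str],
    min_clip: int = 10,
    clip_match_identity: float = 0.8,
    min_match_score: int = 10,
    min_entropy: float = 1.0,
) -> AlignmentEvidence:
    """Collect insertion evidence from a coordinate-sorted SAM.

    Soft-clips of at least ``min_clip`` bases whose clipped tail matches a
    library LTR (either strand, identity >= ``clip_match_identity`` and at
    least ``min_match_score`` matching bases) are retained with their
    best-match lineage; low-complexity tails (dinucleotide entropy below
    ``min_entropy`` bits) are discarded first.  Discordant pairs are
    host-anchored reads whose mates map to a library contig.
    """
    ltrs = library_ltrs(erv_library)
    clips: list[SoftClip] = []
    pairs: list[DiscordantPair] = []
    last: dict[str, int] = {}
    for read in _iter_sam(sam):
        if read.is_unmapped or read.reference_name is None:
            continue
        rname = read.reference_name
        if rname in last and read.reference_start < last[rname]:
            raise ValueError("input SAM must be coordinate-sorted")
        last[rname] = read.reference_start
        if rname.startswith(LIB_PREFIX):
            continue  # never call inside the library contigs
        cig = read.cigartuples or []
        seq = read.query_sequence or ""
        if cig and seq:
            if cig[0][0] == 4 and cig[0][1] >= min_clip:
                tail = seq[: cig[0][1]]
                if dinucleotide_entropy(tail) >= min_entropy:
                    lineage = _match_clip(
                        tail, ltrs, clip_match_identity, min_match_score
                    )
                    if lineage:
                        clips.append(
                            SoftClip(
                                rname,
                                read.reference_start,
                                "left",
                                tail,
                                lineage,
                                read.query_name,
                            )
                        )
            if cig[-1][0] == 4 and cig[-1][1] >= min_clip:
                tail = seq[len(seq) - cig[-1][1] :]
                if dinucleotide_entropy(tail) >= min_entropy:
                    lineage = _match_clip(
                        tail, ltrs, clip_match_identity, min_match_score
                    )
                    if lineage:
                        clips.append(
                            SoftClip(
                                rname,
                                read.reference_end,
                                "right",
                                tail,
                                lineage,
                                read.query_name,
                            )
                        )
        mate_ref = read.next_reference_name
        if (
            read.is_paired
            and mate_ref is not None
            and mate_ref.startswith(LIB_PREFIX)
        ):
            lineage = mate_ref[len(LIB_PREFIX) :]
            if lineage.endswith("_LTR"):
                lineage = lineage[: -len("_LTR")]
            anchor = (
                read.reference_start if read.is_reverse else read.reference_end
            )
            pairs.append(DiscordantPair(rname, anchor, lineage, read.query_name))
    return AlignmentEvidence(softclips=clips, discordant=pairs)


# ---------------------------------------------------------------------------
# non-reference insertion calling


def _modal(values: list[int]) -> int:
    counts = Counter(values)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def _passes_relaxed(pair_support: int, policy: FilterPolicy) -> bool:
    return pair_support >= policy.min_reads


def _passes_stringent(
    pair_support: int, clip5: int, clip3: int, policy: FilterPolicy
) -> bool:
    if pair_support < policy.min_reads:
        return False
    if clip5 < policy.min_clip_each_side or clip3 < policy.min_clip_each_side:
        return False
    if policy.coverage:
        # support-vs-coverage sanity window on pair support: reject both
        # scattered noise and pile-ups far above what one locus can
        # generate at this depth
        if not (policy.coverage / 8 <= pair_support <= 3 * policy.coverage):
            return False
    return True


def call_nonreference_insertions(
    evidence: AlignmentEvidence,
    policy: FilterPolicy,
    window: int = 200,
) -> list[InsertionCall]:
    """Cluster evidence and emit tiered insertion calls.

    Evidence is single-linkage clustered within ``window`` bp per contig
    and lineage.  The breakpoint is the interval between the modal left-
    clip position and the modal right-clip position — the double-clipped
    overlap whose width estimates the TSD length.  The stringent call set
    is a subset of the relaxed set for the same evidence.
    """
    items: dict[tuple[str, str], list[tuple[int, str, object]]] = defaultdict(list)
    for c in evidence.softclips:
        items[(c.contig, c.lineage)].append((c.pos, "clip", c))
    for p in evidence.discordant:
        items[(p.contig, p.lineage)].append((p.anchor_pos, "pair", p))

    calls: list[InsertionCall] = []
    for (contig, lineage), rows in sorted(items.items()):
        rows.sort(key=lambda r: r[0])
        clusters: list[list] = [[rows[0]]]
        for row in rows[1:]:
            if row[0] - clusters[-1][-1][0] <= window:
                clusters[-1].append(row)
            else:
                clusters.append([row])
        for cluster in clusters:
            left = [r[0] for r in cluster if r[1] == "clip" and r[2].side == "left"]
            right = [r[0] for r in cluster if r[1] == "clip" and r[2].side == "right"]
            pair_names = {r[2].read_name for r in cluster if r[1] == "pair"}
            clip3 = len(left)  # clips carrying the element 3' end
            clip5 = len(right)  # reads continuing into the element 5' LTR
            pair_support = len(pair_names)
            if left and right:
                lpos, rpos = _modal(left), _modal(right)
                start, end = min(lpos, rpos), max(lpos, rpos)
                tsd = max(rpos - lpos, 0)
            elif left or right:
                pos = _modal(left or right)
                start = end = pos
                tsd = 0
            else:
                anchors = sorted(r[0] for r in cluster)
                start = end = anchors[len(anchors) // 2]
                tsd = 0
            stringent = _passes_stringent(pair_support, clip5, clip3, policy)
            relaxed = _passes_relaxed(pair_support, policy)
            if policy.mode == "stringent" and not stringent:
                continue
            if not relaxed:
                continue
            calls.append(
                InsertionCall(
                    contig=contig,
                    start=start,
                    end=end,
                    clip5_support=clip5,
                    clip3_support=clip3,
                    pair_support=pair_support,
                    lineage=lineage,
                    tier="stringent" if stringent else "relaxed",
                    tsd_len_est=tsd,
                )
            )
    calls.sort(key=lambda c: (c.contig, c.start, c.lineage))
    return calls


# ---------------------------------------------------------------------------
# reference-locus absence calling


def call_reference_absences(
    sam,
    reference_erv_loci: Sequence[RefLocus],
    policy: FilterPolicy,
    insert_mean: int = 400,
    insert_sd: int = 50,
    reference: dict[str, str] | None = None,
    min_clip: int = 10,
    slack: int = 30,
    max_tsd: int = 20,
    flank_match_identity: float = 0.8,
) -> list[AbsenceCall]:
    """Call reference ERV loci absent (preintegration state) per individual.

    Spanning support: pairs with one mate on each side of the locus whose
    apparent insert is insert_mean + element_length within 4 SD.  Split
    support: reads clipped at the locus's outer flanks whose clipped tail
    matches the opposite flank (checked when the reference sequence is
    provided).  An absence is called when combined support reaches
    ``policy.min_reads``; the zygosity hint is hom_absent when concordant
    coverage inside the element is below depth expectations for a
    heterozygote, else het.
    """
    by_contig: dict[str, list[RefLocus]] = defaultdict(list)
    for locus in reference_erv_loci:
        by_contig[locus.contig].append(locus)
    for rows in by_contig.values():
        rows.sort(key=lambda l: l.start)
    starts = {c: [l.start for l in rows] for c, rows in by_contig.items()}

    spanning: Counter = Counter()
    split: Counter = Counter()
    inside: Counter = Counter()
    read_len_seen = 150

    for read in _iter_sam(sam):
        if read.is_unmapped or read.reference_name is None:
            continue
        rname = read.reference_name
        if rname not in by_contig or rname.startswith(LIB_PREFIX):
            continue
        if read.query_length:
            read_len_seen = max(read_len_seen, read.query_length)
        rstart, rend = read.reference_start, read.reference_end
        loci = by_contig[rname]
        pos_list = starts[rname]
        lo = bisect_left(pos_list, rstart - insert_mean - 8 * insert_sd - 20000)
        hi = bisect_right(pos_list, rend + slack)
        for locus in loci[max(lo, 0) : hi]:
            S, E = locus.start, locus.end
            elem_len = E - S
            # spanning pair (count once, from the forward mate)
            if (
                read.is_paired
                and not read.is_reverse
                and read.template_length > 0
                and read.next_reference_name == rname
                and rend <= S + max_tsd + slack
                and read.next_reference_start >= E - max_tsd - slack
                and abs(read.template_length - (insert_mean + elem_len))
                <= 4 * insert_sd
            ):
                spanning[locus.locus_id] += 1
            # split reads clipped at the outer boundaries
            cig = read.cigartuples or []
            seq = read.query_sequence or ""
            if cig and seq:
                if (
                    cig[-1][0] == 4
                    and cig[-1][1] >= min_clip
                    and S - slack <= rend <= S + max_tsd + slack
                ):
                    tail = seq[len(seq) - cig[-1][1] :]
                    if _flank_ok(
                        tail, reference, rname, E, "after", flank_match_identity
                    ):
                        split[locus.locus_id] += 1
                if (
                    cig[0][0] == 4
                    and cig[0][1] >= min_clip
                    and E - max_tsd - slack <= rstart <= E + slack
                ):
                    tail = seq[: cig[0][1]]
                    if _flank_ok(
                        tail, reference, rname, S, "before", flank_match_identity
                    ):
                        split[locus.locus_id] += 1
            # concordant coverage inside the element (zygosity evidence)
            if (
                read.is_proper_pair
                and not cig_has_clip(cig, min_clip)
                and rstart >= S + max_tsd
                and rend <= E - max_tsd
            ):
                inside[locus.locus_id] += 1

    calls: list[AbsenceCall] = []
    for contig in sorted(by_contig):
        for locus in by_contig[contig]:
            n_span = spanning[locus.locus_id]
            n_split = split[locus.locus_id]
            if n_span + n_split < policy.min_reads:
                continue
            inner = max(locus.end - locus.start - 2 * max_tsd, 1)
            if policy.coverage:
                het_expect = policy.coverage / 2 * inner / read_len_seen
                thr = max(3.0, 0.2 * het_expect)
            else:
                thr = 5.0
            hint = "het" if inside[locus.locus_id] >= thr else "hom_absent"
            calls.append(
                AbsenceCall(
                    locus_id=locus.locus_id,
                    contig=contig,
                    start=locus.start,
                    end=locus.end,
                    spanning_support=n_span,
                    split_support=n_split,
                    zygosity_hint=hint,
                )
            )
    return calls


def cig_has_clip(cig, min_clip: int) -> bool:
    return bool(cig) and (
        (cig[0][0] == 4 and cig[0][1] >= min_clip)
        or (cig[-1][0] == 4 and cig[-1][1] >= min_clip)
    )


def _flank_ok(
    tail: str,
    reference: dict[str, str] | None,
    contig: str,
    boundary: int,
    where: str,
    min_identity: float,
) -> bool:
    if reference is None:
        return True
    seq = reference.get(contig)
    if seq is None:
        return True
    if where == "after":
        target = seq[boundary : boundary + len(tail) + 200]
    else:
        target = seq[max(0, boundary - len(tail) - 200) : boundary]
    ident, matches, _s, _loc = infix_match(tail, target, both_strands=False)
    return ident >= min_identity and matches >= 10


# ---------------------------------------------------------------------------
# soft-clip rescue around known cross-sample loci


@dataclass(frozen=True)
class RescueResult:
    locus_id: str
    clip_support: int
    pair_support: int
    present: bool


def rescue_softclips(
    evidence: AlignmentEvidence,
    candidate_loci: Sequence,
    policy: FilterPolicy,
    window: int = 300,
    match_lineage: bool = True,
) -> dict[str, RescueResult]:
    """Re-count LTR-matching soft-clips around known candidate loci.

    For each candidate locus (an object with locus_id/contig/start/end and
    lineage attributes), clips and discordant anchors within ``window`` bp
    of the locus are pooled; the locus is present for this individual when
    the pooled support reaches ``policy.min_reads``.  Clips in ``evidence``
    have already passed the length, entropy and LTR-identity tests, so the
    re-test is a positional and lineage gate.  Idempotent: rescuing an
    already-present locus leaves it present.
    """
    out: dict[str, RescueResult] = {}
    for locus in candidate_loci:
        lid = getattr(locus, "locus_id", None) or f"{locus.contig}:{locus.start}"
        lo = locus.start - window
        hi = locus.end + window
        clip_names = set()
        pair_names = set()
        for c in evidence.softclips:
            if c.contig != locus.contig or not (lo <= c.pos <= hi):
                continue
            if match_lineage and getattr(locus, "lineage", None) and c.lineage != locus.lineage:
                continue
            clip_names.add((c.read_name, c.side))
        for p in evidence.discordant:
            if p.contig != locus.contig or not (lo <= p.anchor_pos <= hi):
                continue
            if match_lineage and getattr(locus, "lineage", None) and p.lineage != locus.lineage:
                continue
            pair_names.add(p.read_name)
        support = len(clip_names) + len(pair_names)
        out[lid] = RescueResult(
            locus_id=lid,
            clip_support=len(clip_names),
            pair_support=len(pair_names),
            present=support >= policy.min_reads,
        )
    return out


# ---------------------------------------------------------------------------
# tabular output


def calls_to_frame(
    insertions: Sequence[InsertionCall], absences: Sequence[AbsenceCall] = ()
) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for c in insertions:
        rows.append(
            {
                "type": "INS",
                "contig": c.contig,
                "start": c.start,
                "end": c.end,
                "lineage": c.lineage,
                "tier": c.tier,
                "pair_support": c.pair_support,
                "clip5_support": c.clip5_support,
                "clip3_support": c.clip3_support,
                "tsd_len_est": c.tsd_len_est,
                "zygosity_hint": "",
            }
        )
    for a in absences:
        rows.append(
            {
                "type": "ABS",
                "contig": a.contig,
                "start": a.start,
                "end": a.end,
                "lineage": "",
                "tier": "",
                "pair_support": a.spanning_support,
                "clip5_support": a.split_support,
                "clip3_support": 0,
                "tsd_len_est": 0,
                "zygosity_hint": a.zygosity_hint,
            }
        )
    return pd.DataFrame(rows)
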