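"""Caller: evidence extraction, tiered insertion calls, absences, rescue."""

import numpy as np
import pysam
import pytest

from conftest import full_library
from erv_census.callerv import (
    AlignmentEvidence,
    DiscordantPair,
    FilterPolicy,
    RefLocus,
    SoftClip,
    call_nonreference_insertions,
    call_reference_absences,
    extract_evidence,
    rescue_softclips,
)


def _write_sam(path, rows, contigs):
    """rows: (name, flag, rname, pos0, cigar, rnext, pnext, tlen, seq)."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": n} for c, n in contigs],
        }
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for name, flag, rname, pos, cigar, rnext, pnext, tlen, seq in rows:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.flag = flag
            a.reference_name = rname
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            if rnext is not None:
                a.next_reference_name = rnext
                a.next_reference_start = pnext
            a.template_length = tlen
            a.query_sequence = seq
            out.write(a)


# ---------------------------------------------------------------------------
# evidence extraction


def test_ltr_matching_clip_retained_with_lineage(template, tmp_path):
    lib = {"ERVlib_beta": template.full_seq, "ERVlib_beta_LTR": template.ltr}
    rng = np.random.default_rng(0)
    host = "".join(rng.choice(list("ACGT"), 200))
    clip = template.ltr[:120]
    rows = [
        ("r1", 0x1 | 0x40, "chr1", 100, "30M120S", "chr1", 300, 350, host[:30] + clip),
        ("r2", 0x1 | 0x40, "chr1", 150, "120S30M", "chr1", 300, 200, template.ltr[-120:] + host[30:60]),
        ("r3", 0x1 | 0x40, "chr1", 200, "30M120S", "chr1", 400, 350, host[60:90] + "A" * 120),
    ]
    path = tmp_path / "t.sam"
    _write_sam(path, rows, [("chr1", 10_000), ("ERVlib_beta", len(template.full_seq))])
    ev = extract_evidence(path, lib)
    assert len(ev.softclips) == 2  # homopolymer clip removed by entropy filter
    sides = {(c.side, c.lineage) for c in ev.softclips}
    assert sides == {("right", "beta"), ("left", "beta")}
    assert ev.softclips[0].pos in (130, 150)


def test_unsorted_sam_rejected(template, tmp_path):
    rows = [
        ("a", 0x1, "chr1", 500, "50M", None, 0, 0, "A" * 50),
        ("b", 0x1, "chr1", 100, "50M", None, 0, 0, "A" * 50),
    ]
    path = tmp_path / "u.sam"
    _write_sam(path, rows, [("chr1", 10_000)])
    with pytest.raises(ValueError, match="sorted"):
        extract_evidence(path, {"ERVlib_x_LTR": template.ltr})


def test_discordant_mate_to_library_recorded(template, tmp_path):
    rows = [
        ("p1", 0x1 | 0x40, "chr1", 100, "150M", "ERVlib_beta", 10, 0, "A" * 150),
    ]
    path = tmp_path / "d.sam"
    _write_sam(path, rows, [("chr1", 10_000), ("ERVlib_beta", 9000)])
    ev = extract_evidence(path, {"ERVlib_beta_LTR": template.ltr})
    assert len(ev.discordant) == 1
    assert ev.discordant[0].lineage == "beta"
    assert ev.discordant[0].anchor_pos == 250  # junction side of a forward read


def test_no_evidence_from_library_contigs(caller_sim):
    ev = extract_evidence(caller_sim["paths"]["HC1"], full_library(caller_sim["sim"]))
    assert all(not c.contig.startswith("ERVlib_") for c in ev.softclips)
    assert all(not p.contig.startswith("ERVlib_") for p in ev.discordant)


# ---------------------------------------------------------------------------
# insertion calling thresholds


def _cluster(pos, n5, n3, npair, tsd=6, lineage="beta", contig="c"):
    clips = [
        SoftClip(contig, pos + tsd, "right", "X", lineage, f"r5_{i}_{pos}")
        for i in range(n5)
    ] + [
        SoftClip(contig, pos, "left", "X", lineage, f"r3_{i}_{pos}")
        for i in range(n3)
    ]
    pairs = [
        DiscordantPair(contig, pos - 50, lineage, f"p_{i}_{pos}")
        for i in range(npair)
    ]
    return clips, pairs


def test_stringent_call_with_tsd_estimate():
    clips, pairs = _cluster(1000, n5=3, n3=3, npair=4)
    ev = AlignmentEvidence(clips, pairs)
    policy = FilterPolicy(mode="stringent", min_reads=2, coverage=None)
    calls = call_nonreference_insertions(ev, policy)
    assert len(calls) == 1
    c = calls[0]
    assert c.tier == "stringent"
    assert (c.start, c.end) == (1000, 1006)
    assert c.tsd_len_est == 6
    assert (c.clip5_support, c.clip3_support, c.pair_support) == (3, 3, 4)


def test_pair_support_thresholds_follow_policy():
    clips, pairs = _cluster(1000, n5=1, n3=0, npair=1)
    ev = AlignmentEvidence(clips, pairs)
    stringent = FilterPolicy(mode="stringent", min_reads=2)
    relaxed = FilterPolicy(mode="relaxed", min_reads=2)
    assert call_nonreference_insertions(ev, stringent) == []
    # one clip plus one pair: pair support 1 < 2, still no relaxed call
    assert call_nonreference_insertions(ev, relaxed) == []
    clips2, pairs2 = _cluster(1000, n5=0, n3=0, npair=2)
    calls = call_nonreference_insertions(AlignmentEvidence(clips2, pairs2), relaxed)
    assert len(calls) == 1 and calls[0].tier == "relaxed"
    assert call_nonreference_insertions(AlignmentEvidence(clips2, pairs2), stringent) == []


def test_distant_clusters_yield_separate_calls():
    c1, p1 = _cluster(1000, 2, 2, 3)
    c2, p2 = _cluster(2000, 2, 2, 3)
    ev = AlignmentEvidence(c1 + c2, p1 + p2)
    calls = call_nonreference_insertions(
        ev, FilterPolicy(mode="relaxed", min_reads=2)
    )
    assert len(calls) == 2
    assert calls[0].start == 1000 and calls[1].start == 2000


def test_stringent_calls_subset_of_relaxed():
    """Filter monotonicity over randomised evidence."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        clips, pairs = [], []
        for pos in rng.integers(0, 50_000, size=8):
            c, p = _cluster(
                int(pos),
                int(rng.integers(0, 5)),
                int(rng.integers(0, 5)),
                int(rng.integers(0, 9)),
            )
            clips += c
            pairs += p
        ev = AlignmentEvidence(clips, pairs)
        s = call_nonreference_insertions(
            ev, FilterPolicy(mode="stringent", min_reads=5, coverage=40)
        )
        r = call_nonreference_insertions(
            ev, FilterPolicy(mode="relaxed", min_reads=5, coverage=40)
        )
        assert {(c.contig, c.start) for c in s} <= {(c.contig, c.start) for c in r}


# ---------------------------------------------------------------------------
# absence calling against simulated truth


def test_absence_calls_track_truth_genotypes(caller_sim):
    sim = caller_sim["sim"]
    ref_loci = [
        RefLocus(l.locus_id, l.contig, *l.bed_interval, l.lineage)
        for l in sim.loci
        if l.in_reference
    ]
    assert ref_loci
    policy = FilterPolicy(mode="relaxed", min_reads=5, coverage=40.0)
    calls = {
        a.locus_id: a
        for a in call_reference_absences(
            caller_sim["paths"]["HC1"], ref_loci, policy, reference=sim.reference
        )
    }
    for locus in ref_loci:
        g = sim.truth.genotypes[(locus.locus_id, "HC1")]
        if g == 2:
            assert locus.locus_id not in calls
        elif g == 1:
            assert calls[locus.locus_id].zygosity_hint == "het"
        else:
            assert calls[locus.locus_id].zygosity_hint == "hom_absent"


def test_insertion_recall_precision_on_hc_fixture(caller_sim):
    sim = caller_sim["sim"]
    ev = extract_evidence(caller_sim["paths"]["HC1"], full_library(sim))
    calls = call_nonreference_insertions(ev, FilterPolicy.hc(coverage=40.0))
    truth = [
        l.ref_anchor
        for l in sim.loci
        if not l.in_reference and sim.truth.genotypes[(l.locus_id, "HC1")] >= 1
    ]
    matched = sum(
        1 for c in calls if any(abs(c.start - p) <= 25 for p in truth)
    )
    assert truth
    assert matched / len(truth) >= 0.9
    assert matched / len(calls) >= 0.9


# ---------------------------------------------------------------------------
# soft-clip rescue


def test_rescue_pools_nearby_clips_to_presence():
    lineage = "beta"
    locus = RefLocus("L1", "c", 1000, 1006, lineage)
    ev = AlignmentEvidence(
        [
            SoftClip("c", 1003, "right", "X", lineage, "a"),
            SoftClip("c", 1043, "left", "X", lineage, "b"),
        ],
        [],
    )
    res = rescue_softclips(ev, [locus], FilterPolicy(mode="relaxed", min_reads=2))
    assert res["L1"].present and res["L1"].clip_support == 2


def test_rescue_without_window_clips_changes_nothing():
    locus = RefLocus("L1", "c", 1000, 1006, "beta")
    ev = AlignmentEvidence([SoftClip("c", 5000, "right", "X", "beta", "a")], [])
    res = rescue_softclips(ev, [locus], FilterPolicy(mode="relaxed", min_reads=2))
    assert res["L1"].clip_support == 0 and not res["L1"].present


def test_rescue_is_idempotent_on_present_loci():
    locus = RefLocus("L1", "c", 1000, 1006, "beta")
    ev = AlignmentEvidence(
        [SoftClip("c", 1000 + i, "right", "X", "beta", f"r{i}") for i in range(4)],
        [DiscordantPair("c", 950, "beta", f"p{i}") for i in range(3)],
    )
    policy = FilterPolicy(mode="relaxed", min_reads=2)
    first = rescue_softclips(ev, [locus], policy)
    second = rescue_softclips(ev, [locus], policy)
    assert first == second
    assert first["L1"].present
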