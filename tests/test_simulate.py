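"""Simulator: molecular clock, cohort planting, and alignment emulation."""

import numpy as np
import pytest

from erv_census._seq import hamming_fraction, random_dna
from erv_census.simulate import (
    AlleleFreqDist,
    LineageSpec,
    MU_MID,
    ReadSimConfig,
    build_haplotype,
    evolve_copy,
    plant_cohort,
    pol_frameshift_count,
    simulate_alignments,
)
from erv_census.simulate import _emulate_read  # junction arithmetic contract


def _one_lineage(n_loci, age_d=0.006, freq=("beta", 2.0, 2.0), ref_fraction=0.0):
    kind, a, b = (freq if isinstance(freq, tuple) else ("fixed", 0, 0))
    dist = (
        AlleleFreqDist("fixed", value=freq)
        if isinstance(freq, float)
        else AlleleFreqDist(kind, a=a, b=b)
    )
    return LineageSpec(
        name="phaCin-beta",
        age_years=age_d / (2 * MU_MID),
        mu=MU_MID,
        n_loci=n_loci,
        ref_fraction=ref_fraction,
        allele_freq=dist,
        indel_rate=0.0,
    )


# ---------------------------------------------------------------------------
# evolve_copy


def test_age_zero_copy_is_identical_to_template(template):
    copy = evolve_copy(template, 0.0, 3e-9, 3e-10, seed=5)
    assert copy.ltr5 == copy.ltr3 == template.ltr
    assert copy.internal == template.internal
    assert copy.events == ()


def test_negative_rates_rejected(template):
    with pytest.raises(ValueError):
        evolve_copy(template, -1.0, 1e-9, 0, seed=0)
    with pytest.raises(ValueError):
        evolve_copy(template, 1.0, -1e-9, 0, seed=0)


def test_ltr_pair_divergence_matches_clock_expectation(small_template):
    """Mean 5'-3' LTR divergence over replicates approaches 2*mu*age.

    With per-site hit probability p per LTR, two independently evolved
    copies differ per site with probability q = 2p(1-p) + (2/3)p^2.
    """
    p = 3e-3  # mu * age per site; pair expectation ~0.006
    q = 2 * p * (1 - p) + (2 / 3) * p * p
    rng = np.random.default_rng(8)
    divs = [
        hamming_fraction(c.ltr5, c.ltr3)
        for c in (
            evolve_copy(small_template, 1.0, p, 0.0, seed=rng) for _ in range(400)
        )
    ]
    mean = np.mean(divs)
    se = np.std(divs, ddof=1) / np.sqrt(len(divs))
    assert abs(mean - q) < 3 * se + 1e-6


def test_pol_indels_follow_poisson_closed_form(small_template):
    """With one indel expected in pol, ~63% of replicates log >=1 pol indel
    and ~49% log >=1 frameshift (lengths 1-3, so 2/3 disrupt the frame)."""
    a, b = small_template.gene_map["pol"]
    pol_len = b - a
    rate = 1.0 / pol_len  # indel_rate * age
    rng = np.random.default_rng(9)
    n = 500
    any_indel = 0
    any_fs = 0
    for _ in range(n):
        c = evolve_copy(small_template, 1.0, 0.0, rate, seed=rng)
        pol_indels = [
            e
            for e in c.events
            if e.region == "internal"
            and (
                (e.kind == "ins" and a <= e.pos < b)
                or (e.kind == "del" and e.pos < b and e.pos + e.length > a)
            )
        ]
        if pol_indels:
            any_indel += 1
        if pol_frameshift_count(c, small_template) >= 1:
            any_fs += 1
    p_indel = 1 - np.exp(-1)
    p_fs = 1 - np.exp(-2 / 3)
    for observed, expected in ((any_indel / n, p_indel), (any_fs / n, p_fs)):
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3.5 * se


# ---------------------------------------------------------------------------
# plant_cohort


def test_zero_loci_leaves_reference_untouched():
    rng = np.random.default_rng(1)
    host = {"c": random_dna(rng, 20_000)}
    sim = plant_cohort(host, [_one_lineage(0)], [("A", 10.0)], seed=3)
    assert sim.reference == host
    assert sim.loci == []


def test_allele_frequency_one_forces_genotype_two():
    rng = np.random.default_rng(2)
    host = {"c": random_dna(rng, 30_000)}
    sim = plant_cohort(
        host, [_one_lineage(1, freq=1.0)], [("A", 1.0), ("B", 1.0), ("C", 1.0)],
        seed=4,
    )
    (locus,) = sim.loci
    assert all(
        sim.truth.genotypes[(locus.locus_id, ind)] == 2 for ind in "ABC"
    )


def test_genotypes_match_binomial_sampling():
    """Aggregated genotype counts across cohorts fit Binomial(2, f)."""
    from scipy import stats

    f = 0.3
    counts = np.zeros(3)
    host = {"c": random_dna(np.random.default_rng(3), 5_000)}
    for seed in range(30):
        sim = plant_cohort(
            host,
            [_one_lineage(10, freq=f)],
            [(f"I{i}", 1.0) for i in range(11)],
            seed=seed,
            sequences=False,
            edge_margin=10,
        )
        for g in sim.truth.genotypes.values():
            counts[g] += 1
    expected = np.array([(1 - f) ** 2, 2 * f * (1 - f), f * f]) * counts.sum()
    assert stats.chisquare(counts, expected).pvalue > 1e-3


def test_spacing_infeasible_raises():
    rng = np.random.default_rng(4)
    host = {"c": random_dna(rng, 12_000)}
    with pytest.raises(RuntimeError, match="spacing"):
        plant_cohort(host, [_one_lineage(50)], [("A", 1.0)], seed=5)


def test_truth_bed_round_trip():
    """Reference slice at a truth interval reproduces TSD + copy + TSD."""
    rng = np.random.default_rng(6)
    host = {"c": random_dna(rng, 120_000)}
    sim = plant_cohort(
        host, [_one_lineage(4, ref_fraction=0.5)], [("A", 1.0)], seed=7
    )
    assert any(l.in_reference for l in sim.loci)
    for locus in sim.loci:
        a, b = locus.bed_interval
        if locus.in_reference:
            assert (
                sim.reference[locus.contig][a:b]
                == locus.tsd_seq + locus.copy_seq + locus.tsd_seq
            )
        else:
            assert sim.reference[locus.contig][a:b] == locus.tsd_seq


# ---------------------------------------------------------------------------
# alignment emulation


def _single_locus_sim(seed=8, freq=1.0):
    rng = np.random.default_rng(seed)
    host = {"c": random_dna(rng, 40_000)}
    return plant_cohort(host, [_one_lineage(1, freq=freq)], [("A", 20.0)], seed=seed)


def test_junction_read_soft_clip_arithmetic():
    """A read with 30 host bases before a non-reference junction gets 30M120S."""
    sim = _single_locus_sim()
    (locus,) = sim.loci
    hapseq, segs = build_haplotype(sim, "A", 0, "c")
    elem = next(s for s in segs if s.kind == "elem")
    j = elem.hap_start  # hap coordinate of the 5' junction
    s, e = j - 30, j - 30 + 150
    read = _emulate_read(
        sim, "c", segs, [g.hap_start for g in segs], hapseq[s:e], s, e, False, s, 20
    )
    assert read.rname == "c"
    assert read.cigar == [(0, 30), (4, 120)]
    assert read.pos == locus.ref_anchor + locus.tsd_len - 30
    # mirror read crossing the 3' junction: 120 element bases then host
    s2, e2 = elem.hap_end - 120, elem.hap_end - 120 + 150
    read2 = _emulate_read(
        sim, "c", segs, [g.hap_start for g in segs], hapseq[s2:e2], s2, e2, False,
        s2, 20,
    )
    assert read2.cigar == [(4, 120), (0, 30)]
    assert read2.pos == locus.ref_anchor


def test_null_genome_yields_only_concordant_full_matches():
    rng = np.random.default_rng(10)
    host = {"c": random_dna(rng, 60_000)}
    sim = plant_cohort(host, [_one_lineage(0)], [("A", 10.0)], seed=11)
    cfg = ReadSimConfig(seed=1, error_rate=0.0)
    records = simulate_alignments(sim, "A", cfg)
    assert records
    for rname, pos, name, flag, cigar, rnext, pnext, tlen, seq in records:
        assert len(cigar) == 1 and cigar[0][0] == 0  # full match, no clips
        assert rname == "c" and rnext == "c"


def test_mean_depth_tracks_requested_coverage():
    rng = np.random.default_rng(12)
    host = {"c": random_dna(rng, 100_000)}
    sim = plant_cohort(host, [_one_lineage(0)], [("A", 30.0)], seed=13)
    depths = []
    for seed in range(5):
        cfg = ReadSimConfig(seed=seed, error_rate=0.0)
        records = simulate_alignments(sim, "A", cfg)
        aligned = sum(
            sum(n for op, n in cigar if op == 0)
            for _, _, _, _, cigar, _, _, _, _ in records
        )
        depths.append(aligned / len(host["c"]))
    assert abs(np.mean(depths) - 30.0) / 30.0 < 0.05


def test_same_seed_reproduces_alignments_byte_for_byte():
    sim = _single_locus_sim(freq=0.5)
    cfg = ReadSimConfig(seed=42)
    a = simulate_alignments(sim, "A", cfg)
    b = simulate_alignments(sim, "A", cfg)
    c = simulate_alignments(sim, "A", ReadSimConfig(seed=43))
    assert a == b
    assert a != c


def test_coverage_must_be_positive():
    sim = _single_locus_sim()
    sim.truth.individuals[0] = ("A", 0.0)
    with pytest.raises(ValueError):
        simulate_alignments(sim, "A", ReadSimConfig(seed=1))
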