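"""Synthetic study generator: proviruses, cohorts, and read alignments.

This module builds the full synthetic study that the rest of the package
analyses: a host reference genome carrying planted endogenous retrovirus
(ERV) proviruses from several lineages of different ages, a cohort of
diploid individuals polymorphic for those insertions, and per-individual
paired-end alignments in SAM format that carry the breakpoint signatures a
mobile-element caller consumes (soft-clips at insertion junctions,
discordant host/library mate pairs, and stretched inserts plus split reads
at reference loci absent from an individual).

Alignment emulation replaces a production mapper: read placement is
truth-guided, with CIGARs derived from junction arithmetic.  This keeps the
evidence classes exact and the whole study deterministic under a single
seed.

Coordinate conventions
----------------------
All internal and BED coordinates are 0-based half-open; SAM output is
1-based per the standard (handled by pysam).  An insertion point ``pos`` is
the first base of the target site duplication (TSD) in the pre-insertion
sequence; the planted block reads ``TSD + 5'LTR..3'LTR + TSD``.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pysam

from ._seq import array_to_seq, random_dna, revcomp, seq_to_array, write_fasta

STOP_CODONS = {"TAA", "TAG", "TGA"}
LIB_PREFIX = "ERVlib_"

__all__ = [
    "ProvirusTemplate",
    "MutationEvent",
    "EvolvedCopy",
    "AlleleFreqDist",
    "LineageSpec",
    "PlantedLocus",
    "CohortTruth",
    "ReadSimConfig",
    "SimulatedCohort",
    "make_template",
    "evolve_copy",
    "pol_frameshift_count",
    "pol_stop_count",
    "default_lineages",
    "plant_cohort",
    "simulate_alignments",
    "write_individual_sam",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# provirus template


@dataclass(frozen=True)
class ProvirusTemplate:
    """Ancestral full-length provirus: LTR + internal region + LTR.

    ``gene_map`` holds 0-based half-open sub-intervals of ``internal`` for
    gag, pro, pol and env, in that order and disjoint.  Each gene is a
    single open reading frame in the template (ATG ... stop), so premature
    stops and frameshifts in evolved copies are unambiguously mutations.
    """

    ltr: str
    internal: str
    gene_map: dict[str, tuple[int, int]]
    name: str = "provirus"

    def __post_init__(self):
        order = ["gag", "pro", "pol", "env"]
        prev_end = 0
        for g in order:
            a, b = self.gene_map[g]
            if not (prev_end <= a < b <= len(self.internal)):
                raise ValueError(f"gene {g} interval out of order or range")
            prev_end = b

    @property
    def ltr_len(self) -> int:
        return len(self.ltr)

    @property
    def full_seq(self) -> str:
        return self.ltr + self.internal + self.ltr

    @property
    def length(self) -> int:
        return 2 * len(self.ltr) + len(self.internal)


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + stop; length 3*(n_codons+2)."""
    codons = ["ATG"]
    while len(codons) < n_codons + 1:
        c = random_dna(rng, 3)
        if c not in STOP_CODONS and c != "ATG":
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def make_template(
    seed,
    ltr_len: int = 500,
    gene_codons: dict[str, int] | None = None,
    spacer: int = 90,
    leader: int = 180,
    name: str = "provirus",
) -> ProvirusTemplate:
    """Generate a random provirus template with canonical gene order.

    Default gene sizes give a full-length element of roughly 8.5 kb,
    matching a typical betaretroviral provirus.
    """
    rng = _as_rng(seed)
    if gene_codons is None:
        gene_codons = {"gag": 490, "pro": 290, "pol": 890, "env": 590}
    ltr = random_dna(rng, ltr_len)
    parts: list[str] = [random_dna(rng, leader)]
    gene_map: dict[str, tuple[int, int]] = {}
    cursor = leader
    for g in ("gag", "pro", "pol", "env"):
        orf = _random_orf(rng, gene_codons[g])
        gene_map[g] = (cursor, cursor + len(orf))
        parts.append(orf)
        cursor += len(orf)
        sp = random_dna(rng, spacer)
        parts.append(sp)
        cursor += spacer
    internal = "".join(parts)
    return ProvirusTemplate(ltr=ltr, internal=internal, gene_map=gene_map, name=name)


# ---------------------------------------------------------------------------
# molecular evolution of a single copy


@dataclass(frozen=True)
class MutationEvent:
    """One mutation in an evolved copy, in template-region coordinates."""

    region: str  # 'ltr5' | 'internal' | 'ltr3'
    kind: str  # 'sub' | 'ins' | 'del'
    pos: int
    length: int
    ref: str
    alt: str


@dataclass(frozen=True)
class EvolvedCopy:
    ltr5: str
    internal: str
    ltr3: str
    events: tuple[MutationEvent, ...]
    age_years: float

    @property
    def seq(self) -> str:
        return self.ltr5 + self.internal + self.ltr3


def _mutate_region(
    region: str, seq: str, p_sub: float, exp_indels: float, rng: np.random.Generator
) -> tuple[str, list[MutationEvent]]:
    events: list[MutationEvent] = []
    arr = seq_to_array(seq)
    n = len(arr)
    # substitutions: single-hit Jukes-Cantor regime, each site hit with
    # probability p_sub and replaced by one of the three other bases
    mask = rng.random(n) < p_sub
    idx = np.nonzero(mask)[0]
    if idx.size:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        lut = {65: 0, 67: 1, 71: 2, 84: 3}
        cur = np.array([lut[b] for b in arr[idx]])
        new = (cur + rng.integers(1, 4, size=idx.size)) % 4
        for i, pos in enumerate(idx):
            ref = chr(arr[pos])
            alt = "ACGT"[new[i]]
            events.append(MutationEvent(region, "sub", int(pos), 1, ref, alt))
        arr[idx] = bases[new]
    out = list(array_to_seq(arr))
    # indels, length 1-3, positions in template coordinates, applied
    # right-to-left so recorded coordinates stay template-relative
    n_indel = rng.poisson(exp_indels)
    if n_indel:
        positions = sorted(rng.integers(0, n, size=n_indel).tolist(), reverse=True)
        for pos in positions:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion
                length = min(length, n - pos)
                if length <= 0:
                    continue
                ref = seq[pos : pos + length]
                del out[pos : pos + length]
                events.append(MutationEvent(region, "del", pos, length, ref, ""))
            else:
                ins = random_dna(rng, length)
                out[pos:pos] = list(ins)
                events.append(MutationEvent(region, "ins", pos, length, "", ins))
    events.sort(key=lambda e: (e.pos, e.kind))
    return "".join(out), events


def evolve_copy(
    template: ProvirusTemplate,
    age_years: float,
    mu: float,
    indel_rate: float = 0.0,
    seed=None,
) -> EvolvedCopy:
    """Evolve one proviral copy for ``age_years`` under a molecular clock.

    Each site of each LTR and of the internal region is substituted
    independently with probability ``mu * age_years`` (the two LTR copies
    evolve independently, which is what makes the 5'-3' LTR divergence a
    clock with expectation ``2 * mu * age``).  Indels of length 1-3 are
    placed at ``indel_rate * age_years`` per site and drive frameshifts.
    """
    if age_years < 0:
        raise ValueError("age_years must be >= 0")
    if mu < 0 or indel_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = _as_rng(seed)
    p_sub = min(mu * age_years, 0.75)
    all_events: list[MutationEvent] = []
    out: dict[str, str] = {}
    for region, seq in (
        ("ltr5", template.ltr),
        ("internal", template.internal),
        ("ltr3", template.ltr),
    ):
        mutated, events = _mutate_region(
            region, seq, p_sub, indel_rate * age_years * len(seq), rng
        )
        out[region] = mutated
        all_events.extend(events)
    return EvolvedCopy(
        ltr5=out["ltr5"],
        internal=out["internal"],
        ltr3=out["ltr3"],
        events=tuple(all_events),
        age_years=age_years,
    )


def pol_frameshift_count(copy: EvolvedCopy, template: ProvirusTemplate) -> int:
    """Frame-disrupting indels recorded in the pol gene by the mutation log."""
    a, b = template.gene_map["pol"]
    n = 0
    for e in copy.events:
        if e.region != "internal" or e.kind == "sub" or e.length % 3 == 0:
            continue
        if e.kind == "ins" and a <= e.pos < b:
            n += 1
        elif e.kind == "del" and e.pos < b and e.pos + e.length > a:
            n += 1
    return n


def pol_stop_count(copy: EvolvedCopy, template: ProvirusTemplate) -> int:
    """Premature stops in pol created by logged substitutions (template frame)."""
    a, b = template.gene_map["pol"]
    seq = list(template.internal)
    for e in copy.events:
        if e.region == "internal" and e.kind == "sub":
            seq[e.pos] = e.alt
    mutated = "".join(seq[a:b])
    ref = template.internal[a:b]
    n = 0
    for i in range(0, len(ref) - 3, 3):  # exclude the terminal stop codon
        if mutated[i : i + 3] in STOP_CODONS and ref[i : i + 3] not in STOP_CODONS:
            n += 1
    return n


# ---------------------------------------------------------------------------
# lineages and cohorts


@dataclass(frozen=True)
class AlleleFreqDist:
    """Population allele-frequency distribution for loci of one lineage."""

    kind: str = "beta"  # 'beta' | 'fixed'
    a: float = 0.5
    b: float = 2.5
    value: float = 0.5

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return float(self.value)
        if self.kind == "beta":
            return float(rng.beta(self.a, self.b))
        raise ValueError(f"unknown allele_freq_dist kind {self.kind!r}")


@dataclass(frozen=True)
class LineageSpec:
    """One ERV expansion lineage: burst age, clock rate, and locus design.

    ``ref_fraction`` fixes the fraction of loci embedded in the reference
    assembly haplotype (chosen with probability proportional to allele
    frequency).  When None, assembly membership is emergent: each locus is
    in the assembly with probability equal to its allele frequency — the
    assembly being itself one sampled haplotype — which reproduces the
    lower assembly fractions of younger, lower-frequency expansions.
    """

    name: str
    age_years: float
    mu: float  # substitutions / site / year
    n_loci: int
    ref_fraction: float | None = None
    allele_freq: AlleleFreqDist = field(default_factory=AlleleFreqDist)
    indel_rate: float = 0.0  # indels / site / year

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.ref_fraction is not None and not 0 <= self.ref_fraction <= 1:
            raise ValueError("ref_fraction must lie in [0, 1]")
        if self.n_loci < 0:
            raise ValueError("n_loci must be >= 0")


# Reference clock interval used for dating throughout: human-to-mouse
# germline substitution rates.
MU_LOW = 2e-9
MU_HIGH = 4.5e-9
MU_MID = 3.0e-9


def default_lineages(scale: float = 1.0) -> list[LineageSpec]:
    """Three-lineage design: an old, an intermediate and a very young burst.

    Ages are set so the median 5'-3' LTR divergence (2 * mu * median copy
    age, copy ages drawn uniformly over the burst window) is about 2.2%,
    0.6% and ~0% respectively.  Allele-frequency distributions shift lower
    with youth (less time for drift), which makes locus sharing, carrier
    frequency and — through emergent assembly membership — the assembly
    fraction all decrease from the oldest to the youngest lineage.  Locus
    counts are population pool sizes chosen so that, at scale 1, the loci
    detectable in an 11-individual cohort number roughly 80 / 170 / 145
    for the three lineages.  ``scale`` multiplies pool sizes for
    desk-scale runs.
    """
    mk = lambda n: max(1, round(n * scale))
    return [
        LineageSpec(
            name="phaCin-beta-like",
            age_years=0.022 / (2 * MU_MID),
            mu=MU_MID,
            n_loci=mk(90),
            allele_freq=AlleleFreqDist("beta", a=1.2, b=2.5),
            indel_rate=MU_MID / 10,
        ),
        LineageSpec(
            name="phaCin-beta",
            age_years=0.006 / (2 * MU_MID),
            mu=MU_MID,
            n_loci=mk(320),
            allele_freq=AlleleFreqDist("beta", a=0.5, b=6.0),
            indel_rate=MU_MID / 10,
        ),
        LineageSpec(
            name="KoRV",
            age_years=25_000.0,
            mu=MU_MID,
            n_loci=mk(560),
            allele_freq=AlleleFreqDist("beta", a=0.3, b=16.0),
            indel_rate=MU_MID / 10,
        ),
    ]


def default_cohort() -> list[tuple[str, float]]:
    """3 high-coverage (~40x) and 8 low-coverage (~6x) individuals."""
    return [(f"HC{i}", 40.0) for i in range(1, 4)] + [
        (f"LC{i}", 6.0) for i in range(1, 9)
    ]


@dataclass(frozen=True)
class PlantedLocus:
    """A germline integration site with its planted, evolved copy."""

    locus_id: str
    contig: str
    pos: int  # host coords: first base of the TSD
    ref_anchor: int  # same point lifted to reference coords
    tsd_len: int
    tsd_seq: str
    strand: str
    lineage: str
    copy_age_years: float
    allele_freq: float
    in_reference: bool
    copy: EvolvedCopy
    copy_seq: str  # genome-forward orientation (revcomp for '-' strand)

    @property
    def bed_interval(self) -> tuple[int, int]:
        """Truth interval in reference coordinates.

        In-reference loci span TSD + element + TSD; non-reference loci span
        the (single) TSD at the insertion point.
        """
        if self.in_reference:
            return (
                self.ref_anchor,
                self.ref_anchor + 2 * self.tsd_len + len(self.copy_seq),
            )
        return (self.ref_anchor, self.ref_anchor + self.tsd_len)


@dataclass
class CohortTruth:
    individuals: list[tuple[str, float]]
    loci: list[PlantedLocus]
    genotypes: dict[tuple[str, str], int]  # (locus_id, individual) -> 0/1/2
    hap_carry: dict[tuple[str, str], tuple[bool, bool]]

    def coverage(self, individual: str) -> float:
        for name, cov in self.individuals:
            if name == individual:
                return cov
        raise KeyError(individual)


@dataclass(frozen=True)
class ReadSimConfig:
    read_len: int = 150
    insert_mean: int = 400
    insert_sd: int = 50
    error_rate: float = 0.002
    seed: int = 0
    min_anchor: int = 20  # bases of host match needed to anchor at a junction

    def __post_init__(self):
        if self.insert_mean < self.read_len:
            raise ValueError("insert_mean must be >= read_len")


@dataclass
class SimulatedCohort:
    """Everything plant_cohort produces: genomes, truth and ERV library."""

    host: dict[str, str]
    reference: dict[str, str]
    library: dict[str, str]  # SAM/FASTA library contigs (full elements)
    library_ltrs: dict[str, str]  # lineage -> LTR sequence
    templates: dict[str, ProvirusTemplate]
    lineages: list[LineageSpec]
    truth: CohortTruth
    seed: int

    @property
    def loci(self) -> list[PlantedLocus]:
        return self.truth.loci

    def loci_by_id(self) -> dict[str, PlantedLocus]:
        return {l.locus_id: l for l in self.loci}

    def lib_contig(self, lineage: str) -> str:
        return f"{LIB_PREFIX}{lineage}"

    # -- writers ----------------------------------------------------------
    def write_reference(self, path) -> None:
        write_fasta(path, self.reference, description=f"seed={self.seed}")

    def write_library(self, path) -> None:
        recs = dict(self.library)
        for lineage, ltr in self.library_ltrs.items():
            recs[f"{LIB_PREFIX}{lineage}_LTR"] = ltr
        write_fasta(path, recs, description=f"seed={self.seed}")

    def write_truth_bed(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed}\n")
            for locus in sorted(
                self.loci, key=lambda l: (l.contig, l.bed_interval[0])
            ):
                a, b = locus.bed_interval
                name = f"{locus.lineage}|{locus.locus_id}"
                if locus.in_reference:
                    name += "|ref"
                score = int(round(locus.allele_freq * 1000))
                fh.write(
                    f"{locus.contig}\t{a}\t{b}\t{name}\t{score}\t{locus.strand}\n"
                )

    def write_truth_genotypes(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed}\n")
            fh.write("locus_id\tindividual\tgenotype\n")
            for locus in self.loci:
                for ind, _ in self.truth.individuals:
                    g = self.truth.genotypes[(locus.locus_id, ind)]
                    fh.write(f"{locus.locus_id}\t{ind}\t{g}\n")


def plant_cohort(
    host_genome: dict[str, str],
    lineages: Sequence[LineageSpec],
    cohort: Sequence[tuple[str, float]],
    seed: int,
    tsd_range: tuple[int, int] = (4, 6),
    min_spacing: int | None = None,
    edge_margin: int = 2000,
    insert_mean: int = 400,
    templates: dict[str, ProvirusTemplate] | None = None,
    burst_window: bool = True,
    sequences: bool = True,
) -> SimulatedCohort:
    """Plant ERV loci from each lineage into a host genome and draw a cohort.

    Insertion points are drawn uniformly over contigs subject to a minimum
    spacing of ``2 * insert_mean`` (overlapping evidence clusters are out of
    the modelled regime).  ``ref_fraction`` of each lineage's loci are
    embedded in the reference assembly haplotype, chosen with probability
    proportional to allele frequency (the assembly is itself one sampled
    haplotype, so common loci are more likely to be in it).  Per-individual
    genotypes are binomial in the locus allele frequency.  Copy ages are
    drawn uniformly over (0, 2 * age_years] — a burst window centred on the
    lineage age — unless ``burst_window`` is false, in which case every copy
    has exactly the lineage age.

    With ``sequences=False`` the generator runs in population-only mode:
    loci, allele frequencies, assembly membership and genotypes are drawn
    exactly as usual, but no copy sequences are evolved and no sequence is
    inserted into the reference — a fast mode for population-scale
    Monte Carlo over cohort statistics.
    """
    rng = _as_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    if min_spacing is None:
        min_spacing = 2 * insert_mean
    contigs = sorted(host_genome)
    lengths = np.array([len(host_genome[c]) for c in contigs], dtype=float)
    if lengths.sum() <= 2 * edge_margin:
        raise ValueError("host genome too short for the requested edge margin")

    if templates is None:
        templates = {}
        for i, spec in enumerate(lineages):
            templates[spec.name] = make_template(
                np.random.SeedSequence(entropy=seed, spawn_key=(2, i)),
                name=spec.name,
            )

    # --- draw insertion points respecting spacing -------------------------
    taken: dict[str, list[int]] = {c: [] for c in contigs}
    placements: list[tuple[str, int, LineageSpec]] = []
    total_loci = sum(s.n_loci for s in lineages)
    max_attempts = 1000 * max(total_loci, 1)
    attempts = 0
    for spec in lineages:
        for _ in range(spec.n_loci):
            while True:
                attempts += 1
                if attempts > max_attempts:
                    raise RuntimeError(
                        "could not place all loci at the requested spacing; "
                        "use a longer host genome or fewer loci"
                    )
                ci = rng.choice(len(contigs), p=lengths / lengths.sum())
                contig = contigs[ci]
                L = len(host_genome[contig])
                if L < 2 * edge_margin + min_spacing:
                    continue
                pos = int(rng.integers(edge_margin, L - edge_margin))
                if not sequences or all(
                    abs(pos - q) > min_spacing for q in taken[contig]
                ):
                    taken[contig].append(pos)
                    placements.append((contig, pos, spec))
                    break

    # --- per-locus attributes --------------------------------------------
    tsd_lo, tsd_hi = tsd_range
    raw: list[dict] = []
    for contig, pos, spec in placements:
        tsd_len = int(rng.integers(tsd_lo, tsd_hi + 1))
        age = (
            float(rng.uniform(0.0, 2.0 * spec.age_years))
            if burst_window
            else spec.age_years
        )
        freq = min(max(spec.allele_freq.sample(rng), 1e-4), 1.0)
        strand = "+" if rng.random() < 0.5 else "-"
        if sequences:
            copy = evolve_copy(
                templates[spec.name], age, spec.mu, spec.indel_rate, rng
            )
            copy_seq = copy.seq if strand == "+" else revcomp(copy.seq)
        else:
            copy = EvolvedCopy("", "", "", (), age)
            copy_seq = ""
        raw.append(
            dict(
                contig=contig,
                pos=pos,
                tsd_len=tsd_len,
                tsd_seq=host_genome[contig][pos : pos + tsd_len],
                strand=strand,
                lineage=spec.name,
                copy_age_years=age,
                allele_freq=freq,
                copy=copy,
                copy_seq=copy_seq,
            )
        )

    # --- assembly membership per lineage ----------------------------------
    # fixed ref_fraction: frequency-weighted subset of the requested size;
    # emergent (None): Bernoulli(allele_freq), the assembly as one haplotype
    for spec in lineages:
        idx = [i for i, r in enumerate(raw) if r["lineage"] == spec.name]
        if spec.ref_fraction is None:
            for i in idx:
                raw[i]["in_reference"] = bool(
                    rng.random() < raw[i]["allele_freq"]
                )
            continue
        n_ref = round(spec.ref_fraction * len(idx))
        if n_ref:
            w = np.array([raw[i]["allele_freq"] for i in idx])
            chosen = rng.choice(idx, size=n_ref, replace=False, p=w / w.sum())
            chosen = set(int(i) for i in np.atleast_1d(chosen))
        else:
            chosen = set()
        for i in idx:
            raw[i]["in_reference"] = i in chosen

    # --- build the reference and lift coordinates -------------------------
    raw.sort(key=lambda r: (r["contig"], r["pos"]))
    reference: dict[str, str] = {}
    loci: list[PlantedLocus] = []
    counter = 0
    for contig in contigs:
        rows = [r for r in raw if r["contig"] == contig]
        parts: list[str] = []
        cursor = 0
        offset = 0
        hseq = host_genome[contig]
        for r in rows:
            counter += 1
            r["locus_id"] = f"L{counter:04d}"
            r["ref_anchor"] = r["pos"] + offset
            if r["in_reference"] and sequences:
                k = r["tsd_len"]
                # host up to and including the TSD, the element, then the
                # duplicated TSD; downstream host resumes after the original
                parts.append(hseq[cursor : r["pos"] + k])
                parts.append(r["copy_seq"])
                parts.append(r["tsd_seq"])
                cursor = r["pos"] + k
                offset += len(r["copy_seq"]) + k
            loci.append(
                PlantedLocus(
                    locus_id=r["locus_id"],
                    contig=contig,
                    pos=r["pos"],
                    ref_anchor=r["ref_anchor"],
                    tsd_len=r["tsd_len"],
                    tsd_seq=r["tsd_seq"],
                    strand=r["strand"],
                    lineage=r["lineage"],
                    copy_age_years=r["copy_age_years"],
                    allele_freq=r["allele_freq"],
                    in_reference=r["in_reference"],
                    copy=r["copy"],
                    copy_seq=r["copy_seq"],
                )
            )
        parts.append(hseq[cursor:])
        reference[contig] = "".join(parts)

    # --- genotypes ---------------------------------------------------------
    genotypes: dict[tuple[str, str], int] = {}
    hap_carry: dict[tuple[str, str], tuple[bool, bool]] = {}
    for locus in loci:
        for ind, _cov in cohort:
            g = int(rng.binomial(2, locus.allele_freq))
            genotypes[(locus.locus_id, ind)] = g
            if g == 2:
                carry = (True, True)
            elif g == 1:
                carry = (True, False) if rng.random() < 0.5 else (False, True)
            else:
                carry = (False, False)
            hap_carry[(locus.locus_id, ind)] = carry

    library = {f"{LIB_PREFIX}{s.name}": templates[s.name].full_seq for s in lineages}
    library_ltrs = {s.name: templates[s.name].ltr for s in lineages}
    truth = CohortTruth(
        individuals=list(cohort),
        loci=loci,
        genotypes=genotypes,
        hap_carry=hap_carry,
    )
    return SimulatedCohort(
        host=dict(host_genome),
        reference=reference,
        library=library,
        library_ltrs=library_ltrs,
        templates=templates,
        lineages=list(lineages),
        truth=truth,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# haplotypes and alignment emulation


@dataclass(frozen=True)
class _Segment:
    hap_start: int
    hap_end: int
    kind: str  # 'ref' | 'elem'
    ref_start: int = -1  # for 'ref'
    locus: PlantedLocus | None = None  # for 'elem'


def build_haplotype(
    sim: SimulatedCohort, individual: str, hap: int, contig: str
) -> tuple[str, list[_Segment]]:
    """Haplotype sequence plus a piecewise map back to reference coordinates.

    The map has two segment kinds: 'ref' segments place reads directly on
    the reference, 'elem' segments (non-reference proviral copies) place
    reads on the matching library contig.  Adjacent ref segments with
    contiguous mapping are merged, so reads landing in the duplicated TSD
    downstream of a non-reference insertion map seamlessly — exactly the
    double-coverage TSD signature.
    """
    ref = sim.reference[contig]
    events = []
    for locus in sim.loci:
        if locus.contig != contig:
            continue
        carried = sim.truth.hap_carry[(locus.locus_id, individual)][hap]
        if locus.in_reference and not carried:
            events.append(("del", locus))
        elif not locus.in_reference and carried:
            events.append(("ins", locus))
    events.sort(key=lambda e: e[1].ref_anchor)

    parts: list[str] = []
    segs: list[_Segment] = []
    cur = 0
    hap_pos = 0

    def add_ref(a: int, b: int) -> None:
        nonlocal hap_pos
        if b <= a:
            return
        if segs and segs[-1].kind == "ref" and (
            segs[-1].ref_start + (segs[-1].hap_end - segs[-1].hap_start) == a
        ):
            prev = segs.pop()
            segs.append(
                _Segment(prev.hap_start, prev.hap_end + (b - a), "ref", prev.ref_start)
            )
        else:
            segs.append(_Segment(hap_pos, hap_pos + (b - a), "ref", a))
        parts.append(ref[a:b])
        hap_pos += b - a

    for kind, locus in events:
        P = locus.ref_anchor
        k = locus.tsd_len
        if kind == "del":
            # empty allele keeps one TSD copy and skips element + TSD2
            add_ref(cur, P + k)
            cur = P + 2 * k + len(locus.copy_seq)
        else:
            add_ref(cur, P + k)
            segs.append(
                _Segment(hap_pos, hap_pos + len(locus.copy_seq), "elem", locus=locus)
            )
            parts.append(locus.copy_seq)
            hap_pos += len(locus.copy_seq)
            cur = P  # re-emit the TSD: duplication at the insertion site
    add_ref(cur, len(ref))
    return "".join(parts), segs


@dataclass
class _RawRead:
    rname: str
    pos: int  # 0-based leftmost mapped position
    cigar: list[tuple[int, int]]  # pysam op codes (0=M, 4=S)
    reverse: bool
    seq: str
    on_library: bool

    @property
    def aligned_len(self) -> int:
        return sum(n for op, n in self.cigar if op == 0)

    @property
    def end(self) -> int:
        return self.pos + self.aligned_len


def _emulate_read(
    sim: SimulatedCohort,
    contig: str,
    segs: list[_Segment],
    seg_starts: list[int],
    frag_seq: str,
    s: int,
    e: int,
    is_read2: bool,
    frag_start: int,
    min_anchor: int,
) -> _RawRead:
    """Place one read of a fragment against the reference, emulating a mapper."""
    i = bisect_right(seg_starts, s) - 1
    portions: list[tuple[_Segment, int, int]] = []
    while i < len(segs) and segs[i].hap_start < e:
        seg = segs[i]
        lo = max(s, seg.hap_start)
        hi = min(e, seg.hap_end)
        if hi > lo:
            portions.append((seg, lo, hi))
        i += 1
    read_seq = frag_seq[s - frag_start : e - frag_start]

    ref_portions = [p for p in portions if p[0].kind == "ref"]
    anchored = [p for p in ref_portions if p[2] - p[1] >= min_anchor]
    if anchored:
        seg, lo, hi = max(anchored, key=lambda p: p[2] - p[1])
    else:
        seg, lo, hi = max(portions, key=lambda p: p[2] - p[1])

    if seg.kind == "ref":
        pos = seg.ref_start + (lo - seg.hap_start)
        left, right = lo - s, e - hi
        cigar = []
        if left:
            cigar.append((4, left))
        cigar.append((0, hi - lo))
        if right:
            cigar.append((4, right))
        return _RawRead(contig, pos, cigar, is_read2, read_seq, False)

    locus = seg.locus
    lib_name = sim.lib_contig(locus.lineage)
    lib_len = len(sim.library[lib_name])
    off = lo - seg.hap_start
    plen = hi - lo
    left, right = lo - s, e - hi
    if locus.strand == "+":
        pos = max(0, min(off, lib_len - plen))
        reverse = is_read2
        seq = read_seq
    else:
        pos = max(0, min(lib_len - (off + plen), lib_len - plen))
        reverse = not is_read2
        seq = revcomp(read_seq)
        left, right = right, left
    cigar = []
    if left:
        cigar.append((4, left))
    cigar.append((0, plen))
    if right:
        cigar.append((4, right))
    return _RawRead(lib_name, pos, cigar, reverse, seq, True)


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if not n_err:
        return seq
    arr = seq_to_array(seq)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    lut = {65: 0, 67: 1, 71: 2, 84: 3}
    for pos in rng.integers(0, len(seq), size=n_err):
        cur = lut[arr[pos]]
        arr[pos] = bases[(cur + rng.integers(1, 4)) % 4]
    return array_to_seq(arr)


def simulate_alignments(
    sim: SimulatedCohort,
    individual: str,
    cfg: ReadSimConfig,
    seed=None,
) -> list[tuple]:
    """Simulate one individual's paired-end alignments against the reference.

    Returns SAM-ready record tuples sorted by coordinate:
    ``(rname, pos, name, flag, cigar, rnext, pnext, tlen, seq)``.
    """
    cov = sim.truth.coverage(individual)
    if cov <= 0:
        raise ValueError("coverage must be > 0")
    rng = _as_rng(seed if seed is not None else cfg.seed)
    rl = cfg.read_len
    records: list[tuple] = []
    serial = 0
    max_proper = cfg.insert_mean + 4 * cfg.insert_sd
    for hap in (0, 1):
        for contig in sorted(sim.reference):
            hapseq, segs = build_haplotype(sim, individual, hap, contig)
            seg_starts = [g.hap_start for g in segs]
            L = len(hapseq)
            if L < rl:
                continue
            n_frags = int(round(cov / 2 * L / (2 * rl)))
            starts = rng.integers(0, max(L - rl, 1), size=n_frags)
            inserts = rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_frags)
            inserts = np.maximum(inserts.astype(int), rl)
            for fi in range(n_frags):
                fs = int(starts[fi])
                fe = min(fs + int(inserts[fi]), L)  # contig-edge truncation
                r1_e = min(fs + rl, fe)
                r2_s = max(fe - rl, fs)
                frag = hapseq[fs:fe]
                frag = _apply_errors(frag, cfg.error_rate, rng)
                r1 = _emulate_read(
                    sim, contig, segs, seg_starts, frag, fs, r1_e, False, fs,
                    cfg.min_anchor,
                )
                r2 = _emulate_read(
                    sim, contig, segs, seg_starts, frag, r2_s, fe, True, fs,
                    cfg.min_anchor,
                )
                serial += 1
                name = f"{individual}_{serial}"
                flag1 = 0x1 | 0x40 | (0x10 if r1.reverse else 0) | (
                    0x20 if r2.reverse else 0
                )
                flag2 = 0x1 | 0x80 | (0x10 if r2.reverse else 0) | (
                    0x20 if r1.reverse else 0
                )
                if r1.rname == r2.rname:
                    lo = min(r1.pos, r2.pos)
                    hi = max(r1.end, r2.end)
                    span = hi - lo
                    t1 = span if r1.pos <= r2.pos else -span
                    t2 = -t1
                    proper = (
                        r1.reverse != r2.reverse
                        and rl <= span <= max_proper
                    )
                    if proper:
                        flag1 |= 0x2
                        flag2 |= 0x2
                else:
                    t1 = t2 = 0
                records.append(
                    (r1.rname, r1.pos, name, flag1, r1.cigar, r2.rname, r2.pos, t1, r1.seq)
                )
                records.append(
                    (r2.rname, r2.pos, name, flag2, r2.cigar, r1.rname, r1.pos, t2, r2.seq)
                )
    order = {c: i for i, c in enumerate(sam_contigs(sim))}
    records.sort(key=lambda r: (order[r[0]], r[1], r[2]))
    return records


def sam_contigs(sim: SimulatedCohort) -> list[str]:
    return sorted(sim.reference) + sorted(sim.library)


def sam_header(sim: SimulatedCohort, seed=None) -> dict:
    sq = [
        {"SN": c, "LN": len(sim.reference.get(c) or sim.library[c])}
        for c in sam_contigs(sim)
    ]
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": sq}
    header["CO"] = [f"erv-census simulated alignments seed={seed if seed is not None else sim.seed}"]
    return header


def write_individual_sam(
    sim: SimulatedCohort,
    individual: str,
    cfg: ReadSimConfig,
    path,
    seed=None,
) -> None:
    """Write one individual's simulated alignments as coordinate-sorted SAM."""
    records = simulate_alignments(sim, individual, cfg, seed=seed)
    header = pysam.AlignmentHeader.from_dict(sam_header(sim, seed=seed))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rname, pos, name, flag, cigar, rnext, pnext, tlen, seq in records:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.flag = flag
            a.reference_name = rname
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = cigar
            a.next_reference_name = rnext
            a.next_reference_start = pnext
            a.template_length = tlen
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(a)
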