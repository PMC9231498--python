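"""End-to-end orchestration: simulate -> annotate -> call -> date -> cohort.

A single seeded RunConfig drives every stage through independent random
substreams (stage re-runs do not perturb each other), all outputs are
written as plain text (FASTA/SAM/BED/TSV/YAML/Markdown), and a truth
comparison report closes the loop.  Re-running with the same config and
seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import callerv, chronodist, cohort
from ._seq import random_dna, write_fasta
from .annotate import annotate_assembly, write_annotations
from .callerv import FilterPolicy, RefLocus
from .simulate import (
    AlleleFreqDist,
    LineageSpec,
    PlantedLocus,
    ReadSimConfig,
    SimulatedCohort,
    default_cohort,
    default_lineages,
    plant_cohort,
    write_individual_sam,
)

__all__ = [
    "RunConfig",
    "run_end_to_end",
    "evaluate_against_truth",
    "make_host_genome",
    "simulate_study",
]

HC_COVERAGE_CUTOFF = 20.0


@dataclass
class RunConfig:
    """Fully serialisable configuration of one synthetic study run."""

    seed: int = 1
    n_contigs: int = 1
    contig_length: int = 400_000
    lineage_scale: float = 0.06  # scales the three-lineage locus pools
    lineages: list[LineageSpec] = field(default_factory=list)
    cohort: list[tuple[str, float]] = field(default_factory=default_cohort)
    read: ReadSimConfig = field(default_factory=ReadSimConfig)
    mu_low: float = 2e-9
    mu_high: float = 4.5e-9
    hc_min_reads: int = 5
    lc_min_reads: int = 2
    merge_tolerance_bp: int = 100
    eval_tolerance_bp: int = 25
    rescue_window: int = 300
    tsd_range: tuple[int, int] = (4, 6)

    def __post_init__(self):
        if not self.lineages:
            self.lineages = default_lineages(scale=self.lineage_scale)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = [list(c) for c in self.cohort]
        d["tsd_range"] = list(self.tsd_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        _validate_config_dict(d)
        if "lineages" in d and d["lineages"]:
            d["lineages"] = [
                LineageSpec(
                    **{
                        **spec,
                        "allele_freq": AlleleFreqDist(**spec["allele_freq"]),
                    }
                )
                for spec in d["lineages"]
            ]
        if "read" in d and isinstance(d["read"], dict):
            d["read"] = ReadSimConfig(**d["read"])
        if "cohort" in d:
            d["cohort"] = [tuple(c) for c in d["cohort"]]
        if "tsd_range" in d:
            d["tsd_range"] = tuple(d["tsd_range"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_CONFIG_KEYS = {
    "seed": int,
    "n_contigs": int,
    "contig_length": int,
    "lineage_scale": (int, float),
    "lineages": list,
    "cohort": list,
    "read": dict,
    "mu_low": float,
    "mu_high": float,
    "hc_min_reads": int,
    "lc_min_reads": int,
    "merge_tolerance_bp": int,
    "eval_tolerance_bp": int,
    "rescue_window": int,
    "tsd_range": (list, tuple),
}


def _validate_config_dict(d: dict) -> None:
    unknown = set(d) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in d.items():
        if not isinstance(value, _CONFIG_KEYS[key]):
            raise ValueError(f"config key {key!r} has wrong type {type(value).__name__}")


# ---------------------------------------------------------------------------
# stages


def _stage_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def make_host_genome(config: RunConfig) -> dict[str, str]:
    rng = _stage_rng(config.seed, 10)
    return {
        f"contig{i + 1}": random_dna(rng, config.contig_length)
        for i in range(config.n_contigs)
    }


def simulate_study(config: RunConfig) -> SimulatedCohort:
    host = make_host_genome(config)
    return plant_cohort(
        host,
        config.lineages,
        config.cohort,
        seed=config.seed,
        tsd_range=config.tsd_range,
        insert_mean=config.read.insert_mean,
    )


def policy_for(config: RunConfig, coverage: float, mode: str) -> FilterPolicy:
    if coverage >= HC_COVERAGE_CUTOFF:
        return FilterPolicy(
            mode=mode, min_reads=config.hc_min_reads, coverage=coverage
        )
    return FilterPolicy(mode=mode, min_reads=config.lc_min_reads, coverage=coverage)


def run_end_to_end(config: RunConfig, outdir) -> dict:
    """Run the whole synthetic study and write a run directory.

    Returns a dict of in-memory stage products (the report is also written
    to disk).  Any stage failure propagates with partial outputs preserved.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "calls").mkdir(exist_ok=True)
    (out / "sams").mkdir(exist_ok=True)
    (out / "cohort").mkdir(exist_ok=True)
    (out / "dating").mkdir(exist_ok=True)
    config.to_yaml(out / "config.yaml")

    # -- simulate ---------------------------------------------------------
    sim = simulate_study(config)
    sim.write_reference(out / "reference.fa")
    sim.write_library(out / "library.fa")
    sim.write_truth_bed(out / "truth.bed")
    sim.write_truth_genotypes(out / "truth_genotypes.tsv")

    # -- annotate the reference assembly ----------------------------------
    full_len = max(t.length for t in sim.templates.values())
    annotations = annotate_assembly(
        sim.reference,
        sim.templates,
        element_len_range=(int(0.5 * full_len), full_len + 400),
    )
    write_annotations(annotations, out / "annotations.tsv", out / "annotations.bed")
    ref_loci = [
        RefLocus(f"R{i:04d}", a.contig, a.start, a.end, a.lineage or "")
        for i, a in enumerate(
            [a for a in annotations if not a.solo], 1
        )
    ]

    # -- per-individual calling -------------------------------------------
    evidence_by_ind = {}
    ins_by_ind = {}
    abs_by_ind = {}
    for i, (ind, cov) in enumerate(config.cohort):
        sam_path = out / "sams" / f"{ind}.sam"
        sub_seed = int(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(20, i)).generate_state(1)[0]
            % (2**31)
        )
        write_individual_sam(sim, ind, config.read, sam_path, seed=sub_seed)
        library = dict(sim.library)
        for lineage, ltr in sim.library_ltrs.items():
            library[f"ERVlib_{lineage}_LTR"] = ltr
        evidence = callerv.extract_evidence(sam_path, library)
        evidence_by_ind[ind] = evidence
        pol = policy_for(config, cov, "relaxed")
        ins_by_ind[ind] = callerv.call_nonreference_insertions(evidence, pol)
        abs_by_ind[ind] = callerv.call_reference_absences(
            sam_path,
            ref_loci,
            pol,
            insert_mean=config.read.insert_mean,
            insert_sd=config.read.insert_sd,
            reference=sim.reference,
        )

    # -- cross-sample merge and rescue ------------------------------------
    merged, presence = cohort.merge_loci(
        ins_by_ind, tolerance_bp=config.merge_tolerance_bp
    )
    for ind, cov in config.cohort:
        pol = policy_for(config, cov, "relaxed")
        rescued = callerv.rescue_softclips(
            evidence_by_ind[ind], merged, pol, window=config.rescue_window
        )
        for locus in merged:
            res = rescued.get(locus.locus_id)
            if res and res.present and (locus.locus_id, ind) not in presence:
                presence[(locus.locus_id, ind)] = "relaxed"
        calls_df = callerv.calls_to_frame(ins_by_ind[ind], abs_by_ind[ind])
        calls_df.to_csv(out / "calls" / f"{ind}.tsv", sep="\t", index=False)

    individuals = [ind for ind, _ in config.cohort]
    matrix = cohort.build_presence_matrix(
        merged, presence, individuals, ref_loci, abs_by_ind
    )
    matrix.values.to_csv(out / "cohort" / "matrix.tsv", sep="\t")
    summaries = cohort.summarize_lineages(matrix)
    cohort.summaries_to_frame(summaries).to_csv(
        out / "cohort" / "lineage_summary.tsv", sep="\t", index=False
    )
    with open(out / "cohort" / "loci.bed", "w") as fh:
        for locus in merged:
            fh.write(
                f"{locus.contig}\t{locus.start}\t{locus.end}\t{locus.lineage}|{locus.locus_id}\t0\t+\n"
            )

    # -- dating ------------------------------------------------------------
    per_copy = []
    for ann in annotations:
        if ann.solo:
            continue
        d = chronodist.ltr_divergence(ann, sim.reference[ann.contig])
        if d is None:
            continue
        lo, hi = chronodist.estimate_age_interval(d, config.mu_low, config.mu_high)
        pol_prof = ann.genes.get("pol")
        per_copy.append(
            {
                "contig": ann.contig,
                "start": ann.start,
                "end": ann.end,
                "lineage": ann.lineage,
                "ltr_divergence": round(d, 5),
                "age_low_my": chronodist.format_age_my(lo),
                "age_high_my": chronodist.format_age_my(hi),
                "pol_stops": pol_prof.n_stops if pol_prof and pol_prof.detected else "",
                "pol_frameshifts": pol_prof.n_frameshifts
                if pol_prof and pol_prof.detected
                else "",
            }
        )
    per_copy_df = pd.DataFrame(per_copy)
    per_copy_df.to_csv(out / "dating" / "per_copy.tsv", sep="\t", index=False)
    clade_rows = []
    for lineage in sorted(sim.templates):
        anns = [a for a in annotations if a.lineage == lineage and not a.solo]
        divs = [
            chronodist.ltr_divergence(a, sim.reference[a.contig]) for a in anns
        ]
        divs = [d for d in divs if d is not None]
        stats, undet = chronodist.inactivation_summary(anns, lineage)
        row = {"lineage": lineage, "n_copies": len(anns)}
        if divs:
            median_d = float(np.median(divs))
            lo, hi = chronodist.estimate_age_interval(
                median_d, config.mu_low, config.mu_high
            )
            row.update(
                median_ltr_divergence=round(median_d, 5),
                age_low_my=chronodist.format_age_my(lo),
                age_high_my=chronodist.format_age_my(hi),
            )
        if stats:
            row.update(
                inactivation_mean=round(stats.mean, 2),
                inactivation_median=stats.median,
            )
        clade_rows.append(row)
    pd.DataFrame(clade_rows).to_csv(
        out / "dating" / "clade_summary.tsv", sep="\t", index=False
    )

    # -- evaluation and report ---------------------------------------------
    metrics = evaluate_against_truth(
        ins_by_ind, abs_by_ind, matrix, sim, ref_loci, tolerance_bp=config.eval_tolerance_bp
    )
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
    _write_report(out, config, sim, matrix, summaries, clade_rows, metrics)
    return {
        "sim": sim,
        "annotations": annotations,
        "ref_loci": ref_loci,
        "insertions": ins_by_ind,
        "absences": abs_by_ind,
        "matrix": matrix,
        "summaries": summaries,
        "metrics": metrics,
    }


def _write_report(out, config, sim, matrix, summaries, clade_rows, metrics):
    lines = [
        "# erv-census run report",
        "",
        f"- seed: {config.seed}",
        f"- config hash: {config.config_hash()}",
        f"- individuals: {len(config.cohort)}",
        f"- planted loci: {len(sim.loci)}",
        f"- matrix loci: {len(matrix.values)}",
        "",
        "## Lineage summary (loci: assembly / non-assembly, carrier freq)",
        "",
        "| lineage | identified | assembly | nonassembly | sharing % |",
        "|---|---|---|---|---|",
    ]
    for s in summaries:
        share = cohort.sharing_fraction(matrix, s.lineage)
        share_txt = "NA" if share is None else f"{share:.0f}"
        lines.append(
            f"| {s.lineage} | {s.identified_loci} | {s.assembly_cell} |"
            f" {s.nonassembly_cell} | {share_txt} |"
        )
    lines += ["", "## Dating (median LTR divergence, age window in My)", ""]
    for row in clade_rows:
        if "median_ltr_divergence" in row:
            lines.append(
                f"- {row['lineage']}: d={row['median_ltr_divergence']:.4f}, "
                f"{row['age_low_my']}-{row['age_high_my']} My over "
                f"{row['n_copies']} assembly copies"
            )
        else:
            lines.append(f"- {row['lineage']}: no assembly copies annotated")
    lines += ["", "## Calling metrics vs truth", ""]
    lines.append(metrics.to_markdown(index=False))
    lines.append("")
    (out / "report.md").write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# truth comparison


def _match_greedy(call_points, truth_points, tolerance):
    """One-to-one greedy matching by distance; returns number matched."""
    pairs = []
    for ci, cp in enumerate(call_points):
        for ti, tp in enumerate(truth_points):
            d = abs(cp - tp)
            if d <= tolerance:
                pairs.append((d, ci, ti))
    pairs.sort()
    used_c, used_t = set(), set()
    errors = []
    for d, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        errors.append(d)
    return len(used_c), errors


def evaluate_against_truth(
    ins_by_ind: dict,
    abs_by_ind: dict,
    matrix: cohort.PresenceMatrix,
    sim: SimulatedCohort,
    ref_loci: list[RefLocus],
    tolerance_bp: int = 25,
) -> pd.DataFrame:
    """Per-individual precision/recall against the simulator's truth.

    Insertions: calls matched one-to-one to true non-reference loci carried
    by the individual, breakpoints within ``tolerance_bp``.  Absences:
    hom_absent recall over genotype-0 reference loci (precision over
    genotype <= 1).  Genotype concordance over annotated reference loci.
    """
    truth_contigs = set(sim.reference)
    rows = []
    ref_locus_truth = _map_ref_loci_to_truth(ref_loci, sim)
    for ind, _cov in sim.truth.individuals:
        calls = ins_by_ind.get(ind, [])
        for c in calls:
            if c.contig not in truth_contigs:
                raise ValueError(f"call contig {c.contig} not in truth reference")
        truth_pts = [
            l.ref_anchor
            for l in sim.loci
            if not l.in_reference
            and sim.truth.genotypes[(l.locus_id, ind)] >= 1
        ]
        call_pts = [c.start for c in calls]
        n_match, errors = _match_greedy(call_pts, truth_pts, tolerance_bp)
        ins_recall = n_match / len(truth_pts) if truth_pts else np.nan
        ins_prec = n_match / len(call_pts) if call_pts else np.nan

        absences = abs_by_ind.get(ind, [])
        called_absent = {a.locus_id for a in absences}
        hom_truth = set()
        le1_truth = set()
        geno_total = geno_correct = 0
        for rl in ref_loci:
            tl = ref_locus_truth.get(rl.locus_id)
            if tl is None:
                continue
            g = sim.truth.genotypes[(tl.locus_id, ind)]
            if g == 0:
                hom_truth.add(rl.locus_id)
            if g <= 1:
                le1_truth.add(rl.locus_id)
            geno_total += 1
            pred = int(matrix.genotypes.at[rl.locus_id, ind]) if (
                matrix.genotypes is not None and rl.locus_id in matrix.genotypes.index
            ) else 2
            if pred == min(g, 2):
                geno_correct += 1
        abs_recall = (
            len(hom_truth & called_absent) / len(hom_truth) if hom_truth else np.nan
        )
        abs_prec = (
            len(le1_truth & called_absent) / len(called_absent)
            if called_absent
            else np.nan
        )
        rows.append(
            {
                "individual": ind,
                "n_insertion_calls": len(call_pts),
                "insertion_recall": round(ins_recall, 4)
                if not np.isnan(ins_recall)
                else np.nan,
                "insertion_precision": round(ins_prec, 4)
                if not np.isnan(ins_prec)
                else np.nan,
                "absence_recall": round(abs_recall, 4)
                if not np.isnan(abs_recall)
                else np.nan,
                "absence_precision": round(abs_prec, 4)
                if not np.isnan(abs_prec)
                else np.nan,
                "genotype_concordance": round(geno_correct / geno_total, 4)
                if geno_total
                else np.nan,
                "mean_breakpoint_error": round(float(np.mean(errors)), 2)
                if errors
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def truth_presence_matrix(sim: SimulatedCohort) -> cohort.PresenceMatrix:
    """Presence matrix straight from simulator truth (perfect detection).

    A locus appears as a row when it has at least one carrier or sits in
    the reference assembly; presence is genotype >= 1.  Useful for
    population-scale Monte Carlo over cohort statistics without read
    simulation or calling.
    """
    individuals = [ind for ind, _ in sim.truth.individuals]
    meta_rows, val_rows = [], {}
    for locus in sim.loci:
        gts = [
            sim.truth.genotypes[(locus.locus_id, ind)] for ind in individuals
        ]
        if not locus.in_reference and not any(g >= 1 for g in gts):
            continue
        a, b = locus.bed_interval
        meta_rows.append(
            {
                "locus_id": locus.locus_id,
                "contig": locus.contig,
                "start": a,
                "end": b,
                "lineage": locus.lineage,
                "in_reference": locus.in_reference,
            }
        )
        val_rows[locus.locus_id] = [1 if g >= 1 else 0 for g in gts]
    meta = pd.DataFrame(meta_rows).set_index("locus_id")
    values = pd.DataFrame.from_dict(
        val_rows, orient="index", columns=individuals
    ).loc[meta.index]
    return cohort.PresenceMatrix(loci=meta, values=values)


def _map_ref_loci_to_truth(
    ref_loci: list[RefLocus], sim: SimulatedCohort
) -> dict[str, PlantedLocus]:
    truth_ref = [l for l in sim.loci if l.in_reference]
    out = {}
    for rl in ref_loci:
        best, best_ov = None, 0
        for tl in truth_ref:
            if tl.contig != rl.contig:
                continue
            a, b = tl.bed_interval
            ov = min(b, rl.end) - max(a, rl.start)
            if ov > best_ov:
                best, best_ov = tl, ov
        if best is not None:
            out[rl.locus_id] = best
    return out
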