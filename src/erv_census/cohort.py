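"""Population-level aggregation of per-individual ERV calls.

Cross-sample locus merging, the loci x individuals presence matrix,
locus-sharing statistics, per-lineage summary tables (identified loci split
into assembly and non-assembly classes with carrier-frequency ranges), and
deterministic heatmap row ordering.

"Frequency" here is the carrier count: the number of cohort individuals in
which a locus was detected — an integer in [1, n_individuals] — not an
allele-frequency estimate.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MergedLocus",
    "PresenceMatrix",
    "LineageSummary",
    "merge_loci",
    "build_presence_matrix",
    "sharing_fraction",
    "summarize_lineages",
    "order_rows_for_heatmap",
    "plot_heatmap",
]


@dataclass(frozen=True)
class MergedLocus:
    locus_id: str
    contig: str
    start: int
    end: int
    lineage: str
    in_reference: bool = False


def merge_loci(
    calls_by_individual: Mapping[str, Sequence],
    tolerance_bp: int = 100,
) -> tuple[list[MergedLocus], dict[tuple[str, str], str]]:
    """Unify per-individual insertion calls into cross-sample loci.

    Single-linkage clustering of breakpoints within ``tolerance_bp`` on the
    same contig and lineage (clusters never mix lineages).  The locus
    interval is the span of member breakpoints; locus ids are assigned in
    (contig, start) order, so merging is deterministic and idempotent.
    Returns the locus list and a (locus_id, individual) -> tier map.
    """
    items: dict[tuple[str, str], list[tuple[int, int, str, str]]] = defaultdict(list)
    for ind, calls in calls_by_individual.items():
        for c in calls:
            tier = getattr(c, "tier", "relaxed")
            items[(c.contig, c.lineage)].append((c.start, c.end, ind, tier))

    loci: list[tuple[str, int, int, str, list[tuple[str, str]]]] = []
    for (contig, lineage), rows in sorted(items.items()):
        rows.sort()
        cluster: list[tuple[int, int, str, str]] = []
        for row in rows:
            if cluster and row[0] - max(r[0] for r in cluster) > tolerance_bp:
                loci.append(_close_cluster(contig, lineage, cluster))
                cluster = []
            cluster.append(row)
        if cluster:
            loci.append(_close_cluster(contig, lineage, cluster))

    loci.sort(key=lambda l: (l[0], l[1], l[2], l[3]))
    merged: list[MergedLocus] = []
    presence: dict[tuple[str, str], str] = {}
    for i, (contig, start, end, lineage, members) in enumerate(loci, 1):
        lid = f"NR{i:04d}"
        merged.append(MergedLocus(lid, contig, start, end, lineage))
        for ind, tier in members:
            prev = presence.get((lid, ind))
            if prev is None or (prev == "relaxed" and tier == "stringent"):
                presence[(lid, ind)] = tier
    return merged, presence


def _close_cluster(contig, lineage, cluster):
    start = min(r[0] for r in cluster)
    end = max(r[1] for r in cluster)
    members = [(r[2], r[3]) for r in cluster]
    return (contig, start, max(end, start + 1), lineage, members)


@dataclass
class PresenceMatrix:
    """Loci x individuals presence (0/1) with locus metadata.

    ``values`` has locus_id index and individual columns; ``loci`` carries
    contig/interval/lineage/in_reference per row.  ``genotypes`` optionally
    refines presence into copy counts {0,1,2} where resolvable (reference
    loci with zygosity hints).
    """

    loci: pd.DataFrame
    values: pd.DataFrame
    genotypes: pd.DataFrame | None = None

    @property
    def individuals(self) -> list[str]:
        return list(self.values.columns)

    def lineage_rows(self, lineage: str) -> pd.DataFrame:
        ids = self.loci.index[self.loci["lineage"] == lineage]
        return self.values.loc[ids]


def build_presence_matrix(
    merged_loci: Sequence[MergedLocus],
    presence: Mapping[tuple[str, str], str],
    individuals: Sequence[str],
    ref_loci: Sequence = (),
    absences_by_individual: Mapping[str, Sequence] | None = None,
) -> PresenceMatrix:
    """Assemble the presence matrix from non-reference and reference calls.

    Non-reference loci are present where a (possibly rescued) call exists.
    Reference-assembly loci are present unless a hom_absent call was made
    for that individual; het absences keep presence 1 with genotype 1.
    Reference loci absent from every individual are retained (the assembly
    haplotype itself carries them).
    """
    absences_by_individual = absences_by_individual or {}
    meta_rows = []
    val_rows = {}
    gt_rows = {}
    for locus in merged_loci:
        meta_rows.append(
            {
                "locus_id": locus.locus_id,
                "contig": locus.contig,
                "start": locus.start,
                "end": locus.end,
                "lineage": locus.lineage,
                "in_reference": False,
            }
        )
        val_rows[locus.locus_id] = [
            1 if (locus.locus_id, ind) in presence else 0 for ind in individuals
        ]
        gt_rows[locus.locus_id] = [
            1 if (locus.locus_id, ind) in presence else 0 for ind in individuals
        ]
    abs_idx: dict[tuple[str, str], str] = {}
    for ind, calls in absences_by_individual.items():
        for a in calls:
            abs_idx[(a.locus_id, ind)] = a.zygosity_hint
    for locus in ref_loci:
        lid = locus.locus_id
        meta_rows.append(
            {
                "locus_id": lid,
                "contig": locus.contig,
                "start": locus.start,
                "end": locus.end,
                "lineage": getattr(locus, "lineage", "") or "",
                "in_reference": True,
            }
        )
        vals, gts = [], []
        for ind in individuals:
            hint = abs_idx.get((lid, ind))
            if hint == "hom_absent":
                vals.append(0)
                gts.append(0)
            elif hint == "het":
                vals.append(1)
                gts.append(1)
            else:
                vals.append(1)
                gts.append(2)
        val_rows[lid] = vals
        gt_rows[lid] = gts
    meta = pd.DataFrame(meta_rows).set_index("locus_id") if meta_rows else pd.DataFrame(
        columns=["contig", "start", "end", "lineage", "in_reference"]
    )
    values = pd.DataFrame.from_dict(
        val_rows, orient="index", columns=list(individuals)
    ).loc[meta.index if len(meta) else []]
    genotypes = pd.DataFrame.from_dict(
        gt_rows, orient="index", columns=list(individuals)
    ).loc[meta.index if len(meta) else []]
    return PresenceMatrix(loci=meta, values=values, genotypes=genotypes)


def sharing_fraction(matrix: PresenceMatrix, lineage: str) -> float | None:
    """Percent of the lineage's loci present in more than one individual.

    None (undefined) when the lineage has no loci in the matrix.
    """
    rows = matrix.lineage_rows(lineage)
    if rows.empty:
        return None
    carriers = rows.sum(axis=1)
    return float((carriers >= 2).sum() / len(rows) * 100.0)


@dataclass(frozen=True)
class LineageSummary:
    lineage: str
    identified_loci: int
    assembly_loci: int
    assembly_freq_range: tuple[int, int] | None
    assembly_freq_mean: float | None
    nonassembly_loci: int
    nonassembly_freq_range: tuple[int, int] | None
    nonassembly_freq_mean: float | None

    def _fmt(self, n, rng, mean) -> str:
        if n == 0 or rng is None:
            return str(n)
        return f"{n} ({rng[0]}-{rng[1]} / {mean:.1f})"

    @property
    def assembly_cell(self) -> str:
        return self._fmt(
            self.assembly_loci, self.assembly_freq_range, self.assembly_freq_mean
        )

    @property
    def nonassembly_cell(self) -> str:
        return self._fmt(
            self.nonassembly_loci,
            self.nonassembly_freq_range,
            self.nonassembly_freq_mean,
        )


def summarize_lineages(matrix: PresenceMatrix) -> list[LineageSummary]:
    """Per-lineage locus counts and carrier-frequency summaries.

    Splits each lineage's loci into assembly (in the reference) and
    non-assembly classes; carrier-frequency range and mean are computed
    over loci with at least one carrier.
    """
    out = []
    for lineage in sorted(matrix.loci["lineage"].unique()):
        ids = matrix.loci.index[matrix.loci["lineage"] == lineage]
        sub = matrix.loci.loc[ids]
        counts = matrix.values.loc[ids].sum(axis=1)
        blocks = {}
        for label, mask in (
            ("assembly", sub["in_reference"]),
            ("nonassembly", ~sub["in_reference"]),
        ):
            sel = counts[mask.values]
            carried = sel[sel >= 1]
            if len(carried):
                blocks[label] = (
                    int(mask.sum()),
                    (int(carried.min()), int(carried.max())),
                    float(carried.mean()),
                )
            else:
                blocks[label] = (int(mask.sum()), None, None)
        out.append(
            LineageSummary(
                lineage=lineage,
                identified_loci=len(ids),
                assembly_loci=blocks["assembly"][0],
                assembly_freq_range=blocks["assembly"][1],
                assembly_freq_mean=blocks["assembly"][2],
                nonassembly_loci=blocks["nonassembly"][0],
                nonassembly_freq_range=blocks["nonassembly"][1],
                nonassembly_freq_mean=blocks["nonassembly"][2],
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[LineageSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lineage": [s.lineage for s in summaries],
            "identified_loci": [s.identified_loci for s in summaries],
            "assembly": [s.assembly_cell for s in summaries],
            "nonassembly": [s.nonassembly_cell for s in summaries],
        }
    )


def order_rows_for_heatmap(
    matrix: PresenceMatrix, focus_individuals: Sequence[str]
) -> list[str]:
    """Row permutation sorting loci by their presence pattern over a focus set.

    Descending carrier count over the focus individuals, then the binary
    presence pattern itself (descending, so patterns involving the first
    focus individual sort first), then locus id.  Deterministic and
    idempotent; the result is a bijection on rows.
    """
    missing = [f for f in focus_individuals if f not in matrix.values.columns]
    if missing:
        raise KeyError(f"focus individuals not in matrix: {missing}")

    def key(lid: str):
        pattern = tuple(int(matrix.values.at[lid, f]) for f in focus_individuals)
        return (-sum(pattern), tuple(-p for p in pattern), lid)

    return sorted(matrix.values.index, key=key)


def plot_heatmap(
    matrix: PresenceMatrix,
    path,
    focus_individuals: Sequence[str] | None = None,
    lineage: str | None = None,
):
    """Presence heatmap (dark = present), rows ordered by sharing pattern."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = matrix.values
    if lineage is not None:
        values = matrix.lineage_rows(lineage)
    focus = list(focus_individuals or values.columns)
    sub = PresenceMatrix(loci=matrix.loci.loc[values.index], values=values)
    order = order_rows_for_heatmap(sub, focus)
    arr = values.loc[order].to_numpy()
    fig, ax = plt.subplots(figsize=(0.5 * len(values.columns) + 1, 6))
    ax.imshow(arr, aspect="auto", cmap="Greys", vmin=0, vmax=1, interpolation="none")
    ax.set_xticks(np.arange(len(values.columns)))
    ax.set_xticklabels(values.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(order)} loci")
    if lineage:
        ax.set_title(lineage)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
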