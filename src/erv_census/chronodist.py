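"""Divergence and dating statistics for ERV lineage expansions.

The clock: the two LTRs of a provirus are identical at integration and
accumulate substitutions independently afterwards, so for a per-site,
per-year rate mu the expected 5'-3' LTR divergence is d = 2*mu*t and an
integration age estimate is t = d / (2*mu).  Distances are raw p-distances
(mismatched over aligned ungapped columns), matching how percent
divergences are conventionally reported for young expansions; no
multiple-hit correction is applied by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._align import p_distance
from .annotate import ProvirusAnnotation

__all__ = [
    "AgeEstimate",
    "Stats",
    "DistanceSummary",
    "pairwise_p_distance",
    "ltr_divergence",
    "estimate_age",
    "estimate_age_interval",
    "format_age_my",
    "clade_distance_summary",
    "distance_histogram",
    "inactivation_summary",
]


def pairwise_p_distance(seq_a: str, seq_b: str) -> float:
    """Symmetric p-distance between two sequences (global affine alignment)."""
    return p_distance(seq_a, seq_b)


def ltr_divergence(
    annotation: ProvirusAnnotation, contig_seq: str
) -> float | None:
    """5'-3' LTR divergence of an annotated provirus; None for a solo LTR."""
    if annotation.ltr5 is None or annotation.ltr3 is None:
        return None
    a = contig_seq[annotation.ltr5[0] : annotation.ltr5[1]]
    b = contig_seq[annotation.ltr3[0] : annotation.ltr3[1]]
    if not a or not b:
        return None
    return pairwise_p_distance(a, b)


@dataclass(frozen=True)
class AgeEstimate:
    d: float  # LTR divergence, proportion
    mu: float  # substitutions / site / year
    t: float  # years

    def __post_init__(self):
        if not math.isclose(self.t, self.d / (2 * self.mu), rel_tol=1e-12):
            raise ValueError("AgeEstimate requires t == d / (2*mu)")


def estimate_age(d: float, mu: float) -> AgeEstimate:
    """Integration age t = d / (2*mu) in years."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if not 0 <= d <= 1:
        raise ValueError("d must lie in [0, 1]")
    return AgeEstimate(d=d, mu=mu, t=d / (2 * mu))


def estimate_age_interval(
    d: float, mu_low: float, mu_high: float
) -> tuple[float, float]:
    """(t_low, t_high) in years from the faster and slower clock rate."""
    if mu_low <= 0 or mu_high <= 0:
        raise ValueError("mutation rates must be > 0")
    lo = estimate_age(d, mu_high).t
    hi = estimate_age(d, mu_low).t
    return (min(lo, hi), max(lo, hi))


def format_age_my(t_years: float) -> float:
    """Display rounding of an age to millions of years.

    Two significant figures, capped at one decimal place for ages of at
    least ~0.1 My (so 5.5e6 -> 5.5, 2.44e6 -> 2.4, 6.7e5 -> 0.7).
    """
    my = t_years / 1e6
    if my == 0:
        return 0.0
    rounded = float(f"{my:.2g}")
    if rounded >= 0.095:
        rounded = round(rounded, 1)
    return rounded


# ---------------------------------------------------------------------------
# clade summaries


@dataclass(frozen=True)
class Stats:
    min: float
    max: float
    mean: float
    median: float

    @classmethod
    def of(cls, values) -> "Stats | None":
        vals = [float(v) for v in values if v is not None]
        if not vals:
            return None
        return cls(
            min=float(np.min(vals)),
            max=float(np.max(vals)),
            mean=float(np.mean(vals)),
            median=float(np.median(vals)),
        )


@dataclass
class DistanceSummary:
    clade: str
    n_members: int
    pairwise: Stats | None  # intra-clade pairwise p-distances
    ltr: Stats | None  # per-copy 5'-3' LTR divergences
    inactivation: Stats | None  # per-copy pol stops + frameshifts
    n_pol_undetected: int = 0


def clade_distance_summary(
    sequences: list[str],
    clade: str,
    ltr_divergences: list[float | None] | None = None,
    inactivation_counts: list[int] | None = None,
) -> DistanceSummary:
    """Pairwise intra-clade distances plus optional per-copy statistics.

    With fewer than two member sequences the pairwise block is reported
    missing (None), not zero.
    """
    pairwise = None
    if len(sequences) >= 2:
        dists = [
            pairwise_p_distance(sequences[i], sequences[j])
            for i in range(len(sequences))
            for j in range(i + 1, len(sequences))
        ]
        pairwise = Stats.of(dists)
    return DistanceSummary(
        clade=clade,
        n_members=len(sequences),
        pairwise=pairwise,
        ltr=Stats.of(ltr_divergences) if ltr_divergences else None,
        inactivation=Stats.of(inactivation_counts)
        if inactivation_counts is not None and len(inactivation_counts)
        else None,
    )


def distance_histogram(
    distances: list[float], bin_width: float = 0.0025
) -> pd.DataFrame:
    """Histogram of distances with fixed-width bins (default 0.25%)."""
    if not distances:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    hi = max(distances)
    n_bins = max(1, int(math.ceil((hi + 1e-12) / bin_width)))
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(distances, bins=edges)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "count": counts,
        }
    )


def inactivation_summary(
    annotations: list[ProvirusAnnotation], clade: str
) -> tuple[Stats | None, int]:
    """Per-clade pol inactivating-mutation stats (stops + frameshifts).

    Copies whose pol gene was not detected are excluded from the statistics
    and returned as a separate count.
    """
    counts: list[int] = []
    undetected = 0
    for ann in annotations:
        prof = ann.genes.get("pol")
        if prof is None or not prof.detected:
            undetected += 1
            continue
        counts.append(prof.n_stops + prof.n_frameshifts)
    return Stats.of(counts), undetected
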