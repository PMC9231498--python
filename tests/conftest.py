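"""Shared fixtures: templates and a small simulated cohort with SAMs."""

from __future__ import annotations

import numpy as np
import pytest

from erv_census._seq import random_dna
from erv_census.simulate import (
    AlleleFreqDist,
    LineageSpec,
    MU_MID,
    ReadSimConfig,
    make_template,
    plant_cohort,
    write_individual_sam,
)


@pytest.fixture(scope="session")
def template():
    """Full-size provirus template (~8.3 kb, 500 bp LTRs)."""
    return make_template(0)


@pytest.fixture(scope="session")
def small_template():
    """Short template (~2 kb) for Monte-Carlo-heavy tests; 500 bp LTRs."""
    return make_template(
        1,
        gene_codons={"gag": 60, "pro": 40, "pol": 120, "env": 60},
        spacer=30,
        leader=60,
    )


def informative_lineages(n_loci=5, ref_fraction=0.25, ages=(0.022, 0.006, 0.00015)):
    """Three lineages with moderate allele frequencies so that most loci are
    carried by somebody and reference loci show all three genotypes."""
    names = ("phaCin-beta-like", "phaCin-beta", "KoRV")
    return [
        LineageSpec(
            name=name,
            age_years=d / (2 * MU_MID),
            mu=MU_MID,
            n_loci=n_loci,
            ref_fraction=ref_fraction,
            allele_freq=AlleleFreqDist("beta", a=2.0, b=2.0),
            indel_rate=MU_MID / 10,
        )
        for name, d in zip(names, ages)
    ]


@pytest.fixture(scope="session")
def caller_sim(tmp_path_factory):
    """A 300 kb cohort (HC at 40x, LC at 6x) with SAMs on disk."""
    rng = np.random.default_rng(2024)
    host = {"chr1": random_dna(rng, 300_000)}
    sim = plant_cohort(
        host,
        informative_lineages(),
        [("HC1", 40.0), ("LC1", 6.0)],
        seed=11,
    )
    cfg = ReadSimConfig(seed=0)
    outdir = tmp_path_factory.mktemp("caller_sim")
    paths = {}
    for i, ind in enumerate(("HC1", "LC1")):
        path = outdir / f"{ind}.sam"
        write_individual_sam(sim, ind, cfg, path, seed=100 + i)
        paths[ind] = path
    return {"sim": sim, "cfg": cfg, "paths": paths}


def full_library(sim):
    lib = dict(sim.library)
    for lineage, ltr in sim.library_ltrs.items():
        lib[f"ERVlib_{lineage}_LTR"] = ltr
    return lib
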