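"""Shared fixtures: hand-built micro-cohorts and the default synthetic cohort."""

from __future__ import annotations

import math

import numpy as np
import pytest

import trioscreen as ts
from trioscreen.annotate import AnnotatedVariant
from trioscreen.cohort_io import CohortGenotypes, VariantKey

DEFAULT_CALL = (0, 99, 50, 50, 0)  # (gt, gq, dp, ad_ref, ad_alt)


def make_annot(
    key: VariantKey | None = None,
    gene: str = "G1",
    consequence: str = "missense",
    pop_af: float = math.nan,
    dann: float = math.nan,
    dann_rank: float = math.nan,
    splice_ada: float = math.nan,
    plp_label: str = "none",
) -> AnnotatedVariant:
    if key is None:
        key = VariantKey("1", 100, "A", "G")
    return AnnotatedVariant(key, gene, consequence, pop_af, dann, dann_rank, splice_ada, plp_label)


def make_cohort(samples: list[str], site_data: list[tuple[VariantKey, dict]]) -> CohortGenotypes:
    """Build a cohort from per-site dicts of sample -> (gt, gq, dp, ad_ref, ad_alt);
    unlisted samples get a clean hom-ref call."""
    s = len(site_data)
    n = len(samples)
    gt = np.zeros((s, n), dtype=np.int8)
    gq = np.full((s, n), DEFAULT_CALL[1], dtype=np.int32)
    dp = np.full((s, n), DEFAULT_CALL[2], dtype=np.int32)
    adr = np.full((s, n), DEFAULT_CALL[3], dtype=np.int32)
    ada = np.full((s, n), DEFAULT_CALL[4], dtype=np.int32)
    keys = []
    for i, (key, calls) in enumerate(site_data):
        keys.append(key)
        for sid, values in calls.items():
            j = samples.index(sid)
            gt[i, j], gq[i, j], dp[i, j], adr[i, j], ada[i, j] = values
    return CohortGenotypes(
        keys=keys,
        samples=list(samples),
        gt=gt,
        gq=gq,
        dp=dp,
        ad_ref=adr,
        ad_alt=ada,
        filter_pass=np.ones(s, dtype=bool),
    )


def annotation_map(sim: ts.SimulatedCohort) -> dict[VariantKey, AnnotatedVariant]:
    """In-memory equivalent of writing + re-loading the annotation TSV."""
    out = {}
    for r in sim.annotations.itertuples(index=False):
        k = VariantKey(str(r.chrom), int(r.pos), r.ref, r.alt)
        out[k] = AnnotatedVariant(
            k, r.gene, r.consequence, float(r.pop_af), float(r.dann), float(r.dann_rank), float(r.splice_ada), "none"
        )
    return out


@pytest.fixture(scope="session")
def small_sim() -> ts.SimulatedCohort:
    """A scaled-down cohort for fast structural tests."""
    cfg = ts.SimConfig(seed=7, n_trios=8, n_singletons=6, n_controls=40, n_genes=80, sites_per_gene=2)
    return ts.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_sim() -> ts.SimulatedCohort:
    """The default study-scale cohort: 52 trios, 69 singletons, 1,048 controls."""
    return ts.simulate_cohort(ts.SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_filtered(default_sim):
    filtered, report = ts.apply_filters(default_sim.cohort, default_sim.pedigree)
    return filtered, report


@pytest.fixture(scope="session")
def default_annotations(default_sim):
    return annotation_map(default_sim)
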