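"""Digenic screen: gene selection, pair enumeration, exclusion, scoring."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trioscreen as ts
from trioscreen.cohort_io import VariantKey
from trioscreen.digenic_screen import (
    DigenicPair,
    QualifyingVariant,
    ScreenConfig,
    collect_qualifying,
    enumerate_pairs,
    exclude_unaffected_pairs,
    expression_filter,
    recurrent_pairs,
    run_screen,
    score_pair,
    select_hi_genes,
    unaffected_gene_sets,
)

from .conftest import annotation_map, make_annot, make_cohort


def gene_frame(rows):
    """rows: (gene, chrom, pli, brain, skeletal)"""
    return pd.DataFrame(
        {
            "chrom": [r[1] for r in rows],
            "pli": [r[2] for r in rows],
            "brain_expressed": [r[3] for r in rows],
            "skeletal_expressed": [r[4] for r in rows],
            "mu_syn": 1e-6,
            "mu_mis": 2e-6,
            "mu_lgd": 5e-7,
        },
        index=pd.Index([r[0] for r in rows], name="gene"),
    )


def qv(gene, origin="unknown", kind="dmis", dann_rank=0.96, pos=None, carrier="P1"):
    if pos is None:
        qv.counter += 1
        pos = qv.counter
    if kind == "lgd":
        ann = make_annot(VariantKey("1", pos, "A", "G"), gene=gene, consequence="nonsense", pop_af=0.0, dann_rank=dann_rank)
    else:
        ann = make_annot(VariantKey("1", pos, "A", "G"), gene=gene, consequence="missense", pop_af=0.0, dann=0.99, dann_rank=dann_rank)
    return QualifyingVariant(ann, carrier, origin)


qv.counter = 100


# ----------------------------------------------------------- gene selection
def test_select_hi_genes_pli_and_autosome_rules():
    table = gene_frame(
        [
            ("A1", "7", 0.95, True, False),
            ("B1", "7", 0.90, True, False),  # strict > 0.9
            ("C1", "X", 0.99, True, False),  # sex chromosome excluded
            ("D1", "chr12", 0.92, False, False),  # chr prefix normalized
            ("E1", "2", math.nan, True, True),  # missing pLI skipped
        ]
    )
    assert select_hi_genes(table) == {"A1", "D1"}


# --------------------------------------------------------- qualifying rules
def test_collect_qualifying_applies_all_gates():
    samples = ["P1", "FA1", "MO1"]
    keys = [VariantKey("1", p, "A", "G") for p in (100, 200, 300, 400, 500)]
    cohort = make_cohort(
        samples,
        [
            (keys[0], {"P1": (1, 99, 50, 25, 25), "FA1": (1, 99, 50, 25, 25)}),  # qualifying, paternal
            (keys[1], {"P1": (2, 99, 50, 0, 50)}),  # hom-alt: digenic model is het-only
            (keys[2], {"P1": (1, 99, 50, 25, 25)}),  # low-pLI gene
            (keys[3], {"P1": (1, 99, 50, 25, 25)}),  # common variant
            (keys[4], {"P1": (1, 99, 50, 25, 25), "MO1": (1, 99, 50, 25, 25)}),  # maternal LGD
        ],
    )
    annots = {
        keys[0]: make_annot(keys[0], gene="HI1", consequence="missense", pop_af=0.001, dann=0.99, dann_rank=0.9),
        keys[1]: make_annot(keys[1], gene="HI2", consequence="missense", pop_af=0.0, dann=0.99, dann_rank=0.9),
        keys[2]: make_annot(keys[2], gene="LO1", consequence="nonsense", pop_af=0.0),
        keys[3]: make_annot(keys[3], gene="HI1", consequence="missense", pop_af=0.02, dann=0.99, dann_rank=0.9),
        keys[4]: make_annot(keys[4], gene="HI2", consequence="frameshift", pop_af=0.0),
    }
    table = gene_frame([("HI1", "1", 0.97, True, True), ("HI2", "1", 0.95, True, True), ("LO1", "1", 0.5, True, True)])
    hi = select_hi_genes(table)
    fam = ts.Family("F1", "P1", "FA1", "MO1")
    out = collect_qualifying("P1", cohort, annots, hi, family=fam)
    assert [(q.gene, q.origin) for q in out] == [("HI1", "paternal"), ("HI2", "maternal")]


def test_collect_qualifying_denovo_origin():
    samples = ["P1", "FA1", "MO1"]
    key = VariantKey("1", 100, "A", "G")
    cohort = make_cohort(samples, [(key, {"P1": (1, 99, 50, 25, 25)})])
    annots = {key: make_annot(key, gene="HI1", consequence="missense", pop_af=0.0, dann=0.99, dann_rank=0.9)}
    table = gene_frame([("HI1", "1", 0.97, True, True)])
    fam = ts.Family("F1", "P1", "FA1", "MO1")
    out = collect_qualifying("P1", cohort, annots, select_hi_genes(table), family=fam)
    assert out[0].origin == "denovo"


# --------------------------------------------------------- pair enumeration
def test_enumerate_pairs_basic_combinatorics():
    quals = [qv("G1"), qv("G2"), qv("G3")]
    pairs = enumerate_pairs(quals, require_biparental=False)
    assert {p.genes for p in pairs} == {("G1", "G2"), ("G1", "G3"), ("G2", "G3")}


def test_enumerate_pairs_evidence_couples():
    quals = [qv("G1"), qv("G1"), qv("G2")]
    (pair,) = enumerate_pairs(quals, require_biparental=False)
    assert len(pair.evidence) == 2  # 2 variants in G1 x 1 in G2


def test_enumerate_pairs_biparental_rule():
    # both hits paternal: no haplotype from the mother -> dropped
    assert enumerate_pairs([qv("G1", "paternal"), qv("G2", "paternal")], require_biparental=True) == []
    # paternal + maternal: kept
    assert len(enumerate_pairs([qv("G1", "paternal"), qv("G2", "maternal")], require_biparental=True)) == 1
    # a de novo allele may stand in for either parental haplotype
    assert len(enumerate_pairs([qv("G1", "denovo"), qv("G2", "denovo")], require_biparental=True)) == 1
    assert len(enumerate_pairs([qv("G1", "paternal"), qv("G2", "denovo")], require_biparental=True)) == 1
    # unknown origin never satisfies the rule
    assert enumerate_pairs([qv("G1", "unknown"), qv("G2", "maternal")], require_biparental=True) == []


@settings(max_examples=25, derandomize=True, deadline=None)
@given(k=st.integers(min_value=0, max_value=200))
def test_pair_count_is_k_choose_2(k):
    quals = [qv(f"GENE{i:03d}") for i in range(k)]
    pairs = enumerate_pairs(quals, require_biparental=False)
    assert len(pairs) == k * (k - 1) // 2
    # matches a brute-force double loop over distinct gene indices
    brute = {tuple(sorted((f"GENE{i:03d}", f"GENE{j:03d}"))) for i in range(k) for j in range(i + 1, k)}
    assert {p.genes for p in pairs} == brute


def test_pair_identity_is_unordered():
    p1 = DigenicPair("G2", "G1", "P1", [(qv("G2"), qv("G1"))])
    assert p1.genes == ("G1", "G2")  # canonical lexicographic order


# ------------------------------------------------------------- exclusion
def test_exclusion_requires_both_genes_in_one_individual():
    pairs = enumerate_pairs([qv("G1"), qv("G2")], require_biparental=False)
    assert exclude_unaffected_pairs(list(pairs), {"C1": {"G1", "G2"}}) == []
    pairs = enumerate_pairs([qv("G1"), qv("G2")], require_biparental=False)
    assert len(exclude_unaffected_pairs(list(pairs), {"C1": {"G1"}, "C2": {"G2"}})) == 1
    pairs = enumerate_pairs([qv("G1"), qv("G2")], require_biparental=False)
    assert len(exclude_unaffected_pairs(list(pairs), {})) == 1


def test_exclusion_anti_monotone_under_growing_control_sets():
    rng = np.random.default_rng(17)
    genes = [f"G{i}" for i in range(12)]
    quals = [qv(g) for g in genes]
    survivors = None
    gene_sets: dict[str, set] = {}
    for step in range(10):
        gene_sets[f"C{step}"] = set(rng.choice(genes, size=3, replace=False))
        pairs = enumerate_pairs(quals, require_biparental=False)
        now = {p.genes for p in exclude_unaffected_pairs(pairs, gene_sets)}
        if survivors is not None:
            assert now <= survivors
        survivors = now


# ---------------------------------------------------------------- scoring
def test_score_pair_stated_arithmetic():
    table = gene_frame([("G1", "1", 0.95, True, True), ("G2", "1", 0.99, True, True)])
    pair = DigenicPair("G1", "G2", "P1", [(qv("G1", kind="dmis", dann_rank=0.8), qv("G2", kind="lgd"))])
    score, zone = score_pair(pair, table)
    assert score == pytest.approx(0.5 * (0.8 + 1.0) * 0.5 * (0.95 + 0.99))
    assert score == pytest.approx(0.873)
    assert zone == "zone999"


def test_score_pair_maximal_case():
    table = gene_frame([("G1", "1", 1.0, True, True), ("G2", "1", 1.0, True, True)])
    pair = DigenicPair("G1", "G2", "P1", [(qv("G1", kind="lgd"), qv("G2", kind="lgd"))])
    score, zone = score_pair(pair, table)
    assert score == 1.0 and zone == "zone999"


def test_score_pair_external_override():
    table = gene_frame([("G1", "1", 1.0, True, True), ("G2", "1", 1.0, True, True)])
    pair = DigenicPair("G1", "G2", "P1", [(qv("G1"), qv("G2"))])
    score, zone = score_pair(pair, table, external_score=0.12)
    assert score == 0.12 and zone == "neutral"


def test_score_pair_uses_best_evidence_couple():
    table = gene_frame([("G1", "1", 1.0, True, True), ("G2", "1", 1.0, True, True)])
    weak = (qv("G1", dann_rank=0.2), qv("G2", dann_rank=0.2))
    strong = (qv("G1", kind="lgd"), qv("G2", kind="lgd"))
    pair = DigenicPair("G1", "G2", "P1", [weak, strong])
    score, _ = score_pair(pair, table)
    assert score == 1.0


# ------------------------------------------------------------- expression
def test_expression_filter():
    table = gene_frame(
        [("G1", "1", 1.0, True, False), ("G2", "1", 1.0, False, True), ("G3", "1", 1.0, False, False)]
    )
    keep = DigenicPair("G1", "G2", "P1", [(qv("G1"), qv("G2"))])
    drop = DigenicPair("G1", "G3", "P1", [(qv("G1"), qv("G3"))])
    assert expression_filter([keep, drop], table) == [keep]
    assert expression_filter([], table) == []


# ------------------------------------------------------------- recurrence
def test_recurrent_pairs_grouping():
    def pair(proband):
        return DigenicPair("IL6ST", "TRPS1", proband, [(qv("IL6ST", carrier=proband), qv("TRPS1", carrier=proband))])

    solo = DigenicPair("AA1", "BB1", "P007", [(qv("AA1", carrier="P007"), qv("BB1", carrier="P007"))])
    recurrent, secondary, carriers = recurrent_pairs([pair("P051"), pair("P093"), solo])
    assert recurrent == [("IL6ST", "TRPS1")]
    assert secondary == [("AA1", "BB1")]
    assert carriers[("IL6ST", "TRPS1")] == ["P051", "P093"]
    assert recurrent_pairs([]) == ([], [], {})


# --------------------------------------------- pipeline-level invariances
def test_independent_filters_commute(default_sim, default_filtered, default_annotations):
    """Applying unaffected-exclusion and expression filtering in either
    order yields the same surviving pair set."""
    filtered, _ = default_filtered
    cfg = ScreenConfig()
    hi = select_hi_genes(default_sim.gene_table, cfg.pli_min)
    pairs = []
    for fam in default_sim.pedigree.families:
        pairs.extend(enumerate_pairs(collect_qualifying(fam.proband_id, filtered, default_annotations, hi, cfg, family=fam), cfg))
    for sid in default_sim.pedigree.singletons:
        pairs.extend(enumerate_pairs(collect_qualifying(sid, filtered, default_annotations, hi, cfg), cfg, require_biparental=False))
    gene_sets = unaffected_gene_sets(filtered, default_annotations, hi, default_sim.pedigree, cfg)

    a = expression_filter(exclude_unaffected_pairs(list(pairs), gene_sets), default_sim.gene_table)
    b = exclude_unaffected_pairs(expression_filter(list(pairs), default_sim.gene_table), gene_sets)
    assert {(p.proband, p.genes) for p in a} == {(p.proband, p.genes) for p in b}


def test_screen_invariant_to_proband_order(small_sim):
    filtered, _ = ts.apply_filters(small_sim.cohort, small_sim.pedigree)
    annots = annotation_map(small_sim)
    ped = small_sim.pedigree
    reversed_ped = ts.Pedigree(
        families=list(reversed(ped.families)),
        singletons=list(reversed(ped.singletons)),
        controls=ped.controls,
    )
    r1 = run_screen(filtered, annots, small_sim.gene_table, ped)
    r2 = run_screen(filtered, annots, small_sim.gene_table, reversed_ped)
    assert r1.recurrent == r2.recurrent
    assert {(p.proband, p.genes) for p in r1.pairs} == {(p.proband, p.genes) for p in r2.pairs}
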