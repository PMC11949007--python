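"""Exome-wide screen for case-specific digenic variant combinations.

The screen models additive haploinsufficiency: a proband carrying one
rare deleterious heterozygous variant in each of two loss-of-function
intolerant genes (pLI > 0.9, autosomal), with the two hits on distinct
parental haplotypes.  Pipeline stages, in order:

1. select the haploinsufficient autosomal gene set;
2. collect qualifying variants per proband (het, MAF < 0.5%, LGD or
   D-mis, gene in the set), with parental origin labels from the trio;
3. enumerate unordered gene pairs, restricting evidence couples to
   biparental origin combinations when trio data exist;
4. exclude pairs whose two genes both carry qualifying variants in any
   single unaffected individual (parent or population control);
5. score each pair with a configurable stand-in combination score and
   assign a pathogenicity zone, or pass through an externally supplied
   score verbatim;
6. require both genes to be brain- or skeletal-expressed;
7. report gene pairs recurring in two or more unrelated probands.

The pair score here is an explicit, clearly labelled stand-in for a
trained combination-pathogenicity predictor, which is an external tool:
score = (mean per-variant deleteriousness of the best evidence couple)
x (mean pLI of the two genes), with LGD variants scored 1.0 and D-mis
variants by their DANN rank score.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotatedVariant, is_dmis, is_lgd, is_rare
from .cohort_io import CohortGenotypes, Family, Pedigree, VariantKey

__all__ = [
    "ScreenConfig",
    "QualifyingVariant",
    "DigenicPair",
    "ScreenResult",
    "select_hi_genes",
    "collect_qualifying",
    "enumerate_pairs",
    "exclude_unaffected_pairs",
    "unaffected_gene_sets",
    "score_pair",
    "expression_filter",
    "recurrent_pairs",
    "run_screen",
]

_AUTOSOMES = {str(i) for i in range(1, 23)}

ZONES = ("neutral", "candidate", "zone99", "zone999")

ORIGINS = ("paternal", "maternal", "denovo", "unknown")


@dataclass
class ScreenConfig:
    """Tunable thresholds of the digenic screen.

    ``zone_cutoffs`` are the lower score bounds of the candidate, 99%- and
    99.9%-confidence zones; a trained external predictor would supply its
    own calibrated boundaries, so these stand-in defaults are explicit
    configuration, not a claim about any published classifier.
    """

    pli_min: float = 0.9  # strict >
    maf_max: float = 0.005  # strict <
    require_biparental: bool = True  # trios only; forced off for proband-only samples
    zone_cutoffs: tuple[float, float, float] = (0.35, 0.60, 0.85)
    expression_required: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_max < 1.0:
            raise ValueError("maf_max must be in (0,1)")
        if list(self.zone_cutoffs) != sorted(self.zone_cutoffs):
            raise ValueError("zone_cutoffs must be ordered")


@dataclass(frozen=True)
class QualifyingVariant:
    """A rare deleterious het variant in a haploinsufficient gene."""

    annotation: AnnotatedVariant
    carrier: str
    origin: str = "unknown"

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def gene(self) -> str:
        return self.annotation.gene.strip().upper()

    @property
    def deleteriousness(self) -> float:
        """Per-variant contribution to the stand-in pair score."""
        if is_lgd(self.annotation):
            return 1.0
        d = self.annotation.dann_rank
        return 0.0 if math.isnan(d) else d


@dataclass
class DigenicPair:
    """Unordered gene pair carried by one proband, with its evidence couples."""

    gene_a: str
    gene_b: str
    proband: str
    evidence: list[tuple[QualifyingVariant, QualifyingVariant]]
    score: float | None = None
    zone: str | None = None
    survived: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("digenic pair requires two distinct genes")
        if self.gene_a > self.gene_b:
            self.gene_a, self.gene_b = self.gene_b, self.gene_a
            self.evidence = [(b, a) for a, b in self.evidence]
        if not self.evidence:
            raise ValueError("digenic pair requires non-empty evidence")

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class ScreenResult:
    pairs: list[DigenicPair]  # pairs surviving every filter
    recurrent: list[tuple[str, str]]  # gene pairs in >= 2 unrelated probands
    secondary: list[tuple[str, str]]  # surviving pairs seen in exactly 1 proband
    stage_counts: dict[str, int]
    carriers: dict[tuple[str, str], list[str]]

    def table(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            rows.append(
                {
                    "proband": p.proband,
                    "gene_a": p.gene_a,
                    "gene_b": p.gene_b,
                    "variants_a": ";".join(sorted({str(a.annotation.key) for a, _ in p.evidence})),
                    "variants_b": ";".join(sorted({str(b.annotation.key) for _, b in p.evidence})),
                    "origins": ";".join(sorted({f"{a.origin}|{b.origin}" for a, b in p.evidence})),
                    "score": p.score,
                    "zone": p.zone,
                    "recurrence": len(self.carriers.get(p.genes, [])),
                }
            )
        return pd.DataFrame(rows, columns=["proband", "gene_a", "gene_b", "variants_a", "variants_b", "origins", "score", "zone", "recurrence"])


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def select_hi_genes(gene_table: pd.DataFrame, pli_min: float = 0.9) -> set[str]:
    """Haploinsufficient autosomal gene set: pLI strictly above ``pli_min``,
    chromosome in 1..22.  Genes without a pLI value are skipped."""
    out: set[str] = set()
    for gene, row in gene_table.iterrows():
        pli = row["pli"]
        if pli is None or (isinstance(pli, float) and math.isnan(pli)):
            continue
        if pli > pli_min and _norm_chrom(str(row["chrom"])) in _AUTOSOMES:
            out.add(str(gene).strip().upper())
    return out


def _site_qualifies(ann: AnnotatedVariant, hi_genes: set[str], config: ScreenConfig) -> bool:
    return (
        ann.gene.strip().upper() in hi_genes
        and is_rare(ann, config.maf_max)
        and (is_lgd(ann) or is_dmis(ann))
    )


def _origin(father_gt: int, mother_gt: int) -> str:
    fa = father_gt >= 1
    mo = mother_gt >= 1
    if father_gt < 0 or mother_gt < 0:
        return "unknown"
    if fa and not mo:
        return "paternal"
    if mo and not fa:
        return "maternal"
    if not fa and not mo:
        return "denovo"
    return "unknown"  # both parents carry; haplotype not resolvable here


def collect_qualifying(
    sample_id: str,
    cohort: CohortGenotypes,
    annotations: Mapping[VariantKey, AnnotatedVariant],
    hi_genes: set[str],
    config: ScreenConfig | None = None,
    family: Family | None = None,
) -> list[QualifyingVariant]:
    """Qualifying variants carried heterozygously by one sample.

    When the sample is a trio proband (``family`` given), origin is read
    off the parental genotypes: carried by exactly one parent -> that
    parent; by neither -> de novo; by both, or parent genotype missing ->
    unknown.
    """
    cfg = config or ScreenConfig()
    j = cohort.sample_index(sample_id)
    jf = cohort.sample_index(family.father_id) if family else None
    jm = cohort.sample_index(family.mother_id) if family else None
    out: list[QualifyingVariant] = []
    for i in np.flatnonzero(cohort.gt[:, j] == 1):
        ann = annotations.get(cohort.keys[i])
        if ann is None or not _site_qualifies(ann, hi_genes, cfg):
            continue
        if family is not None:
            origin = _origin(int(cohort.gt[i, jf]), int(cohort.gt[i, jm]))
        else:
            origin = "unknown"
        out.append(QualifyingVariant(ann, sample_id, origin))
    return out


def _couple_biparental(a: QualifyingVariant, b: QualifyingVariant) -> bool:
    """True when the two variants can sit on haplotypes from both parents.

    A de novo allele occupies one haplotype and can stand in for either
    parental side; unknown origins never satisfy the requirement.
    """
    o = {a.origin, b.origin}
    if "unknown" in o:
        return False
    if a.origin == b.origin and a.origin in ("paternal", "maternal"):
        return False
    return True


def enumerate_pairs(
    qualifying: Sequence[QualifyingVariant],
    config: ScreenConfig | None = None,
    require_biparental: bool | None = None,
) -> list[DigenicPair]:
    """All unordered gene pairs supported by one proband's qualifying variants.

    With the biparental requirement active, evidence couples are limited
    to origin combinations drawing one haplotype from each parent; pairs
    with no surviving couple are dropped.
    """
    cfg = config or ScreenConfig()
    biparental = cfg.require_biparental if require_biparental is None else require_biparental
    if not qualifying:
        return []
    carriers = {q.carrier for q in qualifying}
    if len(carriers) > 1:
        raise ValueError("enumerate_pairs expects variants from a single proband")
    proband = next(iter(carriers))

    by_gene: dict[str, list[QualifyingVariant]] = {}
    for q in qualifying:
        by_gene.setdefault(q.gene, []).append(q)

    pairs: list[DigenicPair] = []
    for ga, gb in itertools.combinations(sorted(by_gene), 2):
        couples = [(a, b) for a in by_gene[ga] for b in by_gene[gb]]
        if biparental:
            couples = [(a, b) for a, b in couples if _couple_biparental(a, b)]
        if couples:
            pair = DigenicPair(ga, gb, proband, couples)
            pair.survived["biparental"] = True
            pairs.append(pair)
    return pairs


def unaffected_gene_sets(
    cohort: CohortGenotypes,
    annotations: Mapping[VariantKey, AnnotatedVariant],
    hi_genes: set[str],
    pedigree: Pedigree,
    config: ScreenConfig | None = None,
) -> dict[str, set[str]]:
    """Genes in which each unaffected individual (parent or control)
    carries at least one qualifying variant, under the same rules as the
    probands (het, rare, LGD/D-mis, haploinsufficient gene)."""
    cfg = config or ScreenConfig()
    out: dict[str, set[str]] = {}
    for sid in pedigree.parents + list(pedigree.controls):
        genes = {q.gene for q in collect_qualifying(sid, cohort, annotations, hi_genes, cfg)}
        if genes:
            out[sid] = genes
    return out


def exclude_unaffected_pairs(
    pairs: Iterable[DigenicPair],
    gene_sets: Mapping[str, set[str]],
) -> list[DigenicPair]:
    """Drop any pair whose two genes both carry qualifying variants in a
    single unaffected individual.

    The exclusion is gene-level (the individual need not carry the same
    variants as the proband) and anti-monotone in the unaffected set:
    adding individuals can only shrink the surviving pairs.
    """
    excluded: set[tuple[str, str]] = set()
    for genes in gene_sets.values():
        if len(genes) >= 2:
            excluded.update(itertools.combinations(sorted(genes), 2))
    out = []
    for p in pairs:
        ok = p.genes not in excluded
        p.survived["control_exclusion"] = ok
        if ok:
            out.append(p)
    return out


def score_pair(
    pair: DigenicPair,
    gene_table: pd.DataFrame,
    config: ScreenConfig | None = None,
    external_score: float | None = None,
) -> tuple[float, str]:
    """Stand-in combination-pathogenicity score and zone for one pair.

    score = mean per-variant deleteriousness of the best evidence couple
    (LGD -> 1.0, D-mis -> DANN rank) times the mean pLI of the two genes.
    An externally supplied score overrides the stand-in verbatim; zones
    are assigned from ``config.zone_cutoffs`` either way.
    """
    cfg = config or ScreenConfig()
    if external_score is not None:
        score = float(external_score)
    else:
        best = max((a.deleteriousness + b.deleteriousness) / 2.0 for a, b in pair.evidence)
        pli_a = float(gene_table.loc[pair.gene_a, "pli"])
        pli_b = float(gene_table.loc[pair.gene_b, "pli"])
        score = best * (pli_a + pli_b) / 2.0
    c1, c2, c3 = cfg.zone_cutoffs
    if score >= c3:
        zone = "zone999"
    elif score >= c2:
        zone = "zone99"
    elif score >= c1:
        zone = "candidate"
    else:
        zone = "neutral"
    pair.score, pair.zone = score, zone
    return score, zone


def expression_filter(pairs: Iterable[DigenicPair], gene_table: pd.DataFrame) -> list[DigenicPair]:
    """Retain pairs whose genes are both brain- or skeletal-expressed."""

    def expressed(gene: str) -> bool:
        if gene not in gene_table.index:
            return False
        row = gene_table.loc[gene]
        return bool(row["brain_expressed"]) or bool(row["skeletal_expressed"])

    out = []
    for p in pairs:
        ok = expressed(p.gene_a) and expressed(p.gene_b)
        p.survived["expression"] = ok
        if ok:
            out.append(p)
    return out


def recurrent_pairs(pairs: Iterable[DigenicPair]) -> tuple[list[tuple[str, str]], list[tuple[str, str]], dict[tuple[str, str], list[str]]]:
    """Group surviving pairs across unrelated probands.

    Returns (recurrent gene pairs carried by >= 2 probands, single-proband
    pairs retained as a secondary tier, carriers per gene pair).
    """
    carriers: dict[tuple[str, str], set[str]] = {}
    for p in pairs:
        carriers.setdefault(p.genes, set()).add(p.proband)
    carrier_lists = {g: sorted(s) for g, s in carriers.items()}
    recurrent = sorted(g for g, s in carrier_lists.items() if len(s) >= 2)
    secondary = sorted(g for g, s in carrier_lists.items() if len(s) == 1)
    return recurrent, secondary, carrier_lists


def run_screen(
    cohort: CohortGenotypes,
    annotations: Mapping[VariantKey, AnnotatedVariant],
    gene_table: pd.DataFrame,
    pedigree: Pedigree,
    config: ScreenConfig | None = None,
    external_scores: Mapping[tuple[str, str], float] | None = None,
) -> ScreenResult:
    """Run the full digenic screen over every proband of the cohort.

    Trio probands pair variants under the biparental-origin rule (when
    ``config.require_biparental``); proband-only samples pair without
    origin restriction, since origin is unknowable without parents.
    Only pairs reaching the highest-confidence zone enter the recurrence
    report.  ``stage_counts`` records the pipeline flow for audit.
    """
    cfg = config or ScreenConfig()
    hi_genes = select_hi_genes(gene_table, cfg.pli_min)

    stage = {"hi_genes": len(hi_genes), "qualifying_variants": 0, "pairs_enumerated": 0}
    all_pairs: list[DigenicPair] = []
    for fam in pedigree.families:
        quals = collect_qualifying(fam.proband_id, cohort, annotations, hi_genes, cfg, family=fam)
        stage["qualifying_variants"] += len(quals)
        all_pairs.extend(enumerate_pairs(quals, cfg, require_biparental=cfg.require_biparental))
    for sid in pedigree.singletons:
        quals = collect_qualifying(sid, cohort, annotations, hi_genes, cfg)
        stage["qualifying_variants"] += len(quals)
        all_pairs.extend(enumerate_pairs(quals, cfg, require_biparental=False))
    stage["pairs_enumerated"] = len(all_pairs)

    gene_sets = unaffected_gene_sets(cohort, annotations, hi_genes, pedigree, cfg)
    surviving = exclude_unaffected_pairs(all_pairs, gene_sets)
    stage["after_unaffected_exclusion"] = len(surviving)

    for p in surviving:
        ext = external_scores.get(p.genes) if external_scores else None
        score_pair(p, gene_table, cfg, external_score=ext)
    top = [p for p in surviving if p.zone == "zone999"]
    for p in surviving:
        p.survived["zone999"] = p.zone == "zone999"
    stage["zone999"] = len(top)

    if cfg.expression_required:
        top = expression_filter(top, gene_table)
    stage["after_expression"] = len(top)

    recurrent, secondary, carrier_lists = recurrent_pairs(top)
    stage["recurrent_pairs"] = len(recurrent)

    return ScreenResult(
        pairs=top,
        recurrent=recurrent,
        secondary=secondary,
        stage_counts=stage,
        carriers=carrier_lists,
    )
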