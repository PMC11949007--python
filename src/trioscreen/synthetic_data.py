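"""Truth-annotated synthetic trio-cohort generator.

Emulates the structure of a trio exome study of a rare craniofacial
disorder: complete proband-parent trios, proband-only samples, and a
larger panel of unrelated population controls, jointly genotyped at
background polymorphic sites plus planted signal:

* de novo coding variants per proband, Poisson-distributed with a
  configurable per-exome rate, SNVs drawn with a configurable
  transition probability;
* case-specific digenic pairs: private rare deleterious missense
  variants in two haploinsufficient genes, transmitted from opposite
  parents in trio probands; decoy pairs additionally planted into
  population controls so the screen's exclusion logic is exercised.

Founder genotypes are drawn in Hardy-Weinberg proportions from per-site
allele frequencies (a rare stratum concentrated below 0.5% plus a
common stratum); trio probands receive Mendelian-transmitted alleles.
GQ/DP/AD are emitted with a simple noise model — binomial allele depths
around the true allele fraction, jittered genotype qualities, sporadic
missing genotypes — calibrated so that planted truths always pass the
default calling thresholds while background genotypes exercise the QC
masks.  A handful of deliberately bad sites (high missingness, a
Hardy-Weinberg-violating site, a non-PASS site) are planted and
recorded in the truth object.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import ANNOTATION_COLUMNS, GENE_TABLE_COLUMNS
from .cohort_io import CohortGenotypes, Family, Pedigree, VariantKey, chrom_sort_key, write_vcf

__all__ = [
    "CLASS_PROPORTIONS",
    "PlantedPairSpec",
    "SimConfig",
    "SimTruth",
    "SimulatedCohort",
    "default_planted_pairs",
    "simulate_gene_panel",
    "simulate_cohort",
    "write_fixture_set",
    "sample_snv_substitutions",
    "load_sim_config",
]

# split of the total de novo rate across consequence classes; the
# protein-altering share dominates, as in exome sequence context models
CLASS_PROPORTIONS = {"synonymous": 0.30, "missense": 0.60, "lgd": 0.10}

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION_PARTNERS = {
    "A": ["C", "T"],
    "G": ["C", "T"],
    "C": ["A", "G"],
    "T": ["A", "G"],
}


@dataclass(frozen=True)
class PlantedPairSpec:
    """One digenic pair to plant.  Gene symbols of None are auto-assigned
    from the simulated haploinsufficient gene set."""

    gene_a: str | None = None
    gene_b: str | None = None
    n_case_probands: int = 2
    also_in_controls: bool = False


def default_planted_pairs() -> list[PlantedPairSpec]:
    """Two case-specific pairs (each in 2 probands) plus one decoy pair
    that is also planted into population controls."""
    return [
        PlantedPairSpec(n_case_probands=2),
        PlantedPairSpec(n_case_probands=2),
        PlantedPairSpec(n_case_probands=2, also_in_controls=True),
    ]


@dataclass
class SimConfig:
    """Study-scale defaults: 52 trios, 69 proband-only samples, 1,048
    population controls; 1.5 de novo coding variants per exome; SNV
    transition probability 0.71."""

    seed: int = 0
    n_trios: int = 52
    n_singletons: int = 69
    n_controls: int = 1048
    n_genes: int = 400
    fraction_hi: float = 0.15  # fraction of genes with pLI > 0.9
    sites_per_gene: int = 3
    common_site_prob: float = 0.10
    common_af_range: tuple[float, float] = (0.05, 0.40)
    rare_af_beta: tuple[float, float] = (0.5, 400.0)
    rare_af_max: float = 0.005
    denovo_rate: float = 1.5
    transition_prob: float = 0.71
    planted_pairs: list[PlantedPairSpec] = field(default_factory=default_planted_pairs)
    mean_dp: float = 45.0
    low_gq_prob: float = 0.03
    missing_gt_prob: float = 0.005
    n_bad_missing_sites: int = 2
    n_bad_hwe_sites: int = 1
    n_nonpass_sites: int = 1

    def __post_init__(self) -> None:
        for name in ("n_trios", "n_singletons", "n_controls", "n_genes", "sites_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fraction_hi", "common_site_prob", "transition_prob", "low_gq_prob", "missing_gt_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


@dataclass
class SimTruth:
    """What was planted, keyed to the emitted records."""

    planted_denovo: list[dict] = field(default_factory=list)
    planted_pairs: list[dict] = field(default_factory=list)
    qc_planted: dict = field(default_factory=dict)
    denovo_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    def denovo_keys(self) -> set[tuple[str, str]]:
        return {(d["proband"], d["variant"]) for d in self.planted_denovo}


@dataclass
class SimulatedCohort:
    config: SimConfig
    cohort: CohortGenotypes
    pedigree: Pedigree
    annotations: pd.DataFrame  # ANNOTATION_COLUMNS, aligned to cohort.keys
    gene_table: pd.DataFrame  # GENE_TABLE_COLUMNS minus 'gene' (index)
    truth: SimTruth


def sample_snv_substitutions(rng: np.random.Generator, n: int, transition_prob: float) -> tuple[np.ndarray, np.ndarray]:
    """Draw n SNV ref/alt base pairs; each substitution is a transition
    (A<->G, C<->T) with probability ``transition_prob``."""
    refs = rng.choice(_BASES, size=n)
    is_ti = rng.random(n) < transition_prob
    alts = np.empty(n, dtype=object)
    tv_pick = rng.integers(0, 2, size=n)
    for i in range(n):
        r = refs[i]
        alts[i] = _TRANSITION_PARTNER[r] if is_ti[i] else _TRANSVERSION_PARTNERS[r][tv_pick[i]]
    return refs.astype(object), alts


def simulate_gene_panel(config: SimConfig) -> pd.DataFrame:
    """Simulate the per-gene info table.

    pLI is bimodal: haploinsufficient genes (the configured fraction)
    draw from (0.905, 0.9999), the rest from a low-skewed beta rescaled
    below 0.9.  Per-gene mutation-rate weights are log-uniform and the
    class rates are normalized so the exome-wide expectation matches the
    configured de novo rate: 2 * sum_g sum_c mu = denovo_rate.
    """
    rng = np.random.default_rng([config.seed, 11])
    n = config.n_genes
    genes = [f"GENE{i + 1:04d}" for i in range(n)]
    chrom_pool = [str(i) for i in range(1, 23)] + ["X"]
    chroms = rng.choice(np.array(chrom_pool, dtype=object), size=n)
    # deterministic per-chromosome layout: one 100 kb block per gene
    counters: dict[str, int] = {}
    starts = np.empty(n, dtype=np.int64)
    for i, c in enumerate(chroms):
        k = counters.get(c, 0)
        starts[i] = 1_000_000 + k * 100_000
        counters[c] = k + 1

    hi = rng.random(n) < config.fraction_hi
    pli = np.where(hi, rng.uniform(0.905, 0.9999, n), rng.beta(0.5, 3.0, n) * 0.89)
    brain = rng.random(n) < 0.65
    skeletal = rng.random(n) < 0.50

    weights = 10.0 ** rng.uniform(-1.0, 1.0, n)
    weights /= weights.sum()
    total_mu = config.denovo_rate / 2.0
    df = pd.DataFrame(
        {
            "gene": genes,
            "chrom": chroms,
            "pli": pli,
            "brain_expressed": brain,
            "skeletal_expressed": skeletal,
            "mu_syn": CLASS_PROPORTIONS["synonymous"] * total_mu * weights,
            "mu_mis": CLASS_PROPORTIONS["missense"] * total_mu * weights,
            "mu_lgd": CLASS_PROPORTIONS["lgd"] * total_mu * weights,
            "tx_start": starts,
        }
    )
    return df.set_index("gene")


@dataclass
class _Site:
    """Assembly record for one variant site before matrix construction."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    pop_af: float
    dann: float
    dann_rank: float
    splice_ada: float
    gt: np.ndarray
    filter_pass: bool = True
    planted: str = ""  # "", "denovo", "pair", "bad_*"
    forced: list[tuple[int, str]] = field(default_factory=list)  # (col, role)

    @property
    def key_str(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def _pick_class(rng: np.random.Generator) -> str:
    r = rng.random()
    acc = 0.0
    for cls, p in CLASS_PROPORTIONS.items():
        acc += p / sum(CLASS_PROPORTIONS.values())
        if r < acc:
            return cls
    return "lgd"


def simulate_cohort(config: SimConfig, panel: pd.DataFrame | None = None) -> SimulatedCohort:
    """Simulate the full cohort; see the module docstring for the model."""
    if panel is None:
        panel = simulate_gene_panel(config)
    rng = np.random.default_rng([config.seed, 23])

    # ---- samples and pedigree -------------------------------------------
    trio_pro = [f"P{i + 1:03d}" for i in range(config.n_trios)]
    fathers = [f"FA{i + 1:03d}" for i in range(config.n_trios)]
    mothers = [f"MO{i + 1:03d}" for i in range(config.n_trios)]
    singles = [f"P{config.n_trios + i + 1:03d}" for i in range(config.n_singletons)]
    controls = [f"C{i + 1:04d}" for i in range(config.n_controls)]
    samples: list[str] = []
    for p, f, m in zip(trio_pro, fathers, mothers):
        samples.extend([p, f, m])
    samples.extend(singles)
    samples.extend(controls)
    col = {s: j for j, s in enumerate(samples)}
    n_samples = len(samples)

    pedigree = Pedigree(
        families=[Family(f"FAM{i + 1:03d}", p, f, m) for i, (p, f, m) in enumerate(zip(trio_pro, fathers, mothers))],
        singletons=singles,
        controls=controls,
    )
    founder_ids = fathers + mothers + singles + controls  # genetically unrelated draws

    genes = list(panel.index)
    gene_chrom = panel["chrom"].to_dict()
    gene_start = panel["tx_start"].to_dict() if "tx_start" in panel.columns else {g: 1_000_000 for g in genes}
    gene_pli = panel["pli"].to_dict()
    pos_cursor = {g: 0 for g in genes}  # extra-site offset counter per gene

    def new_pos(gene: str) -> int:
        pos_cursor[gene] += 1
        return int(gene_start[gene]) + 500 * config.sites_per_gene + 37 * pos_cursor[gene]

    sites: list[_Site] = []

    # ---- background polymorphic sites -----------------------------------
    s0 = config.n_genes * config.sites_per_gene
    site_gene = np.repeat(np.array(genes, dtype=object), config.sites_per_gene)
    offsets = np.tile(np.arange(1, config.sites_per_gene + 1) * 500, config.n_genes)
    positions = np.array([int(gene_start[g]) for g in site_gene]) + offsets

    is_common = rng.random(s0) < config.common_site_prob
    a, b = config.rare_af_beta
    af = rng.beta(a, b, s0)
    resample = af >= config.rare_af_max
    af[resample] = rng.uniform(config.rare_af_max * 0.02, config.rare_af_max * 0.98, resample.sum())
    af = np.maximum(af, 2e-5)
    af[is_common] = rng.uniform(*config.common_af_range, is_common.sum())

    refs, alts = sample_snv_substitutions(rng, s0, config.transition_prob)
    csq = rng.choice(
        np.array(["synonymous", "missense", "inframe", "frameshift", "splice_site", "nonsense", "other"], dtype=object),
        size=s0,
        p=[0.35, 0.45, 0.03, 0.02, 0.05, 0.02, 0.08],
    )
    dann = rng.random(s0)
    dann_rank = rng.random(s0)
    splice_ada = np.where(csq == "splice_site", rng.random(s0), np.nan)

    # founder genotypes in HWE; probands by Mendelian transmission
    founder_cols = np.array([col[s] for s in founder_ids])
    gt_bg = np.zeros((s0, n_samples), dtype=np.int8)
    gt_bg[:, founder_cols] = rng.binomial(2, af[:, None], size=(s0, len(founder_ids))).astype(np.int8)
    for p, f, m in zip(trio_pro, fathers, mothers):
        gf = gt_bg[:, col[f]]
        gm = gt_bg[:, col[m]]
        a_f = (rng.random(s0) < gf / 2.0).astype(np.int8)
        a_m = (rng.random(s0) < gm / 2.0).astype(np.int8)
        gt_bg[:, col[p]] = a_f + a_m

    for i in range(s0):
        sites.append(
            _Site(
                chrom=str(gene_chrom[site_gene[i]]),
                pos=int(positions[i]),
                ref=str(refs[i]),
                alt=str(alts[i]),
                gene=str(site_gene[i]),
                consequence=str(csq[i]),
                pop_af=float(af[i]),
                dann=float(dann[i]),
                dann_rank=float(dann_rank[i]),
                splice_ada=float(splice_ada[i]),
                gt=gt_bg[i],
            )
        )

    truth = SimTruth()

    # ---- planted deliberately-bad sites ---------------------------------
    bg_idx = rng.permutation(s0)
    cursor = 0
    bad_missing = list(bg_idx[cursor : cursor + config.n_bad_missing_sites])
    cursor += config.n_bad_missing_sites
    nonpass = list(bg_idx[cursor : cursor + config.n_nonpass_sites])
    cursor += config.n_nonpass_sites
    common_pool = [i for i in bg_idx[cursor:] if is_common[i]]
    bad_hwe = common_pool[: config.n_bad_hwe_sites]
    for i in bad_hwe:
        sites[i].gt = np.ones(n_samples, dtype=np.int8)  # all-het artifact
        sites[i].planted = "bad_hwe"
    for i in nonpass:
        sites[i].filter_pass = False
        sites[i].planted = "bad_nonpass"
    for i in bad_missing:
        sites[i].planted = "bad_missing"
    truth.qc_planted = {
        "high_missing_sites": [sites[i].key_str for i in bad_missing],
        "hwe_violation_sites": [sites[i].key_str for i in bad_hwe],
        "non_pass_sites": [sites[i].key_str for i in nonpass],
    }

    # ---- de novo variants ------------------------------------------------
    mu_total = (panel["mu_syn"] + panel["mu_mis"] + panel["mu_lgd"]).to_numpy()
    gene_weights = mu_total / mu_total.sum()
    all_probands = trio_pro + singles
    fam_by_pro = {f.proband_id: f for f in pedigree.families}
    dn_counts = rng.poisson(config.denovo_rate, len(all_probands))
    truth.denovo_counts = {p: int(c) for p, c in zip(all_probands, dn_counts)}
    for pid, count in zip(all_probands, dn_counts):
        for _ in range(count):
            gene = str(rng.choice(np.array(genes, dtype=object), p=gene_weights))
            cls = _pick_class(rng)
            if cls == "synonymous":
                csq_dn = "synonymous"
            elif cls == "missense":
                csq_dn = "missense"
            else:
                csq_dn = str(rng.choice(np.array(["nonsense", "frameshift", "splice_site"], dtype=object), p=[0.5, 0.35, 0.15]))
            if csq_dn == "frameshift":
                base = str(rng.choice(_BASES))
                ref_dn, alt_dn = base, base + str(rng.choice(_BASES))
            else:
                r_, a_ = sample_snv_substitutions(rng, 1, config.transition_prob)
                ref_dn, alt_dn = str(r_[0]), str(a_[0])
            gt_row = np.zeros(n_samples, dtype=np.int8)
            gt_row[col[pid]] = 1
            site = _Site(
                chrom=str(gene_chrom[gene]),
                pos=new_pos(gene),
                ref=ref_dn,
                alt=alt_dn,
                gene=gene,
                consequence=csq_dn,
                pop_af=0.0,
                dann=float(rng.random()),
                dann_rank=float(rng.random()),
                splice_ada=float(rng.uniform(0.91, 1.0)) if csq_dn == "splice_site" else math.nan,
                gt=gt_row,
                planted="denovo",
            )
            site.forced.append((col[pid], "het"))
            fam = fam_by_pro.get(pid)
            in_trio = fam is not None
            if in_trio:
                site.forced.append((col[fam.father_id], "parent_ref"))
                site.forced.append((col[fam.mother_id], "parent_ref"))
            sites.append(site)
            truth.planted_denovo.append(
                {"proband": pid, "variant": site.key_str, "gene": gene, "class": cls, "in_trio": in_trio}
            )

    # ---- planted digenic pairs ------------------------------------------
    eligible = [
        g
        for g in genes
        if gene_pli[g] >= 0.95
        and str(gene_chrom[g]) != "X"
        and bool(panel.loc[g, "brain_expressed"] or panel.loc[g, "skeletal_expressed"])
    ]
    rng.shuffle(eligible)
    trio_pool = list(rng.permutation(np.array(trio_pro, dtype=object)))
    single_pool = list(rng.permutation(np.array(singles, dtype=object)))
    control_pool = list(rng.permutation(np.array(controls, dtype=object)))

    def plant_variant(gene: str, carrier_cols: list[tuple[int, str]], ref_cols: tuple[int, ...] = ()) -> _Site:
        r_, a_ = sample_snv_substitutions(rng, 1, config.transition_prob)
        gt_row = np.zeros(n_samples, dtype=np.int8)
        for c, _role in carrier_cols:
            gt_row[c] = 1
        site = _Site(
            chrom=str(gene_chrom[gene]),
            pos=new_pos(gene),
            ref=str(r_[0]),
            alt=str(a_[0]),
            gene=gene,
            consequence="missense",
            pop_af=float(rng.uniform(0.0005, 0.004)),
            dann=float(rng.uniform(0.985, 0.999)),
            dann_rank=float(rng.uniform(0.95, 0.995)),
            splice_ada=math.nan,
            gt=gt_row,
            planted="pair",
        )
        site.forced.extend((c, "het") for c, _role in carrier_cols)
        # the non-transmitting parent must stay cleanly hom-ref so the
        # variant's parental origin is recoverable after QC masking
        site.forced.extend((c, "parent_ref") for c in ref_cols)
        sites.append(site)
        return site

    for spec in config.planted_pairs:
        if spec.gene_a is not None and spec.gene_b is not None:
            ga, gb = spec.gene_a.strip().upper(), spec.gene_b.strip().upper()
            for g in (ga, gb):
                if g not in gene_pli or gene_pli[g] <= 0.9:
                    raise ValueError(f"planted pair gene {g} lacks pLI > 0.9; truth would be unrecoverable")
        else:
            if len(eligible) < 2:
                raise ValueError("not enough eligible haploinsufficient genes to plant pairs")
            ga, gb = eligible.pop(), eligible.pop()

        carriers: list[str] = []
        for k in range(spec.n_case_probands):
            pool = trio_pool if (k % 2 == 0 and trio_pool) else (single_pool or trio_pool)
            if not pool:
                raise ValueError("not enough probands to plant pairs")
            carriers.append(str(pool.pop()))
        pair_variants: dict[str, list[str]] = {}
        for pid in carriers:
            fam = fam_by_pro.get(pid)
            if fam is not None:
                # one variant transmitted from each parent
                pa_gene, ma_gene = (ga, gb) if rng.random() < 0.5 else (gb, ga)
                s1 = plant_variant(pa_gene, [(col[pid], "het"), (col[fam.father_id], "het")], ref_cols=(col[fam.mother_id],))
                s2 = plant_variant(ma_gene, [(col[pid], "het"), (col[fam.mother_id], "het")], ref_cols=(col[fam.father_id],))
            else:
                s1 = plant_variant(ga, [(col[pid], "het")])
                s2 = plant_variant(gb, [(col[pid], "het")])
            pair_variants[pid] = [s1.key_str, s2.key_str]
        control_carriers: list[str] = []
        if spec.also_in_controls:
            for _ in range(2):
                if control_pool:
                    cid = str(control_pool.pop())
                    control_carriers.append(cid)
                    plant_variant(ga, [(col[cid], "het")])
                    plant_variant(gb, [(col[cid], "het")])
        g1, g2 = sorted((ga, gb))
        truth.planted_pairs.append(
            {
                "gene_a": g1,
                "gene_b": g2,
                "probands": sorted(carriers),
                "control_carriers": sorted(control_carriers),
                "also_in_controls": spec.also_in_controls,
                "reportable": (not spec.also_in_controls) and spec.n_case_probands >= 2,
                "variants": pair_variants,
            }
        )

    # ---- assemble matrices and emit read evidence ------------------------
    sites.sort(key=lambda s: (chrom_sort_key(s.chrom), s.pos, s.ref, s.alt))
    n_sites = len(sites)
    gt = np.vstack([s.gt for s in sites])
    dp = rng.poisson(config.mean_dp, (n_sites, n_samples)).astype(np.int32)
    np.maximum(dp, 8, out=dp)
    gq = rng.integers(60, 100, (n_sites, n_samples), dtype=np.int32)
    low = rng.random((n_sites, n_samples)) < config.low_gq_prob
    gq[low] = rng.integers(0, 20, int(low.sum()))
    gt[rng.random((n_sites, n_samples)) < config.missing_gt_prob] = -1

    # high-missingness sites: knock out ~15% of samples
    for i, st in enumerate(sites):
        if st.planted == "bad_missing":
            hit = rng.random(n_samples) < 0.15
            gt[i, hit] = -1

    # allele depths around the true allele fraction; low error on hom calls
    ad_alt = np.zeros((n_sites, n_samples), dtype=np.int32)
    het_mask = gt == 1
    ad_alt[het_mask] = rng.binomial(dp[het_mask], 0.5)
    hom_ref_mask = gt == 0
    ad_alt[hom_ref_mask] = rng.binomial(dp[hom_ref_mask], 0.002)
    hom_alt_mask = gt == 2
    ad_alt[hom_alt_mask] = dp[hom_alt_mask] - rng.binomial(dp[hom_alt_mask], 0.002)
    ad_ref = dp - ad_alt
    ad_ref[gt == -1] = 0
    ad_alt[gt == -1] = 0

    # guarantee quality for planted truths (carriers and trio parents)
    for i, st in enumerate(sites):
        for c, role in st.forced:
            d = int(rng.integers(30, 70))
            dp[i, c] = d
            gq[i, c] = int(rng.integers(62, 99))
            if role == "het":
                gt[i, c] = 1
                alt = int(round(d * rng.uniform(0.42, 0.58)))
                ad_alt[i, c] = alt
                ad_ref[i, c] = d - alt
            else:  # parent_ref: clean homozygous-reference evidence
                gt[i, c] = 0
                ad_alt[i, c] = 0
                ad_ref[i, c] = d

    keys = [VariantKey(s.chrom, s.pos, s.ref, s.alt) for s in sites]
    cohort = CohortGenotypes(
        keys=keys,
        samples=samples,
        gt=gt,
        gq=gq,
        dp=dp,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        filter_pass=np.array([s.filter_pass for s in sites], dtype=bool),
    )
    annotations = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref for s in sites],
            "alt": [s.alt for s in sites],
            "gene": [s.gene for s in sites],
            "consequence": [s.consequence for s in sites],
            "pop_af": [s.pop_af for s in sites],
            "dann": [s.dann for s in sites],
            "dann_rank": [s.dann_rank for s in sites],
            "splice_ada": [s.splice_ada for s in sites],
            "plp_label": ["none"] * n_sites,
        },
        columns=ANNOTATION_COLUMNS,
    )
    gene_table = panel.drop(columns=[c for c in panel.columns if c not in GENE_TABLE_COLUMNS])
    return SimulatedCohort(config, cohort, pedigree, annotations, gene_table, truth)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_ped(pedigree: Pedigree, path: str | Path) -> None:
    lines = []
    for fam in pedigree.families:
        lines.append(f"{fam.family_id}\t{fam.father_id}\t0\t0\t1\t1")
        lines.append(f"{fam.family_id}\t{fam.mother_id}\t0\t0\t2\t1")
        lines.append(f"{fam.family_id}\t{fam.proband_id}\t{fam.father_id}\t{fam.mother_id}\t0\t2")
    for sid in pedigree.singletons:
        lines.append(f"{sid}\t{sid}\t0\t0\t0\t2")
    for sid in pedigree.controls:
        lines.append(f"{sid}\t{sid}\t0\t0\t0\t1")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixture_set(sim: SimulatedCohort, out_dir: str | Path) -> dict[str, str]:
    """Write the fixture files (VCF, PED, annotation/gene TSVs, truth JSON)
    and a manifest of SHA-256 content hashes.  Bit-identical across runs
    with the same configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_vcf(sim.cohort, out / "cohort.vcf")
    write_ped(sim.pedigree, out / "cohort.ped")
    sim.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False, float_format="%.6g")
    gt = sim.gene_table.reset_index()
    gt.to_csv(out / "genes.tsv", sep="\t", index=False, float_format="%.6g", columns=GENE_TABLE_COLUMNS)
    (out / "truth.json").write_text(sim.truth.to_json() + "\n")

    names = ["cohort.vcf", "cohort.ped", "annotations.tsv", "genes.tsv", "truth.json"]
    manifest = {name: _sha256(out / name) for name in names}
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return manifest


def load_sim_config(path: str | Path) -> SimConfig:
    """Parse a flat key = value configuration file mirroring SimConfig.

    Planted pairs use the compact form
    ``planted_pairs = GENEA:GENEB:2:false, :_:2:true`` where an empty or
    ``_`` gene symbol requests auto-assignment.
    """
    kwargs: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"expected 'key = value', got {raw!r}")
        key, value = (t.strip() for t in line.split("=", 1))
        if key == "planted_pairs":
            specs = []
            for chunk in filter(None, (c.strip() for c in value.split(","))):
                parts = [p.strip() for p in chunk.split(":")]
                if len(parts) != 4:
                    raise ValueError(f"planted pair spec needs 4 fields, got {chunk!r}")
                ga = parts[0] if parts[0] not in ("", "_") else None
                gb = parts[1] if parts[1] not in ("", "_") else None
                specs.append(PlantedPairSpec(ga, gb, int(parts[2]), parts[3].lower() == "true"))
            kwargs["planted_pairs"] = specs
            continue
        if key in ("common_af_range", "rare_af_beta"):
            lo, hi = (float(t) for t in value.split())
            kwargs[key] = (lo, hi)
            continue
        if key not in SimConfig.__dataclass_fields__:
            raise ValueError(f"unknown simulation parameter {key!r}")
        field_type = SimConfig.__dataclass_fields__[key].type
        if "int" in str(field_type):
            kwargs[key] = int(value)
        elif "float" in str(field_type):
            kwargs[key] = float(value)
        else:
            kwargs[key] = value
    return SimConfig(**kwargs)
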