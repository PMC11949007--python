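"""Cohort ingestion and quality control for multi-sample exome VCFs.

This module reads a jointly genotyped cohort VCF together with a 6-column
PED pedigree, holds the genotype matrix in memory as numpy arrays, and
applies hard site/genotype filters of the kind used in trio exome studies:
per-genotype GQ/DP minima, allele-balance windows, per-site missingness,
the VCF FILTER column, and a Hardy-Weinberg exact test computed on
founders (parents and unrelated controls).

Genotypes are coded as integers: 0 = hom-ref, 1 = het, 2 = hom-alt,
-1 = missing.  Multiallelic records are split into one biallelic variant
per ALT allele at read time; no further normalization (left-alignment,
trimming) is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "GT_HOM_REF",
    "GT_HET",
    "GT_HOM_ALT",
    "GT_MISSING",
    "VariantKey",
    "GenotypeCall",
    "Family",
    "Pedigree",
    "CohortGenotypes",
    "FilterThresholds",
    "SiteQC",
    "read_ped",
    "read_cohort",
    "write_vcf",
    "allele_balance",
    "hwe_exact_test",
    "apply_filters",
]

GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1

_GT_NAMES = {GT_HOM_REF: "hom_ref", GT_HET: "het", GT_HOM_ALT: "hom_alt", GT_MISSING: "missing"}

# chromosome sort order used by the writers: 1..22, X, Y, MT, then anything else
_CHROM_ORDER = {str(i): i for i in range(1, 23)}
_CHROM_ORDER.update({"X": 23, "Y": 24, "MT": 25, "M": 25})


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (_CHROM_ORDER.get(c, 99), c)


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a biallelic, normalized variant (1-based VCF coordinates)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:  # chrom:pos:ref:alt, used in reports
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one site, with its quality evidence."""

    sample_id: str
    gt: int  # GT_* code
    gq: int
    dp: int
    ad_ref: int
    ad_alt: int

    @property
    def gt_name(self) -> str:
        return _GT_NAMES[self.gt]


@dataclass(frozen=True)
class Family:
    family_id: str
    proband_id: str
    father_id: str
    mother_id: str
    affected: bool = True


@dataclass
class Pedigree:
    """Cohort structure: complete trios, proband-only samples, and controls.

    Controls are unrelated unaffected samples with no family links; parents
    of trios are unaffected but are *not* controls.
    """

    families: list[Family] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)
    controls: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for fam in self.families:
            members = [fam.proband_id, fam.father_id, fam.mother_id]
            if len(set(members)) != len(members):
                raise ValueError(f"sample appears in two roles in family {fam.family_id}")

    @property
    def trio_probands(self) -> list[str]:
        return [f.proband_id for f in self.families]

    @property
    def probands(self) -> list[str]:
        return self.trio_probands + list(self.singletons)

    @property
    def parents(self) -> list[str]:
        out: list[str] = []
        for f in self.families:
            out.extend([f.father_id, f.mother_id])
        return out

    @property
    def founders(self) -> list[str]:
        """Parents plus unrelated controls; used for the HWE site test."""
        return self.parents + list(self.controls)

    def family_of(self, proband_id: str) -> Family | None:
        for f in self.families:
            if f.proband_id == proband_id:
                return f
        return None


def read_ped(ped_path: str | Path, controls_path: str | Path | None = None) -> Pedigree:
    """Parse a standard 6-column PED file.

    Rows with phenotype code 2 are affected probands (a trio if both parent
    ids are non-zero, otherwise a singleton).  Rows with phenotype code 1
    that are never referenced as a parent are unrelated controls; an
    explicit control-ID file overrides that inference.
    """
    rows = []
    with open(ped_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"PED line has fewer than 6 columns: {line!r}")
            rows.append(parts[:6])

    parent_ids = set()
    for fid, iid, pat, mat, sex, pheno in rows:
        if pat != "0":
            parent_ids.add(pat)
        if mat != "0":
            parent_ids.add(mat)

    sample_ids = {r[1] for r in rows}
    families: list[Family] = []
    singletons: list[str] = []
    controls: list[str] = []
    for fid, iid, pat, mat, sex, pheno in rows:
        affected = pheno == "2"
        if affected:
            if pat != "0" and mat != "0":
                for parent in (pat, mat):
                    if parent not in sample_ids:
                        raise ValueError(f"parent {parent} of {iid} missing from PED")
                families.append(Family(fid, iid, pat, mat, affected=True))
            elif pat == "0" and mat == "0":
                singletons.append(iid)
            else:
                raise ValueError(f"proband {iid} has exactly one parent listed; mark both or neither")
        elif iid not in parent_ids and pat == "0" and mat == "0":
            controls.append(iid)

    if controls_path is not None:
        with open(controls_path) as fh:
            controls = [ln.strip() for ln in fh if ln.strip()]
    return Pedigree(families=families, singletons=singletons, controls=controls)


@dataclass
class CohortGenotypes:
    """Site-by-sample genotype matrix with per-genotype quality evidence.

    Arrays are shaped (n_sites, n_samples).  ``gq``/``dp``/``ad_*`` use -1
    for values absent from the VCF.
    """

    keys: list[VariantKey]
    samples: list[str]
    gt: np.ndarray
    gq: np.ndarray
    dp: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    filter_pass: np.ndarray  # (n_sites,) bool

    def __post_init__(self) -> None:
        shape = (len(self.keys), len(self.samples))
        for name in ("gt", "gq", "dp", "ad_ref", "ad_alt"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        self._sample_index = {s: j for j, s in enumerate(self.samples)}

    @property
    def n_sites(self) -> int:
        return len(self.keys)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in cohort") from None

    def call(self, site: int, sample_id: str) -> GenotypeCall:
        j = self.sample_index(sample_id)
        return GenotypeCall(
            sample_id,
            int(self.gt[site, j]),
            int(self.gq[site, j]),
            int(self.dp[site, j]),
            int(self.ad_ref[site, j]),
            int(self.ad_alt[site, j]),
        )

    def subset_sites(self, mask: np.ndarray) -> "CohortGenotypes":
        idx = np.flatnonzero(mask)
        return CohortGenotypes(
            keys=[self.keys[i] for i in idx],
            samples=list(self.samples),
            gt=self.gt[idx].copy(),
            gq=self.gq[idx].copy(),
            dp=self.dp[idx].copy(),
            ad_ref=self.ad_ref[idx].copy(),
            ad_alt=self.ad_alt[idx].copy(),
            filter_pass=self.filter_pass[idx].copy(),
        )

    def copy(self) -> "CohortGenotypes":
        return self.subset_sites(np.ones(self.n_sites, dtype=bool))


def _clean_format(arr, n_samples: int, column: int = 0) -> np.ndarray:
    """Normalize a cyvcf2 FORMAT array to int32 with -1 for missing."""
    if arr is None:
        return np.full(n_samples, -1, dtype=np.int32)
    a = np.asarray(arr)
    if a.ndim == 2:
        a = a[:, column]
    a = a.astype(np.float64)
    a = np.where(np.isnan(a) | (a < 0), -1, a)
    return a.astype(np.int32)


def read_cohort(
    vcf_path: str | Path,
    ped_path: str | Path | None = None,
    controls_path: str | Path | None = None,
    on_missing_format: str = "mask",
) -> tuple[CohortGenotypes, Pedigree | None]:
    """Read a multi-sample VCF (GT:GQ:DP:AD) and its pedigree.

    Multiallelic records are split into one biallelic key per ALT; for a
    split ALT, alleles belonging to *other* ALTs are counted as reference
    and AD is taken from that ALT's own column.

    Parameters
    ----------
    on_missing_format
        ``"mask"``: absent GQ/DP/AD fields become -1 (genotype will fail
        strict AB-dependent filters); ``"error"``: raise on first record
        missing any of GQ/DP/AD.
    """
    if on_missing_format not in ("mask", "error"):
        raise ValueError("on_missing_format must be 'mask' or 'error'")
    ped = read_ped(ped_path, controls_path) if ped_path is not None else None

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    n = len(samples)
    if ped is not None:
        known = set(samples)
        for sid in ped.probands + ped.parents + list(ped.controls):
            if sid not in known:
                raise ValueError(f"PED sample {sid!r} absent from VCF")

    keys: list[VariantKey] = []
    gt_rows, gq_rows, dp_rows, adr_rows, ada_rows, fpass = [], [], [], [], [], []
    for v in vcf:
        alts = v.ALT
        if not alts:
            continue
        gq_arr = v.format("GQ")
        dp_arr = v.format("DP")
        ad_arr = v.format("AD")
        if on_missing_format == "error" and (gq_arr is None or dp_arr is None or ad_arr is None):
            raise ValueError(f"record {v.CHROM}:{v.POS} missing GQ/DP/AD FORMAT field")
        gq = _clean_format(gq_arr, n)
        dp = _clean_format(dp_arr, n)
        is_pass = v.FILTER is None

        if len(alts) == 1:
            gt = np.asarray(v.gt_types, dtype=np.int8)  # gts012: 3 = unknown
            gt = np.where(gt == 3, GT_MISSING, gt).astype(np.int8)
            keys.append(VariantKey(v.CHROM, v.POS, v.REF, alts[0]))
            gt_rows.append(gt)
            gq_rows.append(gq)
            dp_rows.append(dp)
            adr_rows.append(_clean_format(ad_arr, n, 0))
            ada_rows.append(_clean_format(ad_arr, n, 1))
            fpass.append(is_pass)
        else:
            genos = v.genotypes  # [a0, a1, phased] per sample
            a0 = np.array([g[0] for g in genos], dtype=np.int16)
            a1 = np.array([g[1] for g in genos], dtype=np.int16)
            missing = (a0 < 0) | (a1 < 0)
            for k, alt in enumerate(alts):
                count = (a0 == k + 1).astype(np.int8) + (a1 == k + 1).astype(np.int8)
                gt = np.where(missing, GT_MISSING, count).astype(np.int8)
                keys.append(VariantKey(v.CHROM, v.POS, v.REF, alt))
                gt_rows.append(gt)
                gq_rows.append(gq.copy())
                dp_rows.append(dp.copy())
                adr_rows.append(_clean_format(ad_arr, n, 0))
                ada_rows.append(_clean_format(ad_arr, n, k + 1))
                fpass.append(is_pass)

    def stack(rows, dtype):
        if not rows:
            return np.zeros((0, n), dtype=dtype)
        return np.vstack(rows).astype(dtype)

    cohort = CohortGenotypes(
        keys=keys,
        samples=samples,
        gt=stack(gt_rows, np.int8),
        gq=stack(gq_rows, np.int32),
        dp=stack(dp_rows, np.int32),
        ad_ref=stack(adr_rows, np.int32),
        ad_alt=stack(ada_rows, np.int32),
        filter_pass=np.asarray(fpass, dtype=bool),
    )
    return cohort, ped


def write_vcf(cohort: CohortGenotypes, path: str | Path, non_pass_label: str = "LowQual") -> None:
    """Write the cohort as an uncompressed VCF 4.2 file (GT:GQ:DP:AD).

    Output is byte-deterministic for a given cohort: integer fields only,
    sites emitted in stored order.
    """
    chroms: list[str] = []
    for k in cohort.keys:
        if k.chrom not in chroms:
            chroms.append(k.chrom)
    chroms.sort(key=chrom_sort_key)
    lines = ["##fileformat=VCFv4.2", "##source=trioscreen"]
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append(f'##FILTER=<ID={non_pass_label},Description="Failed upstream site filters">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.samples))

    gt_str = {GT_HOM_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1", GT_MISSING: "./."}
    for i, key in enumerate(cohort.keys):
        filt = "PASS" if cohort.filter_pass[i] else non_pass_label
        fields = [key.chrom, str(key.pos), ".", key.ref, key.alt, ".", filt, ".", "GT:GQ:DP:AD"]
        gt = cohort.gt[i]
        gq = cohort.gq[i]
        dp = cohort.dp[i]
        adr = cohort.ad_ref[i]
        ada = cohort.ad_alt[i]
        for j in range(cohort.n_samples):
            g = gt_str[int(gt[j])]
            q = "." if gq[j] < 0 else str(int(gq[j]))
            d = "." if dp[j] < 0 else str(int(dp[j]))
            if adr[j] < 0 or ada[j] < 0:
                ad = "."
            else:
                ad = f"{int(adr[j])},{int(ada[j])}"
            fields.append(f"{g}:{q}:{d}:{ad}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def allele_balance(call: GenotypeCall) -> float | None:
    """Fraction of reads supporting the alternate allele: ad_alt/(ad_ref+ad_alt).

    Returns None when allele depths are absent or sum to zero; callers
    treat None as failing any AB-dependent filter under strict mode.
    """
    if call.ad_ref < 0 or call.ad_alt < 0:
        return None
    total = call.ad_ref + call.ad_alt
    if total == 0:
        return None
    return call.ad_alt / total


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact test on one biallelic site.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    that of the observed configuration (the standard SNP-HWE formulation).
    Extreme departures (e.g. an all-heterozygote common site) return
    p far below 1e-12, the usual exclusion threshold for genotyping
    artifacts.
    """
    for name, v in (("n_hom_ref", n_hom_ref), ("n_het", n_het), ("n_hom_alt", n_hom_alt)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotyped samples")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0

    # Conditional distribution over het counts h (parity fixed by n_rare),
    # built by recurrence outward from an interior starting value.
    h_obs = n_het
    h_vals = list(range(n_rare % 2, n_rare + 1, 2))
    probs = {h: 0.0 for h in h_vals}
    # start near the distributional mode
    h_start = h_vals[min(range(len(h_vals)), key=lambda i: abs(h_vals[i] - n_rare * (2 * n - n_rare) / (2 * n - 1 if n > 0 else 1)))]
    probs[h_start] = 1.0
    # upward: P(h+2) = P(h) * 4*a*c / ((h+1)(h+2)) with a,c the current homs
    h = h_start
    while h + 2 <= n_rare:
        a = (n_rare - h) // 2
        c = n - h - a
        probs[h + 2] = probs[h] * 4.0 * a * c / ((h + 1.0) * (h + 2.0))
        h += 2
    # downward: P(h-2) = P(h) * h(h-1) / (4*(a+1)(c+1))
    h = h_start
    while h - 2 >= h_vals[0]:
        a = (n_rare - h) // 2
        c = n - h - a
        probs[h - 2] = probs[h] * h * (h - 1.0) / (4.0 * (a + 1.0) * (c + 1.0))
        h -= 2
    total = sum(probs.values())
    p_obs = probs[h_obs] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1.0 + 1e-12)) / total
    return min(p, 1.0)


@dataclass
class FilterThresholds:
    """Hard-filter thresholds; defaults follow common trio-exome practice."""

    gq_min: int = 20
    dp_min: int = 20
    missing_max: float = 0.10
    hwe_min: float = 1e-12
    het_ab: tuple[float, float] = (0.3, 0.7)  # strict (open) window
    hom_ab_min: float = 0.98  # strict
    controls_dp_min: int | None = None  # per-genotype DP override for controls
    strict_missing_ad: bool = True  # absent AD on a variant genotype -> masked


@dataclass
class SiteQC:
    missing_rate: float
    hwe_p: float
    filter_field_pass: bool
    dropped_reason: str  # "" if retained


def _mask_genotypes(cohort: CohortGenotypes, pedigree: Pedigree | None, thr: FilterThresholds) -> np.ndarray:
    """Return a masked copy of the GT matrix: failing genotypes become -1."""
    gt = cohort.gt.copy()
    present = gt >= 0

    dp_min = np.full(cohort.n_samples, thr.dp_min, dtype=np.int32)
    if thr.controls_dp_min is not None and pedigree is not None:
        for sid in pedigree.controls:
            dp_min[cohort.sample_index(sid)] = thr.controls_dp_min

    bad = present & ((cohort.gq < thr.gq_min) | (cohort.dp < dp_min[None, :]))

    ad_known = (cohort.ad_ref >= 0) & (cohort.ad_alt >= 0)
    ad_sum = np.where(ad_known, cohort.ad_ref + cohort.ad_alt, 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.where(ad_sum > 0, cohort.ad_alt / np.maximum(ad_sum, 1), np.nan)
    ab_defined = ad_known & (ad_sum > 0)

    lo, hi = thr.het_ab
    het = gt == GT_HET
    hom_alt = gt == GT_HOM_ALT
    bad |= het & ab_defined & ~((ab > lo) & (ab < hi))
    bad |= hom_alt & ab_defined & ~(ab > thr.hom_ab_min)
    if thr.strict_missing_ad:
        bad |= (het | hom_alt) & ~ab_defined

    gt[bad] = GT_MISSING
    return gt


def apply_filters(
    cohort: CohortGenotypes,
    pedigree: Pedigree | None = None,
    thresholds: FilterThresholds | None = None,
) -> tuple[CohortGenotypes, pd.DataFrame]:
    """Apply per-genotype masks and per-site drops; return (filtered cohort, QC report).

    Genotypes failing GQ/DP/AB are masked to missing *before* the per-site
    missing rate is computed.  A site is dropped when its FILTER field is
    not PASS, its missing rate exceeds ``missing_max``, or the founder HWE
    exact test falls below ``hwe_min``.  The operation is idempotent.

    The QC report has one row per input site with columns
    chrom, pos, ref, alt, missing_rate, hwe_p, dropped_reason.
    """
    thr = thresholds or FilterThresholds()
    gt = _mask_genotypes(cohort, pedigree, thr)

    missing_rate = (gt == GT_MISSING).mean(axis=1) if cohort.n_samples else np.zeros(cohort.n_sites)

    if pedigree is not None and pedigree.founders:
        founder_cols = np.array([cohort.sample_index(s) for s in pedigree.founders])
    else:
        founder_cols = np.arange(cohort.n_samples)
    fg = gt[:, founder_cols] if cohort.n_samples else gt
    n_rr = (fg == GT_HOM_REF).sum(axis=1)
    n_ra = (fg == GT_HET).sum(axis=1)
    n_aa = (fg == GT_HOM_ALT).sum(axis=1)
    hwe_p = np.ones(cohort.n_sites)
    for i in range(cohort.n_sites):
        total = n_rr[i] + n_ra[i] + n_aa[i]
        # sites with no genotyped founders carry no HWE evidence
        hwe_p[i] = hwe_exact_test(int(n_rr[i]), int(n_ra[i]), int(n_aa[i])) if total > 0 else 1.0

    reasons = []
    keep = np.ones(cohort.n_sites, dtype=bool)
    for i in range(cohort.n_sites):
        why = []
        if not cohort.filter_pass[i]:
            why.append("filter_field")
        if missing_rate[i] > thr.missing_max:
            why.append("missing_rate")
        if hwe_p[i] < thr.hwe_min:
            why.append("hwe")
        reasons.append(";".join(why))
        keep[i] = not why

    report = pd.DataFrame(
        {
            "chrom": [k.chrom for k in cohort.keys],
            "pos": [k.pos for k in cohort.keys],
            "ref": [k.ref for k in cohort.keys],
            "alt": [k.alt for k in cohort.keys],
            "missing_rate": missing_rate,
            "hwe_p": hwe_p,
            "dropped_reason": reasons,
        }
    )

    masked = CohortGenotypes(
        keys=list(cohort.keys),
        samples=list(cohort.samples),
        gt=gt,
        gq=cohort.gq.copy(),
        dp=cohort.dp.copy(),
        ad_ref=cohort.ad_ref.copy(),
        ad_alt=cohort.ad_alt.copy(),
        filter_pass=cohort.filter_pass.copy(),
    )
    return masked.subset_sites(keep), report
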