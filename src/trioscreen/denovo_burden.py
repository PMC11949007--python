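"""Trio de novo variant identification and mutation-rate burden testing.

De novo candidates are sites where the proband is confidently
heterozygous (GQ >= 60, DP >= 20, allele balance in the closed window
[0.3, 0.7]) while both parents are confidently homozygous reference
(GQ >= 25, DP >= 20, allele balance < 0.03), restricted to alleles with
population frequency below 0.1%.  Burden is assessed against a
per-generation mutation-rate model: with per-gene rates mu for a
consequence class, the expected count over a cohort of trios is

    E[X] = 2 * n_trios * sum_g mu_g(class)

(two transmitted haploid genomes per trio) and the observed count is
compared by the upper-tail Poisson probability P(X >= observed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import AnnotatedVariant
from .cohort_io import CohortGenotypes, Family, GenotypeCall, Pedigree, VariantKey, allele_balance

__all__ = [
    "DeNovoThresholds",
    "TrioGenotype",
    "DeNovoCall",
    "BurdenResult",
    "GofResult",
    "call_denovo",
    "call_denovo_site",
    "mark_confirmed",
    "titv_ratio",
    "burden_test",
    "per_trio_gof",
    "parental_age_association",
    "CLASS_TO_RATE",
]

# burden consequence class -> mutation-rate column of the gene table
CLASS_TO_RATE = {"synonymous": "mu_syn", "missense": "mu_mis", "lgd": "mu_lgd"}


@dataclass
class DeNovoThresholds:
    proband_gq_min: int = 60
    proband_dp_min: int = 20
    proband_ab: tuple[float, float] = (0.3, 0.7)  # closed window
    parent_gq_min: int = 25
    parent_dp_min: int = 20
    parent_ab_max: float = 0.03  # strict
    pop_af_max: float = 0.001  # strict


@dataclass(frozen=True)
class TrioGenotype:
    """Proband/father/mother calls aligned at one variant."""

    key: VariantKey
    proband: GenotypeCall
    father: GenotypeCall
    mother: GenotypeCall


@dataclass
class DeNovoCall:
    key: VariantKey
    proband_id: str
    annotation: AnnotatedVariant
    confirmed: bool = True


@dataclass
class BurdenResult:
    consequence_class: str
    observed: int
    expected: float
    enrichment: float
    p_value: float


@dataclass
class GofResult:
    statistic: float
    dof: int
    p_value: float
    rate: float
    perfect_fit: bool = False


def call_denovo_site(trio: TrioGenotype, pop_af: float, thresholds: DeNovoThresholds | None = None) -> bool:
    """Decide one trio at one site; reference implementation for the matrix path."""
    thr = thresholds or DeNovoThresholds()
    p, fa, mo = trio.proband, trio.father, trio.mother
    if p.gt != 1 or fa.gt != 0 or mo.gt != 0:
        return False
    if p.gq < thr.proband_gq_min or p.dp < thr.proband_dp_min:
        return False
    ab = allele_balance(p)
    if ab is None or not (thr.proband_ab[0] <= ab <= thr.proband_ab[1]):
        return False
    for parent in (fa, mo):
        if parent.gq < thr.parent_gq_min or parent.dp < thr.parent_dp_min:
            return False
        pab = allele_balance(parent)
        if pab is None or not (pab < thr.parent_ab_max):
            return False
    af = 0.0 if math.isnan(pop_af) else pop_af
    return af < thr.pop_af_max


def call_denovo(
    cohort: CohortGenotypes,
    pedigree: Pedigree,
    annotations: Mapping[VariantKey, AnnotatedVariant],
    thresholds: DeNovoThresholds | None = None,
) -> list[DeNovoCall]:
    """Identify de novo variants across all complete trios of the cohort.

    Sites where any trio member's genotype is missing are skipped for that
    trio.  Variants without an annotation row are skipped (no population
    frequency evidence).  Output order follows (site order, family order)
    and is invariant to the ordering of trios in the pedigree.
    """
    thr = thresholds or DeNovoThresholds()
    n_sites = cohort.n_sites
    if n_sites == 0 or not pedigree.families:
        return []

    pop_af = np.zeros(n_sites)
    annotated = np.zeros(n_sites, dtype=bool)
    for i, key in enumerate(cohort.keys):
        ann = annotations.get(key)
        if ann is not None:
            annotated[i] = True
            pop_af[i] = 0.0 if math.isnan(ann.pop_af) else ann.pop_af
    af_ok = annotated & (pop_af < thr.pop_af_max)

    ad_known = (cohort.ad_ref >= 0) & (cohort.ad_alt >= 0)
    ad_sum = cohort.ad_ref + cohort.ad_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.where(ad_known & (ad_sum > 0), cohort.ad_alt / np.maximum(ad_sum, 1), np.nan)

    hits: list[tuple[int, str]] = []  # (site index, proband) gathered per family
    for fam in sorted(pedigree.families, key=lambda f: f.proband_id):
        jp = cohort.sample_index(fam.proband_id)
        jf = cohort.sample_index(fam.father_id)
        jm = cohort.sample_index(fam.mother_id)
        ok = (
            (cohort.gt[:, jp] == 1)
            & (cohort.gt[:, jf] == 0)
            & (cohort.gt[:, jm] == 0)
            & (cohort.gq[:, jp] >= thr.proband_gq_min)
            & (cohort.dp[:, jp] >= thr.proband_dp_min)
            & (ab[:, jp] >= thr.proband_ab[0])
            & (ab[:, jp] <= thr.proband_ab[1])
        )
        for j in (jf, jm):
            ok &= (
                (cohort.gq[:, j] >= thr.parent_gq_min)
                & (cohort.dp[:, j] >= thr.parent_dp_min)
                & (ab[:, j] < thr.parent_ab_max)
            )
        ok &= af_ok
        for i in np.flatnonzero(ok):
            hits.append((int(i), fam.proband_id))

    hits.sort(key=lambda t: (t[0], t[1]))
    return [DeNovoCall(cohort.keys[i], pid, annotations[cohort.keys[i]]) for i, pid in hits]


def mark_confirmed(
    calls: Iterable[DeNovoCall],
    confirmed: set[tuple[str, VariantKey]] | None = None,
) -> list[DeNovoCall]:
    """Apply an external confirmation table (second caller / Sanger hook).

    ``confirmed`` holds (proband_id, key) pairs that validated; when None,
    every call is treated as confirmed (the default when no orthogonal
    evidence is supplied).
    """
    out = []
    for c in calls:
        c.confirmed = True if confirmed is None else (c.proband_id, c.key) in confirmed
        out.append(c)
    return out


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def titv_ratio(calls: Iterable[DeNovoCall | VariantKey]) -> float | None:
    """Transition/transversion ratio over the SNVs in ``calls``.

    Returns None when there are no transversions (ratio undefined).
    """
    ti = tv = 0
    for c in calls:
        key = c.key if isinstance(c, DeNovoCall) else c
        if not key.is_snv:
            continue
        if (key.ref, key.alt) in _TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ti / tv


def burden_test(
    observed: int,
    n_trios: int,
    mu_table: pd.DataFrame,
    consequence_class: str,
    gene_set: Iterable[str] | None = None,
) -> BurdenResult:
    """Poisson burden test of observed de novo counts in one class.

    ``mu_table`` is the per-gene info table (columns mu_syn/mu_mis/mu_lgd,
    indexed by gene).  ``gene_set`` restricts the expectation to a subset
    of genes; default is every gene in the table.
    """
    if consequence_class not in CLASS_TO_RATE:
        raise ValueError(f"consequence_class must be one of {sorted(CLASS_TO_RATE)}")
    rates = mu_table[CLASS_TO_RATE[consequence_class]]
    if gene_set is not None:
        genes = [g.strip().upper() for g in gene_set]
        rates = rates.loc[rates.index.intersection(genes)]
    expected = 2.0 * n_trios * float(rates.sum())

    if expected == 0.0:
        if observed == 0:
            return BurdenResult(consequence_class, 0, 0.0, 0.0, 1.0)
        return BurdenResult(consequence_class, observed, 0.0, math.inf, 0.0)
    enrichment = observed / expected
    # upper tail P(X >= observed); scipy's survival function is evaluated
    # in log space internally and is stable far into the tail
    p = float(stats.poisson.sf(observed - 1, expected))
    p = min(max(p, 0.0), 1.0)
    return BurdenResult(consequence_class, observed, expected, enrichment, p)


def per_trio_gof(counts: Sequence[int]) -> GofResult:
    """Chi-square goodness of fit of per-trio de novo counts to a Poisson law.

    The rate is the sample mean; count bins are pooled from the upper tail
    so every expected bin holds at least 5 trios, and degrees of freedom
    are (bins - 2), one lost to the total and one to the estimated rate.
    A cohort with all-zero counts fits a rate-0 Poisson perfectly.
    """
    counts = np.asarray(list(counts), dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 trios")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    lam = counts.mean()
    if lam == 0.0:
        return GofResult(0.0, 0, 1.0, 0.0, perfect_fit=True)

    n = counts.size
    kmax = int(counts.max())
    raw_exp = n * stats.poisson.pmf(np.arange(kmax + 1), lam)
    raw_exp = np.append(raw_exp, n * stats.poisson.sf(kmax, lam))  # open tail bin
    raw_obs = np.append(np.bincount(counts.astype(int), minlength=kmax + 1), 0)

    # pool from the right until every bin's expectation reaches 5
    exp_bins: list[float] = []
    obs_bins: list[float] = []
    acc_e = acc_o = 0.0
    for e, o in zip(raw_exp[::-1], raw_obs[::-1]):
        acc_e += e
        acc_o += o
        if acc_e >= 5.0:
            exp_bins.append(acc_e)
            obs_bins.append(acc_o)
            acc_e = acc_o = 0.0
    if acc_e > 0 or acc_o > 0:
        if exp_bins:
            exp_bins[-1] += acc_e
            obs_bins[-1] += acc_o
        else:
            exp_bins, obs_bins = [acc_e], [acc_o]
    exp_bins.reverse()
    obs_bins.reverse()

    if len(exp_bins) < 3:  # too few bins to test after estimating the rate
        return GofResult(0.0, 0, 1.0, lam, perfect_fit=True)
    statistic = float(np.sum((np.array(obs_bins) - np.array(exp_bins)) ** 2 / np.array(exp_bins)))
    dof = len(exp_bins) - 2
    p = float(stats.chi2.sf(statistic, dof))
    return GofResult(statistic, dof, p, lam)


def parental_age_association(
    counts_by_proband: Mapping[str, int],
    ages: pd.DataFrame,
) -> dict[str, tuple[float, float]]:
    """Spearman rank correlation of de novo counts against parental ages.

    ``ages`` is indexed by proband with columns ``father_age`` and/or
    ``mother_age``.  Returns {column: (rho, p)}; this is a descriptive
    report, not a model.
    """
    shared = [p for p in counts_by_proband if p in ages.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 probands with ages")
    y = np.array([counts_by_proband[p] for p in shared], dtype=float)
    out: dict[str, tuple[float, float]] = {}
    for col in ("father_age", "mother_age"):
        if col in ages.columns:
            rho, p = stats.spearmanr(ages.loc[shared, col].to_numpy(dtype=float), y)
            out[col] = (float(rho), float(p))
    return out
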