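"""Cohort ingestion, allele balance, HWE exact test, and hard filters."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trioscreen as ts
from trioscreen.cohort_io import (
    FilterThresholds,
    GenotypeCall,
    VariantKey,
    allele_balance,
    apply_filters,
    hwe_exact_test,
    read_cohort,
    read_ped,
    write_vcf,
)

from .conftest import make_cohort


# ---------------------------------------------------------------- oracles
def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Brute-force enumeration over all heterozygote counts conditional on
    the allele counts, via the log-multinomial formula."""
    n = n_hom_ref + n_het + n_hom_alt
    rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if rare == 0:
        return 1.0

    def logprob(h: int) -> float:
        a = (rare - h) // 2
        c = n - h - a
        return (
            math.lgamma(n + 1)
            - math.lgamma(a + 1)
            - math.lgamma(h + 1)
            - math.lgamma(c + 1)
            + h * math.log(2.0)
            + math.lgamma(rare + 1)
            + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )

    hs = list(range(rare % 2, rare + 1, 2))
    ps = [math.exp(logprob(h)) for h in hs]
    total = sum(ps)
    p_obs = ps[hs.index(n_het)] / total
    return min(1.0, sum(p for p in ps if p / total <= p_obs * (1 + 1e-12)) / total)


# ------------------------------------------------------------------- PED
def test_read_ped_roles(tmp_path):
    ped = tmp_path / "c.ped"
    ped.write_text(
        "F1 FA1 0 0 1 1\n"
        "F1 MO1 0 0 2 1\n"
        "F1 P1 FA1 MO1 1 2\n"
        "S1 P2 0 0 0 2\n"
        "C1 C1 0 0 0 1\n"
    )
    out = read_ped(ped)
    assert len(out.families) == 1
    fam = out.families[0]
    assert (fam.proband_id, fam.father_id, fam.mother_id, fam.affected) == ("P1", "FA1", "MO1", True)
    assert out.singletons == ["P2"]
    assert out.controls == ["C1"]  # unaffected, never referenced as parent
    assert out.founders == ["FA1", "MO1", "C1"]


def test_read_ped_rejects_single_parent(tmp_path):
    ped = tmp_path / "c.ped"
    ped.write_text("F1 P1 FA1 0 1 2\n")
    with pytest.raises(ValueError, match="one parent"):
        read_ped(ped)


# ------------------------------------------------------------------- VCF
VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
)


def test_multiallelic_split_conserves_alt_alleles(tmp_path):
    vcf = tmp_path / "m.vcf"
    vcf.write_text(
        VCF_HEADER
        + "1\t100\t.\tG\tA,T\t.\tPASS\t.\tGT:GQ:DP:AD\t0/1:50:30:15,15,0\t0/2:50:30:15,0,15\t1/2:50:30:0,15,15\n"
    )
    cohort, _ = read_cohort(vcf)
    assert [str(k) for k in cohort.keys] == ["1:100:G:A", "1:100:G:T"]
    # allele-count conservation: summed split alt-dosage equals total
    # non-ref allele dosage of the original record (1 + 1 + 2)
    assert int(cohort.gt.clip(min=0).sum()) == 4
    # the 1/2 sample is an alt carrier in both splits
    j = cohort.sample_index("S3")
    assert cohort.gt[0, j] == 1 and cohort.gt[1, j] == 1
    # AD follows each split allele's own column
    assert cohort.ad_alt[0, cohort.sample_index("S1")] == 15
    assert cohort.ad_alt[1, cohort.sample_index("S1")] == 0


def test_empty_vcf_body(tmp_path):
    vcf = tmp_path / "e.vcf"
    vcf.write_text(VCF_HEADER)
    ped = tmp_path / "e.ped"
    ped.write_text("F1 S1 S2 S3 1 2\nF1 S2 0 0 1 1\nF1 S3 0 0 2 1\n")
    cohort, pedigree = read_cohort(vcf, ped)
    assert cohort.n_sites == 0
    assert len(pedigree.families) == 1


def test_ped_sample_absent_from_vcf_is_hard_error(tmp_path):
    vcf = tmp_path / "a.vcf"
    vcf.write_text(VCF_HEADER)
    ped = tmp_path / "a.ped"
    ped.write_text("F1 NOPE S2 S3 1 2\nF1 S2 0 0 1 1\nF1 S3 0 0 2 1\n")
    with pytest.raises(ValueError, match="NOPE"):
        read_cohort(vcf, ped)


def test_vcf_round_trip(tmp_path, small_sim):
    path = tmp_path / "rt.vcf"
    write_vcf(small_sim.cohort, path)
    back, _ = read_cohort(path)
    assert back.keys == small_sim.cohort.keys
    assert back.samples == small_sim.cohort.samples
    np.testing.assert_array_equal(back.gt, small_sim.cohort.gt)
    np.testing.assert_array_equal(back.gq, small_sim.cohort.gq)
    np.testing.assert_array_equal(back.dp, small_sim.cohort.dp)
    np.testing.assert_array_equal(back.ad_ref, small_sim.cohort.ad_ref)
    np.testing.assert_array_equal(back.ad_alt, small_sim.cohort.ad_alt)
    np.testing.assert_array_equal(back.filter_pass, small_sim.cohort.filter_pass)


# --------------------------------------------------------- allele balance
@pytest.mark.parametrize(
    "ad_ref, ad_alt, expected",
    [(5, 5, 0.5), (7, 3, 0.3), (0, 10, 1.0), (0, 0, None), (-1, -1, None)],
)
def test_allele_balance(ad_ref, ad_alt, expected):
    call = GenotypeCall("S", 1, 99, 30, ad_ref, ad_alt)
    assert allele_balance(call) == expected


def test_ab_boundary_fails_strict_het_window():
    """AB exactly 0.3 sits outside the open (0.3, 0.7) window."""
    thr = FilterThresholds()
    assert not (thr.het_ab[0] < 0.3 < thr.het_ab[1])


# ----------------------------------------------------------- HWE exact test
def test_hwe_most_probable_configuration_is_near_one():
    assert hwe_exact_test(25, 50, 25) > 0.9


def test_hwe_all_het_site_is_extreme():
    assert hwe_exact_test(0, 100, 0) < 1e-12


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(50, 0, 0) == 1.0


def test_hwe_requires_genotypes():
    with pytest.raises(ValueError, match="no genotyped samples"):
        hwe_exact_test(0, 0, 0)
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)


@settings(max_examples=300, derandomize=True, deadline=None)
@given(
    n_hom_ref=st.integers(min_value=0, max_value=50),
    n_het=st.integers(min_value=0, max_value=50),
    n_hom_alt=st.integers(min_value=0, max_value=50),
)
def test_hwe_matches_bruteforce_oracle(n_hom_ref, n_het, n_hom_alt):
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0 or n > 50:
        return
    assert hwe_exact_test(n_hom_ref, n_het, n_hom_alt) == pytest.approx(
        hwe_oracle(n_hom_ref, n_het, n_hom_alt), abs=1e-10
    )


# ------------------------------------------------------------ hard filters
def _trio_samples():
    return ["P1", "FA1", "MO1", "C1", "C2", "C3", "C4", "C5", "C6", "C7"]


def _pedigree():
    return ts.Pedigree(
        families=[ts.Family("F1", "P1", "FA1", "MO1")],
        singletons=[],
        controls=[f"C{i}" for i in range(1, 8)],
    )


def test_low_gq_het_is_masked_and_high_quality_hom_alt_retained():
    key1 = VariantKey("1", 100, "A", "G")
    key2 = VariantKey("1", 200, "C", "T")
    cohort = make_cohort(
        _trio_samples(),
        [
            (key1, {"P1": (1, 19, 30, 15, 15)}),  # GQ below 20 -> masked
            (key2, {"P1": (2, 60, 40, 0, 40)}),  # AB 1.0 > 0.98 -> retained
        ],
    )
    filtered, report = apply_filters(cohort, _pedigree())
    j = filtered.sample_index("P1")
    assert filtered.gt[0, j] == -1
    assert filtered.gt[1, j] == 2
    assert list(report.dropped_reason) == ["", ""]


def test_high_missing_rate_drops_site():
    key = VariantKey("1", 100, "A", "G")
    samples = _trio_samples()
    # 2/10 genotypes missing after masking -> 20% > 10%
    cohort = make_cohort(samples, [(key, {"C1": (-1, -1, -1, -1, -1), "C2": (1, 10, 30, 15, 15)})])
    _, report = apply_filters(cohort, _pedigree())
    assert report.dropped_reason[0] == "missing_rate"


def test_hom_alt_ab_boundary():
    """Hom-alt AB must strictly exceed 0.98: 0.98 exactly fails."""
    key = VariantKey("1", 100, "A", "G")
    cohort = make_cohort(_trio_samples(), [(key, {"P1": (2, 60, 50, 1, 49)})])
    filtered, _ = apply_filters(cohort, _pedigree())
    assert filtered.gt[0, filtered.sample_index("P1")] == -1  # 49/50 = 0.98


def test_apply_filters_is_idempotent(small_sim):
    ped = small_sim.pedigree
    once, rep1 = apply_filters(small_sim.cohort, ped)
    twice, rep2 = apply_filters(once, ped)
    assert once.keys == twice.keys
    np.testing.assert_array_equal(once.gt, twice.gt)


def test_masking_monotone_in_thresholds(small_sim):
    """Raising gq_min/dp_min can only mask more genotypes and drop more sites."""
    ped = small_sim.pedigree
    loose, _ = apply_filters(small_sim.cohort, ped, FilterThresholds(gq_min=20, dp_min=20))
    tight, _ = apply_filters(small_sim.cohort, ped, FilterThresholds(gq_min=40, dp_min=30))
    assert set(tight.keys) <= set(loose.keys)
    loose_by_key = {k: loose.gt[i] for i, k in enumerate(loose.keys)}
    for i, k in enumerate(tight.keys):
        was_missing = loose_by_key[k] == -1
        assert np.all(tight.gt[i][was_missing] == -1)


def test_non_pass_filter_field_drops_site():
    key = VariantKey("1", 100, "A", "G")
    cohort = make_cohort(_trio_samples(), [(key, {})])
    cohort.filter_pass[0] = False
    filtered, report = apply_filters(cohort, _pedigree())
    assert filtered.n_sites == 0
    assert report.dropped_reason[0] == "filter_field"
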