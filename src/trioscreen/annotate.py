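"""Functional annotation joins and variant class predicates.

The package consumes a pre-computed per-variant annotation table (gene,
consequence, population allele frequency, DANN missense-deleteriousness
scores, dbscSNV ADA splice score, optional expert P/LP labels) rather
than running an annotator itself.  This module joins that table to
cohort variants on the exact (chrom, pos, ref, alt) key and implements
the deleteriousness classes used downstream:

* LGD (likely gene-disrupting): frameshift, nonsense, or a splice-site
  variant with ADA > 0.9;
* D-mis (deleterious missense): missense with DANN > 0.98;
* rare: population allele frequency strictly below a context-dependent
  cutoff (0.5% for the digenic screen, 0.1% for de novo calling), with
  an absent frequency treated as 0 (allele unseen in the panel).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import VariantKey

__all__ = [
    "CONSEQUENCES",
    "ANNOTATION_COLUMNS",
    "GENE_TABLE_COLUMNS",
    "AnnotatedVariant",
    "load_annotations",
    "load_gene_table",
    "is_lgd",
    "is_dmis",
    "is_rare",
]

logger = logging.getLogger(__name__)

CONSEQUENCES = ("synonymous", "missense", "inframe", "frameshift", "splice_site", "nonsense", "other")

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence",
    "pop_af", "dann", "dann_rank", "splice_ada", "plp_label",
]

GENE_TABLE_COLUMNS = [
    "gene", "chrom", "pli", "brain_expressed", "skeletal_expressed",
    "mu_syn", "mu_mis", "mu_lgd",
]


@dataclass(frozen=True)
class AnnotatedVariant:
    """A normalized variant joined to its functional annotations.

    ``pop_af``/``splice_ada`` use ``nan`` for absent values; ``plp_label``
    is one of {"P", "LP", "none"} and is an input (expert curation), never
    computed here.
    """

    key: VariantKey
    gene: str
    consequence: str
    pop_af: float = math.nan
    dann: float = math.nan
    dann_rank: float = math.nan
    splice_ada: float = math.nan
    plp_label: str = "none"

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r} at {self.key}")
        for name in ("pop_af", "dann", "dann_rank", "splice_ada"):
            v = getattr(self, name)
            if not math.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} out of [0,1] at {self.key}")
        if self.plp_label not in ("P", "LP", "none"):
            raise ValueError(f"plp_label must be P/LP/none, got {self.plp_label!r}")


def _float_or_nan(value, row_label, col) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "" or value == ".":
        return math.nan
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(f"malformed {col} value {value!r} in annotation row {row_label}") from None


def load_annotations(
    tsv_path: str | Path,
    variants: list[VariantKey] | None = None,
) -> tuple[dict[VariantKey, AnnotatedVariant], list[VariantKey]]:
    """Load a per-variant annotation TSV and join it to cohort variants.

    The join is exact on (chrom, pos, ref, alt).  Returns the mapping of
    annotated variants plus the list of cohort variants absent from the
    table (excluded from downstream analyses, reported for audit).
    Duplicate keys in the table are a hard error.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"annotation table missing columns: {missing_cols}")

    table: dict[VariantKey, AnnotatedVariant] = {}
    for row in df.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        if key in table:
            raise ValueError(f"duplicate annotation rows for {key}")
        label = row.plp_label if isinstance(row.plp_label, str) and row.plp_label else "none"
        table[key] = AnnotatedVariant(
            key=key,
            gene=str(row.gene),
            consequence=str(row.consequence),
            pop_af=_float_or_nan(row.pop_af, key, "pop_af"),
            dann=_float_or_nan(row.dann, key, "dann"),
            dann_rank=_float_or_nan(row.dann_rank, key, "dann_rank"),
            splice_ada=_float_or_nan(row.splice_ada, key, "splice_ada"),
            plp_label=label,
        )

    if variants is None:
        return table, []
    unannotated = [k for k in variants if k not in table]
    if unannotated:
        logger.info("%d cohort variants have no annotation row", len(unannotated))
    return table, unannotated


def load_gene_table(tsv_path: str | Path) -> pd.DataFrame:
    """Load the per-gene info table (pLI, expression flags, mutation rates).

    Returns a DataFrame indexed by gene symbol.  Duplicate gene symbols
    are a hard error (symbols on different chromosomes cannot be merged).
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    missing_cols = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"gene table missing columns: {missing_cols}")
    df["gene"] = df["gene"].astype(str).str.strip().str.upper()
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene symbol in gene table: {dup}")
    for col in ("brain_expressed", "skeletal_expressed"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().map({"true": True, "1": True, "false": False, "0": False})
            if df[col].isna().any():
                raise ValueError(f"unparseable boolean in column {col}")
    return df.set_index("gene")


def is_lgd(v: AnnotatedVariant) -> bool:
    """Likely gene-disrupting: frameshift, nonsense, or deleterious splice.

    Splice-site variants qualify only with ADA > 0.9 (strict); a splice
    variant lacking an ADA score is not LGD and is logged.
    """
    if v.consequence in ("frameshift", "nonsense"):
        return True
    if v.consequence == "splice_site":
        if math.isnan(v.splice_ada):
            logger.info("splice_site variant %s lacks ADA score; not LGD", v.key)
            return False
        return v.splice_ada > 0.9
    return False


def is_dmis(v: AnnotatedVariant) -> bool:
    """Deleterious missense: missense consequence with DANN > 0.98 (strict)."""
    return v.consequence == "missense" and not math.isnan(v.dann) and v.dann > 0.98


def is_rare(v: AnnotatedVariant, maf_max: float) -> bool:
    """Population allele frequency strictly below ``maf_max``.

    An absent frequency is treated as 0 (the allele is unseen in the
    reference panel), so the variant counts as rare.
    """
    af = 0.0 if math.isnan(v.pop_af) else v.pop_af
    return af < maf_max
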