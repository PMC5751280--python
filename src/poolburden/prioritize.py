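"""Variant prioritization: coding, non-synonymous, rare, predicted-deleterious.

Filters an annotated variant table down to rare damaging candidates using
two thresholds: a maximum cohort minor-allele frequency (default 1%) and a
minimum scaled CADD deleteriousness score (default 10, the top 10% most
deleterious substitutions genome-wide).  Stop-gain variants qualify
alongside missense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DAMAGING_CONSEQUENCES = frozenset({"nonsynonymous", "stopgain"})
CODING_CONSEQUENCES = frozenset({"nonsynonymous", "stopgain", "synonymous"})

VARIANT_COLUMNS = [
    "chrom", "gene", "pos", "ref", "alt", "rsid", "cdna", "protein",
    "consequence", "cadd", "maf_ctrl", "maf_case",
]


@dataclass
class VariantRecord:
    """One annotated exonic single-nucleotide variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    cadd_scaled: float | None = None
    rsid: str = ""
    cdna_change: str = ""
    protein_change: str = ""
    maf_ctrl: float = 0.0
    maf_case: float = 0.0

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        for maf in (self.maf_ctrl, self.maf_case):
            if not 0.0 <= maf <= 1.0:
                raise ValueError(f"MAF {maf} outside [0, 1]")
        if self.cadd_scaled is not None and self.cadd_scaled < 0:
            raise ValueError("scaled CADD must be >= 0")

    @property
    def is_novel(self) -> bool:
        return self.rsid == ""


@dataclass
class FilterSummary:
    """Counts accumulated while filtering a variant table."""

    n_total: int = 0
    n_coding: int = 0
    n_nonsynonymous: int = 0
    n_retained: int = 0
    n_novel: int = 0
    n_known: int = 0
    n_missing_cadd: int = 0
    n_duplicates_dropped: int = 0
    duplicate_keys: list[tuple] = field(default_factory=list)


def is_rare_damaging(
    v: VariantRecord,
    maf_max: float = 0.01,
    cadd_min: float = 10.0,
) -> bool:
    """True iff the variant is protein-altering, rare in both cohorts, and
    predicted deleterious.

    The MAF gate uses the maximum across cohorts (strictest reading of
    "rare").  A missing CADD score excludes the variant with a warning.
    """
    if v.consequence not in DAMAGING_CONSEQUENCES:
        return False
    if v.cadd_scaled is None or np.isnan(v.cadd_scaled):
        log.warning(
            "variant %s:%s %s>%s has no CADD score; excluded",
            v.chrom, v.pos, v.ref, v.alt,
        )
        return False
    return max(v.maf_ctrl, v.maf_case) < maf_max and v.cadd_scaled >= cadd_min


def _row_to_record(row: pd.Series) -> VariantRecord:
    cadd = row.get("cadd", np.nan)
    return VariantRecord(
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        gene=str(row.get("gene", "")),
        consequence=str(row["consequence"]),
        cadd_scaled=None if pd.isna(cadd) else float(cadd),
        rsid="" if pd.isna(row.get("rsid", "")) else str(row.get("rsid", "")),
        maf_ctrl=0.0 if pd.isna(row.get("maf_ctrl")) else float(row["maf_ctrl"]),
        maf_case=0.0 if pd.isna(row.get("maf_case")) else float(row["maf_case"]),
    )


def filter_table(
    variants: pd.DataFrame,
    maf_max: float = 0.01,
    cadd_min: float = 10.0,
) -> tuple[pd.DataFrame, FilterSummary]:
    """Apply the rare-damaging filter to an annotated variant table.

    Returns the retained rows sorted by (chrom, pos, alt) and a summary.
    Rows that are fully identical are deduplicated with a warning; rows
    sharing a (chrom, pos, ref, alt) key but differing elsewhere (e.g.
    the same site reported once per cohort) are kept and flagged, since
    published variant lists count such rows individually.
    """
    summary = FilterSummary(n_total=len(variants))
    if variants.empty:
        cols = list(variants.columns) if len(variants.columns) else VARIANT_COLUMNS
        return pd.DataFrame(columns=cols), summary

    df = variants.copy()
    exact_dupes = df.duplicated(keep="first")
    if exact_dupes.any():
        summary.n_duplicates_dropped = int(exact_dupes.sum())
        log.warning("dropped %d fully duplicated variant rows", summary.n_duplicates_dropped)
        df = df[~exact_dupes]
    key_dupes = df.duplicated(subset=["chrom", "pos", "ref", "alt"], keep=False)
    if key_dupes.any():
        keys = sorted(
            set(map(tuple, df.loc[key_dupes, ["chrom", "pos", "ref", "alt"]].to_numpy()))
        )
        summary.duplicate_keys = keys
        log.warning("%d variant keys appear in multiple rows: %s", len(keys), keys)

    keep = np.zeros(len(df), dtype=bool)
    for i, (_, row) in enumerate(df.iterrows()):
        rec = _row_to_record(row)
        if rec.consequence in CODING_CONSEQUENCES:
            summary.n_coding += 1
        if rec.consequence in DAMAGING_CONSEQUENCES:
            summary.n_nonsynonymous += 1
        if rec.cadd_scaled is None:
            summary.n_missing_cadd += 1
        keep[i] = is_rare_damaging(rec, maf_max=maf_max, cadd_min=cadd_min)

    retained = df[keep].sort_values(["chrom", "pos", "alt"], kind="stable")
    summary.n_retained = len(retained)
    rsids = retained["rsid"].fillna("") if "rsid" in retained else pd.Series("", index=retained.index)
    summary.n_novel = int((rsids == "").sum())
    summary.n_known = summary.n_retained - summary.n_novel
    return retained.reset_index(drop=True), summary


class RegionAssignmentError(KeyError):
    """A variant's gene has no region and is not on the drop-list."""


DROP_SENTINEL = "."


def assign_regions(
    variants: pd.DataFrame,
    region_map: pd.DataFrame,
) -> pd.DataFrame:
    """Map each variant to exactly one collapsing region via its gene.

    ``region_map`` has columns ``gene`` and ``region``; a region value of
    ``"."`` places the gene on the explicit drop-list (its variants are
    excluded with a log line, e.g. variants that failed downstream assay
    design).  Composite regions (two genes sharing one region name) are
    expressed by mapping both genes to the same region.
    """
    mapping = dict(zip(region_map["gene"], region_map["region"]))
    rows = []
    for _, row in variants.iterrows():
        gene = str(row["gene"])
        if gene not in mapping:
            raise RegionAssignmentError(
                f"gene {gene!r} has no region assignment and is not on the drop-list"
            )
        region = mapping[gene]
        if region == DROP_SENTINEL:
            log.info("variant %s:%s in gene %s dropped (drop-list)", row["chrom"], row["pos"], gene)
            continue
        rows.append({**row.to_dict(), "region": region})
    out = pd.DataFrame(rows, columns=[*variants.columns, "region"])
    return out.reset_index(drop=True)
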