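"""File formats: VCF 4.2 genotypes, BED regions, and the pipeline's TSV schemas.

Coordinates are 1-based inclusive internally (the VCF convention); BED's
0-based half-open intervals are converted at the boundary.  TSV readers
address columns by name, so column order never matters; unknown columns
warn and missing required columns raise.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .containers import COHORTS, GenotypeMatrix, PoolSiteCounts

log = logging.getLogger(__name__)

POOL_COUNT_COLUMNS = [
    "pool_id", "cohort", "n_individuals", "chrom", "pos", "depth",
    "k_minor", "k_other", "variant_id",
]
COHORT_COLUMNS = ["sample_id", "cohort", "comorbid"]


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        log.warning("%s: ignoring unknown columns %s", what, extra)


# ---------------------------------------------------------------------------
# VCF


def _variant_site_frame(g: GenotypeMatrix, variants: pd.DataFrame | None) -> pd.DataFrame:
    if variants is not None:
        v = variants.set_index("variant_id") if "variant_id" in variants else variants
        return v.loc[g.variant_ids, ["chrom", "pos", "ref", "alt"]]
    # synthesise stable placeholder coordinates for simulated variants
    return pd.DataFrame(
        {
            "chrom": "chrS",
            "pos": np.arange(1, len(g.variant_ids) + 1),
            "ref": "A",
            "alt": "C",
        },
        index=pd.Index(g.variant_ids),
    )


def write_genotype_vcf(
    g: GenotypeMatrix,
    path: str | Path,
    variants: pd.DataFrame | None = None,
) -> Path:
    """Write a GT-only VCF 4.2 with one sample column per individual.

    ``variants`` optionally supplies chrom/pos/ref/alt per variant id
    (column ``variant_id``); simulated variants get placeholder
    coordinates.  The variant id is preserved in the VCF ID field.
    """
    path = Path(path)
    sites = _variant_site_frame(g, variants)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for contig in pd.unique(sites["chrom"]):
        header.contigs.add(str(contig), length=2_000_000_000)
    for sid in g.samples.index:
        header.add_sample(str(sid))
    geno = g.genotypes.to_numpy()
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, vid in enumerate(g.variant_ids):
            row = sites.iloc[j]
            rec = vcf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])),
                id=str(vid),
            )
            col = geno[:, j]
            for i, sid in enumerate(g.samples.index):
                gt = int(col[i])
                rec.samples[str(sid)]["GT"] = (
                    (None, None) if gt < 0 else ((0, 0), (0, 1), (1, 1))[gt]
                )
            vcf.write(rec)
    return path


def read_genotype_vcf(path: str | Path, cohorts: pd.DataFrame) -> GenotypeMatrix:
    """Read a GT VCF plus a cohort-assignment table into a GenotypeMatrix.

    ``cohorts`` follows the cohort TSV schema (sample_id, cohort,
    comorbid).  Genotypes are minor-allele dosages; missing calls map
    to -1.
    """
    _check_columns(cohorts, COHORT_COLUMNS, "cohort table")
    cohorts = cohorts.set_index("sample_id")
    variant_ids: list[str] = []
    columns: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        for rec in vcf:
            vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}>{rec.alts[0]}"
            dosages = np.empty(len(sample_ids), dtype=np.int8)
            for i, sid in enumerate(sample_ids):
                gt = rec.samples[sid].get("GT")
                if gt is None or any(a is None for a in gt):
                    dosages[i] = -1
                else:
                    dosages[i] = sum(gt)
            variant_ids.append(vid)
            columns.append(dosages)
    geno = pd.DataFrame(
        dict(zip(variant_ids, columns)),
        index=pd.Index(sample_ids, name="sample_id"),
    )
    samples = cohorts.loc[geno.index, ["cohort", "comorbid"]]
    samples["comorbid"] = samples["comorbid"].astype(bool)
    return GenotypeMatrix(geno, samples)


# ---------------------------------------------------------------------------
# cohort / pool-count / region TSVs


def write_cohort_tsv(g: GenotypeMatrix, path: str | Path) -> Path:
    path = Path(path)
    out = g.samples.reset_index()
    out.columns = COHORT_COLUMNS
    out["comorbid"] = out["comorbid"].astype(int)
    out.to_csv(path, sep="\t", index=False)
    return path


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, COHORT_COLUMNS, str(path))
    df["comorbid"] = df["comorbid"].astype(bool)
    bad = set(df["cohort"]) - set(COHORTS)
    if bad:
        raise ValueError(f"unknown cohort labels in {path}: {sorted(bad)}")
    return df[COHORT_COLUMNS]


def write_pool_counts_tsv(counts: Iterable[PoolSiteCounts], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "pool_id": c.pool_id,
            "cohort": c.cohort,
            "n_individuals": c.n_individuals,
            "chrom": c.chrom,
            "pos": c.pos,
            "depth": c.depth,
            "k_minor": c.k_minor,
            "k_other": c.k_other,
            "variant_id": c.variant_id or "",
        }
        for c in counts
    ]
    pd.DataFrame(rows, columns=POOL_COUNT_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_pool_counts_tsv(path: str | Path) -> list[PoolSiteCounts]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values={"variant_id": []})
    _check_columns(df, POOL_COUNT_COLUMNS, str(path))
    return [
        PoolSiteCounts(
            pool_id=str(r["pool_id"]),
            cohort=str(r["cohort"]),
            n_individuals=int(r["n_individuals"]),
            chrom=str(r["chrom"]),
            pos=int(r["pos"]),
            depth=int(r["depth"]),
            k_minor=int(r["k_minor"]),
            k_other=int(r["k_other"]),
            variant_id=str(r["variant_id"]) or None,
        )
        for _, r in df.iterrows()
    ]


def read_variant_tsv(path: str | Path) -> pd.DataFrame:
    """Annotated variant table in the packaged-table schema."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"rsid": "string", "chrom": "string"},
        keep_default_na=False,
        na_values={"maf_ctrl": [""], "maf_case": [""], "cadd": [""]},
    )
    required = ["chrom", "gene", "pos", "ref", "alt", "consequence", "cadd"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "rsid" in df:
        df["rsid"] = df["rsid"].fillna("")
    else:
        df["rsid"] = ""
    for col in ("maf_ctrl", "maf_case"):
        if col not in df:
            df[col] = np.nan
    return df


def read_region_tsv(path: str | Path) -> pd.DataFrame:
    """Gene-to-region map TSV ('.' region = drop-list)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    _check_columns(df, ["gene", "region"], str(path))
    return df[["gene", "region"]]


# ---------------------------------------------------------------------------
# BED


def read_bed_regions(path: str | Path) -> pd.DataFrame:
    """Read a BED file of regions into 1-based inclusive coordinates.

    BED is 0-based half-open: interval [start, end) becomes 1-based
    positions start+1 .. end.  The optional 4th column is the region name.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            rows.append(
                {
                    "chrom": chrom,
                    "start_1based": start + 1,
                    "end_1based": end,
                    "name": parts[3] if len(parts) > 3 else f"region{lineno}",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start_1based", "end_1based", "name"])
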