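"""Packaged study tables and the carrier-level fixture built from them.

Three small TSVs ship with the package:

* ``rare_damaging_variants.tsv`` — the 38 printed rare, damaging,
  non-synonymous single-nucleotide variants (chrom, gene, position,
  alleles, dbSNP id, cDNA/protein change, scaled CADD, per-cohort MAF).
* ``carrier_counts.tsv`` — per-region carrier counts for the full
  1000-subject analysis and for the subset remaining after excluding
  subjects with cardiac comorbidities.
* ``region_map.tsv`` — gene-to-region assignments for the collapsing
  tests, including composite regions (P2RY1/P2RY12, ITGA2B/ITGB3) and a
  drop-list ("." region) for genes without a tested region.

Individual-level genotypes were not published, so
:func:`build_carrier_genotypes` reconstructs a synthetic genotype matrix
consistent with the printed carrier counts: each carrier is a distinct
individual with exactly one heterozygous genotype at one region variant
(the single-variant-per-carrier assumption), and comorbidity flags are
placed so the subset re-analysis reproduces the subset panel's carrier
counts with 400 controls and 205 cases remaining.
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, GenotypeMatrix

__all__ = [
    "load_variant_table",
    "load_carrier_counts",
    "load_region_map",
    "fixture_region_variants",
    "build_carrier_genotypes",
    "write_fixtures",
]

_DATA_FILES = ("rare_damaging_variants.tsv", "carrier_counts.tsv", "region_map.tsv")

#: Cohort sizes of the genotyped study population.
N_CTRL = 500
N_CASE = 500

#: Remaining cohort sizes after comorbidity exclusion (n = 605 total); the
#: split is chosen to match the printed control-side subset cMAFs
#: (5/400 = 0.0125, 1/400 = 0.0025, 2/400 = 0.005).
N_CTRL_SUBSET = 400
N_CASE_SUBSET = 205


def _data_path(name: str):
    return resources.files("poolburden.data").joinpath(name)


def load_variant_table() -> pd.DataFrame:
    """The packaged rare-damaging variant table (38 rows as printed)."""
    with resources.as_file(_data_path("rare_damaging_variants.tsv")) as p:
        df = pd.read_csv(
            p,
            sep="\t",
            dtype={"rsid": "string", "chrom": "string"},
            keep_default_na=False,
            na_values={"maf_ctrl": [""], "maf_case": [""], "cadd": [""]},
        )
    df["rsid"] = df["rsid"].fillna("")
    df["functional_assay"] = df["functional_assay"].astype(bool)
    return df


def load_carrier_counts() -> pd.DataFrame:
    """Per-region carrier counts (full and comorbidity-excluded panels)."""
    with resources.as_file(_data_path("carrier_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="region")


def load_region_map() -> pd.DataFrame:
    """Gene-to-region map with the explicit drop-list ('.')."""
    with resources.as_file(_data_path("region_map.tsv")) as p:
        return pd.read_csv(p, sep="\t", keep_default_na=False)


def fixture_region_variants() -> dict[str, list[str]]:
    """Unique variant ids per tested region, derived from the packaged
    variant table through the region map (drop-list genes excluded)."""
    variants = load_variant_table()
    region_of = dict(zip(load_region_map()["gene"], load_region_map()["region"]))
    out: dict[str, list[str]] = {}
    seen = set()
    for _, row in variants.iterrows():
        region = region_of[row["gene"]]
        if region == ".":
            continue
        vid = f"{row['chrom']}:{row['pos']}:{row['ref']}>{row['alt']}"
        if vid in seen:
            continue
        seen.add(vid)
        out.setdefault(region, []).append(vid)
    return out


def build_carrier_genotypes() -> GenotypeMatrix:
    """Synthetic genotype matrix reproducing the printed carrier counts.

    Every carrier is a distinct individual with one heterozygous genotype
    at one of its region's variants (assigned round-robin); comorbidity
    flags reproduce the subset panel when flagged subjects are excluded.
    """
    counts = load_carrier_counts()
    region_variants = fixture_region_variants()
    missing = set(counts.index) - set(region_variants)
    if missing:
        raise ValueError(f"regions without variants in the fixture table: {missing}")

    sample_ids = [f"ctrl{i:04d}" for i in range(N_CTRL)] + [
        f"case{i:04d}" for i in range(N_CASE)
    ]
    all_vids = [v for vids in region_variants.values() for v in vids]
    geno = pd.DataFrame(
        np.zeros((N_CTRL + N_CASE, len(all_vids)), dtype=np.int8),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=all_vids,
    )
    comorbid = pd.Series(False, index=geno.index)

    next_free = {CONTROL: 0, CASE: 0}
    offset = {CONTROL: 0, CASE: N_CTRL}
    for region, row in counts.iterrows():
        vids = region_variants[region]
        for cohort, col_full, col_sub in (
            (CONTROL, "carriers_ctrl", "carriers_ctrl_subset"),
            (CASE, "carriers_case", "carriers_case_subset"),
        ):
            n_carriers = int(row[col_full])
            n_kept = int(row[col_sub])
            for j in range(n_carriers):
                sample = sample_ids[offset[cohort] + next_free[cohort]]
                next_free[cohort] += 1
                geno.loc[sample, vids[j % len(vids)]] = 1
                # flag the carriers that disappear in the subset panel
                if j >= n_kept:
                    comorbid.loc[sample] = True

    # top up comorbidity flags among non-carriers to reach the remaining
    # cohort sizes of 400 controls / 205 cases
    for cohort, n_total, n_remaining in (
        (CONTROL, N_CTRL, N_CTRL_SUBSET),
        (CASE, N_CASE, N_CASE_SUBSET),
    ):
        ids = sample_ids[offset[cohort] : offset[cohort] + n_total]
        need = (n_total - n_remaining) - int(comorbid.loc[ids].sum())
        noncarriers = [s for s in reversed(ids) if not comorbid.loc[s] and geno.loc[s].sum() == 0]
        comorbid.loc[noncarriers[:need]] = True

    samples = pd.DataFrame(
        {
            "cohort": [CONTROL] * N_CTRL + [CASE] * N_CASE,
            "comorbid": comorbid,
        },
        index=geno.index,
    )
    return GenotypeMatrix(geno, samples)


def write_fixtures(out_dir: str | Path) -> list[Path]:
    """Copy the packaged study tables into ``out_dir`` (byte-stable)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _DATA_FILES:
        with resources.as_file(_data_path(name)) as src:
            dest = out_dir / name
            shutil.copyfile(src, dest)
            written.append(dest)
    return written
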