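"""Pipeline orchestration: simulate -> pool-call -> prioritize -> burden -> report.

A single YAML config drives the whole run; one root seed feeds every
stochastic stage through deterministically derived substreams, so a rerun
with the same config reproduces every output file byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, fixtures, io, synth
from .burden import BurdenResult, run_burden_analysis, subset_analysis
from .containers import ConfigurationError, GenotypeMatrix
from .poolcall import cohort_site_table
from .prioritize import assign_regions, filter_table

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run.

    ``mode`` selects the input source: ``"fixture"`` runs on the packaged
    study tables; ``"simulate"`` generates a synthetic cohort first;
    ``"files"`` reads a genotype VCF, cohort TSV, variant TSV and region
    map from ``inputs``.
    """

    mode: str = "fixture"
    seed: int = 0
    n_perm: int = 10_000
    alpha: float = 0.05
    maf_max: float = 0.01
    cadd_min: float = 10.0
    min_depth: int = 50
    epsilon: float | str = "auto"
    allele_based_cmaf: bool = False
    combine_rule: str = "sum-counts"
    exclude_comorbid: bool = True
    inputs: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.mode not in ("fixture", "simulate", "files"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if not 0 < self.maf_max <= 1:
            raise ConfigurationError("maf_max must be in (0, 1]")
        if self.cadd_min < 0:
            raise ConfigurationError("cadd_min must be >= 0")
        if self.min_depth < 0:
            raise ConfigurationError("min_depth must be >= 0")
        if self.epsilon != "auto" and not 0 <= float(self.epsilon) < 0.5:
            raise ConfigurationError("epsilon must be 'auto' or in [0, 0.5)")
        if self.combine_rule not in ("sum-counts", "depth-weighted"):
            raise ConfigurationError(f"unknown combine_rule {self.combine_rule!r}")
        if self.mode == "files":
            for key in ("vcf", "cohorts", "variants", "regions"):
                if key not in self.inputs:
                    raise ConfigurationError(f"mode 'files' requires inputs.{key}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def synthetic_annotations(
    g: GenotypeMatrix, truth: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Annotation table for simulated variants in the variant-TSV schema.

    All simulated variants are non-synonymous with scaled CADD drawn
    uniformly in [10, 35]; cohort MAFs are the empirical allele
    frequencies in the simulated genotypes, as an annotation pipeline
    would report them.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    geno = g.genotypes.to_numpy().clip(min=0)
    is_case = (g.samples["cohort"] == "case").to_numpy()
    rows = []
    for j, vid in enumerate(g.variant_ids):
        maf_ctrl = geno[~is_case, j].sum() / (2.0 * max((~is_case).sum(), 1))
        maf_case = geno[is_case, j].sum() / (2.0 * max(is_case.sum(), 1))
        rows.append(
            {
                "chrom": "chrS",
                "gene": truth.loc[truth["variant_id"] == vid, "region"].iloc[0],
                "pos": j + 1,
                "ref": "A",
                "alt": "C",
                "rsid": "",
                "consequence": "nonsynonymous",
                "cadd": round(float(rng.uniform(10, 35)), 2),
                "maf_ctrl": maf_ctrl if maf_ctrl > 0 else np.nan,
                "maf_case": maf_case if maf_case > 0 else np.nan,
                "variant_id": vid,
            }
        )
    return pd.DataFrame(rows)


def _burden_frame(result: BurdenResult) -> pd.DataFrame:
    df = result.to_frame()
    df["cmaf_ctrl"] = df["cmaf_ctrl"].round(6)
    df["cmaf_case"] = df["cmaf_case"].round(6)
    return df


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages and write the report bundle.

    Writes per-stage TSVs plus ``report.json`` with seeds, thresholds,
    input checksums and the software version; returns the report dict.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "inputs"
        },
        "stages": {},
        "input_checksums": {},
    }

    pool_counts = None
    variant_cols_in_matrix = "variant_id"
    if config.mode == "simulate":
        sim_cfg = synth.default_config(seed=config.seed, **config.simulation)
        g, truth = synth.simulate_cohort(sim_cfg)
        pool_counts = synth.simulate_pools(g, sim_cfg)
        variants = synthetic_annotations(g, truth, config.seed)
        region_map = pd.DataFrame(
            {"gene": [r.name for r in sim_cfg.regions],
             "region": [r.name for r in sim_cfg.regions]}
        )
        io.write_genotype_vcf(g, out / "genotypes.vcf", variants)
        io.write_cohort_tsv(g, out / "cohorts.tsv")
        io.write_pool_counts_tsv(pool_counts, out / "pool_counts.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        report["stages"]["simulate"] = {
            "n_ctrl": sim_cfg.n_ctrl, "n_case": sim_cfg.n_case,
            "n_variants": len(g.variant_ids), "seed": sim_cfg.seed,
        }
    elif config.mode == "fixture":
        g = fixtures.build_carrier_genotypes()
        variants = fixtures.load_variant_table()
        variants = variants.assign(
            variant_id=[
                f"{r.chrom}:{r.pos}:{r.ref}>{r.alt}" for r in variants.itertuples()
            ]
        )
        region_map = fixtures.load_region_map()
    else:
        for key, path in config.inputs.items():
            report["input_checksums"][key] = _sha256(Path(path))
        cohorts = io.read_cohort_tsv(config.inputs["cohorts"])
        g = io.read_genotype_vcf(config.inputs["vcf"], cohorts)
        variants = io.read_variant_tsv(config.inputs["variants"])
        if "variant_id" not in variants:
            variants = variants.assign(
                variant_id=[
                    f"{r.chrom}:{r.pos}:{r.ref}>{r.alt}" for r in variants.itertuples()
                ]
            )
        region_map = io.read_region_tsv(config.inputs["regions"])
        if "pool_counts" in config.inputs:
            pool_counts = io.read_pool_counts_tsv(config.inputs["pool_counts"])

    if pool_counts is not None:
        site_table = cohort_site_table(
            pool_counts,
            eps=config.epsilon,
            min_depth_per_pool=config.min_depth,
            rule=config.combine_rule,
        )
        site_table.to_csv(out / "pooled_maf.tsv", sep="\t", index=False, float_format="%.8g")
        report["stages"]["poolcall"] = {
            "n_sites": int(site_table[["chrom", "pos"]].drop_duplicates().shape[0]),
            "epsilon": float(site_table["epsilon"].iloc[0]),
        }

    retained, summary = filter_table(variants, maf_max=config.maf_max, cadd_min=config.cadd_min)
    assigned = assign_regions(retained, region_map)
    retained.drop(columns=["variant_id"], errors="ignore").to_csv(
        out / "retained_variants.tsv", sep="\t", index=False
    )
    report["stages"]["prioritize"] = {
        "n_total": summary.n_total,
        "n_retained": summary.n_retained,
        "n_novel": summary.n_novel,
        "maf_max": config.maf_max,
        "cadd_min": config.cadd_min,
    }

    regions: dict[str, list[str]] = {}
    for _, row in assigned.iterrows():
        vid = row[variant_cols_in_matrix]
        if vid in g.genotypes.columns and vid not in regions.get(row["region"], ()):
            regions.setdefault(row["region"], []).append(vid)
    if not regions:
        raise ConfigurationError("no retained variant is present in the genotype matrix")

    full = run_burden_analysis(
        g, regions,
        n_perm=config.n_perm, seed=config.seed, alpha=config.alpha,
        allele_based_cmaf=config.allele_based_cmaf,
    )
    _burden_frame(full).to_csv(out / "burden_full.tsv", sep="\t", index=False, float_format="%.6g")
    report["stages"]["burden"] = {
        "n_regions": full.n_regions,
        "bonferroni_alpha": full.bonferroni_alpha,
        "n_perm": config.n_perm,
        "seed": config.seed,
        "total_carriers_ctrl": full.total.carriers_ctrl,
        "total_carriers_case": full.total.carriers_case,
        "total_p": full.total.p_value,
    }

    if config.exclude_comorbid:
        sub = subset_analysis(
            g, regions,
            n_perm=config.n_perm, seed=config.seed, alpha=config.alpha,
            allele_based_cmaf=config.allele_based_cmaf,
        )
        _burden_frame(sub).to_csv(out / "burden_subset.tsv", sep="\t", index=False, float_format="%.6g")
        report["stages"]["burden_subset"] = {
            "n_ctrl": sub.n_ctrl,
            "n_case": sub.n_case,
            "total_carriers_ctrl": sub.total.carriers_ctrl,
            "total_carriers_case": sub.total.carriers_case,
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
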