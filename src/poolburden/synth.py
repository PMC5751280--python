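"""Synthetic case-control cohorts and pooled read counts.

Generates genotype matrices with the structure the burden analysis
assumes — independent rare variants, heterozygous carriers, a causal
region whose carrier probability is enriched in cases through an odds
ratio — and pooled sequencing read counts over those genotypes with a
symmetric per-read miscall model.

The default design mirrors a pooled re-sequencing case-control study:
500 cases and 500 controls, 5 pools of 100 per cohort, mean 120x depth
per individual, carrier frequencies of 1/500 to 10/500 per variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    CASE,
    CONTROL,
    ConfigurationError,
    GenotypeMatrix,
    PoolSiteCounts,
    RegionSpec,
    SimulationConfig,
)

__all__ = ["default_config", "simulate_cohort", "simulate_pools", "region_variant_map"]

#: Carrier frequencies above this are no longer forced heterozygous;
#: genotypes are drawn from Hardy-Weinberg proportions instead.
HET_ONLY_MAX_FREQ = 0.1


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The study-design default: 10 regions over 26 genes' worth of
    variants, carrier frequencies spanning 1/500 to 10/500, comorbidity
    prevalences leaving ~605 of 1000 after exclusion."""
    regions = overrides.get("regions", [RegionSpec(f"R{i:02d}", 4) for i in range(10)])
    if "carrier_freqs" in overrides:
        freqs = overrides["carrier_freqs"]
    else:
        # deterministic spread of carrier frequencies across the rare range
        freqs = {
            r.name: list(np.linspace(1, 10, r.n_variants) / 500.0) for r in regions
        }
    cfg = dict(
        n_ctrl=500,
        n_case=500,
        regions=regions,
        carrier_freqs=freqs,
        causal_region=None,
        carrier_or=1.0,
        # control group enriched for cardiac comorbidity relative to cases;
        # together these exclude ~395/1000 subjects
        comorbidity_prev_ctrl=0.49,
        comorbidity_prev_case=0.30,
        pools_per_cohort=5,
        individuals_per_pool=100,
        mean_depth=120.0,
        error_rate=0.001,
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def _case_freq(f_ctrl: float, carrier_or: float) -> float:
    """Carrier probability in cases from the control probability and a
    carrier odds ratio: odds_case = OR * odds_ctrl."""
    if f_ctrl in (0.0, 1.0) or carrier_or == 1.0:
        return f_ctrl if carrier_or > 0 else 0.0
    odds = carrier_or * f_ctrl / (1.0 - f_ctrl)
    return odds / (1.0 + odds)


def region_variant_map(config: SimulationConfig) -> dict[str, list[str]]:
    """Variant ids per region, as laid out by :func:`simulate_cohort`."""
    out: dict[str, list[str]] = {}
    for region_spec in config.regions:
        freqs = config.carrier_freqs.get(region_spec.name)
        n_var = len(freqs) if freqs else region_spec.n_variants
        out[region_spec.name] = [f"{region_spec.name}:v{j}" for j in range(n_var)]
    return out


def _draw_genotypes(rng, n: int, carrier_freq: float, allow_hom: bool) -> np.ndarray:
    """Genotypes for one variant in one cohort.

    Rare variants (carrier frequency <= 0.1) yield heterozygous carriers
    only.  Commoner variants — or ``allow_hom`` — draw from Hardy-Weinberg
    proportions with the allele frequency q solving 1-(1-q)^2 = f.
    """
    if carrier_freq <= HET_ONLY_MAX_FREQ and not allow_hom:
        return rng.binomial(1, carrier_freq, size=n).astype(np.int8)
    q = 1.0 - np.sqrt(max(1.0 - carrier_freq, 0.0))
    return rng.binomial(2, q, size=n).astype(np.int8)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate case/control genotypes plus a per-variant truth table.

    Variants are independent; each individual carries 0/1/2 copies drawn
    with a cohort-specific carrier probability.  In the causal region the
    case probability is the control probability pushed through the
    configured carrier odds ratio.  Returns the genotype matrix and a
    truth table with the generating carrier frequencies per cohort.
    """
    if not config.regions:
        raise ConfigurationError("simulation needs at least one region")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_ctrl, n_case = config.n_ctrl, config.n_case
    sample_ids = [f"ctrl{i:04d}" for i in range(n_ctrl)] + [
        f"case{i:04d}" for i in range(n_case)
    ]
    cohorts = [CONTROL] * n_ctrl + [CASE] * n_case

    cols: dict[str, np.ndarray] = {}
    truth_rows = []
    for region_spec in config.regions:
        freqs = config.carrier_freqs.get(region_spec.name)
        if freqs is None:
            freqs = [2.0 / max(n_ctrl, 1)] * region_spec.n_variants
        causal = region_spec.name == config.causal_region
        for j, f_ctrl in enumerate(freqs):
            f_case = _case_freq(f_ctrl, config.carrier_or) if causal else f_ctrl
            vid = f"{region_spec.name}:v{j}"
            g_ctrl = _draw_genotypes(rng, n_ctrl, f_ctrl, config.allow_homozygotes)
            g_case = _draw_genotypes(rng, n_case, f_case, config.allow_homozygotes)
            cols[vid] = np.concatenate([g_ctrl, g_case])
            truth_rows.append(
                {
                    "variant_id": vid,
                    "region": region_spec.name,
                    "carrier_freq_ctrl": f_ctrl,
                    "carrier_freq_case": f_case,
                    "causal": causal,
                }
            )

    comorbid = np.concatenate(
        [
            rng.random(n_ctrl) < config.comorbidity_prev_ctrl,
            rng.random(n_case) < config.comorbidity_prev_case,
        ]
    )
    genotypes = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))
    samples = pd.DataFrame(
        {"cohort": cohorts, "comorbid": comorbid},
        index=genotypes.index,
    )
    truth = pd.DataFrame(truth_rows)
    return GenotypeMatrix(genotypes, samples), truth


def _pool_assignment(config: SimulationConfig, n: int, rng, cohort: str) -> np.ndarray:
    idx = np.arange(n)
    if config.randomize_pools:
        rng.shuffle(idx)
    return idx.reshape(config.pools_per_cohort, config.individuals_per_pool)


def simulate_pools(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    positions: pd.DataFrame | None = None,
) -> list[PoolSiteCounts]:
    """Pooled read counts per pool x site over simulated genotypes.

    Depth per pool-site is Poisson (or negative binomial when
    ``depth_dispersion`` is set) with mean individuals_per_pool x
    mean_depth.  Reads are multinomial: minor with probability
    phi(p) = p(1-eps) + (1-p)eps where p is the true pool frequency,
    third-allele (non-ref non-alt) with probability (2/3)eps — the share
    of miscalls landing on the two observable error bases — and major
    otherwise, so counts sum exactly to the depth.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    eps = config.error_rate
    out: list[PoolSiteCounts] = []
    variant_ids = genotypes.variant_ids
    if positions is None:
        positions = pd.DataFrame(
            {"chrom": "chrS", "pos": np.arange(1, len(variant_ids) + 1)},
            index=variant_ids,
        )
    mean_pool_depth = config.individuals_per_pool * config.mean_depth
    for cohort in (CONTROL, CASE):
        cohort_idx = genotypes.cohort_index(cohort)
        if len(cohort_idx) == 0:
            continue
        geno = genotypes.genotypes.loc[cohort_idx].to_numpy()
        geno = np.where(geno < 0, 0, geno)
        assignment = _pool_assignment(config, len(cohort_idx), rng, cohort)
        for pool_no, members in enumerate(assignment):
            if len(members) == 0:
                raise ValueError("empty pool")
            pool_geno = geno[members]
            p_true = pool_geno.sum(axis=0) / (2.0 * len(members))
            if config.depth_dispersion:
                r = config.depth_dispersion
                depths = rng.negative_binomial(
                    r, r / (r + mean_pool_depth), size=len(variant_ids)
                )
            else:
                depths = rng.poisson(mean_pool_depth, size=len(variant_ids))
            phi = p_true * (1 - eps) + (1 - p_true) * eps
            p_other = (2.0 / 3.0) * eps * np.ones_like(phi)
            probs = np.stack([phi, p_other, 1.0 - phi - p_other], axis=1)
            for s, vid in enumerate(variant_ids):
                k_minor, k_other, _ = rng.multinomial(depths[s], probs[s])
                out.append(
                    PoolSiteCounts(
                        pool_id=f"{cohort}_pool{pool_no}",
                        cohort=cohort,
                        n_individuals=len(members),
                        chrom=str(positions.loc[vid, "chrom"]),
                        pos=int(positions.loc[vid, "pos"]),
                        depth=int(depths[s]),
                        k_minor=int(k_minor),
                        k_other=int(k_other),
                        variant_id=vid,
                    )
                )
    return out
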