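"""Core in-memory containers shared across the pipeline stages.

The pipeline moves three kinds of data around: per-individual genotypes
with cohort labels (``GenotypeMatrix``), per-pool per-site read counts
(``PoolSiteCounts``), and the simulation configuration that generates
both (``SimulationConfig``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"
COHORTS = (CONTROL, CASE)


class ConfigurationError(ValueError):
    """Raised when a configuration or its cross-field invariants are invalid."""


@dataclass
class RegionSpec:
    """A named gene region with a fixed number of simulated variants."""

    name: str
    n_variants: int

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ConfigurationError(f"region {self.name!r} needs >= 1 variant")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic case-control pooled-sequencing design.

    Defaults mirror the study design this package emulates: two cohorts of
    500 individuals, each sequenced as 5 pools of 100, with a mean
    per-individual depth of 120x and rare heterozygous carriers at
    frequencies of 1/500 to 10/500 per variant.
    """

    n_ctrl: int = 500
    n_case: int = 500
    regions: list[RegionSpec] = field(default_factory=list)
    carrier_freqs: dict[str, list[float]] = field(default_factory=dict)
    causal_region: str | None = None
    carrier_or: float = 1.0
    comorbidity_prev_ctrl: float = 0.0
    comorbidity_prev_case: float = 0.0
    pools_per_cohort: int = 5
    individuals_per_pool: int = 100
    mean_depth: float = 120.0
    depth_dispersion: float | None = None  # None => Poisson depth
    error_rate: float = 0.001
    allow_homozygotes: bool = False
    randomize_pools: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for label, frac in (
            ("comorbidity_prev_ctrl", self.comorbidity_prev_ctrl),
            ("comorbidity_prev_case", self.comorbidity_prev_case),
            ("error_rate", self.error_rate),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{label}={frac} outside [0, 1]")
        if self.carrier_or < 0:
            raise ConfigurationError("carrier_or must be >= 0")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be > 0")
        for cohort_n in (self.n_ctrl, self.n_case):
            if self.pools_per_cohort * self.individuals_per_pool != cohort_n:
                raise ConfigurationError(
                    "pools_per_cohort * individuals_per_pool must equal the "
                    f"cohort size (got {self.pools_per_cohort} x "
                    f"{self.individuals_per_pool} vs {cohort_n})"
                )
        region_names = [r.name for r in self.regions]
        if len(set(region_names)) != len(region_names):
            raise ConfigurationError("duplicate region names")
        if self.causal_region is not None and self.causal_region not in region_names:
            raise ConfigurationError(
                f"causal_region {self.causal_region!r} not among regions"
            )
        for name, freqs in self.carrier_freqs.items():
            if name not in region_names:
                raise ConfigurationError(f"carrier_freqs for unknown region {name!r}")
            for f in freqs:
                if not 0.0 <= f <= 1.0:
                    raise ConfigurationError(f"carrier frequency {f} outside [0, 1]")


@dataclass
class GenotypeMatrix:
    """Individuals x variants genotype matrix with cohort/comorbidity labels.

    ``genotypes`` is a DataFrame indexed by sample id with one integer
    column per variant id; values are 0/1/2 copies of the minor allele,
    with -1 encoding a missing genotype.  ``samples`` is indexed the same
    way and carries ``cohort`` (control/case) and boolean ``comorbid``.
    """

    genotypes: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.genotypes.index.equals(self.samples.index):
            raise ValueError("genotypes and samples must share one sample index")
        bad = set(self.samples["cohort"].unique()) - set(COHORTS)
        if bad:
            raise ValueError(f"unknown cohort labels: {sorted(bad)}")
        vals = self.genotypes.to_numpy()
        if vals.size and not np.isin(vals, (-1, 0, 1, 2)).all():
            raise ValueError("genotypes must be in {0, 1, 2} or -1 for missing")
        if "comorbid" not in self.samples.columns:
            self.samples = self.samples.assign(comorbid=False)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    def cohort_index(self, cohort: str) -> pd.Index:
        if cohort not in COHORTS:
            raise ValueError(f"unknown cohort {cohort!r}")
        return self.samples.index[self.samples["cohort"] == cohort]

    def n_in_cohort(self, cohort: str) -> int:
        return int((self.samples["cohort"] == cohort).sum())

    def subset_samples(self, index: pd.Index) -> "GenotypeMatrix":
        return GenotypeMatrix(self.genotypes.loc[index], self.samples.loc[index])


@dataclass
class PoolSiteCounts:
    """Read counts for one pool at one site.

    ``k_minor`` counts reads supporting the minor (alt) allele, ``k_other``
    reads supporting neither ref nor alt (the third-allele error channel
    used to estimate the per-read miscall rate).
    """

    pool_id: str
    cohort: str
    n_individuals: int
    chrom: str
    pos: int
    depth: int
    k_minor: int
    k_other: int = 0
    variant_id: str | None = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.depth < 0 or self.k_minor < 0 or self.k_other < 0:
            raise ValueError("counts must be nonnegative")
        if self.k_minor + self.k_other > self.depth:
            raise ValueError("k_minor + k_other exceeds depth")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
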