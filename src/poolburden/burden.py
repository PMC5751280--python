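"""Gene-region collapsing (burden) association tests for rare variants.

A region's rare-variant burden in a cohort is summarised by its carrier
count (individuals with at least one minor allele at any region variant)
and the carrier-based cumulative MAF, cMAF = carriers / cohort size.

Region-level significance uses the cumulative minor-allele test (CMAT): the
region's variants are collapsed into pooled minor/major allele counts per
cohort, the Pearson chi-squared of that 2x2 allele table is the statistic,
and its null distribution is obtained by permuting case/control labels over
individuals.  Regions where only one cohort carries any variant fall back
to Fisher's exact test on the carrier table; the study-wide totals row uses
Pearson's chi-squared on summed carrier counts plus a carrier odds ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CASE, CONTROL, GenotypeMatrix

log = logging.getLogger(__name__)

#: Tie tolerance when comparing permuted statistics with the observed one.
TIE_TOL = 1e-12

PLOIDY = 2


@dataclass
class CmatCounts:
    """Weighted collapsed minor/major allele counts for one region."""

    m_case: float
    M_case: float
    m_ctrl: float
    M_ctrl: float
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if min(self.m_case, self.M_case, self.m_ctrl, self.M_ctrl) < 0:
            raise ValueError("allele counts must be nonnegative")


@dataclass
class BurdenRow:
    """Per-region burden result mirroring one row of the association table."""

    region: str
    carriers_ctrl: int
    carriers_case: int
    cmaf_ctrl: float
    cmaf_case: float
    method: str  # "CMAT" | "Fisher" | "NA"
    p_value: float  # NaN when method == "NA"
    n_perm: int = 0
    seed: int | None = None
    or_point: float = math.nan
    or_low: float = math.nan
    or_high: float = math.nan


@dataclass
class BurdenResult:
    """Full burden table: per-region rows plus the totals row."""

    rows: list[BurdenRow]
    total: BurdenRow
    n_ctrl: int
    n_case: int
    bonferroni_alpha: float
    n_regions: int

    def to_frame(self) -> pd.DataFrame:
        records = [vars(r) for r in self.rows] + [vars(self.total)]
        return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# carrier counting and cMAF


def carriers(
    g: GenotypeMatrix,
    region_variants: Sequence[str],
    cohort: str,
) -> int:
    """Individuals in a cohort with >= 1 minor allele at >= 1 region variant.

    Missing genotypes (-1) count as reference; the missingness rate is
    logged when nonzero.
    """
    missing_ids = [v for v in region_variants if v not in g.genotypes.columns]
    if missing_ids:
        raise KeyError(f"region variants not in genotype matrix: {missing_ids}")
    sub = g.genotypes.loc[g.cohort_index(cohort), list(region_variants)]
    vals = sub.to_numpy()
    n_missing = int((vals == -1).sum())
    if n_missing:
        log.info(
            "%.2f%% missing genotypes treated as reference in cohort %s",
            100.0 * n_missing / vals.size, cohort,
        )
    return int(((vals >= 1).any(axis=1)).sum())


def cmaf(carrier_count: int, cohort_size: int, *, allele_based: bool = False) -> float:
    """Cumulative MAF of a region: carriers / cohort size.

    The carrier-based convention matches published per-region tables
    (e.g. 10 carriers among 500 -> 0.02).  ``allele_based`` divides by
    chromosomes (2n) instead, the convention used in power calculations.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    if not 0 <= carrier_count <= cohort_size:
        raise ValueError("carrier_count outside [0, cohort_size]")
    denom = PLOIDY * cohort_size if allele_based else cohort_size
    return carrier_count / denom


# ---------------------------------------------------------------------------
# 2x2 tests (scipy-backed) and odds ratios


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on a 2x2 table.

    Rows are groups, columns outcome (e.g. carriers/non-carriers x
    cohorts).  A zero margin makes the statistic undefined; callers should
    use Fisher's exact test for such tables.
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("cell counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin: use fisher_exact_2x2 for this table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    tables no more likely than the observed one (degenerate tables -> 1)."""
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("cell counts must be nonnegative")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def odds_ratio_carriers(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Carrier odds ratio with a 95% Woolf confidence interval.

    Cells: case carriers ``a``, case non-carriers ``b``, control carriers
    ``c``, control non-carriers ``d``.  Any zero cell triggers the
    Haldane-Anscombe +0.5 correction on all four cells.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if 0 in (a, b, c, d) else (a, b, c, d)
    orr = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return orr, orr * math.exp(-1.959963984540054 * se), orr * math.exp(1.959963984540054 * se)


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise significance threshold alpha/m for m tested regions."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# CMAT


def cmat_statistic(counts: CmatCounts) -> float:
    """CMAT collapsing statistic: Pearson chi-squared of the pooled
    minor/major x case/control allele table built from weighted counts.

    X^2 = N * (m_case*M_ctrl - m_ctrl*M_case)^2
          / ((m_case+M_case)(m_ctrl+M_ctrl)(m_case+m_ctrl)(M_case+M_ctrl))

    Returns 0 for degenerate tables (no minor or no major alleles).
    """
    m1, M1, m0, M0 = counts.m_case, counts.M_case, counts.m_ctrl, counts.M_ctrl
    N = m1 + M1 + m0 + M0
    denom = (m1 + M1) * (m0 + M0) * (m1 + m0) * (M1 + M0)
    if denom == 0:
        return 0.0
    return N * (m1 * M0 - m0 * M1) ** 2 / denom


def _collapsed_allele_counts(
    g: GenotypeMatrix,
    region_variants: Sequence[str],
    weights: np.ndarray | None = None,
    *,
    complete_case: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual weighted (minor, major) allele counts over a region.

    Missing genotypes contribute 0 minor / 2 major alleles by default; in
    ``complete_case`` mode a missing genotype contributes to neither count
    for that variant.
    """
    geno = g.genotypes[list(region_variants)].to_numpy(dtype=float)
    missing = geno < 0
    w = np.ones(geno.shape[1]) if weights is None else np.asarray(weights, dtype=float)
    if w.shape[0] != geno.shape[1]:
        raise ValueError("one weight per region variant required")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    geno = np.where(missing, 0.0, geno)
    major = PLOIDY - g.genotypes[list(region_variants)].to_numpy(dtype=float)
    major = np.where(missing, 0.0 if complete_case else float(PLOIDY), major)
    m_i = geno @ w
    M_i = major @ w
    return m_i, M_i


def cmat_counts_for_region(
    g: GenotypeMatrix,
    region_variants: Sequence[str],
    weights: np.ndarray | None = None,
    *,
    complete_case: bool = False,
) -> CmatCounts:
    """Collapse a region's genotypes into per-cohort CMAT allele counts."""
    m_i, M_i = _collapsed_allele_counts(g, region_variants, weights, complete_case=complete_case)
    is_case = (g.samples["cohort"] == CASE).to_numpy()
    return CmatCounts(
        m_case=float(m_i[is_case].sum()),
        M_case=float(M_i[is_case].sum()),
        m_ctrl=float(m_i[~is_case].sum()),
        M_ctrl=float(M_i[~is_case].sum()),
    )


def cmat_permutation_p(
    g: GenotypeMatrix,
    region_variants: Sequence[str],
    n_perm: int = 10_000,
    seed: int | None = None,
    weights: np.ndarray | None = None,
    *,
    complete_case: bool = False,
    chunk: int = 2_000,
) -> tuple[float, dict]:
    """Permutation p-value for the CMAT statistic of one region.

    Case/control labels are shuffled over individuals (cohort sizes
    preserved; within-individual multi-variant structure kept intact) and
    the statistic recomputed each time.  The add-one estimator
    p = (1 + #{permuted >= observed}) / (1 + n_perm) is used, so p = 0 is
    impossible and ties (within 1e-12) count against the observed value.
    """
    if n_perm < 100:
        log.warning("n_perm=%d is very small; permutation p will be coarse", n_perm)
    n_case = g.n_in_cohort(CASE)
    n_ctrl = g.n_in_cohort(CONTROL)
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both cohorts must be nonempty")
    m_i, M_i = _collapsed_allele_counts(g, region_variants, weights, complete_case=complete_case)
    if m_i.sum() == 0:
        raise ValueError("region has no minor alleles; burden test not applicable")
    is_case = (g.samples["cohort"] == CASE).to_numpy()
    m_tot, M_tot = m_i.sum(), M_i.sum()

    def stat(mc: np.ndarray, Mc: np.ndarray) -> np.ndarray:
        m1, M1 = mc, Mc
        m0, M0 = m_tot - mc, M_tot - Mc
        N = m_tot + M_tot
        denom = (m1 + M1) * (m0 + M0) * (m1 + m0) * (M1 + M0)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = N * (m1 * M0 - m0 * M1) ** 2 / denom
        return np.where(denom == 0, 0.0, s)

    observed = float(stat(np.array([m_i[is_case].sum()]), np.array([M_i[is_case].sum()]))[0])

    rng = np.random.default_rng(seed)
    n = len(m_i)
    n_ge = 0
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # each row of `order` is an independent uniform permutation of samples
        order = np.argsort(rng.random((b, n)), axis=1)[:, :n_case]
        mc = m_i[order].sum(axis=1)
        Mc = M_i[order].sum(axis=1)
        n_ge += int((stat(mc, Mc) >= observed - TIE_TOL).sum())
        done += b
    p = (1 + n_ge) / (1 + n_perm)
    diagnostics = {
        "statistic": observed,
        "n_perm": n_perm,
        "n_ge": n_ge,
        "seed": seed,
        "n_case": n_case,
        "n_ctrl": n_ctrl,
    }
    return p, diagnostics


# ---------------------------------------------------------------------------
# full analysis


def _total_row(
    name: str,
    carr_ctrl: int,
    carr_case: int,
    n_ctrl: int,
    n_case: int,
    *,
    allele_based: bool = False,
) -> BurdenRow:
    row = BurdenRow(
        region=name,
        carriers_ctrl=carr_ctrl,
        carriers_case=carr_case,
        cmaf_ctrl=cmaf(min(carr_ctrl, n_ctrl), n_ctrl, allele_based=allele_based),
        cmaf_case=cmaf(min(carr_case, n_case), n_case, allele_based=allele_based),
        method="chi2",
        p_value=math.nan,
    )
    if carr_ctrl == 0 and carr_case == 0:
        row.method = "NA"
        row.p_value = 1.0
        return row
    try:
        _, row.p_value = pearson_chi2_2x2(
            carr_ctrl, n_ctrl - carr_ctrl, carr_case, n_case - carr_case
        )
    except ValueError:
        row.method = "Fisher"
        row.p_value = fisher_exact_2x2(
            carr_ctrl, n_ctrl - carr_ctrl, carr_case, n_case - carr_case
        )
    row.or_point, row.or_low, row.or_high = odds_ratio_carriers(
        carr_case, n_case - carr_case, carr_ctrl, n_ctrl - carr_ctrl
    )
    return row


def run_burden_analysis(
    g: GenotypeMatrix,
    regions: Mapping[str, Sequence[str]],
    *,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    allele_based_cmaf: bool = False,
    complete_case: bool = False,
) -> BurdenResult:
    """Per-region burden table plus totals row.

    Method selection per region: CMAT permutation when both cohorts have
    carriers; Fisher exact on the carrier table when exactly one cohort
    has carriers; NA when neither.  All p-values are raw; the Bonferroni
    threshold alpha/#regions is reported alongside.
    """
    if not regions:
        raise ValueError("empty region set")
    n_ctrl = g.n_in_cohort(CONTROL)
    n_case = g.n_in_cohort(CASE)
    if n_ctrl == 0 or n_case == 0:
        raise ValueError("both cohorts must be nonempty")

    seed_seq = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    rows: list[BurdenRow] = []
    for region_name in regions:
        variant_ids = regions[region_name]
        c_ctrl = carriers(g, variant_ids, CONTROL)
        c_case = carriers(g, variant_ids, CASE)
        row = BurdenRow(
            region=region_name,
            carriers_ctrl=c_ctrl,
            carriers_case=c_case,
            cmaf_ctrl=cmaf(c_ctrl, n_ctrl, allele_based=allele_based_cmaf),
            cmaf_case=cmaf(c_case, n_case, allele_based=allele_based_cmaf),
            method="NA",
            p_value=math.nan,
        )
        region_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
        if c_ctrl > 0 and c_case > 0:
            row.method = "CMAT"
            row.p_value, diag = cmat_permutation_p(
                g, variant_ids, n_perm=n_perm, seed=region_seed,
                complete_case=complete_case,
            )
            row.n_perm = n_perm
            row.seed = region_seed
        elif c_ctrl > 0 or c_case > 0:
            row.method = "Fisher"
            row.p_value = fisher_exact_2x2(
                c_ctrl, n_ctrl - c_ctrl, c_case, n_case - c_case
            )
        if c_ctrl > 0 or c_case > 0:
            row.or_point, row.or_low, row.or_high = odds_ratio_carriers(
                c_case, n_case - c_case, c_ctrl, n_ctrl - c_ctrl
            )
        rows.append(row)

    total = _total_row(
        "Total",
        sum(r.carriers_ctrl for r in rows),
        sum(r.carriers_case for r in rows),
        n_ctrl,
        n_case,
        allele_based=allele_based_cmaf,
    )
    return BurdenResult(
        rows=rows,
        total=total,
        n_ctrl=n_ctrl,
        n_case=n_case,
        bonferroni_alpha=bonferroni_threshold(alpha, len(regions)),
        n_regions=len(regions),
    )


def subset_analysis(
    g: GenotypeMatrix,
    regions: Mapping[str, Sequence[str]],
    **kwargs,
) -> BurdenResult:
    """Re-run the burden analysis after excluding comorbid individuals.

    Drops every sample whose ``comorbid`` flag is set (in both cohorts) and
    reruns :func:`run_burden_analysis` on the remainder.
    """
    keep = ~g.samples["comorbid"].astype(bool)
    sub = g.subset_samples(g.samples.index[keep])
    if sub.n_in_cohort(CONTROL) == 0 or sub.n_in_cohort(CASE) == 0:
        raise ValueError("comorbidity exclusion emptied a cohort")
    return run_burden_analysis(sub, regions, **kwargs)
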