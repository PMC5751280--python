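"""Allele-frequency estimation from pooled read counts with a sequencing-error model.

Each read at a site is modelled as showing the minor allele with probability

    phi(p) = p * (1 - eps) + (1 - p) * eps

where ``p`` is the true pool minor-allele frequency and ``eps`` the per-read
miscall probability.  Inverting the read fraction gives the closed-form
maximum-likelihood estimate

    p_hat = (k/n - eps) / (1 - 2*eps),   clamped to [0, 1],

and a likelihood-ratio statistic Lambda = 2*(l(p_hat) - l(0)) tests the
null of monomorphism (p = 0) at the site.  The null sits on the boundary
of the parameter space, so referring Lambda to chi-squared(1) is
conservative (the exact null is a 50:50 mixture of a point mass at 0 and
chi-squared(1)); the plain chi-squared(1) p-value is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .containers import CASE, COHORTS, CONTROL, PoolSiteCounts

__all__ = [
    "PoolMafEstimate",
    "estimate_error_rate",
    "estimate_pool_maf",
    "lrt_polymorphism",
    "combine_pools",
    "min_detectable_cmaf",
]

#: Reads at the two non-ref non-alt bases observe 2 of the 3 possible
#: miscall outcomes; the 3/2 factor rescales their rate to the total
#: per-read miscall probability.
ERROR_CHANNEL_FACTOR = 1.5

#: Upper clamp for the estimated error rate.
MAX_ERROR_RATE = 0.25


@dataclass
class PoolMafEstimate:
    """MLE of a pool's minor-allele frequency plus the monomorphism LRT."""

    p_hat: float
    epsilon: float
    loglik_alt: float
    loglik_null: float
    lam: float
    p_lrt: float

    @property
    def polymorphic(self) -> bool:
        return self.p_hat > 0


def _phi(p: float, eps: float) -> float:
    return p * (1.0 - eps) + (1.0 - p) * eps


def estimate_error_rate(counts: Iterable[PoolSiteCounts]) -> float:
    """Estimate the per-read miscall rate from third-allele read counts.

    eps = (sum k_other / sum depth) * 3/2, clamped to [0, 0.25].  Sites
    carrying genuine minor alleles do not bias the estimate because only
    the non-ref non-alt channel is counted.
    """
    total_other = 0
    total_depth = 0
    for c in counts:
        total_other += c.k_other
        total_depth += c.depth
    if total_depth == 0:
        raise ValueError("cannot estimate error rate from zero total depth")
    eps = (total_other / total_depth) * ERROR_CHANNEL_FACTOR
    return min(max(eps, 0.0), MAX_ERROR_RATE)


def _check_kn_eps(k: int, n: int, eps: float) -> None:
    if n <= 0:
        raise ValueError("depth n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not 0.0 <= eps < 0.5:
        raise ValueError(f"error rate {eps} must lie in [0, 0.5) to be identifiable")


def estimate_pool_maf(
    k: int,
    n: int,
    eps: float = 0.0,
    *,
    n_individuals: int | None = None,
    round_to_chromosomes: bool = False,
) -> float:
    """Closed-form MLE of the pool minor-allele frequency.

    With ``round_to_chromosomes`` the estimate is snapped to the nearest
    multiple of 1/(2*n_individuals), the granularity an actual pool of
    diploid individuals can realise (off by default).
    """
    _check_kn_eps(k, n, eps)
    p_hat = (k / n - eps) / (1.0 - 2.0 * eps)
    p_hat = min(max(p_hat, 0.0), 1.0)
    if round_to_chromosomes:
        if not n_individuals:
            raise ValueError("round_to_chromosomes requires n_individuals")
        step = 1.0 / (2 * n_individuals)
        p_hat = round(p_hat / step) * step
    return p_hat


def _loglik(k: int, n: int, p: float, eps: float) -> float:
    """Binomial log-likelihood of k minor reads in n at frequency p (up to the constant binomial term)."""
    phi = _phi(p, eps)
    if phi == 0.0:
        return 0.0 if k == 0 else -math.inf
    if phi == 1.0:
        return 0.0 if k == n else -math.inf
    return k * math.log(phi) + (n - k) * math.log1p(-phi)


def lrt_polymorphism(k: int, n: int, eps: float = 0.0) -> PoolMafEstimate:
    """Likelihood-ratio test of monomorphism (p = 0) at one site.

    Returns the full estimate record.  When eps = 0 and k > 0 the null
    likelihood is zero, so Lambda = +inf and p = 0 by convention.
    """
    _check_kn_eps(k, n, eps)
    p_hat = estimate_pool_maf(k, n, eps)
    ll_alt = _loglik(k, n, p_hat, eps)
    ll_null = _loglik(k, n, 0.0, eps)
    if math.isinf(ll_null):
        return PoolMafEstimate(p_hat, eps, ll_alt, ll_null, math.inf, 0.0)
    lam = max(2.0 * (ll_alt - ll_null), 0.0)
    p_lrt = float(stats.chi2.sf(lam, df=1)) if lam > 0 else 1.0
    return PoolMafEstimate(p_hat, eps, ll_alt, ll_null, lam, p_lrt)


def combine_pools(
    pools: Sequence[PoolSiteCounts],
    cohort: str,
    eps: float = 0.0,
    *,
    rule: str = "sum-counts",
    min_depth_per_pool: int = 0,
) -> PoolMafEstimate:
    """Per-cohort MAF at one site from that cohort's pools.

    The default rule sums read counts across pools before estimation,
    equivalent to treating the cohort as one large pool.  The alternative
    ``"depth-weighted"`` rule estimates per pool and averages with depth
    weights.  Pools below ``min_depth_per_pool`` are excluded as
    low-coverage.
    """
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    if not pools:
        raise ValueError("no pools supplied")
    cohorts_seen = {p.cohort for p in pools}
    if cohorts_seen != {cohort}:
        raise ValueError(
            f"pools from cohorts {sorted(cohorts_seen)} passed for cohort {cohort!r}"
        )
    kept = [p for p in pools if p.depth >= min_depth_per_pool]
    if not kept:
        raise ValueError("all pools below the low-coverage floor")
    if rule == "sum-counts":
        k = sum(p.k_minor for p in kept)
        n = sum(p.depth for p in kept)
        return lrt_polymorphism(k, n, eps)
    if rule == "depth-weighted":
        weights = np.array([p.depth for p in kept], dtype=float)
        phats = np.array(
            [estimate_pool_maf(p.k_minor, p.depth, eps) for p in kept]
        )
        p_bar = float(np.average(phats, weights=weights))
        # LRT still computed on the pooled counts; only p_hat is averaged.
        k = sum(p.k_minor for p in kept)
        n = sum(p.depth for p in kept)
        est = lrt_polymorphism(k, n, eps)
        return PoolMafEstimate(p_bar, eps, est.loglik_alt, est.loglik_null, est.lam, est.p_lrt)
    raise ValueError(f"unknown combination rule {rule!r}")


def min_detectable_cmaf(n_individuals: int) -> float:
    """Smallest reliably detectable cumulative MAF for a pooled cohort.

    Near-certain detection of a rare signal needs about 10 minor alleles
    among the 2*n sampled chromosomes, i.e. 10/(2n) (1% for a cohort of
    500), capped at 1.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    return min(10.0 / (2 * n_individuals), 1.0)


def cohort_site_table(
    counts: Sequence[PoolSiteCounts],
    eps: float | str = "auto",
    *,
    min_depth_per_pool: int = 50,
    rule: str = "sum-counts",
) -> "pd.DataFrame":
    """Per-site, per-cohort frequency estimates from a batch of pool counts.

    ``eps="auto"`` estimates a shared error rate from the third-allele
    channel of all pools first.  Pools below the low-coverage floor are
    excluded per site; sites losing every pool of a cohort are flagged.
    Returns one row per (chrom, pos, cohort) with p_hat, the monomorphism
    LRT, and a flags column.
    """
    import pandas as pd  # local import keeps module import light

    if not counts:
        raise ValueError("no pool counts supplied")
    eps_val = estimate_error_rate(counts) if eps == "auto" else float(eps)
    rows = []
    by_site: dict[tuple, dict[str, list[PoolSiteCounts]]] = {}
    for c in counts:
        by_site.setdefault((c.chrom, c.pos, c.variant_id), {}).setdefault(c.cohort, []).append(c)
    for (chrom, pos, vid), cohorts in sorted(by_site.items(), key=lambda t: (t[0][0], t[0][1])):
        for cohort, pools in sorted(cohorts.items()):
            usable = [p for p in pools if p.depth >= min_depth_per_pool]
            flags = []
            if len(usable) < len(pools):
                flags.append("low_coverage_pools")
            if not usable:
                rows.append(
                    {
                        "chrom": chrom, "pos": pos, "variant_id": vid, "cohort": cohort,
                        "p_hat": float("nan"), "lam": float("nan"),
                        "p_lrt": float("nan"), "epsilon": eps_val,
                        "flags": "no_usable_pool",
                    }
                )
                continue
            est = combine_pools(usable, cohort, eps_val, rule=rule)
            rows.append(
                {
                    "chrom": chrom, "pos": pos, "variant_id": vid, "cohort": cohort,
                    "p_hat": est.p_hat, "lam": est.lam, "p_lrt": est.p_lrt,
                    "epsilon": eps_val, "flags": ";".join(flags),
                }
            )
    return pd.DataFrame(rows)
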