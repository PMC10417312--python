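"""Hypergeometric enrichment of feature intervals in called regions.

The sampling universe defaults to bins of the calling resolution: of N
autosomal bins, m overlap a feature, k lie inside the query regions, and q of
those are feature-overlapping — the probability of drawing q or more feature
bins among k without replacement is then hypergeometric.  The default tail is
the *exclusive* upper tail P(X > q), matching the R idiom
``1 - phyper(q, m, n, k)``; the inclusive tail P(X >= q) is always reported
alongside since the exclusive convention understates significance by one pmf
term.

The pmf and tails are computed in log space (log-gamma binomials with
log-sum-exp accumulation) for stability at genome-scale counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .genome import GenomeModel
from .intervals import IntervalSet, intervals_to_bins

__all__ = [
    "EnrichmentInput",
    "EnrichmentResult",
    "hypergeom_pmf",
    "upper_tail",
    "count_overlap_units",
    "enrichment_test",
]


@dataclass(frozen=True)
class EnrichmentInput:
    """Canonical hypergeometric counts.

    N: population size; m: successes in the population; k: sample size;
    q: observed successes in the sample.
    """

    N: int
    m: int
    k: int
    q: int

    def __post_init__(self) -> None:
        if not (0 <= self.m <= self.N and 0 <= self.k <= self.N):
            raise ValueError("need 0 <= m <= N and 0 <= k <= N")
        lo = max(0, self.k + self.m - self.N)
        hi = min(self.k, self.m)
        if not lo <= self.q <= hi:
            raise ValueError(f"q={self.q} outside hypergeometric support [{lo}, {hi}]")


@dataclass
class EnrichmentResult:
    counts: EnrichmentInput
    fold: float
    p_exclusive: float  # P(X > q)
    p_inclusive: float  # P(X >= q)
    unit: str = "bin"
    tail: str = "exclusive"

    @property
    def p_upper(self) -> float:
        return self.p_exclusive if self.tail == "exclusive" else self.p_inclusive


def _log_pmf(x: int, N: int, m: int, k: int) -> float:
    return float(
        gammaln(m + 1) - gammaln(x + 1) - gammaln(m - x + 1)
        + gammaln(N - m + 1) - gammaln(k - x + 1) - gammaln(N - m - k + x + 1)
        - (gammaln(N + 1) - gammaln(k + 1) - gammaln(N - k + 1))
    )


def hypergeom_pmf(x: int, N: int, m: int, k: int) -> float:
    """P(X = x) for X ~ Hypergeometric(N, m, k); 0 outside the support."""
    if not (0 <= m <= N and 0 <= k <= N):
        raise ValueError("need 0 <= m <= N and 0 <= k <= N")
    if x < max(0, k + m - N) or x > min(k, m):
        return 0.0
    return float(np.exp(_log_pmf(x, N, m, k)))


def upper_tail(q: int, N: int, m: int, k: int, inclusive: bool = False) -> float:
    """Upper-tail probability: P(X > q) (default) or P(X >= q)."""
    if not (0 <= m <= N and 0 <= k <= N):
        raise ValueError("need 0 <= m <= N and 0 <= k <= N")
    lo = q if inclusive else q + 1
    lo = max(lo, max(0, k + m - N))
    hi = min(k, m)
    if lo > hi:
        return 0.0
    logs = [_log_pmf(x, N, m, k) for x in range(lo, hi + 1)]
    return float(min(1.0, np.exp(logsumexp(logs))))


def count_overlap_units(
    features: IntervalSet,
    regions: IntervalSet,
    genome: GenomeModel,
    unit: str = "bin",
    universe: IntervalSet | None = None,
) -> EnrichmentInput:
    """Build the hypergeometric counts for features vs. regions.

    unit='bin' (default): N = autosomal bins, m = feature-overlapping bins,
    k = region bins, q = feature-overlapping region bins.

    unit='peak': draws are peaks from an explicit background ``universe``:
    N = universe peaks, m = features (the marked subset, matched by midpoint
    containment in a universe peak is not required — m = len(features)),
    k = universe peaks with midpoint inside regions, q = feature peaks with
    midpoint inside regions.
    """
    if len(regions) == 0:
        raise ValueError("regions are empty")
    if unit == "bin":
        fmask = intervals_to_bins(features, genome)
        rmask = intervals_to_bins(regions, genome)
        N = m = k = q = 0
        for chrom in genome.autosomes:
            N += genome.n_bins(chrom)
            m += int(fmask[chrom].sum())
            k += int(rmask[chrom].sum())
            q += int((fmask[chrom] & rmask[chrom]).sum())
        return EnrichmentInput(N, m, k, q)
    if unit == "peak":
        if universe is None:
            raise ValueError("unit='peak' requires a background peak universe")
        region_merged = regions.merge()

        def _inside(iv: IntervalSet) -> int:
            count = 0
            for chrom, pos in iv.midpoints().itertuples(index=False):
                for c, s, e, *_ in region_merged:
                    if c == chrom and s <= pos < e:
                        count += 1
                        break
            return count

        N = len(universe)
        m = len(features)
        k = _inside(universe)
        q = _inside(features)
        return EnrichmentInput(N, m, k, q)
    raise ValueError(f"unknown unit {unit!r}")


def enrichment_test(
    features: IntervalSet,
    regions: IntervalSet,
    genome: GenomeModel,
    unit: str = "bin",
    inclusive: bool = False,
    universe: IntervalSet | None = None,
) -> EnrichmentResult:
    """Hypergeometric over-representation test of features inside regions."""
    counts = count_overlap_units(features, regions, genome, unit, universe)
    N, m, k, q = counts.N, counts.m, counts.k, counts.q
    fold = float("nan") if k == 0 or m == 0 else (q / k) / (m / N)
    return EnrichmentResult(
        counts=counts,
        fold=fold,
        p_exclusive=upper_tail(q, N, m, k, inclusive=False),
        p_inclusive=upper_tail(q, N, m, k, inclusive=True),
        unit=unit,
        tail="inclusive" if inclusive else "exclusive",
    )
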