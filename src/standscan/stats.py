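"""Classical summary statistics of nucleotide variation.

Implements the estimators used to summarize a resequencing survey:
number of segregating sites S, nucleotide diversity per bp
(:func:`nucleotide_diversity`), Watterson's estimator of the population
mutation rate theta = 4*Ne*mu (:func:`watterson_theta`), and Tajima's D
with the full set of variance constants (:func:`tajima_constants`).

Per-bp quantities are normalized by the number of base pairs actually
surveyed (``L``), not by the coordinate span, and are conventionally
reported scaled by 1e4 in tabular output; all internal values are
unscaled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import HaplotypeMatrix, RegionSpec


@dataclass(frozen=True)
class TajimaConstants:
    """Variance constants of Tajima's D for a sample of n chromosomes."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@dataclass(frozen=True)
class SummaryStats:
    """One row of a summary table: n, L, S, pi/bp, theta_W/bp, Tajima's D.

    ``tajima_d`` is NaN when S = 0 (the statistic is undefined there).
    """

    n: int
    L: int
    S: int
    pi_per_bp: float
    theta_w_per_bp: float
    tajima_d: float

    def as_row(self) -> dict:
        """Table-convention dict with per-bp values scaled by 1e4."""
        return {
            "N": self.n,
            "L": self.L,
            "S": self.S,
            "pi_x1e4": round(self.pi_per_bp * 1e4, 2),
            "theta_w_x1e4": round(self.theta_w_per_bp * 1e4, 2),
            "tajima_d": round(self.tajima_d, 2) if np.isfinite(self.tajima_d) else float("nan"),
        }


def tajima_constants(n: int) -> TajimaConstants:
    """Harmonic sums and variance constants for sample size ``n`` >= 2."""
    if n < 2:
        raise ValueError("sample size must be >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def segregating_sites(h: HaplotypeMatrix) -> int:
    """Number of sites at which both alleles are present in the sample."""
    return int(h.is_segregating().sum())


def pairwise_diversity_total(h: HaplotypeMatrix) -> float:
    """Mean number of pairwise differences over all C(n,2) haplotype pairs.

    Computed from derived-allele counts: sum over sites of
    c*(n-c)/C(n,2), which equals the unbiased frequency form
    sum 2*p*(1-p)*n/(n-1).
    """
    n = h.n_hap
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    c = h.derived_counts().astype(np.float64)
    return float((c * (n - c)).sum() / (n * (n - 1) / 2.0))


def nucleotide_diversity(h: HaplotypeMatrix, L: int) -> float:
    """Nucleotide diversity per base pair over ``L`` surveyed bp."""
    if L <= 0:
        raise ValueError("surveyed length L must be positive")
    return pairwise_diversity_total(h) / L


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's theta per bp: S / (a1 * L)."""
    if L <= 0:
        raise ValueError("surveyed length L must be positive")
    if S == 0:
        return 0.0
    return S / (tajima_constants(n).a1 * L)


def tajima_d(S: int, pi_total: float, n: int) -> float:
    """Tajima's D from S and the total (not per-bp) pairwise diversity.

    Returns NaN for S = 0, where the statistic is undefined.
    """
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if S == 0:
        return float("nan")
    k = tajima_constants(n)
    var = k.e1 * S + k.e2 * S * (S - 1)
    return (pi_total - S / k.a1) / math.sqrt(var)


def summarize(h: HaplotypeMatrix, L: int) -> SummaryStats:
    """Bundle S, pi/bp, theta_W/bp and Tajima's D for one sample."""
    S = segregating_sites(h)
    pi_total = pairwise_diversity_total(h)
    return SummaryStats(
        n=h.n_hap,
        L=L,
        S=S,
        pi_per_bp=pi_total / L,
        theta_w_per_bp=watterson_theta(S, h.n_hap, L),
        tajima_d=tajima_d(S, pi_total, h.n_hap),
    )


def summarize_region(h: HaplotypeMatrix, region: RegionSpec) -> SummaryStats:
    """Summary statistics for the sites falling inside ``region``.

    ``region.L_surveyed`` must be set; the coordinate span is never used
    as a stand-in for the surveyed length.
    """
    if region.L_surveyed is None:
        raise ValueError(f"region {region.label!r} has no L_surveyed")
    sub = h.restrict_to_region(region)
    return summarize(sub, region.L_surveyed)
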