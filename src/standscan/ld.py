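"""Pairwise linkage disequilibrium between biallelic sites.

D, |D'| and r^2 are computed from exact two-site haplotype counts of
phased data. ``complete_ld_groups`` clusters sites that travel together
on the same haplotype background (|D'| = 1 and r^2 above a threshold),
the grouping used to tie co-segregating functional alleles into a
single long-range variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import HaplotypeMatrix


@dataclass(frozen=True)
class TwoSiteCounts:
    """2x2 haplotype table for derived (1) / ancestral (0) alleles."""

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def freqs(self) -> tuple[float, float, float]:
        """(p11, p1., p.1): joint and marginal derived frequencies."""
        n = self.n
        return (
            self.n11 / n,
            (self.n11 + self.n10) / n,
            (self.n11 + self.n01) / n,
        )


def two_site_counts(h: HaplotypeMatrix, i: int, j: int) -> TwoSiteCounts:
    """Exact haplotype counts between segregating sites ``i`` and ``j``."""
    if i == j:
        raise ValueError("need two distinct sites")
    a = h.haplotypes[:, i]
    b = h.haplotypes[:, j]
    for name, col in (("i", a), ("j", b)):
        if col.min() == col.max():
            raise ValueError(f"site {name} is monomorphic")
    return TwoSiteCounts(
        n11=int(((a == 1) & (b == 1)).sum()),
        n10=int(((a == 1) & (b == 0)).sum()),
        n01=int(((a == 0) & (b == 1)).sum()),
        n00=int(((a == 0) & (b == 0)).sum()),
    )


def d_coefficient(c: TwoSiteCounts) -> float:
    p11, p1, q1 = c.freqs()
    return p11 - p1 * q1


def d_prime(c: TwoSiteCounts) -> float:
    """|D'|: D normalized by its maximum given the allele frequencies."""
    p11, p1, q1 = c.freqs()
    if p1 in (0.0, 1.0) or q1 in (0.0, 1.0):
        raise ValueError("|D'| undefined for a fixed allele")
    D = p11 - p1 * q1
    if D > 0:
        dmax = min(p1 * (1 - q1), (1 - p1) * q1)
    else:
        dmax = min(p1 * q1, (1 - p1) * (1 - q1))
    if dmax == 0:
        return 0.0
    return abs(D) / dmax


def r_squared(c: TwoSiteCounts) -> float:
    p11, p1, q1 = c.freqs()
    if p1 in (0.0, 1.0) or q1 in (0.0, 1.0):
        raise ValueError("r^2 undefined for a fixed allele")
    D = p11 - p1 * q1
    return D * D / (p1 * (1 - p1) * q1 * (1 - q1))


def ld_matrix(h: HaplotypeMatrix, min_maf: float = 0.05) -> pd.DataFrame:
    """Long-format table of all site pairs passing the MAF filter.

    Columns: pos_i, pos_j, D, dprime_abs, r2 (pairs with i < j; the
    statistics are symmetric).
    """
    freqs = h.derived_freqs()
    maf = np.minimum(freqs, 1 - freqs)
    keep = np.flatnonzero(maf >= min_maf)
    rows = []
    for a_idx in range(len(keep)):
        for b_idx in range(a_idx + 1, len(keep)):
            i, j = int(keep[a_idx]), int(keep[b_idx])
            c = two_site_counts(h, i, j)
            rows.append(
                {
                    "pos_i": int(h.positions[i]),
                    "pos_j": int(h.positions[j]),
                    "D": d_coefficient(c),
                    "dprime_abs": d_prime(c),
                    "r2": r_squared(c),
                }
            )
    return pd.DataFrame(rows, columns=["pos_i", "pos_j", "D", "dprime_abs", "r2"])


def complete_ld_groups(
    m: pd.DataFrame,
    dprime_min: float = 1.0,
    r2_min: float = 0.90,
    tol: float = 1e-9,
) -> list[set[int]]:
    """Transitive closure of site pairs in (near-)complete LD.

    Pairs with |D'| >= ``dprime_min`` and r^2 >= ``r2_min`` are linked;
    groups are the connected components (union-find closure). Positions
    not meeting the thresholds with any partner are omitted.
    """
    for name, v in (("dprime_min", dprime_min), ("r2_min", r2_min)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    hits = m[
        (m["dprime_abs"] >= dprime_min - tol) & (m["r2"] >= r2_min - tol)
    ]
    for _, row in hits.iterrows():
        union(int(row["pos_i"]), int(row["pos_j"]))
    groups: dict[int, set[int]] = {}
    for x in parent:
        groups.setdefault(find(x), set()).add(x)
    return sorted(groups.values(), key=lambda g: min(g))
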