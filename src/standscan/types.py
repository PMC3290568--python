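"""Core containers shared by every analysis stage.

The universal carrier is :class:`HaplotypeMatrix`: an ``n_hap x n_site``
0/1 matrix of phased haplotypes over biallelic SNPs, polarized so that
0 is the ancestral allele, with strictly increasing 1-based chromosomal
positions. Regions are half-open ``[start, end)`` intervals in the same
coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

FUNCTIONAL_CLASSES = frozenset(
    {"nonsynonymous", "synonymous", "noncoding", "nonsense"}
)


@dataclass(frozen=True)
class SiteAnnotation:
    """Functional annotation of a single polymorphic site."""

    position: int
    functional_class: str
    ancestral_allele: str
    derived_allele: str
    ihs_significant: bool = False

    def __post_init__(self) -> None:
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(
                f"unknown functional class {self.functional_class!r}; "
                f"expected one of {sorted(FUNCTIONAL_CLASSES)}"
            )
        if self.ancestral_allele == self.derived_allele:
            raise ValueError("ancestral and derived alleles must differ")


@dataclass(frozen=True)
class RegionSpec:
    """Half-open genomic region with the length actually surveyed.

    ``L_surveyed`` is the number of base pairs sequenced within the
    region, which is what per-bp statistics are normalized by; it can be
    smaller than ``end - start`` when the survey has gaps.
    """

    label: str
    start: int
    end: int
    L_surveyed: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.label}: start must be < end")
        if self.L_surveyed is not None and self.L_surveyed > self.end - self.start:
            raise ValueError(
                f"region {self.label}: L_surveyed exceeds the region span"
            )


class HaplotypeMatrix:
    """Phased 0/1 haplotypes over biallelic sites, 0 = ancestral.

    Parameters
    ----------
    haplotypes
        ``n_hap x n_site`` array of 0/1 allele codes.
    positions
        Strictly increasing 1-based chromosomal coordinates, one per site.
    site_ids, sample_ids
        Optional labels (e.g. rs identifiers, chromosome labels).
    """

    def __init__(
        self,
        haplotypes: np.ndarray,
        positions: Sequence[int],
        site_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> None:
        hap = np.asarray(haplotypes, dtype=np.int8)
        if hap.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        pos = np.asarray(positions, dtype=np.int64)
        if pos.ndim != 1 or pos.shape[0] != hap.shape[1]:
            raise ValueError("positions must have one entry per site")
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(hap, (0, 1))
        if bad.any():
            raise ValueError("haplotype entries must all be 0 or 1")
        self.haplotypes = hap
        self.positions = pos
        self.site_ids = list(site_ids) if site_ids is not None else None
        self.sample_ids = list(sample_ids) if sample_ids is not None else None
        if self.site_ids is not None and len(self.site_ids) != self.n_site:
            raise ValueError("site_ids length mismatch")
        if self.sample_ids is not None and len(self.sample_ids) != self.n_hap:
            raise ValueError("sample_ids length mismatch")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_site(self) -> int:
        return self.haplotypes.shape[1]

    def derived_counts(self) -> np.ndarray:
        """Number of derived (1) alleles at each site."""
        return self.haplotypes.sum(axis=0)

    def derived_freqs(self) -> np.ndarray:
        return self.derived_counts() / self.n_hap

    def is_segregating(self) -> np.ndarray:
        c = self.derived_counts()
        return (c > 0) & (c < self.n_hap)

    def take_sites(self, index: np.ndarray | Sequence[int]) -> "HaplotypeMatrix":
        index = np.atleast_1d(np.asarray(index))
        site_ids = [self.site_ids[i] for i in index] if self.site_ids else None
        return HaplotypeMatrix(
            self.haplotypes[:, index], self.positions[index], site_ids, self.sample_ids
        )

    def restrict_to_region(self, region: RegionSpec) -> "HaplotypeMatrix":
        """Sites with ``start <= pos < end``; raises if none fall inside."""
        keep = (self.positions >= region.start) & (self.positions < region.end)
        if not keep.any():
            raise ValueError(f"no sites in region {region.label!r}")
        return self.take_sites(np.flatnonzero(keep))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.haplotypes, other.haplotypes)
            and np.array_equal(self.positions, other.positions)
            and self.site_ids == other.site_ids
            and self.sample_ids == other.sample_ids
        )

    def __repr__(self) -> str:
        return f"HaplotypeMatrix(n_hap={self.n_hap}, n_site={self.n_site})"


@dataclass
class LoadReport:
    """Bookkeeping for sites filtered while loading external data."""

    n_loaded: int = 0
    dropped_unpolarized: list[int] = field(default_factory=list)
    dropped_missing: list[int] = field(default_factory=list)
    skipped_records: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_unpolarized) + len(self.dropped_missing)
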