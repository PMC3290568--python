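"""Extended haplotype homozygosity (EHH) and the integrated haplotype
score (iHS).

EHH at distance x from a core allele is the probability that two
randomly drawn carrier haplotypes are identical over every site between
the core and x. iHS is the log-ratio of the EHH integrals (iHH) around
the ancestral versus the derived core allele, standardized within
derived-allele-frequency bins so that extreme values (|iHS| > 2,
roughly the outer 5% of a standard normal) flag unusually long
haplotypes around one allele — the footprint of a recent partial sweep.

Distances are physical (bp) by default; an optional genetic map
(cumulative Morgans per site) can replace them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import HaplotypeMatrix

DEFAULT_TRUNCATION = 0.05
DEFAULT_MAF = 0.05
DEFAULT_BINS = 20
SIGNIFICANCE_THRESHOLD = 2.0


@dataclass
class EHHCurve:
    """EHH values at signed bp offsets from the core (offset 0 -> 1.0)."""

    core_site: int
    allele_class: str  # "ancestral" | "derived"
    distances: np.ndarray  # signed offsets, negative = upstream
    ehh: np.ndarray

    def side(self, direction: str) -> tuple[np.ndarray, np.ndarray]:
        """(|distance|, ehh) for one side, ordered outward from the core."""
        sel = self.distances <= 0 if direction == "upstream" else self.distances >= 0
        d = np.abs(self.distances[sel])
        e = self.ehh[sel]
        order = np.argsort(d)
        return d[order], e[order]


@dataclass
class IHSResult:
    site: int
    position: int
    daf: float
    ihh_a: float
    ihh_d: float
    ihs_unstd: float
    ihs_std: float = math.nan
    significant: bool = False
    edge_flag: bool = False


def _homozygosity(groups: np.ndarray) -> float:
    """Probability two random haplotypes share the same group label."""
    n = len(groups)
    _, counts = np.unique(groups, return_counts=True)
    pairs = (counts * (counts - 1)).sum() / 2.0
    return float(pairs / (n * (n - 1) / 2.0))


def ehh(
    h: HaplotypeMatrix,
    core: int,
    allele: str,
    direction: str = "both",
    stop_below: float | None = None,
) -> EHHCurve:
    """EHH decay curve around one allele class at the core site.

    At each successive site the carriers are partitioned by their
    haplotype from the core to that site; EHH is the within-group pair
    fraction sum(C(c_g, 2)) / C(c, 2). ``stop_below`` truncates the
    walk one point after EHH first drops below it (all that integration
    needs), turning a chromosome-length scan into a local one.
    """
    if allele not in ("ancestral", "derived"):
        raise ValueError("allele must be 'ancestral' or 'derived'")
    want = 0 if allele == "ancestral" else 1
    carriers = np.flatnonzero(h.haplotypes[:, core] == want)
    if len(carriers) < 2:
        raise ValueError(f"fewer than 2 carriers of the {allele} allele at core")
    sub = h.haplotypes[carriers]
    dists = [0]
    values = [1.0]
    sides = {"upstream": range(core - 1, -1, -1), "downstream": range(core + 1, h.n_site)}
    if direction != "both":
        sides = {direction: sides[direction]}
    for name, order in sides.items():
        groups = np.zeros(len(carriers), dtype=np.int64)
        for j in order:
            # refine the partition by the allele at site j
            groups = groups * 2 + sub[:, j]
            _, groups = np.unique(groups, return_inverse=True)
            off = int(h.positions[j] - h.positions[core])
            dists.append(off)
            values.append(_homozygosity(groups))
            if stop_below is not None and values[-1] < stop_below:
                break
    d = np.array(dists)
    e = np.array(values)
    order = np.argsort(d, kind="stable")
    return EHHCurve(core, allele, d[order], e[order])


def ihh(curve: EHHCurve, truncation: float = DEFAULT_TRUNCATION) -> tuple[float, bool]:
    """Integrated EHH (bp): trapezoid area on each side until EHH decays
    below ``truncation``, interpolating the crossing point.

    Returns (area, edge_flag); the flag is set when either side runs out
    of data before reaching the truncation level.
    """
    total = 0.0
    edge = False
    for direction in ("upstream", "downstream"):
        d, e = curve.side(direction)
        if len(d) < 2:
            edge = True
            continue
        reached = False
        for k in range(1, len(d)):
            d0, d1 = d[k - 1], d[k]
            e0, e1 = e[k - 1], e[k]
            if e1 < truncation:
                # interpolate to where EHH == truncation
                frac = (e0 - truncation) / (e0 - e1)
                total += 0.5 * (e0 + truncation) * (d1 - d0) * frac
                reached = True
                break
            total += 0.5 * (e0 + e1) * (d1 - d0)
        if not reached:
            edge = True
    return total, edge


def ihs_unstandardized(
    h: HaplotypeMatrix, core: int, truncation: float = DEFAULT_TRUNCATION
) -> IHSResult | None:
    """ln(iHH_ancestral / iHH_derived) at one core site.

    Returns None when either allele class is degenerate (fewer than two
    carriers or a vanishing integral).
    """
    counts = int(h.haplotypes[:, core].sum())
    n = h.n_hap
    if counts < 2 or n - counts < 2:
        return None
    curves = {
        a: ehh(h, core, a, stop_below=truncation)
        for a in ("ancestral", "derived")
    }
    ihh_a, edge_a = ihh(curves["ancestral"], truncation)
    ihh_d, edge_d = ihh(curves["derived"], truncation)
    if ihh_a <= 0 or ihh_d <= 0:
        return None
    return IHSResult(
        site=core,
        position=int(h.positions[core]),
        daf=counts / n,
        ihh_a=ihh_a,
        ihh_d=ihh_d,
        ihs_unstd=math.log(ihh_a / ihh_d),
        edge_flag=edge_a or edge_d,
    )


def scan_ihs(
    h: HaplotypeMatrix,
    min_maf: float = DEFAULT_MAF,
    truncation: float = DEFAULT_TRUNCATION,
) -> list[IHSResult]:
    """Unstandardized iHS for every site passing the MAF floor."""
    out = []
    freqs = h.derived_freqs()
    maf = np.minimum(freqs, 1 - freqs)
    for core in np.flatnonzero(maf >= min_maf):
        r = ihs_unstandardized(h, int(core), truncation)
        if r is not None:
            out.append(r)
    return out


def standardize_ihs(
    results: list[IHSResult],
    n_bins: int = DEFAULT_BINS,
    include_edge: bool = False,
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> list[IHSResult]:
    """Standardize scores within derived-allele-frequency bins.

    Within each equal-width DAF bin the bin mean is subtracted and the
    bin SD divides; sites alone in their bin (SD undefined) keep a NaN
    standardized score. Curves flagged as edge-truncated are excluded
    from (and left unstandardized by) the default standardization.
    """
    usable = [r for r in results if include_edge or not r.edge_flag]
    if not usable:
        return results
    dafs = np.array([r.daf for r in usable])
    scores = np.array([r.ihs_unstd for r in usable])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = np.clip(np.digitize(dafs, edges) - 1, 0, n_bins - 1)
    for b in np.unique(bins):
        sel = bins == b
        if sel.sum() < 2:
            continue
        mu = scores[sel].mean()
        sd = scores[sel].std(ddof=1)
        if sd == 0:
            continue
        for idx in np.flatnonzero(sel):
            r = usable[idx]
            r.ihs_std = (r.ihs_unstd - mu) / sd
            r.significant = abs(r.ihs_std) > threshold
    return results


class StandardizationReference:
    """Frequency-binned moments of unstandardized iHS from a reference
    (typically neutral or genome-wide) score set.

    Scoring a candidate site against an independent reference avoids
    contaminating the bin moments with sites linked to the very signal
    under test — the situation genome-wide standardization approximates.
    """

    def __init__(self, results: list[IHSResult], n_bins: int = DEFAULT_BINS,
                 min_bin_size: int = 5, include_edge: bool = False):
        usable = [r for r in results if include_edge or not r.edge_flag]
        dafs = np.array([r.daf for r in usable])
        scores = np.array([r.ihs_unstd for r in usable])
        self.edges = np.linspace(0.0, 1.0, n_bins + 1)
        self.n_bins = n_bins
        bins = np.clip(np.digitize(dafs, self.edges) - 1, 0, n_bins - 1)
        self.moments: dict[int, tuple[float, float]] = {}
        for b in np.unique(bins):
            sel = scores[bins == b]
            if len(sel) >= min_bin_size and sel.std(ddof=1) > 0:
                self.moments[int(b)] = (float(sel.mean()), float(sel.std(ddof=1)))

    def z(self, daf: float, score: float) -> float:
        """Standardized score, NaN if the site's bin is unpopulated."""
        b = int(np.clip(np.digitize(daf, self.edges) - 1, 0, self.n_bins - 1))
        if b not in self.moments:
            return math.nan
        mu, sd = self.moments[b]
        return (score - mu) / sd

    def z_scores(self, results: list[IHSResult]) -> np.ndarray:
        return np.array([self.z(r.daf, r.ihs_unstd) for r in results])


def cluster_significant(
    results: list[IHSResult], max_gap: int
) -> list[list[IHSResult]]:
    """Maximal runs of significant sites separated by <= ``max_gap`` bp."""
    sig = sorted((r for r in results if r.significant), key=lambda r: r.position)
    clusters: list[list[IHSResult]] = []
    for r in sig:
        if clusters and r.position - clusters[-1][-1].position <= max_gap:
            clusters[-1].append(r)
        else:
            clusters.append([r])
    return clusters


def gene_enrichment_p(observed_fraction: float, background: np.ndarray) -> float:
    """Empirical p for a gene's fraction of significant sites against a
    background of comparable units: (1 + #{bg >= obs}) / (len + 1)."""
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("empty background")
    return (1 + int((background >= observed_fraction).sum())) / (background.size + 1)


def results_table(results: list[IHSResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pos": r.position,
                "daf": r.daf,
                "ihh_a": r.ihh_a,
                "ihh_d": r.ihh_d,
                "ihs_unstd": r.ihs_unstd,
                "ihs_std": r.ihs_std,
                "significant": r.significant,
                "edge_flag": r.edge_flag,
            }
            for r in results
        ]
    )
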