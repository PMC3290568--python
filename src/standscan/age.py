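"""Allele age from the decay of haplotype sharing (DHS).

A young allele sits on a long shared haplotype; recombination erodes
that sharing at a rate proportional to the allele's age in generations.
For each carrier chromosome and each side of the core site we measure
the genetic distance (Morgans) to the first marker at which it departs
from the ancestral (consensus) carrier haplotype. Under a star-shaped
genealogy of age G generations those distances are exponential with
rate G per Morgan, plus a small per-marker mutation hazard; the
censored-exponential maximum-likelihood estimate is

    G_hat = (#uncensored breaks) / sum_i (d_i + mu * k_i)

where d_i is the sharing distance, k_i the number of markers scanned,
and mu the per-marker per-generation mutation rate. The decay statistic
tau = 1 / G_hat converts to the age in generations as 1/tau, and to
years through the generation time.

Two refinements keep the estimator honest away from the core: the
ancestral haplotype is reconstructed by sequential majority vote among
still-unbroken carriers (a global majority drifts to the recombined
background once most copies have broken), and, when control haplotypes
are supplied, the mean distance over which controls coincidentally
match the consensus is subtracted from each observed sharing distance
(chance matching otherwise pushes observed breaks beyond the true
recombination point and biases ages downward).

This estimator is a deliberate simplification of full
haplotype-sharing likelihood machinery; it is validated by parameter
recovery on synthetic sweeps of known age rather than claimed
equivalent to any particular fine-mapping package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import HaplotypeMatrix

DEFAULT_MU_PER_MARKER = 2.5e-8
DEFAULT_GENERATION_TIME = 25.0
DEFAULT_SPLIT_TIME_YEARS = 5.4e6


@dataclass(frozen=True)
class DHSEstimate:
    tau: float
    generations: float
    years: float
    n_cases: int
    censored: int
    ci_generations: tuple[float, float] | None = None


@dataclass(frozen=True)
class MutationRateCalibration:
    """Per-site per-generation mutation rate from interspecies divergence."""

    dxy_per_site: float
    split_time_years: float = DEFAULT_SPLIT_TIME_YEARS
    generation_time_years: float = DEFAULT_GENERATION_TIME

    @property
    def mu_per_site_per_gen(self) -> float:
        return mutation_rate_from_divergence(
            self.dxy_per_site, self.split_time_years, self.generation_time_years
        )


def mutation_rate_from_divergence(
    dxy: float, split_years: float, gen_years: float
) -> float:
    """mu = Dxy / (2 * split_years / gen_years).

    Divergence accumulates along both lineages since the split, hence
    the factor 2 on the number of elapsed generations.
    """
    if dxy <= 0 or split_years <= 0 or gen_years <= 0:
        raise ValueError("divergence, split time and generation time must be > 0")
    return dxy / (2.0 * split_years / gen_years)


def generations_to_years(g: float, gen_time: float = DEFAULT_GENERATION_TIME) -> float:
    if g < 0:
        raise ValueError("generations must be >= 0")
    return g * gen_time


def ancestral_haplotype(cases: HaplotypeMatrix) -> np.ndarray:
    """Majority allele among carriers per marker; ties go to ancestral (0)."""
    counts = cases.derived_counts()
    return (counts * 2 > cases.n_hap).astype(np.int8)


def _side_distances_fixed(
    cases: HaplotypeMatrix,
    core: int,
    anc_hap: np.ndarray,
    gmap: np.ndarray,
    order: range,
):
    """(distance, markers scanned, censored) per carrier against a fixed
    ancestral haplotype, on one side of the core."""
    out = []
    for row in cases.haplotypes:
        k = 0
        hit = None
        for j in order:
            k += 1
            if row[j] != anc_hap[j]:
                hit = (abs(gmap[j] - gmap[core]), k, False)
                break
        if hit is None:
            edge = order[-1] if k else core
            hit = (abs(gmap[edge] - gmap[core]), k, True)
        out.append(hit)
    path = [(j, int(anc_hap[j])) for j in order]
    return out, path


def _side_distances_sequential(
    cases: HaplotypeMatrix,
    core: int,
    gmap: np.ndarray,
    order: range,
) -> list[tuple[float, int, bool]]:
    """Sharing distances against a sequential-majority consensus.

    At each marker the vote is taken only among carriers still identical
    to the consensus so far; carriers on the losing allele break and
    leave the electorate. The survivors are exactly the intact copies of
    the shared ancestral haplotype, so the consensus tracks that
    haplotype even far out, where a global majority vote would drift to
    the recombined background. When fewer than two carriers survive, the
    remainder of the side is uninformative and survivors are censored.
    """
    n = cases.n_hap
    active = list(range(n))
    result: dict[int, tuple[float, int, bool]] = {}
    consensus_path: list[tuple[int, int]] = []  # (site index, consensus allele)
    k = 0
    last_j = core
    for j in order:
        k += 1
        last_j = j
        col = cases.haplotypes[:, j]
        votes = sum(col[i] for i in active)
        consensus = 1 if 2 * votes > len(active) else 0
        consensus_path.append((j, consensus))
        leavers = [i for i in active if col[i] != consensus]
        for i in leavers:
            result[i] = (abs(gmap[j] - gmap[core]), k, False)
        active = [i for i in active if i not in leavers]
        if len(active) < 2:
            break
    # survivors are censored at the last marker actually scanned
    for i in active:
        result[i] = (abs(gmap[last_j] - gmap[core]), k, True)
    return [result[i] for i in range(n)], consensus_path


def _coincidental_sharing(
    controls: HaplotypeMatrix,
    consensus_path: list[tuple[int, int]],
    gmap: np.ndarray,
) -> list[float]:
    """Sharing distances of control haplotypes with the case consensus.

    Controls do not descend from the focal haplotype, so the distance
    over which they happen to match the consensus estimates the
    coincidental-matching overshoot that inflates case sharing
    distances (allele-frequency matching plus background LD).
    """
    if not consensus_path:
        return []
    start = consensus_path[0][0]
    out = []
    for row in controls.haplotypes:
        d = 0.0
        for j, allele in consensus_path:
            d = abs(gmap[j] - gmap[start])
            if row[j] != allele:
                break
        out.append(d)
    return out


def dhs_tau(
    cases: HaplotypeMatrix,
    core: int,
    ancestral_hap: np.ndarray | None = None,
    controls: HaplotypeMatrix | None = None,
    genetic_map: np.ndarray | None = None,
    morgans_per_bp: float = 1e-8,
    mu_per_marker: float = DEFAULT_MU_PER_MARKER,
    generation_time: float = DEFAULT_GENERATION_TIME,
    n_bootstrap: int = 0,
    rng: np.random.Generator | None = None,
) -> DHSEstimate:
    """Age of the haplotype carried by ``cases`` around ``core``.

    ``cases`` must already be restricted to carrier chromosomes.
    ``genetic_map`` gives cumulative Morgans per site; when absent a
    uniform ``morgans_per_bp`` map over positions is used. By default
    the shared ancestral haplotype is reconstructed by sequential
    majority vote among still-unbroken carriers (robust far from the
    core); pass ``ancestral_hap`` to score against a known haplotype
    instead. ``controls`` (non-carrier haplotypes over the same markers)
    enable the coincidental-sharing correction: the mean distance over
    which a control matches the consensus estimates how far beyond the
    true recombination point a case keeps matching by chance, and that
    overshoot is subtracted from the exposure of every observed break.
    """
    if cases.n_hap < 2:
        raise ValueError("need at least 2 carrier haplotypes")
    if ancestral_hap is not None and len(ancestral_hap) != cases.n_site:
        raise ValueError("ancestral haplotype must cover all markers")
    gmap = (
        np.asarray(genetic_map, dtype=float)
        if genetic_map is not None
        else cases.positions * morgans_per_bp
    )
    sides = (range(core - 1, -1, -1), range(core + 1, cases.n_site))
    obs: list[tuple[float, int, bool]] = [None, None] * cases.n_hap  # type: ignore
    overshoot = 0.0
    overshoot_obs: list[float] = []
    for s, order in enumerate(sides):
        if ancestral_hap is not None:
            side_obs, path = _side_distances_fixed(
                cases, core, ancestral_hap, gmap, order
            )
        else:
            side_obs, path = _side_distances_sequential(cases, core, gmap, order)
        if controls is not None and controls.n_hap > 0:
            overshoot_obs.extend(_coincidental_sharing(controls, path, gmap))
        for i, o in enumerate(side_obs):
            obs[2 * i + s] = o
    if overshoot_obs:
        overshoot = float(np.mean(overshoot_obs))
    dists = [o[0] for o in obs]
    markers = [o[1] for o in obs]
    cens = [o[2] for o in obs]

    def estimate(idx: np.ndarray) -> float:
        u = sum(1 for i in idx if not cens[i])
        exposure = sum(dists[i] + mu_per_marker * markers[i] for i in idx)
        # subtract the expected coincidental-sharing overshoot of each
        # observed break; never remove more than half the exposure
        exposure = max(exposure - u * overshoot, 0.5 * exposure)
        if u == 0 or exposure <= 0:
            return math.nan
        return u / exposure

    all_idx = np.arange(len(dists))
    g_hat = estimate(all_idx)
    n_cens = sum(cens)
    if math.isnan(g_hat):
        raise ValueError("no decay observed; age unresolved (all observations censored)")
    ci = None
    if n_bootstrap > 0:
        if rng is None:
            rng = np.random.default_rng()
        # resample carriers (pairs of per-side observations stay together)
        n_cases = cases.n_hap
        boots = []
        for _ in range(n_bootstrap):
            carriers = rng.integers(n_cases, size=n_cases)
            idx = np.concatenate([[2 * c, 2 * c + 1] for c in carriers])
            g = estimate(idx)
            if not math.isnan(g):
                boots.append(g)
        if boots:
            lo, hi = np.percentile(boots, [2.5, 97.5])
            ci = (float(lo), float(hi))
    return DHSEstimate(
        tau=1.0 / g_hat,
        generations=g_hat,
        years=generations_to_years(g_hat, generation_time),
        n_cases=cases.n_hap,
        censored=n_cens,
        ci_generations=ci,
    )
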