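"""Synthetic-data generators with machine-readable ground truth.

Every generator emulates the statistical structure one pipeline stage
assumes — neutral coalescent backgrounds, partial-sweep haplotype
structure around a core allele of known age and frequency,
multi-population frequency tables with an environmental effect of known
strength, and codon alignments evolved at a known omega — and returns a
truth record so recovery tests never peek at internals.

Sweeps are injected by haplotype copying rather than forward simulation
with selection: a fraction of haplotypes is replaced by copies of one
template, each copy truncated on either side at an exponential genetic
distance with rate equal to the sweep age in generations (the
recombination scars a real sweep would leave), then overlaid with
mutation noise. This creates exactly the extended-homozygosity and
haplotype-sharing-decay structure that the EHH/iHS and DHS estimators
detect, with fully controllable truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalescent import DemographicModel, SimParams, simulate_sample
from .dnds import _BASES, is_stop, translate
from .types import HaplotypeMatrix


@dataclass(frozen=True)
class SweepScenario:
    core_frequency: float
    sweep_age_generations: float
    morgans_per_bp: float = 1e-8
    mutation_noise: float = 2.5e-8  # per marker per generation
    frequency_tolerance: float = 0.1
    # fractional span of the region eligible to host the core; keeping the
    # core central avoids truncating the sharing signal at the boundaries
    core_window: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not 0 < self.core_frequency < 1:
            raise ValueError("core frequency must be in (0, 1)")
        if self.sweep_age_generations <= 0:
            raise ValueError("sweep age must be positive")
        lo, hi = self.core_window
        if not 0 <= lo < hi <= 1:
            raise ValueError("core_window must satisfy 0 <= lo < hi <= 1")


@dataclass(frozen=True)
class EnvEffectScenario:
    n_populations: int = 50
    n_countries: int = 21
    effect_tau: float = 0.4
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if abs(self.effect_tau) > 1:
            raise ValueError("|effect_tau| must be <= 1")


def generate_neutral(
    params: SimParams, model: DemographicModel, rng: np.random.Generator
) -> HaplotypeMatrix:
    """One neutral haplotype sample (delegates to the coalescent engine)."""
    return simulate_sample(params, model, rng)


def inject_sweep(
    h: HaplotypeMatrix, s: SweepScenario, rng: np.random.Generator
) -> tuple[HaplotypeMatrix, dict]:
    """Plant a partial sweep of known age and frequency into ``h``.

    Returns the modified matrix and a truth record with the core site,
    carrier rows, template row and true age.
    """
    freqs = h.derived_freqs()
    # pick the segregating site whose derived frequency is closest to target
    seg = np.flatnonzero((freqs > 0) & (freqs < 1))
    lo, hi = s.core_window
    span0, span1 = h.positions[0], h.positions[-1]
    in_window = (h.positions[seg] >= span0 + lo * (span1 - span0)) & (
        h.positions[seg] <= span0 + hi * (span1 - span0)
    )
    seg = seg[in_window]
    if seg.size == 0:
        raise ValueError("no segregating site available for the core")
    core = int(seg[np.argmin(np.abs(freqs[seg] - s.core_frequency))])
    if abs(freqs[core] - s.core_frequency) > s.frequency_tolerance:
        raise ValueError(
            f"no site within {s.frequency_tolerance} of requested core "
            f"frequency {s.core_frequency}"
        )
    n_carriers = int(round(s.core_frequency * h.n_hap))
    n_carriers = max(2, min(h.n_hap - 2, n_carriers))
    carriers = rng.choice(h.n_hap, size=n_carriers, replace=False)
    # the template donor stays outside the carrier set: a carrier whose
    # spliced background equals the template would never show a scar
    others = np.setdiff1d(np.arange(h.n_hap), carriers)
    template_row = int(rng.choice(others))
    template = h.haplotypes[template_row].copy()
    template[core] = 1

    gdist = np.abs(h.positions - h.positions[core]) * s.morgans_per_bp
    new = h.haplotypes.copy()
    age = s.sweep_age_generations
    for row in carriers:
        copy = h.haplotypes[row].copy()
        b_up = rng.exponential(1.0 / age)
        b_dn = rng.exponential(1.0 / age)
        inside = np.zeros(h.n_site, dtype=bool)
        inside[: core + 1] = gdist[: core + 1] <= b_up
        inside[core:] = gdist[core:] <= b_dn
        inside[core] = True
        copy[inside] = template[inside]
        # mutation noise accumulated over the sweep's lifetime
        flip_p = min(1.0, s.mutation_noise * age)
        if flip_p > 0:
            flips = inside & (rng.random(h.n_site) < flip_p)
            flips[core] = False
            copy[flips] = 1 - copy[flips]
        copy[core] = 1
        new[row] = copy
    non_carriers = np.setdiff1d(np.arange(h.n_hap), carriers)
    new[non_carriers, core] = 0
    truth = {
        "core_site": core,
        "core_position": int(h.positions[core]),
        "carriers": sorted(int(c) for c in carriers),
        "template_row": template_row,
        "age_generations": age,
        "core_frequency": n_carriers / h.n_hap,
    }
    return HaplotypeMatrix(new, h.positions, h.site_ids, h.sample_ids), truth


def generate_env_table(
    e: EnvEffectScenario, rng: np.random.Generator, variant: str = "variant_1"
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Population frequency table + pathogen matrix with a planted effect.

    Country-level pathogen richness arises from a random presence/absence
    matrix; population frequencies follow a Gaussian-copula dependence
    on richness calibrated so the expected Kendall tau is approximately
    ``effect_tau`` (rho = sin(pi*tau/2)), plus clipping noise.
    """
    countries = [f"country_{i:02d}" for i in range(e.n_countries)]
    n_path = 40
    pathogens = [f"path_{i:02d}" for i in range(n_path)]
    classes = [PATH_CLASSES[i % 3] for i in range(n_path)]
    presence = rng.integers(0, 2, size=(n_path, e.n_countries))
    pmat = pd.DataFrame(
        [
            {"pathogen": p, "class": c, "country": co, "presence": int(v)}
            for (p, c), row in zip(zip(pathogens, classes), presence)
            for co, v in zip(countries, row)
        ]
    )
    richness = presence.sum(axis=0).astype(float)
    # normal scores of richness; tied countries share a score so a
    # deterministic effect yields matching tie patterns (tau-b = 1)
    from scipy.stats import norm, rankdata

    u = rankdata(richness, method="average") / (e.n_countries + 1)
    z_country = norm.ppf(u)
    rho = math.sin(math.pi * e.effect_tau / 2.0)
    rows = []
    for i in range(e.n_populations):
        country = countries[i % e.n_countries]
        zc = z_country[countries.index(country)]
        latent = rho * zc
        if abs(rho) < 1.0:
            latent += math.sqrt(1 - rho * rho) * rng.normal()
        freq = float(norm.cdf(latent))
        if e.noise_sd > 0:
            freq += rng.normal(0, e.noise_sd)
        rows.append(
            {
                "population": f"pop_{i:02d}",
                "country": country,
                "variant": variant,
                "frequency": float(np.clip(freq, 0.0, 1.0)),
            }
        )
    truth = {"effect_tau": e.effect_tau, "noise_sd": e.noise_sd}
    return pd.DataFrame(rows), pmat, truth


PATH_CLASSES = ("virus", "bacteria", "protozoa")


def _codon_neighbors(codon: str) -> list[tuple[str, bool]]:
    """Sense single-base neighbors with a synonymous flag."""
    out = []
    aa = translate(codon)
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if is_stop(alt):
                continue
            out.append((alt, translate(alt) == aa))
    return out


def _evolve_codon(codon: str, t: float, omega: float, rng: np.random.Generator) -> str:
    """Continuous-time substitution walk: synonymous changes at relative
    rate 1, nonsynonymous at rate omega, stops forbidden."""
    time = 0.0
    while True:
        nbrs = _codon_neighbors(codon)
        rates = np.array([1.0 if syn else omega for _, syn in nbrs])
        total = rates.sum()
        if total <= 0:
            return codon
        time += rng.exponential(1.0 / total)
        if time > t:
            return codon
        codon = nbrs[rng.choice(len(nbrs), p=rates / total)][0]


def generate_codon_alignment(
    n_codons: int,
    tree_scale: float,
    omega: float,
    rng: np.random.Generator,
    taxa: tuple[str, ...] = ("focal", "out1", "out2"),
) -> tuple["CodonAlignment", dict]:
    """Codon alignment evolved on a star tree at a known omega.

    Each taxon's sequence evolves independently from a common random
    root for ``tree_scale`` expected events per codon per branch (before
    omega-weighting of nonsynonymous changes).
    """
    from .dnds import CodonAlignment

    if omega < 0:
        raise ValueError("omega must be >= 0")
    sense = [a + b + c for a in _BASES for b in _BASES for c in _BASES
             if not is_stop(a + b + c)]
    root = [sense[i] for i in rng.integers(len(sense), size=n_codons)]
    seqs = []
    for _ in taxa:
        seqs.append(
            "".join(_evolve_codon(c, tree_scale, omega, rng) for c in root)
        )
    truth = {"omega": omega, "tree_scale": tree_scale, "root": "".join(root)}
    return CodonAlignment(list(taxa), seqs), truth
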