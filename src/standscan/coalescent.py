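"""Neutral coalescent simulator with recombination and gene conversion.

A Hudson-style ancestral-recombination-graph simulator, run backward in
time, for samples of phased haplotypes under the infinite-sites mutation
model. It supports:

* crossover recombination at population rate ``rho = 4*Ne*r`` for the
  whole locus;
* gene conversion with initiation rate ``f * rho`` (``f`` is the
  conversion-to-crossover ratio) and exponentially distributed tract
  lengths, the continuous analogue of geometric tracts;
* piecewise demographic histories: constant size, instantaneous
  expansion, exponential two-fold growth, bottlenecks and a symmetric
  island model with migration;
* two mutation modes: ``"theta"`` (Poisson mutations at rate theta per locus
  per unit of 4*N0 generations, the standard parameterization) and
  ``"fixed_s"`` (exactly S mutations placed on the realized ancestral
  genealogy with probability proportional to branch length, the ``-s``
  conditioning of classical simulators).

Time is measured in units of ``4*N0`` generations where ``N0`` is the
model's reference (equilibrium/ancestral) effective size; ``theta`` and
``rho`` are scaled by the same ``N0``. Sequence coordinates are
continuous on [0, 1) internally and mapped to integer bp on output.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from . import stats as _stats
from .types import HaplotypeMatrix

__all__ = [
    "SimParams",
    "DemographicModel",
    "NullDistribution",
    "simulate_sample",
    "null_distribution",
    "percentile",
    "neutrality_test",
    "write_ms",
]


@dataclass(frozen=True)
class SimParams:
    """Inputs of one simulation run.

    ``theta_per_bp`` and ``rho_per_bp`` are 4*Ne*mu and 4*Ne*r per base
    pair; total locus rates are obtained by multiplying by ``L``.
    ``fixed_s``, when set, switches mutation placement to conditioning
    on exactly that many segregating sites.
    """

    n: int
    L: int
    theta_per_bp: float
    rho_per_bp: float
    conv_ratio_f: float = 2.0
    tract_mean: float = 500.0
    reps: int = 1
    seed: int = 0
    fixed_s: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("sample size must be >= 2")
        for name in ("theta_per_bp", "rho_per_bp", "conv_ratio_f"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.tract_mean < 1:
            raise ValueError("tract_mean must be >= 1 bp")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise demographic history relative to a reference size N0.

    Named encodings (times in generations before present):

    ``constant``
        Size N0 at all times.
    ``recent_expansion``
        Size N1 from the present back to ``t``, N0 before.
    ``twofold_growth``
        Exponential growth reaching ``2*N0`` at present, starting from
        N0 at ``t`` generations ago; N0 before.
    ``bottleneck``
        Size ``b*N0`` during [t1, t0] generations ago, N0 elsewhere.
    ``structure``
        ``npop`` islands of size N0 each, symmetric migration at scaled
        rate ``m = 4*N0*m_gen``; the sample is split evenly.
    ``best_fit``
        A coarse two-epoch stand-in for a calibrated African history:
        recent size ``N1`` (default 24000) back to ``t`` (default 5000
        generations), ancestral ``N0`` (default 12500).
    """

    name: str = "constant"
    N0: float = 1e4
    N1: float | None = None
    t: float | None = None
    t0: float | None = None
    t1: float | None = None
    b: float | None = None
    npop: int = 1
    m: float = 0.0

    _NAMES = ("constant", "recent_expansion", "twofold_growth", "bottleneck",
              "structure", "best_fit")

    def __post_init__(self) -> None:
        if self.name not in self._NAMES:
            raise ValueError(f"unknown demographic model {self.name!r}")
        if self.N0 <= 0:
            raise ValueError("N0 must be positive")
        if self.name == "bottleneck":
            if self.t0 is None or self.t1 is None or self.b is None:
                raise ValueError("bottleneck needs t0, t1 and b")
            if not (0 < self.b <= 1):
                raise ValueError("bottleneck intensity b must be in (0, 1]")
            if self.t1 > self.t0:
                raise ValueError("bottleneck requires t1 <= t0")
        if self.name == "recent_expansion" and (self.N1 is None or self.t is None):
            raise ValueError("recent_expansion needs N1 and t")
        if self.name == "twofold_growth" and self.t is None:
            raise ValueError("twofold_growth needs t")
        if self.name == "structure" and self.npop < 2:
            raise ValueError("structure needs npop >= 2")
        if self.m < 0:
            raise ValueError("migration rate must be >= 0")

    def epochs(self) -> list[tuple[float, float, float, float]]:
        """Coalescence-intensity epochs ``(start, end, rate0, beta)``.

        Within an epoch the pairwise coalescence-rate multiplier at
        scaled time ``u`` is ``rate0 * exp(beta * (u - start))``; the
        multiplier is ``N0 / N(u)``. Times are in 4*N0 generations.
        """
        inf = math.inf
        scale = 4.0 * self.N0
        if self.name in ("constant", "structure"):
            return [(0.0, inf, 1.0, 0.0)]
        if self.name in ("recent_expansion", "best_fit"):
            N1 = self.N1 if self.N1 is not None else 24000.0
            t = (self.t if self.t is not None else 5000.0) / scale
            return [(0.0, t, self.N0 / N1, 0.0), (t, inf, 1.0, 0.0)]
        if self.name == "twofold_growth":
            ts = self.t / scale
            beta = math.log(2.0) / ts
            return [(0.0, ts, 0.5, beta), (ts, inf, 1.0, 0.0)]
        if self.name == "bottleneck":
            t1 = self.t1 / scale
            t0 = self.t0 / scale
            return [(0.0, t1, 1.0, 0.0), (t1, t0, 1.0 / self.b, 0.0),
                    (t0, inf, 1.0, 0.0)]
        raise AssertionError(self.name)


# Named presets for the standard comparison set of human demographies.
MODEL_PRESETS: dict[str, DemographicModel] = {
    "constant": DemographicModel("constant", N0=1e4),
    "recent_expansion": DemographicModel("recent_expansion", N0=1e4, N1=1e7, t=1000),
    "twofold_growth": DemographicModel("twofold_growth", N0=1e4, t=1000),
    "bottleneck_short_severe": DemographicModel(
        "bottleneck", N0=1e4, t0=1600, t1=1200, b=0.1),
    "bottleneck_long_mild": DemographicModel(
        "bottleneck", N0=1e4, t0=1600, t1=1200, b=0.4),
    "structure_m1": DemographicModel("structure", N0=1e4, npop=2, m=1.0),
    "structure_m05": DemographicModel("structure", N0=1e4, npop=2, m=0.5),
    "best_fit": DemographicModel("best_fit", N0=12500, N1=24000, t=5000),
}


class _Lineage:
    """Ancestral lineage: sorted disjoint segments carrying sample sets."""

    __slots__ = ("segs", "pop", "t_birth")

    def __init__(self, segs: list[tuple[float, float, int]], pop: int, t: float):
        self.segs = segs
        self.pop = pop
        self.t_birth = t

    @property
    def span(self) -> float:
        return self.segs[-1][1] - self.segs[0][0]


def _merge_segments(a: list, b: list, full: int) -> list:
    """Union of two ancestral-segment lists with sample-set OR.

    Segments whose merged sample set equals ``full`` have reached their
    marginal MRCA and are discarded.
    """
    bounds = sorted({x for l, r, _ in a for x in (l, r)}
                    | {x for l, r, _ in b for x in (l, r)})
    out: list[tuple[float, float, int]] = []

    def mask_at(segs: list, lo: float, hi: float) -> int:
        # segments are disjoint; at most one covers (lo, hi)
        for l, r, m in segs:
            if l <= lo and r >= hi:
                return m
            if l >= hi:
                break
        return 0

    for lo, hi in zip(bounds[:-1], bounds[1:]):
        m = mask_at(a, lo, hi) | mask_at(b, lo, hi)
        if m == 0 or m == full:
            continue
        if out and out[-1][1] == lo and out[-1][2] == m:
            out[-1] = (out[-1][0], hi, m)
        else:
            out.append((lo, hi, m))
    return out


def _split_at(segs: list, x: float) -> tuple[list, list]:
    """Partition segments at coordinate ``x`` (left: < x, right: >= x)."""
    left, right = [], []
    for l, r, m in segs:
        if r <= x:
            left.append((l, r, m))
        elif l >= x:
            right.append((l, r, m))
        else:
            left.append((l, x, m))
            right.append((x, r, m))
    return left, right


def _extract_tract(segs: list, lo: float, hi: float) -> tuple[list, list]:
    """Partition segments into the part inside [lo, hi) and the rest."""
    inside, outside = [], []
    for l, r, m in segs:
        il, ir = max(l, lo), min(r, hi)
        if il >= ir:
            outside.append((l, r, m))
            continue
        if l < il:
            outside.append((l, il, m))
        inside.append((il, ir, m))
        if ir < r:
            outside.append((ir, r, m))
    return inside, outside


def _simulate_arg(p: SimParams, d: DemographicModel, rng: np.random.Generator):
    """One ARG realization; returns exposure records (weight, mask, l, r).

    ``weight`` is branch-duration times segment length, the mutation
    opportunity of that piece of the genealogy.
    """
    n = p.n
    full = (1 << n) - 1
    rho = p.rho_per_bp * p.L
    g_init = p.conv_ratio_f * rho
    lam = p.tract_mean / p.L
    npop = d.npop if d.name == "structure" else 1
    mig = d.m if npop > 1 else 0.0

    lineages = [
        _Lineage([(0.0, 1.0, 1 << i)], i % npop, 0.0) for i in range(n)
    ]
    records: list[tuple[float, int, float, float]] = []

    def flush(lin: _Lineage, now: float) -> None:
        dt = now - lin.t_birth
        if dt > 0.0:
            for l, r, m in lin.segs:
                records.append((dt * (r - l), m, l, r))

    epochs = d.epochs()
    ei = 0
    t = 0.0
    expo = rng.exponential

    while lineages:
        k = len(lineages)
        sum_span = sum(lin.span for lin in lineages)
        r_cross = rho * sum_span
        r_conv = g_init * (1.0 + lam) * k
        r_mig = mig * k
        r_other = r_cross + r_conv + r_mig
        if npop > 1:
            kp = [0] * npop
            for lin in lineages:
                kp[lin.pop] += 1
            coal_base = float(sum(c * (c - 1) for c in kp))
        else:
            coal_base = float(k * (k - 1))

        # next event within the current epoch (resample at boundaries)
        e_start, e_end, rate0, beta = epochs[ei]
        du = t - e_start
        t_other = expo() / r_other if r_other > 0 else math.inf
        if coal_base > 0:
            if beta == 0.0:
                t_coal = expo() / (coal_base * rate0)
            else:
                E = expo()
                arg = math.exp(beta * du) + beta * E / (coal_base * rate0)
                t_coal = math.log(arg) / beta - du
        else:
            t_coal = math.inf
        wait = min(t_other, t_coal)
        if t + wait >= e_end:
            t = e_end
            ei += 1
            continue
        t += wait

        if t_coal < t_other:
            # coalescence: uniform pair within a deme
            if npop > 1:
                weights = [c * (c - 1) for c in kp]
                tot = sum(weights)
                u = rng.random() * tot
                pop = 0
                acc = 0.0
                for pop, w in enumerate(weights):
                    acc += w
                    if u < acc:
                        break
                idxs = [i for i, lin in enumerate(lineages) if lin.pop == pop]
                i, j = rng.choice(len(idxs), size=2, replace=False)
                ia, ib = idxs[i], idxs[j]
            else:
                pop = 0
                ia, ib = rng.choice(k, size=2, replace=False)
            a = lineages[ia]
            b = lineages[ib]
            flush(a, t)
            flush(b, t)
            merged = _merge_segments(a.segs, b.segs, full)
            for idx in sorted((ia, ib), reverse=True):
                lineages.pop(idx)
            if merged:
                lineages.append(_Lineage(merged, pop, t))
            continue

        u = rng.random() * r_other
        if u < r_cross:
            # crossover: breakpoint uniform on the span of one lineage
            target = u / rho  # position along cumulative span
            acc = 0.0
            lin = lineages[-1]
            ii = k - 1
            for ii, cand in enumerate(lineages):
                if acc + cand.span >= target:
                    lin = cand
                    break
                acc += cand.span
            x = lin.segs[0][0] + (target - acc)
            left, right = _split_at(lin.segs, x)
            if left and right:
                flush(lin, t)
                lineages.pop(ii)
                lineages.append(_Lineage(left, lin.pop, t))
                lineages.append(_Lineage(right, lin.pop, t))
            continue
        if u < r_cross + r_conv:
            # gene conversion: stationary tract process on the unit interval
            ii = int(rng.integers(k))
            lin = lineages[ii]
            if rng.random() < lam / (1.0 + lam):
                lo, hi = 0.0, expo(lam)
            else:
                lo = rng.random()
                hi = lo + expo(lam)
            inside, outside = _extract_tract(lin.segs, lo, hi)
            if inside and outside:
                flush(lin, t)
                lineages.pop(ii)
                lineages.append(_Lineage(inside, lin.pop, t))
                lineages.append(_Lineage(outside, lin.pop, t))
            continue
        # migration
        ii = int(rng.integers(k))
        lin = lineages[ii]
        step = 1 + int(rng.integers(npop - 1))
        lin.pop = (lin.pop + step) % npop
    return records


def _mutations_to_matrix(
    muts: list[tuple[float, int]], n: int, L: int
) -> HaplotypeMatrix:
    """Build a haplotype matrix from (position-fraction, carrier-mask) pairs."""
    muts = sorted(muts)
    nbytes = (n + 7) // 8
    cols = np.zeros((len(muts), n), dtype=np.int8)
    positions = np.empty(len(muts), dtype=np.int64)
    prev = 0
    for j, (x, mask) in enumerate(muts):
        pos = int(x * L) + 1
        if pos <= prev:  # infinite-sites collisions on the bp grid
            pos = prev + 1
        positions[j] = pos
        prev = pos
        bits = np.unpackbits(
            np.frombuffer(mask.to_bytes(nbytes, "little"), dtype=np.uint8),
            bitorder="little",
        )
        cols[j] = bits[:n]
    return HaplotypeMatrix(cols.T.copy(), positions)


def child_seed(seed: int, i: int) -> int:
    """Stable per-replicate seed derived from (seed, i)."""
    h = hashlib.sha256(f"{seed}:{i}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def simulate_sample(
    p: SimParams, d: DemographicModel, rng: np.random.Generator
) -> HaplotypeMatrix:
    """Draw one neutral sample of ``p.n`` phased haplotypes."""
    records = _simulate_arg(p, d, rng)
    weights = np.array([w for w, _, _, _ in records])
    total = float(weights.sum())
    theta = p.theta_per_bp * p.L
    if p.fixed_s is not None:
        n_mut = p.fixed_s
    else:
        n_mut = int(rng.poisson(theta * total)) if total > 0 else 0
    if n_mut == 0:
        return HaplotypeMatrix(
            np.zeros((p.n, 0), dtype=np.int8), np.empty(0, dtype=np.int64)
        )
    idx = rng.choice(len(records), size=n_mut, p=weights / total)
    muts = []
    for i in idx:
        _, mask, l, r = records[i]
        muts.append((l + rng.random() * (r - l), mask))
    return _mutations_to_matrix(muts, p.n, p.L)


@dataclass(frozen=True)
class NullDistribution:
    """Sorted simulated values of one statistic plus provenance digest."""

    statistic_name: str
    values: np.ndarray
    reps: int
    params_digest: str
    n_excluded: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.sort(np.asarray(self.values, float)))


_STATISTICS = ("pi_per_bp", "tajima_d", "S")


def null_distribution(
    p: SimParams,
    d: DemographicModel,
    statistic: str,
    progress: Callable[[int], None] | None = None,
) -> NullDistribution:
    """Simulate ``p.reps`` samples and collect one statistic per replicate.

    Replicates with S = 0 yield an undefined Tajima's D and are excluded
    from that statistic's distribution (the exclusion count is kept).
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if p.reps < 100:
        raise ValueError("need at least 100 replicates for a null distribution")
    values = []
    excluded = 0
    for i in range(p.reps):
        rng = np.random.default_rng(child_seed(p.seed, i))
        h = simulate_sample(p, d, rng)
        s = _stats.summarize(h, p.L)
        v = {"pi_per_bp": s.pi_per_bp, "tajima_d": s.tajima_d, "S": float(s.S)}[
            statistic
        ]
        if math.isnan(v):
            excluded += 1
        else:
            values.append(v)
        if progress is not None:
            progress(i)
    if not values:
        raise ValueError("all replicates were excluded (S = 0 throughout)")
    digest = hashlib.sha256(repr((p, d, statistic)).encode()).hexdigest()[:12]
    return NullDistribution(statistic, np.array(values), p.reps, digest, excluded)


def null_table(
    p: SimParams,
    d: DemographicModel,
    progress: Callable[[int], None] | None = None,
):
    """Per-replicate summary statistics (S, pi_per_bp, tajima_d) as a
    DataFrame — one simulation pass serving several null distributions."""
    import pandas as pd

    rows = []
    for i in range(p.reps):
        rng = np.random.default_rng(child_seed(p.seed, i))
        h = simulate_sample(p, d, rng)
        s = _stats.summarize(h, p.L)
        rows.append((s.S, s.pi_per_bp, s.tajima_d))
        if progress is not None:
            progress(i)
    return pd.DataFrame(rows, columns=["S", "pi_per_bp", "tajima_d"])


def percentile(nd: NullDistribution, q: float) -> float:
    """Linear-interpolation quantile of the sorted null values."""
    if not 0 < q < 100:
        raise ValueError("q must be strictly between 0 and 100")
    if len(nd.values) == 0:
        raise ValueError("empty null distribution")
    return float(np.percentile(nd.values, q, method="linear"))


def neutrality_test(
    observed: float, nd: NullDistribution, statistic: str, q: float = 97.5
) -> tuple[float, bool]:
    """One-sided empirical p-value and exceedance flag.

    p = (1 + #{simulated >= observed}) / (reps_used + 1); the flag is
    True when the observed value exceeds the ``q``-th percentile.
    """
    if statistic != nd.statistic_name:
        raise ValueError(
            f"statistic mismatch: observed {statistic!r}, null {nd.statistic_name!r}"
        )
    m = len(nd.values)
    p = (1 + int((nd.values >= observed).sum())) / (m + 1)
    return p, observed > percentile(nd, q)


def write_ms(
    samples: Iterable[HaplotypeMatrix], L: int, out, header: str = "standscan"
) -> None:
    """Write replicates in ms-compatible text (// blocks, segsites, positions)."""
    out.write(f"{header}\n\n")
    for h in samples:
        out.write("//\n")
        out.write(f"segsites: {h.n_site}\n")
        if h.n_site:
            pos = " ".join(f"{(p - 1) / L:.5f}" for p in h.positions)
            out.write(f"positions: {pos}\n")
            for row in h.haplotypes:
                out.write("".join(str(int(v)) for v in row) + "\n")
        out.write("\n")
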