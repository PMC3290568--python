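"""Pathogen richness and Kendall rank correlation with allele frequencies.

Pathogen richness is the number of distinct pathogen species (optionally
restricted to classes, e.g. intracellular protozoa/viruses/bacteria)
recorded present in a country. Population allele or haplotype
frequencies are correlated with the richness of the country each
population sits in; because many populations share a country, the
richness variable is heavily tied, so the tie-corrected tau-b variant
is used throughout.

P-values: exact null enumeration (inversion-count recurrence) for
tie-free data up to n = 10, a normal approximation with continuity
correction and tie-corrected variance otherwise, and an optional
permutation test as the assumption-free fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

PATHOGEN_CLASSES = ("virus", "bacteria", "protozoa")


@dataclass(frozen=True)
class KendallResult:
    tau: float
    p_value: float
    n: int
    method: str  # exact | normal_approx | permutation


def pathogen_richness(
    matrix: pd.DataFrame, classes: tuple[str, ...] | list[str] = PATHOGEN_CLASSES
) -> pd.Series:
    """Per-country count of pathogens present, restricted to ``classes``.

    ``matrix`` is long format with columns pathogen, class, country,
    presence (0/1).
    """
    if not classes:
        raise ValueError("empty class subset")
    unknown = set(classes) - set(PATHOGEN_CLASSES)
    if unknown:
        raise ValueError(f"unknown pathogen classes: {sorted(unknown)}")
    sel = matrix[matrix["class"].isin(classes)]
    return sel.groupby("country")["presence"].sum().astype(int)


def _concordance(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int, int]:
    """(C, D, n0, n1, n2): concordant/discordant counts and tie terms."""
    n = len(x)
    C = D = 0
    for i in range(n - 1):
        dx = x[i + 1 :] - x[i]
        dy = y[i + 1 :] - y[i]
        s = np.sign(dx) * np.sign(dy)
        C += int((s > 0).sum())
        D += int((s < 0).sum())
    n0 = n * (n - 1) // 2

    def tie_term(v: np.ndarray) -> int:
        _, counts = np.unique(v, return_counts=True)
        return int((counts * (counts - 1) // 2).sum())

    return C, D, n0, tie_term(x), tie_term(y)


@lru_cache(maxsize=None)
def _exact_s_distribution(n: int) -> np.ndarray:
    """Null counts of permutations by number of concordance excesses.

    Entry k is the number of permutations of 1..n with k discordant
    pairs (inversions); the classic Mahonian recurrence.
    """
    counts = np.array([1.0])
    for m in range(2, n + 1):
        new = np.convolve(counts, np.ones(m))
        counts = new
    return counts


def kendall_tau(
    x,
    y,
    method: str = "auto",
    n_permutations: int = 10000,
    rng: np.random.Generator | None = None,
) -> KendallResult:
    """Tie-corrected Kendall's tau-b with a two-sided p-value.

    ``method``: "auto" picks exact enumeration for tie-free n <= 10 and
    the normal approximation otherwise; "permutation" forces a
    permutation test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    C, D, n0, n1, n2 = _concordance(x, y)
    if n0 == n1 or n0 == n2:
        raise ValueError("Kendall's tau undefined for a constant vector")
    tau = (C - D) / math.sqrt((n0 - n1) * (n0 - n2))

    if method == "permutation":
        if rng is None:
            rng = np.random.default_rng()
        obs = abs(tau)
        hits = 0
        yp = y.copy()
        for _ in range(n_permutations):
            rng.shuffle(yp)
            Cp, Dp, _, _, n2p = _concordance(x, yp)
            taup = (Cp - Dp) / math.sqrt((n0 - n1) * (n0 - n2p))
            if abs(taup) >= obs - 1e-12:
                hits += 1
        return KendallResult(tau, (1 + hits) / (n_permutations + 1), n, "permutation")

    if method == "auto" and n <= 10 and n1 == 0 and n2 == 0:
        counts = _exact_s_distribution(n)
        total = counts.sum()
        # discordant count D in 0..n0; S = C - D = n0 - 2D
        obs = abs(C - D)
        svals = n0 - 2 * np.arange(len(counts))
        p = counts[np.abs(svals) >= obs].sum() / total
        return KendallResult(tau, float(min(1.0, p)), n, "exact")

    # normal approximation with tie-corrected variance and continuity corr.
    def tie_sums(v: np.ndarray) -> tuple[float, float, float]:
        _, t = np.unique(v, return_counts=True)
        return (
            float((t * (t - 1) * (2 * t + 5)).sum()),
            float((t * (t - 1) * (t - 2)).sum()),
            float((t * (t - 1)).sum()),
        )

    vt, t2, t1s = tie_sums(x)
    vu, u2, u1s = tie_sums(y)
    v0 = n * (n - 1) * (2 * n + 5)
    var_s = (
        (v0 - vt - vu) / 18.0
        + t2 * u2 / (9.0 * n * (n - 1) * (n - 2))
        + t1s * u1s / (2.0 * n * (n - 1))
    )
    s = C - D
    z = (abs(s) - 1) / math.sqrt(var_s) if var_s > 0 else 0.0
    z = max(z, 0.0)
    p = math.erfc(z / math.sqrt(2.0))
    return KendallResult(tau, min(1.0, p), n, "normal_approx")


def correlate_frequencies(
    freqs: pd.DataFrame,
    richness: pd.Series,
    method: str = "auto",
    average_by_country: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Kendall correlation of each variant's frequencies with richness.

    ``freqs`` columns: population, country, variant, frequency.
    Populations sharing a country share its richness value (tau-b
    absorbs the resulting ties); ``average_by_country`` collapses
    populations to country means first.
    """
    missing = set(freqs["country"]) - set(richness.index)
    if missing:
        raise ValueError(f"populations in unmapped countries: {sorted(missing)}")
    rows = []
    for variant, grp in freqs.groupby("variant"):
        if average_by_country:
            grp = (
                grp.groupby("country", as_index=False)["frequency"].mean()
            )
        r = kendall_tau(
            grp["country"].map(richness).to_numpy(),
            grp["frequency"].to_numpy(),
            method=method,
            rng=rng,
        )
        rows.append(
            {"variant": variant, "tau": r.tau, "p_value": r.p_value,
             "n": r.n, "method": r.method}
        )
    return pd.DataFrame(rows)
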