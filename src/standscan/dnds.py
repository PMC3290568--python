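"""Counting-based dN/dS (Nei–Gojobori style) for codon alignments.

The method counts, for every codon, the expected numbers of synonymous
(S) and nonsynonymous (N) sites from the fraction of single-base
changes to sense codons that preserve the amino acid, tallies observed
synonymous/nonsynonymous differences between sequences (averaging over
all minimal mutational pathways that avoid stop codons), applies the
Jukes–Cantor multiple-hit correction d = -3/4 ln(1 - 4p/3), and reports
omega = dN/dS. omega < 1 indicates purifying selection, omega > 1
positive selection.

Codons containing a stop in any compared sequence carry a
pseudogenization signal rather than a rate and are excluded from the
counts but reported separately. ``lineage_changes`` assigns
substitutions to a focal branch by strict-consensus parsimony against
two or more outgroups, which is how multi-step codon histories (e.g. a
stop codon arising and later being overwritten) are localized to a
lineage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

_BASES = "ACGT"
_STOPS = frozenset(standard_dna_table.stop_codons)
_AA = dict(standard_dna_table.forward_table)


def translate(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop."""
    codon = codon.upper()
    if codon in _STOPS:
        return None
    return _AA[codon]


def is_stop(codon: str) -> bool:
    return codon.upper() in _STOPS


@dataclass(frozen=True)
class DnDsResult:
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float
    dS: float
    omega: float
    n_codons: int
    skipped_stop_codons: int


@dataclass
class CodonAlignment:
    """Equal-length, gap-free codon sequences over ACGT."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences differ in number")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("sequences must be equal length")
        (L,) = lengths
        if L % 3 != 0:
            raise ValueError("alignment length must be divisible by 3")
        for t, s in zip(self.taxa, self.sequences):
            if set(s.upper()) - set(_BASES):
                raise ValueError(f"sequence {t!r} contains non-ACGT characters")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def codon(self, taxon_idx: int, codon_idx: int) -> str:
        return self.sequences[taxon_idx][3 * codon_idx : 3 * codon_idx + 3]

    def get(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        from .io import read_fasta

        seqs = read_fasta(path)
        return cls(list(seqs), list(seqs.values()))


def count_sites_ng86(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one sense codon.

    Per position, the synonymous fraction is the share of single-base
    changes to *sense* codons that preserve the amino acid; changes to
    stop codons are excluded from the denominator, so the two counts
    always sum to 3.
    """
    codon = codon.upper()
    aa = translate(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon} has no site counts")
    s_sites = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if is_stop(alt):
                continue
            valid += 1
            if translate(alt) == aa:
                syn += 1
        if valid:
            s_sites += syn / valid
    return 3.0 - s_sites, s_sites


def _path_differences(a: str, b: str) -> tuple[float, float] | None:
    """(nonsyn, syn) differences averaged over minimal pathways a -> b.

    Pathways passing through a stop codon are discarded; returns None
    when every pathway is blocked.
    """
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in set(permutations(diff)):
        cur = a
        nd = sd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                ok = False
                break
            if translate(cur) == translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((nd, sd))
    if not totals:
        return None
    nd = sum(t[0] for t in totals) / len(totals)
    sd = sum(t[1] for t in totals) / len(totals)
    return nd, sd


def jukes_cantor(p: float) -> float:
    """JC69 distance; NaN when p >= 3/4 (correction undefined)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def pairwise_dnds(a: str, b: str) -> DnDsResult:
    """NG86 dN/dS between two equal-length codon sequences."""
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("sequences must be equal length, divisible by 3")
    a, b = a.upper(), b.upper()
    N = S = Nd = Sd = 0.0
    n_codons = len(a) // 3
    skipped = 0
    for k in range(n_codons):
        ca, cb = a[3 * k : 3 * k + 3], b[3 * k : 3 * k + 3]
        if is_stop(ca) or is_stop(cb):
            skipped += 1
            continue
        diffs = _path_differences(ca, cb)
        if diffs is None:
            skipped += 1
            continue
        na, sa = count_sites_ng86(ca)
        nb, sb = count_sites_ng86(cb)
        N += (na + nb) / 2.0
        S += (sa + sb) / 2.0
        Nd += diffs[0]
        Sd += diffs[1]
    pN = Nd / N if N > 0 else math.nan
    pS = Sd / S if S > 0 else math.nan
    dN = jukes_cantor(pN) if not math.isnan(pN) else math.nan
    dS = jukes_cantor(pS) if not math.isnan(pS) else math.nan
    omega = dN / dS if dS and not math.isnan(dS) and dS > 0 else math.nan
    return DnDsResult(N, S, Nd, Sd, pN, pS, dN, dS, omega,
                      n_codons, skipped)


@dataclass(frozen=True)
class LineageChange:
    codon_index: int
    ancestral_codon: str
    derived_codon: str
    n_steps: int
    kind: str  # substitution | ambiguous | unassigned


def lineage_changes(
    aln: CodonAlignment, focal: str, outgroups: list[str]
) -> list[LineageChange]:
    """Codon substitutions assigned to the focal branch by parsimony.

    A change is assigned when all outgroups agree on a codon and the
    focal sequence differs; codons with disagreeing outgroups are
    flagged ambiguous.
    """
    if len(outgroups) < 2:
        raise ValueError("need at least 2 outgroups")
    fi = aln.taxa.index(focal)
    oi = [aln.taxa.index(o) for o in outgroups]
    out: list[LineageChange] = []
    for k in range(aln.n_codons):
        oc = {aln.codon(i, k) for i in oi}
        fc = aln.codon(fi, k)
        if len(oc) > 1:
            out.append(LineageChange(k, "", fc, 0, "ambiguous"))
            continue
        (anc,) = oc
        if anc == fc:
            continue
        steps = sum(1 for x, y in zip(anc, fc) if x != y)
        out.append(LineageChange(k, anc, fc, steps, "substitution"))
    return out


def classify_omega(omega: float, neutral_band: float = 0.0) -> str:
    """{purifying, neutral, positive, undefined} with a band around 1."""
    if omega is None or math.isnan(omega):
        return "undefined"
    if omega < 1.0 - neutral_band:
        return "purifying"
    if omega > 1.0 + neutral_band:
        return "positive"
    return "neutral"
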