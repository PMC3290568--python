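"""Readers and writers for the formats the pipeline touches.

Supported inputs: HapMap-phase-II-style phased haplotype tables (and a
plain 0/1 matrix dialect), minimal VCF (phased GT, biallelic SNPs), and
FASTA. All loaders polarize alleles against an ancestral-state map so
that 0 = ancestral, and report every site they drop.

Coordinates are 1-based; missing data is never imputed — sites with
missing calls or an unpolarizable ancestral state are dropped and
counted in the :class:`~standscan.types.LoadReport`.
"""

from __future__ import annotations

import logging
import os
from typing import Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import HaplotypeMatrix, LoadReport

log = logging.getLogger(__name__)

_MISSING = {"?", "N", ".", "-"}


def read_phased_haplotypes(
    path: str | os.PathLike,
    ancestral_map: Mapping[int, str] | None = None,
) -> tuple[HaplotypeMatrix, LoadReport]:
    """Read a phased haplotype table.

    The expected layout is two header lines (site IDs, then positions)
    followed by one whitespace-separated row per chromosome. Rows may
    contain bases (polarized through ``ancestral_map``: position -> base)
    or 0/1 codes (taken as already polarized).
    """
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise ValueError(f"{path}: expected 2 header lines plus >=1 haplotype row")
    ids_row, pos_row = lines[0], lines[1]
    if ids_row[0].lower() in ("rsid", "site", "id"):
        ids_row = ids_row[1:]
    if pos_row[0].lower() in ("pos", "position", "positions"):
        pos_row = pos_row[1:]
    positions = [int(x) for x in pos_row]
    if len(ids_row) != len(positions):
        raise ValueError(f"{path}: site-ID and position headers differ in length")
    rows = []
    sample_ids = []
    for ln in lines[2:]:
        label, alleles = ln[0], ln[1:]
        if len(alleles) != len(positions):
            raise ValueError(
                f"{path}: row {label!r} has {len(alleles)} alleles, "
                f"expected {len(positions)}"
            )
        sample_ids.append(label)
        rows.append([a.upper() for a in alleles])
    report = LoadReport()
    cols: list[np.ndarray] = []
    keep_pos, keep_ids = [], []
    for j, pos in enumerate(positions):
        col = [r[j] for r in rows]
        if any(a in _MISSING for a in col):
            report.dropped_missing.append(pos)
            continue
        if set(col) <= {"0", "1"}:
            coded = np.array([int(a) for a in col], dtype=np.int8)
        else:
            if ancestral_map is None or pos not in ancestral_map:
                report.dropped_unpolarized.append(pos)
                continue
            anc = ancestral_map[pos].upper()
            observed = sorted(set(col))
            if anc not in observed:
                log.warning(
                    "site %d: ancestral base %s matches neither observed allele %s; dropped",
                    pos, anc, observed,
                )
                report.dropped_unpolarized.append(pos)
                continue
            if len(observed) > 2:
                report.dropped_unpolarized.append(pos)
                continue
            coded = np.array([0 if a == anc else 1 for a in col], dtype=np.int8)
        cols.append(coded)
        keep_pos.append(pos)
        keep_ids.append(ids_row[j])
    report.n_loaded = len(keep_pos)
    hap = (
        np.column_stack(cols)
        if cols
        else np.zeros((len(rows), 0), dtype=np.int8)
    )
    return HaplotypeMatrix(hap, keep_pos, keep_ids, sample_ids), report


def write_phased_haplotypes(h: HaplotypeMatrix, path: str | os.PathLike) -> None:
    """Write the 0/1 dialect that :func:`read_phased_haplotypes` accepts."""
    site_ids = h.site_ids or [f"site{p}" for p in h.positions]
    sample_ids = h.sample_ids or [f"hap{i}" for i in range(h.n_hap)]
    with open(path, "w") as fh:
        fh.write("rsID " + " ".join(site_ids) + "\n")
        fh.write("pos " + " ".join(str(p) for p in h.positions) + "\n")
        for label, row in zip(sample_ids, h.haplotypes):
            fh.write(label + " " + " ".join(str(int(v)) for v in row) + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA records as an ordered {label: uppercased sequence} mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA label {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_vcf_minimal(
    path: str | os.PathLike, ancestral_tag: str = "AA"
) -> tuple[HaplotypeMatrix, LoadReport]:
    """Read phased biallelic SNPs from a minimal VCF.

    Multiallelic records and indels are skipped and counted. The
    ancestral allele is taken from the INFO field named by
    ``ancestral_tag``; records lacking the tag assume REF-ancestral. An
    unphased genotype raises, naming the offending record.
    """
    from cyvcf2 import VCF

    report = LoadReport()
    cols, positions, ids = [], [], []
    vcf = VCF(str(path))
    sample_ids = [f"{s}_{hap}" for s in vcf.samples for hap in ("A", "B")]
    for v in vcf:
        label = f"{v.CHROM}:{v.POS}"
        if len(v.ALT) != 1 or not v.is_snp:
            report.skipped_records.append(label)
            continue
        gts = v.genotype.array()
        if np.any(gts[:, :2] < 0):
            report.dropped_missing.append(v.POS)
            continue
        if not np.all(gts[:, 2] == 1):
            raise ValueError(f"{path}: unphased genotype at record {label}")
        col = gts[:, :2].reshape(-1).astype(np.int8)
        anc = v.INFO.get(ancestral_tag)
        anc = (anc or v.REF).upper()
        if anc == v.REF.upper():
            pass
        elif anc == v.ALT[0].upper():
            col = (1 - col).astype(np.int8)
        else:
            log.warning("site %s: ancestral %s matches neither allele; dropped",
                        label, anc)
            report.dropped_unpolarized.append(v.POS)
            continue
        cols.append(col)
        positions.append(v.POS)
        ids.append(v.ID or label)
    report.n_loaded = len(positions)
    hap = (
        np.column_stack(cols)
        if cols
        else np.zeros((2 * len(vcf.samples), 0), dtype=np.int8)
    )
    return HaplotypeMatrix(hap, positions, ids, sample_ids), report
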