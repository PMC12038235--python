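"""Allele-specific expression of MybA genes via private SNPs.

RNA reads are quantified against one consensus reference per gene; the
per-allele share of a gene's expression is then estimated by averaging the
read frequencies of the allele's private SNPs (alignment columns where
exactly one allele differs from all others), and the gene-level TPM is
split by those proportions.  Alleles whose proportion falls below a
detection floor are reported as not detected ("n.d.").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .synthetic_locus import SimulatedReadSet

logger = logging.getLogger(__name__)

GAP_CHARS = set("-.")


@dataclass(frozen=True)
class PrivateSnp:
    gene: str
    allele: str
    column: int          # 0-based alignment column
    allele_state: str
    background_state: str


@dataclass(frozen=True)
class AlleleExpression:
    gene: str
    allele: str
    proportion: float
    tpm: float
    n_snps_used: int
    detected: bool

    def tpm_display(self, digits: int = 0) -> str:
        return "n.d." if not self.detected else f"{self.tpm:.{digits}f}"


# ---------------------------------------------------------------------------
# Private SNP discovery
# ---------------------------------------------------------------------------

def find_private_snps(allele_cdnas: Mapping[str, str],
                      gene: str = "") -> list[PrivateSnp]:
    """Columns of a multiple alignment at which exactly one allele holds a
    distinct base while all others share one state, with no gaps."""
    names = list(allele_cdnas)
    if len(names) < 2:
        raise ValueError("need at least two aligned sequences")
    seqs = [allele_cdnas[n].upper() for n in names]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("ragged alignment: sequences differ in length")
    out: list[PrivateSnp] = []
    for col in range(length):
        states = [s[col] for s in seqs]
        if any(c in GAP_CHARS for c in states):
            continue
        counts: dict[str, int] = {}
        for c in states:
            counts[c] = counts.get(c, 0) + 1
        if len(counts) != 2:
            continue
        (b1, n1), (b2, n2) = sorted(counts.items(), key=lambda kv: kv[1])
        if n1 != 1:
            continue  # e.g. a 2-vs-2 split is not private
        odd = names[states.index(b1)]
        out.append(PrivateSnp(gene, odd, col, b1, b2))
    return out


def private_snps_to_vcf(snps: Sequence[PrivateSnp], reference_name: str,
                        path) -> None:
    """Minimal VCF export of private SNP positions (1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snps, key=lambda s: s.column):
            fh.write(f"{reference_name}\t{s.column + 1}\t"
                     f"{s.gene}_{s.allele}_{s.column + 1}\t"
                     f"{s.background_state}\t{s.allele_state}\t.\tPASS\t"
                     f"GENE={s.gene};ALLELE={s.allele}\n")


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

def pileup_from_reads(readset: SimulatedReadSet,
                      reference_length: int) -> dict[int, dict[str, int]]:
    """Base counts per consensus column from simulated reads, using their
    true origin coordinates (alleles are equal length, so allele and
    consensus coordinates coincide)."""
    counts: dict[int, dict[str, int]] = {}
    for read in readset.reads:
        start = read.origin[0]
        for i, base in enumerate(read.sequence):
            pos = start + i
            if pos >= reference_length:
                break
            col = counts.setdefault(pos, {})
            col[base] = col.get(base, 0) + 1
    return counts


def pileup_from_sam(path, reference: str) -> dict[int, dict[str, int]]:
    """Base counts per reference column from a SAM/BAM of RNA reads."""
    counts: dict[int, dict[str, int]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                    or rec.reference_name != reference):
                continue
            seq = rec.query_sequence
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                col = counts.setdefault(rpos, {})
                base = seq[qpos]
                col[base] = col.get(base, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Allele frequencies and proportions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpFrequency:
    snp: PrivateSnp
    depth: int
    frequency: float


def allele_frequencies_at_snps(pileup: Mapping[int, Mapping[str, int]],
                               snps: Sequence[PrivateSnp],
                               min_depth: int = 10) -> list[SnpFrequency]:
    """Frequency of the allele state at each private SNP; columns below
    ``min_depth`` are skipped (and logged)."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    out: list[SnpFrequency] = []
    for snp in snps:
        col = pileup.get(snp.column, {})
        depth = sum(col.values())
        if depth < min_depth:
            logger.warning("SNP column %d (%s/%s) depth %d < %d: skipped",
                           snp.column, snp.gene, snp.allele, depth, min_depth)
            continue
        out.append(SnpFrequency(snp, depth,
                                col.get(snp.allele_state, 0) / depth))
    if not out:
        logger.warning("no private SNP reached min_depth %d", min_depth)
    return out


def estimate_allele_proportion(frequencies: Sequence[float | SnpFrequency],
                               weighted: bool = False) -> float:
    """Mean of per-SNP allele frequencies (unweighted by default; a
    depth-weighted mean is available as an extension)."""
    if len(frequencies) == 0:
        raise ValueError("no frequencies to average")
    if frequencies and isinstance(frequencies[0], SnpFrequency):
        freqs = np.array([f.frequency for f in frequencies])
        depths = np.array([f.depth for f in frequencies], float)
    else:
        freqs = np.asarray(frequencies, float)
        depths = np.ones_like(freqs)
    if weighted:
        return float(np.average(freqs, weights=depths))
    return float(freqs.mean())


def allele_proportions(pileup: Mapping[int, Mapping[str, int]],
                       snps: Sequence[PrivateSnp],
                       min_depth: int = 10,
                       weighted: bool = False) -> dict[str, tuple[float, int]]:
    """Per-allele proportion for one gene, renormalized to sum to 1.

    Returns ``allele -> (proportion, n_snps_used)``.  Alleles present in
    the SNP table but with no usable column get proportion 0 from 0 SNPs.
    When only one allele of a pair carries private SNPs, the remaining
    share is attributed to the implicit background allele named
    ``"<gene>_other"`` only if requested by callers; here, proportions of
    listed alleles are normalized among themselves.
    """
    freqs = allele_frequencies_at_snps(pileup, snps, min_depth)
    by_allele: dict[str, list[SnpFrequency]] = {}
    for s in snps:
        by_allele.setdefault(s.allele, [])
    for f in freqs:
        by_allele[f.snp.allele].append(f)
    raw: dict[str, tuple[float, int]] = {}
    for allele, fl in by_allele.items():
        raw[allele] = ((estimate_allele_proportion(fl, weighted), len(fl))
                       if fl else (0.0, 0))
    total = sum(p for p, _ in raw.values())
    if total > 0:
        raw = {a: (p / total, n) for a, (p, n) in raw.items()}
    return raw


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def compute_tpm(counts: Sequence[float],
                lengths: Sequence[float]) -> np.ndarray:
    """tpm_i = (c_i / l_i) / sum_j (c_j / l_j) * 1e6."""
    counts = np.asarray(counts, float)
    lengths = np.asarray(lengths, float)
    if np.any(lengths <= 0):
        raise ValueError("effective lengths must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        logger.warning("all counts zero: TPM undefined, returning zeros")
        return np.zeros_like(rate)
    return rate / total * 1e6


def partition_tpm(gene_tpm: float,
                  proportions: Mapping[str, tuple[float, int]] |
                  Mapping[str, float],
                  gene: str = "",
                  detection_floor: float = 0.01) -> list[AlleleExpression]:
    """Split a gene's TPM across alleles; proportions below the detection
    floor are reported as not detected (Table-style "n.d.")."""
    if gene_tpm < 0:
        raise ValueError("gene_tpm must be non-negative")
    rows: list[AlleleExpression] = []
    for allele, value in proportions.items():
        if isinstance(value, tuple):
            prop, n_snps = value
        else:
            prop, n_snps = value, 0
        if prop < 0:
            raise ValueError("proportions must be non-negative")
        detected = prop >= detection_floor
        rows.append(AlleleExpression(gene, allele, prop, gene_tpm * prop,
                                     n_snps, detected))
    return rows


def expression_table(rows: Iterable[AlleleExpression]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in rows])
    return df[["gene", "allele", "n_snps_used", "proportion", "tpm",
               "detected"]]
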