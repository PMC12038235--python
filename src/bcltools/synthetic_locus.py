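"""Synthetic berry color locus (BCL) haplotypes and read simulation.

The grapevine BCL on chromosome 2 is a cluster of ``VvMybA`` transcription
factor genes controlling anthocyanin accumulation in berry skin.  This module
builds schematic but sequence-realistic models of the five structural
haplotypes of the locus:

``HapA``
    canonical white haplotype: 8 genes, *Gret1* retrotransposon in the
    ``VvMybA1`` promoter, 209-bp deletion in ``VvMybA3`` exon 3, inactivating
    mutations in ``VvMybA2``.
``HapC-N``
    colored reference haplotype: 8 genes, functional ``VvMybA1c`` and
    ``VvMybA2r`` (282-bp C-terminal duplication).
``HapF1``
    divergent colored haplotype: 8 genes including ``VvMybA13``;
    ``VvMybA1_SUB`` carries three small intronic insertions (44/111/33 bp).
``HapF2``
    HapF1 plus a tandem duplication of the ``VvMybA4`` region (9 genes); one
    copy carries a 213-bp insertion in exon 3, the other an RLG
    retrotransposon in exon 1.
``HapF_DEL``
    HapF2 with a ~76-kb deletion removing six genes (``VvMybA3`` ..
    ``VvMybA4b``); only ``VvMybA1``, ``VvMybA9`` and ``VvMybA13`` remain.

Sequences are pseudo-random (GC ~ 0.45), generated from a seed; they are not
real *Vitis* sequence.  Paralog templates descend from one ancestral R2R3
core so that gene discovery and phylogenetics behave like the real gene
family (within-group identity ~94%, ``VvMybA13`` at 60-78% of the probe).

Coordinates are 0-based half-open internally and 1-based closed in GFF3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_BASES = b"ACGT"
_STOPS = {b"TAA", b"TAG", b"TGA"}
_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


class CoordinateConflictError(ValueError):
    """A variant overlaps an exon boundary inconsistently."""


def revcomp(seq: str) -> str:
    return seq.encode().translate(_COMPLEMENT)[::-1].decode()


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return np.frombuffer(_BASES, dtype="S1")[idx].tobytes().decode()


def random_cds(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + (n_aa - 1) sense codons + one stop codon; no internal stops."""
    codons = ["ATG"]
    while len(codons) < n_aa:
        c = random_seq(rng, 3)
        if c.encode() not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSpec:
    """One edit applied to a gene template.

    ``payload`` is a DNA string for insertion/substitution/te_insertion and
    an integer length for deletion/duplication.  ``identity`` controls how
    similar a duplicated copy is to the original (1.0 = exact).
    """

    kind: str
    position: int
    payload: str | int
    label: str = ""
    identity: float = 1.0
    seed: int | None = None

    _KINDS = ("insertion", "deletion", "substitution", "duplication",
              "te_insertion")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("duplication identity must be in [0, 1]")


@dataclass(frozen=True)
class AppliedEdit:
    """Record of an edit in final (allele) coordinates."""

    label: str
    kind: str
    start: int
    end: int
    delta: int  # length change relative to the template


@dataclass
class GeneTemplate:
    name: str
    sequence: str
    exons: list[tuple[int, int]]
    promoter_span: tuple[int, int] = (0, 0)
    edits: list[AppliedEdit] = field(default_factory=list)

    def __post_init__(self):
        last = -1
        for s, e in self.exons:
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"{self.name}: exon ({s},{e}) out of bounds")
            if s <= last:
                raise ValueError(f"{self.name}: exons overlap or unsorted")
            last = e

    def spliced(self) -> str:
        return "".join(self.sequence[s:e] for s, e in self.exons)

    def cds_positions(self) -> np.ndarray:
        """Template coordinate of each CDS base."""
        return np.concatenate([np.arange(s, e) for s, e in self.exons])


@dataclass(frozen=True)
class TeFeature:
    name: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]

    def shifted(self, delta: int) -> "TeFeature":
        return TeFeature(self.name, self.start + delta, self.end + delta,
                         (self.ltr5[0] + delta, self.ltr5[1] + delta),
                         (self.ltr3[0] + delta, self.ltr3[1] + delta))


@dataclass
class GenePlacement:
    name: str
    allele: GeneTemplate
    strand: str
    offset: int

    @property
    def start(self) -> int:
        return self.offset

    @property
    def end(self) -> int:
        return self.offset + len(self.allele.sequence)

    def exon_spans(self) -> list[tuple[int, int]]:
        return [(self.offset + s, self.offset + e) for s, e in self.allele.exons]


@dataclass
class HaplotypeModel:
    name: str
    sequence: str
    genes: list[GenePlacement]
    te_features: list[TeFeature]
    meta: dict = field(default_factory=dict)

    def gene(self, name: str) -> GenePlacement:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def annotations(self) -> list[tuple]:
        """Flat, comparable view of the structural annotation."""
        rows: list[tuple] = []
        for g in self.genes:
            rows.append(("gene", g.name, g.start, g.end, g.strand))
            for s, e in g.exon_spans():
                rows.append(("exon", g.name, s, e, g.strand))
        for t in self.te_features:
            rows.append(("te", t.name, t.start, t.end, "+"))
            rows.append(("ltr5", t.name, *t.ltr5, "+"))
            rows.append(("ltr3", t.name, *t.ltr3, "+"))
        return sorted(rows, key=lambda r: (r[2], r[3], r[0], r[1]))

    def same_structure(self, other: "HaplotypeModel") -> bool:
        return (self.sequence == other.sequence
                and self.annotations() == other.annotations())


@dataclass
class SimRead:
    id: str
    sequence: str
    origin: tuple[int, int]
    haplotype: str


@dataclass
class SimulatedReadSet:
    reads: list[SimRead]
    read_len: int
    error_rate: float
    seed: int

    def __len__(self) -> int:
        return len(self.reads)

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f">{r.id}\n{r.sequence}\n")


@dataclass
class RnaSimConfig:
    allele_cdnas: Mapping[str, str]
    allele_tpm: Mapping[str, float]
    read_length: int = 100
    n_reads: int = 50_000
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        names = list(self.allele_cdnas)
        if len(set(names)) != len(names):
            raise ValueError("allele names must be unique")
        if any(v < 0 for v in self.allele_tpm.values()):
            raise ValueError("expression levels must be non-negative")
        if not any(v > 0 for v in self.allele_tpm.values()):
            raise ValueError("at least one allele must be expressed")


# ---------------------------------------------------------------------------
# build_allele: variant application with exon remapping
# ---------------------------------------------------------------------------

def _remap_exons_insertion(exons, pos, length):
    out = []
    for s, e in exons:
        if pos <= s:
            out.append((s + length, e + length))
        elif pos < e:  # strictly inside the exon
            out.append((s, e + length))
        else:
            out.append((s, e))
    return out


def _remap_exons_deletion(exons, pos, length, name):
    dstart, dend = pos, pos + length
    out = []
    for s, e in exons:
        if dend <= s:
            out.append((s - length, e - length))
        elif dstart >= e:
            out.append((s, e))
        elif dstart >= s and dend <= e:  # fully inside the exon
            out.append((s, e - length))
        else:
            raise CoordinateConflictError(
                f"{name}: deletion [{dstart},{dend}) crosses boundary of "
                f"exon ({s},{e})")
    return out


def build_allele(template: GeneTemplate,
                 variants: Sequence[VariantSpec]) -> GeneTemplate:
    """Apply variants to a gene template, remapping exons across indels.

    Variants are applied right-to-left so coordinates given on the template
    never shift under earlier edits.  The returned allele keeps an edit log
    (``.edits``) in final allele coordinates.
    """
    seq = template.sequence
    exons = list(template.exons)
    promoter = template.promoter_span
    pending: list[tuple[VariantSpec, int, int, int]] = []  # spec, start, end, delta

    for v in sorted(variants, key=lambda v: v.position, reverse=True):
        pos = v.position
        if not 0 <= pos <= len(template.sequence):
            raise ValueError(
                f"{template.name}: variant position {pos} outside template")
        if v.kind in ("insertion", "te_insertion"):
            payload = str(v.payload)
            seq = seq[:pos] + payload + seq[pos:]
            exons = _remap_exons_insertion(exons, pos, len(payload))
            pending.append((v, pos, pos + len(payload), len(payload)))
        elif v.kind == "deletion":
            length = int(v.payload)
            if pos + length > len(seq):
                raise ValueError(f"{template.name}: deletion runs off template")
            seq = seq[:pos] + seq[pos + length:]
            exons = _remap_exons_deletion(exons, pos, length, template.name)
            pending.append((v, pos, pos, -length))
        elif v.kind == "substitution":
            payload = str(v.payload)
            if pos + len(payload) > len(seq):
                raise ValueError(f"{template.name}: substitution off template")
            seq = seq[:pos] + payload + seq[pos + len(payload):]
            pending.append((v, pos, pos + len(payload), 0))
        elif v.kind == "duplication":
            length = int(v.payload)
            if pos + length > len(seq):
                raise ValueError(f"{template.name}: duplication off template")
            block = seq[pos:pos + length]
            if v.identity < 1.0:
                rng = np.random.default_rng(
                    v.seed if v.seed is not None else 0)
                block = mutate_sequence(block, 1.0 - v.identity, rng)
            insert_at = pos + length
            seq = seq[:insert_at] + block + seq[insert_at:]
            exons = _remap_exons_insertion(exons, insert_at, length)
            pending.append((v, insert_at, insert_at + length, length))

    # convert edit coordinates to final allele coordinates: each recorded
    # edit must absorb the length changes of edits to its left
    edits = []
    for v, start, end, delta in pending:
        shift = sum(d for _, s, _, d in pending if s < start)
        edits.append(AppliedEdit(v.label or v.kind, v.kind,
                                 start + shift, end + shift, delta))
    edits.sort(key=lambda e: e.start)
    return GeneTemplate(template.name, seq, exons, promoter, edits)


def mutate_sequence(seq: str, divergence: float,
                    rng: np.random.Generator) -> str:
    """Substitute a ``divergence`` fraction of positions (no indels)."""
    arr = bytearray(seq.encode())
    n = int(round(divergence * len(arr)))
    if n == 0:
        return seq
    positions = rng.choice(len(arr), size=min(n, len(arr)), replace=False)
    for pos in positions:
        alts = [b for b in _BASES if b != arr[pos]]
        arr[pos] = alts[rng.integers(len(alts))]
    return arr.decode()


def _diverge_coding(template: GeneTemplate, divergence: float,
                    rng: np.random.Generator, name: str) -> GeneTemplate:
    """Paralog-style divergence: substitutions that never create an in-frame
    stop codon and never touch the start or stop codon."""
    arr = bytearray(template.sequence.encode())
    cds_pos = template.cds_positions()
    cds_index = {int(p): i for i, p in enumerate(cds_pos)}
    cds_len = len(cds_pos)
    n = int(round(divergence * len(arr)))
    positions = rng.choice(len(arr), size=min(n, len(arr)), replace=False)
    for pos in positions:
        pos = int(pos)
        alts = [b for b in _BASES if b != arr[pos]]
        order = rng.permutation(len(alts))
        i = cds_index.get(pos)
        if i is None:
            arr[pos] = alts[int(order[0])]
            continue
        if i < 3 or i >= cds_len - 3:
            continue  # protect start and stop codons
        frame = i % 3
        codon_pos = [int(cds_pos[i - frame + k]) for k in range(3)]
        for j in order:
            cand = alts[int(j)]
            codon = bytes(arr[p] if p != pos else cand for p in codon_pos)
            if codon not in _STOPS:
                arr[pos] = cand
                break
    return GeneTemplate(name, arr.decode(), list(template.exons),
                        template.promoter_span)


def synonymous_snps(template: GeneTemplate, n: int,
                    rng: np.random.Generator,
                    label_prefix: str = "syn") -> list[VariantSpec]:
    """Pick ``n`` third-codon-position substitutions that preserve the
    protein (used to plant allele-private coding SNPs)."""
    cds_pos = template.cds_positions()
    cds = template.spliced().encode()
    third = np.arange(2, len(cds_pos) - 3, 3)  # skip the stop codon
    rng.shuffle(third)
    out: list[VariantSpec] = []
    for i in third:
        i = int(i)
        codon = cds[i - 2:i + 1]
        aa = str(Seq(codon.decode()).translate())
        for b in b"ACGT":
            if b == cds[i]:
                continue
            cand = bytes([codon[0], codon[1], b])
            if cand in _STOPS:
                continue
            if str(Seq(cand.decode()).translate()) == aa:
                out.append(VariantSpec("substitution", int(cds_pos[i]),
                                       chr(b), f"{label_prefix}{len(out)+1}"))
                break
        if len(out) == n:
            break
    if len(out) < n:
        raise RuntimeError("could not place enough synonymous SNPs")
    return out


# ---------------------------------------------------------------------------
# Gene templates: one ancestral R2R3 MYB core, paralogs by seeded divergence
# ---------------------------------------------------------------------------

PROMOTER_LEN = 300
_EXON1, _INTRON1, _EXON2, _INTRON2, _EXON3 = 240, 150, 130, 500, 383

#: nominal substitution divergence of each paralog from its group ancestor,
#: and of each group ancestor from the family root.  VvMybA1/2/3 form one
#: close group, VvMybA4/11 a second, VvMybA13 (and the schematic VvMybA12)
#: are distant (probe identity 60-78%).
_GROUP_DIV = {"g123": 0.05, "g411": 0.08}
_PARALOG_DIV = {
    "VvMybA1": ("g123", 0.030),
    "VvMybA2": ("g123", 0.035),
    "VvMybA3": ("g123", 0.030),
    "VvMybA4": ("g411", 0.040),
    "VvMybA11": ("g411", 0.045),
    "VvMybA9": ("root", 0.150),
    "VvMybA10": ("root", 0.160),
    "VvMybA12": ("root", 0.280),
    "VvMybA13": ("root", 0.300),
}
OUTGROUP_NAME = "AtMyb75"
_OUTGROUP_DIV = 0.45

DEFAULT_SEED = 1001

_template_cache: dict[int, dict[str, GeneTemplate]] = {}


def _ancestral_template(rng: np.random.Generator) -> GeneTemplate:
    cds = random_cds(rng, 250)  # 250 aa incl. Met, + stop = 753 bp
    e1 = cds[:_EXON1]
    e2 = cds[_EXON1:_EXON1 + _EXON2]
    e3 = cds[_EXON1 + _EXON2:]
    assert len(e3) == _EXON3
    promoter = random_seq(rng, PROMOTER_LEN)
    i1 = random_seq(rng, _INTRON1)
    i2 = random_seq(rng, _INTRON2)
    seq = promoter + e1 + i1 + e2 + i2 + e3
    o = PROMOTER_LEN
    exons = [(o, o + _EXON1),
             (o + _EXON1 + _INTRON1, o + _EXON1 + _INTRON1 + _EXON2),
             (o + _EXON1 + _INTRON1 + _EXON2 + _INTRON2, len(seq))]
    return GeneTemplate("ancestor", seq, exons, (0, PROMOTER_LEN))


def default_gene_templates(seed: int = DEFAULT_SEED) -> dict[str, GeneTemplate]:
    """Paralog gene templates plus the distant outgroup probe donor."""
    if seed in _template_cache:
        return _template_cache[seed]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    anc = _ancestral_template(rng)
    groups = {"root": anc}
    for gname, d in _GROUP_DIV.items():
        groups[gname] = _diverge_coding(anc, d, rng, gname)
    out: dict[str, GeneTemplate] = {}
    for name, (group, d) in _PARALOG_DIV.items():
        out[name] = _diverge_coding(groups[group], d, rng, name)
    out[OUTGROUP_NAME] = _diverge_coding(anc, _OUTGROUP_DIV, rng,
                                         OUTGROUP_NAME)
    _template_cache[seed] = out
    return out


def r2r3_probe(templates: Mapping[str, GeneTemplate] | None = None,
               seed: int = DEFAULT_SEED) -> str:
    """Conserved R2R3 probe: exon 1, intron 1 and exon 2 of ``VvMybA1``."""
    t = (templates or default_gene_templates(seed))["VvMybA1"]
    return t.sequence[t.exons[0][0]:t.exons[1][1]]


def paralog_probe_alignment(seed: int = DEFAULT_SEED,
                            haplotype: str = "HapF2") -> dict[str, str]:
    """Ungapped alignment of the R2R3 region of every paralog on one
    haplotype plus the outgroup; substitution-only divergence keeps all
    region coordinates identical, so no aligner is needed."""
    templates = default_gene_templates(seed)
    names = HAPLOTYPE_GENE_ORDER[haplotype]
    aln = {}
    for label in names:
        if label == "VvMybA4b":
            t, _flank = a4b_gene_template(LocusConfig(seed=seed))
        else:
            t = templates[_template_of(label)]
        aln[label] = t.sequence[t.exons[0][0]:t.exons[1][1]]
    t = templates[OUTGROUP_NAME]
    aln[OUTGROUP_NAME] = t.sequence[t.exons[0][0]:t.exons[1][1]]
    return aln


# ---------------------------------------------------------------------------
# Locus configuration and haplotype assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusConfig:
    """Geometry and rates of the synthetic locus.

    Spacer lengths are chosen so that HapF2 spans ~138 kb while the
    HapF_DEL deletion spans ~76 kb; both are schematic defaults.
    """

    seed: int = DEFAULT_SEED
    spacer_core: int = 9_070     # intergenic gaps inside the deleted interval
    spacer_flank: int = 12_200   # all other intergenic gaps and locus flanks
    unit_spacer: int = 4_200     # downstream flank inside the VvMybA4 tandem unit
    ltr_len: int = 600
    te_internal_len: int = 3_000
    mu: float = 1.3e-8           # substitutions / site / year
    tandem_identity: float = 0.90
    del_upstream: int = 1_400    # deletion breakpoint upstream of VvMybA3
    del_downstream: int = 10_800  # deletion breakpoint downstream of VvMybA4b
    te_ages: Mapping[str, float] = field(default_factory=lambda: {
        "Gret1": 0.15e6, "RLC_1": 1.19e6, "RLC_2": 0.19e6,
        "RLG_1": 0.45e6, "RLG_2": 0.69e6,
    })


DEFAULT_CONFIG = LocusConfig()

HAPLOTYPE_GENE_ORDER: dict[str, list[str]] = {
    "HapA": ["VvMybA1", "VvMybA9", "VvMybA12", "VvMybA3", "VvMybA11",
             "VvMybA10", "VvMybA2", "VvMybA4"],
    "HapC-N": ["VvMybA1", "VvMybA9", "VvMybA12", "VvMybA3", "VvMybA11",
               "VvMybA10", "VvMybA2", "VvMybA4"],
    "HapF1": ["VvMybA1", "VvMybA9", "VvMybA13", "VvMybA3", "VvMybA11",
              "VvMybA10", "VvMybA2", "VvMybA4"],
    "HapF2": ["VvMybA1", "VvMybA9", "VvMybA13", "VvMybA3", "VvMybA11",
              "VvMybA10", "VvMybA2", "VvMybA4a", "VvMybA4b"],
    "HapF_DEL": ["VvMybA1", "VvMybA9", "VvMybA13"],
}

#: genes removed by the HapF_DEL deletion, in locus order
DELETED_GENES = ("VvMybA3", "VvMybA11", "VvMybA10", "VvMybA2",
                 "VvMybA4a", "VvMybA4b")

# private (synonymous) coding SNPs per HapF allele; these let RNA reads be
# assigned to alleles even though the large HapF/HapA differences are
# intronic or structural
_N_PRIVATE_SNPS = {"VvMybA1": 4, "VvMybA2": 3, "VvMybA3": 3}


def _template_of(gene_label: str) -> str:
    return {"VvMybA4a": "VvMybA4", "VvMybA4b": "VvMybA4"}.get(
        gene_label, gene_label)


def make_te(name: str, rng: np.random.Generator, ltr_len: int,
            internal_len: int, age: float = 0.0, mu: float = 1.3e-8,
            seed: int = 0) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """A complete LTR retrotransposon: identical LTRs flanking an internal
    region, then aged by :func:`mutate_ltr_pair`."""
    ltr = random_seq(rng, ltr_len)
    internal = random_seq(rng, internal_len)
    seq = ltr + internal + ltr
    ltr5 = (0, ltr_len)
    ltr3 = (ltr_len + internal_len, len(seq))
    if age > 0:
        seq = mutate_ltr_pair(seq, ltr5, ltr3, age, mu, seed)
    return seq, ltr5, ltr3


def mutate_ltr_pair(te_seq: str, ltr5: tuple[int, int], ltr3: tuple[int, int],
                    age: float, mu: float,
                    seed: int | np.random.Generator = 0) -> str:
    """Age a TE: each LTR independently accumulates ``Poisson(mu*age*L)``
    substitutions at uniform positions, so the expected LTR-pair divergence
    is ``2*mu*age``."""
    if age < 0 or mu < 0:
        raise ValueError("age and mu must be non-negative")
    if te_seq[ltr5[0]:ltr5[1]] == "" or te_seq[ltr3[0]:ltr3[1]] == "":
        raise ValueError("TE must have annotated LTRs")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    arr = bytearray(te_seq.encode())
    for s, e in (ltr5, ltr3):
        n = rng.poisson(mu * age * (e - s))
        for _ in range(n):
            pos = int(rng.integers(s, e))
            alts = [b for b in _BASES if b != arr[pos]]
            arr[pos] = alts[int(rng.integers(3))]
    return arr.decode()


def _allele_variants(hap: str, gene: str, templates, cfg: LocusConfig,
                     rng_hapA: np.random.Generator,
                     rng_hapF: np.random.Generator,
                     te_bank: dict) -> list[VariantSpec]:
    """Variant specs giving each haplotype its allele of ``gene``."""
    t = templates[_template_of(gene)]
    e3s = t.exons[2][0]
    e3e = t.exons[2][1]
    i1s, i2s = t.exons[0][1], t.exons[1][1]
    fam_f = hap in ("HapF1", "HapF2", "HapF_DEL")
    variants: list[VariantSpec] = []
    if gene == "VvMybA1":
        if hap == "HapA":
            te_seq, l5, l3 = te_bank["Gret1"]
            variants.append(VariantSpec("te_insertion", 150, te_seq, "Gret1"))
        elif fam_f:
            # VvMybA1_SUB: 44 bp in intron 1; 33 bp and 111 bp in intron 2;
            # the diagnostic SNP sits at position 99 of intron 2 (before
            # either intron-2 insertion, so its intron coordinate is stable)
            variants += [
                VariantSpec("insertion", i1s + 60,
                            random_seq(rng_hapF, 44), "ins44"),
                VariantSpec("substitution", i2s + 99,
                            _transversion(t.sequence[i2s + 99]), "snp_intron2_99"),
                VariantSpec("insertion", i2s + 150,
                            random_seq(rng_hapF, 33), "ins33"),
                VariantSpec("insertion", i2s + 320,
                            random_seq(rng_hapF, 111), "ins111"),
            ]
            variants += synonymous_snps(t, _N_PRIVATE_SNPS["VvMybA1"],
                                        rng_hapF, "A1F_snp")
    elif gene == "VvMybA2":
        if hap == "HapA":
            variants += [
                VariantSpec("substitution", t.exons[0][0] + 129, "CTG", "R44L"),
                VariantSpec("deletion", t.exons[1][0] + 50, 2, "CA_del"),
            ]
        else:  # HapC-N and HapF: functional, 282-bp C-terminal duplication
            variants.append(VariantSpec("duplication", e3e - 9 - 282, 282,
                                        "dup282"))
            if fam_f:
                variants += synonymous_snps(t, _N_PRIVATE_SNPS["VvMybA2"],
                                            rng_hapF, "A2F_snp")
    elif gene == "VvMybA3":
        if not fam_f:  # HapA and HapC-N: 209-bp deletion in exon 3
            variants.append(VariantSpec("deletion", e3s + 60, 209, "del209"))
        else:
            variants += synonymous_snps(t, _N_PRIVATE_SNPS["VvMybA3"],
                                        rng_hapF, "A3F_snp")
    elif gene == "VvMybA4a":
        variants.append(VariantSpec("insertion", e3s + 30,
                                    random_seq(rng_hapF, 213), "ins213"))
    elif gene == "VvMybA4b":
        te_seq, l5, l3 = te_bank["RLG_2"]
        variants.append(VariantSpec("te_insertion", t.exons[0][0] + 80,
                                    te_seq, "RLG_2"))
    return variants


def _transversion(base: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[base]


def _family_assets(family: str, cfg: LocusConfig):
    """Spacer sequences and TE bank for one haplotype family, generated in a
    fixed order so every haplotype of the family shares them."""
    stream = {"A": 1, "F": 2}[family]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))
    slots = {}
    slots["L"] = random_seq(rng, cfg.spacer_flank)
    for i in range(7):
        width = cfg.spacer_core if i in (3, 4, 5, 6) else cfg.spacer_flank
        slots[f"g{i}"] = random_seq(rng, width)
    slots["unit"] = random_seq(rng, cfg.unit_spacer)
    slots["R"] = random_seq(rng, cfg.spacer_flank)
    te_bank = {}
    te_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, stream, 9]))
    if family == "A":
        te_bank["Gret1"] = make_te("Gret1", te_rng, cfg.ltr_len,
                                   cfg.te_internal_len,
                                   cfg.te_ages["Gret1"], cfg.mu, seed=te_rng)
    else:
        for te_name in ("RLC_1", "RLC_2", "RLG_1", "RLG_2"):
            te_bank[te_name] = make_te(te_name, te_rng, cfg.ltr_len,
                                       cfg.te_internal_len,
                                       cfg.te_ages[te_name], cfg.mu,
                                       seed=te_rng)
    return slots, te_bank


#: which intergenic slot carries which HapF-family TE
_F_SLOT_TES = {"g1": "RLC_1", "g3": "RLC_2", "g5": "RLG_1"}


def a4b_gene_template(cfg: LocusConfig | None = None
                      ) -> tuple[GeneTemplate, str]:
    """The second VvMybA4 tandem copy before its TE insertion: the
    pre-duplication unit (gene + downstream flank) mutated to the
    configured copy identity (~90%).  Returns (gene template, mutated
    flank sequence)."""
    cfg = cfg or DEFAULT_CONFIG
    templates = default_gene_templates(cfg.seed)
    slots, _ = _family_assets("F", cfg)
    tmpl4 = templates["VvMybA4"]
    unit_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 13]))
    base_unit = tmpl4.sequence + slots["unit"]
    mut_unit = mutate_sequence(base_unit, 1.0 - cfg.tandem_identity, unit_rng)
    tmpl = GeneTemplate("VvMybA4b", mut_unit[:len(tmpl4.sequence)],
                        list(tmpl4.exons), tmpl4.promoter_span)
    return tmpl, mut_unit[len(tmpl4.sequence):]


def build_haplotype(name: str,
                    config: LocusConfig | None = None) -> HaplotypeModel:
    """Assemble one BCL haplotype model (sequence + annotations)."""
    cfg = config or DEFAULT_CONFIG
    if name not in HAPLOTYPE_GENE_ORDER:
        raise ValueError(f"unknown haplotype {name!r}; expected one of "
                         f"{sorted(HAPLOTYPE_GENE_ORDER)}")
    if name == "HapF_DEL":
        return _build_hapf_del(cfg)

    templates = default_gene_templates(cfg.seed)
    family = "A" if name in ("HapA", "HapC-N") else "F"
    slots, te_bank = _family_assets(family, cfg)
    rng_hapA = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    rng_hapF = np.random.default_rng(np.random.SeedSequence([cfg.seed, 12]))

    order = HAPLOTYPE_GENE_ORDER[name]
    # per-gene alleles
    alleles: dict[str, GeneTemplate] = {}
    for gene in order:
        tmpl = templates[_template_of(gene)]
        if gene == "VvMybA4b":
            continue  # built from the mutated tandem copy below
        variants = _allele_variants(name, gene, templates, cfg,
                                    rng_hapA, rng_hapF, te_bank)
        alleles[gene] = build_allele(replace_name(tmpl, gene), variants)

    parts: list[str] = []
    genes: list[GenePlacement] = []
    tes: list[TeFeature] = []
    pos = 0

    def emit(seq: str) -> None:
        nonlocal pos
        parts.append(seq)
        pos += len(seq)

    def emit_slot(slot: str) -> None:
        seq = slots[slot]
        te_name = _F_SLOT_TES.get(slot) if family == "F" else None
        if te_name is None:
            emit(seq)
            return
        te_seq, l5, l3 = te_bank[te_name]
        half = len(seq) // 2
        emit(seq[:half])
        te_start = pos
        tes.append(TeFeature(te_name, te_start, te_start + len(te_seq),
                             (te_start + l5[0], te_start + l5[1]),
                             (te_start + l3[0], te_start + l3[1])))
        emit(te_seq)
        emit(seq[half:])

    emit_slot("L")
    plain = [g for g in order if g not in ("VvMybA4a", "VvMybA4b")]
    for i, gene in enumerate(plain):
        allele = alleles[gene]
        placement = GenePlacement(gene, allele, "+", pos)
        genes.append(placement)
        _register_gene_tes(placement, tes, cfg.ltr_len)
        emit(allele.sequence)
        if i < len(plain) - 1:
            emit_slot(f"g{i}")

    if "VvMybA4a" in order:
        # tandem unit pair replaces the single VvMybA4; the last plain gene
        # was VvMybA2, so the g6 gap still has to be emitted first
        emit_slot("g6")
        a4a = alleles["VvMybA4a"]
        placement = GenePlacement("VvMybA4a", a4a, "+", pos)
        genes.append(placement)
        emit(a4a.sequence)
        emit(slots["unit"])
        # second tandem copy: the pre-duplication unit (plain VvMybA4 +
        # its downstream flank) mutated to ~90% identity, then the RLG TE
        # inserted into exon 1
        tmpl4b, mut_flank = a4b_gene_template(cfg)
        a4b = build_allele(tmpl4b, _allele_variants(name, "VvMybA4b",
                                                    templates, cfg, rng_hapA,
                                                    rng_hapF, te_bank))
        placement = GenePlacement("VvMybA4b", a4b, "+", pos)
        genes.append(placement)
        _register_gene_tes(placement, tes, cfg.ltr_len)
        emit(a4b.sequence)
        emit(mut_flank)  # mutated copy of the unit flank
    elif "VvMybA4" in order:
        emit(slots["unit"])  # ancestral single-copy layout keeps the flank

    emit_slot("R")
    sequence = "".join(parts)
    model = HaplotypeModel(name, sequence, genes, tes,
                           meta={"config_seed": cfg.seed})
    if name == "HapF2":
        g3 = model.gene("VvMybA3")
        g4b = model.gene("VvMybA4b")
        model.meta["deletion_interval"] = (g3.start - cfg.del_upstream,
                                           g4b.end + cfg.del_downstream)
    return model


def replace_name(tmpl: GeneTemplate, name: str) -> GeneTemplate:
    return GeneTemplate(name, tmpl.sequence, list(tmpl.exons),
                        tmpl.promoter_span)


def _register_gene_tes(placement: GenePlacement, tes: list[TeFeature],
                       ltr_len: int) -> None:
    """TEs inserted inside a gene (Gret1, RLG_2) become locus-level TE
    features, located through the allele's edit log; the LTRs are the first
    and last ``ltr_len`` bases of the inserted element."""
    for edit in placement.allele.edits:
        if edit.kind == "te_insertion":
            start = placement.offset + edit.start
            end = placement.offset + edit.end
            tes.append(TeFeature(edit.label, start, end,
                                 (start, start + ltr_len),
                                 (end - ltr_len, end)))


def _build_hapf_del(cfg: LocusConfig) -> HaplotypeModel:
    parent = build_haplotype("HapF2", cfg)
    bp_left, bp_right = parent.meta["deletion_interval"]
    sequence = parent.sequence[:bp_left] + parent.sequence[bp_right:]
    delta = bp_right - bp_left
    genes = []
    for g in parent.genes:
        if g.end <= bp_left:
            genes.append(g)
        elif g.start >= bp_right:
            genes.append(GenePlacement(g.name, g.allele, g.strand,
                                       g.offset - delta))
        # genes inside [bp_left, bp_right) are deleted
    tes = []
    for t in parent.te_features:
        if t.end <= bp_left:
            tes.append(t)
        elif t.start >= bp_right:
            tes.append(t.shifted(-delta))
    model = HaplotypeModel("HapF_DEL", sequence, genes, tes,
                           meta={"config_seed": cfg.seed,
                                 "parent": "HapF2",
                                 "deleted_interval_on_parent":
                                     (bp_left, bp_right)})
    return model


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _apply_errors(seq: str, error_rate: float,
                  rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    k = rng.binomial(len(seq), error_rate)
    if k == 0:
        return seq
    arr = bytearray(seq.encode())
    for pos in rng.integers(0, len(arr), size=k):
        alts = [b for b in _BASES if b != arr[pos]]
        arr[pos] = alts[int(rng.integers(3))]
    return arr.decode()


def simulate_dna_reads(haplotypes: HaplotypeModel | Sequence[HaplotypeModel],
                       depth: float, read_len: int = 150,
                       error_rate: float = 0.0,
                       seed: int = 0) -> SimulatedReadSet:
    """Uniform single-end shotgun reads from a haplotype or a diploid pair.

    ``depth`` is the total fold-coverage; for a diploid pair each read is
    drawn from either haplotype with probability 1/2.
    """
    haps = ([haplotypes] if isinstance(haplotypes, HaplotypeModel)
            else list(haplotypes))
    if depth <= 0:
        raise ValueError("depth must be positive")
    for h in haps:
        if read_len >= len(h.sequence):
            raise ValueError("read_len must be shorter than the haplotype")
    rng = np.random.default_rng(seed)
    mean_len = float(np.mean([len(h.sequence) for h in haps]))
    n_reads = int(round(depth * mean_len / read_len))
    which = (rng.integers(0, len(haps), size=n_reads) if len(haps) > 1
             else np.zeros(n_reads, dtype=int))
    reads: list[SimRead] = []
    for i in range(n_reads):
        h = haps[which[i]]
        start = int(rng.integers(0, len(h.sequence) - read_len + 1))
        seq = _apply_errors(h.sequence[start:start + read_len], error_rate, rng)
        reads.append(SimRead(f"r{i}_{h.name}", seq,
                             (start, start + read_len), h.name))
    return SimulatedReadSet(reads, read_len, error_rate, seed)


def simulate_rna_reads(cfg: RnaSimConfig) -> SimulatedReadSet:
    """Multinomial RNA reads: allele read counts are proportional to
    ``tpm_a * length_a`` (abundance times transcript length)."""
    names = list(cfg.allele_cdnas)
    lengths = np.array([len(cfg.allele_cdnas[n]) for n in names], float)
    if np.any(lengths <= cfg.read_length):
        raise ValueError("read_length must be shorter than every transcript")
    tpm = np.array([cfg.allele_tpm.get(n, 0.0) for n in names], float)
    weights = tpm * lengths
    p = weights / weights.sum()
    rng = np.random.default_rng(cfg.seed)
    counts = rng.multinomial(cfg.n_reads, p)
    reads: list[SimRead] = []
    i = 0
    for name, count in zip(names, counts):
        seq_full = cfg.allele_cdnas[name]
        hi = len(seq_full) - cfg.read_length + 1
        starts = rng.integers(0, hi, size=count)
        for start in starts:
            start = int(start)
            seq = _apply_errors(seq_full[start:start + cfg.read_length],
                                cfg.error_rate, rng)
            reads.append(SimRead(f"t{i}_{name}", seq,
                                 (start, start + cfg.read_length), name))
            i += 1
    return SimulatedReadSet(reads, cfg.read_length, cfg.error_rate, cfg.seed)


def allele_cdna(model: HaplotypeModel, gene: str) -> str:
    """Spliced cDNA of a gene on a haplotype."""
    return model.gene(gene).allele.spliced()


# ---------------------------------------------------------------------------
# FASTA / GFF3 round trip
# ---------------------------------------------------------------------------

def write_fasta(model: HaplotypeModel, path) -> None:
    SeqIO.write([SeqRecord(Seq(model.sequence), id=model.name,
                           description="synthetic BCL haplotype")],
                str(path), "fasta")


def write_gff3(model: HaplotypeModel, path) -> None:
    """1-based closed coordinates (GFF3 convention)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {model.name} 1 {len(model.sequence)}\n")
        for g in model.genes:
            fh.write(f"{model.name}\tbcltools\tgene\t{g.start + 1}\t{g.end}\t"
                     f".\t{g.strand}\t.\tID={g.name}\n")
            for k, (s, e) in enumerate(g.exon_spans(), 1):
                fh.write(f"{model.name}\tbcltools\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={g.name}.exon{k};Parent={g.name}\n")
        for t in model.te_features:
            fh.write(f"{model.name}\tbcltools\trepeat_region\t{t.start + 1}\t"
                     f"{t.end}\t.\t+\t.\tID={t.name}\n")
            for tag, (s, e) in (("ltr5", t.ltr5), ("ltr3", t.ltr3)):
                fh.write(f"{model.name}\tbcltools\tlong_terminal_repeat\t"
                         f"{s + 1}\t{e}\t.\t+\t.\t"
                         f"ID={t.name}.{tag};Parent={t.name}\n")


def read_haplotype(fasta_path, gff3_path) -> HaplotypeModel:
    """Rebuild a HaplotypeModel from FASTA + GFF3 written by this module."""
    import gffutils

    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    sequence = str(record.seq)
    db = gffutils.create_db(str(gff3_path), ":memory:",
                            merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GenePlacement] = []
    for f in db.features_of_type("gene", order_by="start"):
        exons = sorted((c.start - 1, c.end)
                       for c in db.children(f, featuretype="exon"))
        start, end = f.start - 1, f.end
        local_exons = [(s - start, e - start) for s, e in exons]
        allele = GeneTemplate(f.id, sequence[start:end], local_exons, (0, 0))
        genes.append(GenePlacement(f.id, allele, f.strand, start))
    tes: list[TeFeature] = []
    for f in db.features_of_type("repeat_region", order_by="start"):
        ltrs = {}
        for c in db.children(f, featuretype="long_terminal_repeat"):
            tag = c.id.rsplit(".", 1)[-1]
            ltrs[tag] = (c.start - 1, c.end)
        tes.append(TeFeature(f.id, f.start - 1, f.end,
                             ltrs.get("ltr5", (f.start - 1, f.start - 1)),
                             ltrs.get("ltr3", (f.end, f.end))))
    return HaplotypeModel(record.id, sequence, genes, tes)
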