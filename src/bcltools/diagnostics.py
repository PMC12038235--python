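"""BCL haplotype calling from read alignments.

Implements the read-level diagnostic criteria used to genotype the berry
color locus from whole-genome sequencing data mapped onto the HapF
reference:

* HapF presence: reads spanning the 33-bp insertion in intron 2 of
  ``VvMybA1_SUB`` (with a corroborating SNP at position 99 of that intron);
* HapF2: reads spanning (i) the junction of the two ``VvMybA4`` tandem
  copies, (ii) the 213-bp insertion in ``VvMybA4a`` and (iii) the junction
  between the RLG retrotransposon and ``VvMybA4b``;
* HapF_DEL: confirmed zero coverage over HapF-specific intergenic segments
  inside the deleted ``VvMybA3``..``VvMybA4b`` interval, with covered
  flanks (so a deletion is distinguished from missing data).

A junction- or insertion-spanning read must align contiguously (one
gapless block) with at least ``min_overhang`` matched bases on each side
of the breakpoint.  The decision rule is a pure function of the collected
evidence; conflicting or sub-threshold evidence yields ``ambiguous``
rather than a hard call.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
import yaml

from .synthetic_locus import (HaplotypeModel, SimulatedReadSet, revcomp,
                              write_fasta)

logger = logging.getLogger(__name__)

MARKER_KINDS = ("junction", "private_snp", "insertion_span", "absence_region")

CALLS = ("HapF1", "HapF2", "HapF_DEL", "no_HapF", "ambiguous")


class IncompleteEvidenceError(ValueError):
    """A marker required by the decision rule has no evidence."""


@dataclass(frozen=True)
class DiagnosticMarker:
    id: str
    kind: str
    reference: str
    position: int | None = None               # junction, private_snp
    interval: tuple[int, int] | None = None   # insertion_span, absence_region
    expected_state: str | None = None         # private_snp
    supports: str = ""                        # subhaplotype label
    flank: int = 1500                         # absence_region flank window

    def __post_init__(self):
        if self.kind not in MARKER_KINDS:
            raise ValueError(f"unknown marker kind {self.kind!r}")
        if self.kind in ("junction", "private_snp") and self.position is None:
            raise ValueError(f"{self.id}: marker kind {self.kind} needs a "
                             "position")
        if self.kind in ("insertion_span", "absence_region") \
                and self.interval is None:
            raise ValueError(f"{self.id}: marker kind {self.kind} needs an "
                             "interval")
        if self.kind == "private_snp" and not self.expected_state:
            raise ValueError(f"{self.id}: private_snp needs expected_state")


@dataclass(frozen=True)
class ReadEvidence:
    marker_id: str
    supporting_reads: int
    opposing_reads: int
    mean_overhang: float = 0.0


@dataclass(frozen=True)
class Thresholds:
    min_reads: int = 3
    min_overhang: int = 20


@dataclass
class HaplotypeCall:
    accession_id: str
    call: str
    evidence: list[ReadEvidence]
    thresholds: Thresholds
    notes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class HapFDetection:
    detected: bool
    low_evidence: bool
    supporting_reads: int

    def __bool__(self) -> bool:
        return self.detected


# ---------------------------------------------------------------------------
# Alignment scanning
# ---------------------------------------------------------------------------

def _iter_records(alignments):
    """Accept a SAM/BAM path or an iterable of AlignedSegment records;
    unmapped and secondary/supplementary records are ignored."""
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            if fh.header.nreferences == 0:
                raise ValueError("alignment file has no reference in header")
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                yield rec
    else:
        for rec in alignments:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            yield rec


def _spanning_block(rec, window: tuple[int, int]):
    """The single gapless aligned block covering [window), if any."""
    for s, e in rec.get_blocks():
        if s <= window[0] and e >= window[1]:
            return (s, e)
    return None


def _touches(rec, start: int, end: int) -> bool:
    return any(s < end and e > start for s, e in rec.get_blocks())


def _base_at(rec, pos: int):
    for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
        if rpos == pos:
            return rec.query_sequence[qpos]
    return None


def scan_marker(alignments, marker: DiagnosticMarker,
                min_overhang: int = 20) -> ReadEvidence:
    """Count reads supporting / opposing one diagnostic marker.

    junction / insertion_span
        supporting: one gapless block extends >= min_overhang beyond both
        sides of the breakpoint (junction) or the inserted interval;
        opposing: reads touching the breakpoint region that fail the
        contiguity requirement.
    private_snp
        supporting: aligned base at the position equals expected_state;
        opposing: any other aligned base.
    absence_region
        supporting: min of the two flank-window coverages when the interior
        has zero coverage (deletion confirmed, not just missing data),
        else 0; opposing: reads covering the interior.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            if marker.reference not in fh.references:
                raise ValueError(f"marker reference {marker.reference!r} "
                                 "absent from alignment header")
    m = marker
    supporting = opposing = 0
    overhangs: list[float] = []
    left_cov = right_cov = 0

    if m.kind in ("junction", "insertion_span"):
        if m.kind == "junction":
            windows = [(m.position - min_overhang, m.position + min_overhang)]
        else:
            # one window per insert boundary: reads cannot physically span
            # an insert longer than themselves, but a gapless block across
            # either boundary is proof the insert is present (reads without
            # it align with a deletion, splitting the block exactly there)
            windows = [(m.interval[0] - min_overhang,
                        m.interval[0] + min_overhang),
                       (m.interval[1] - min_overhang,
                        m.interval[1] + min_overhang)]
        probe = (windows[0][0], windows[-1][1])
        for rec in _iter_records(alignments):
            if rec.reference_name != m.reference:
                continue
            if not _touches(rec, probe[0], probe[1]):
                continue
            block = None
            for window in windows:
                block = _spanning_block(rec, window)
                if block is not None:
                    break
            if block is not None:
                supporting += 1
                overhangs.append(min(window[0] - block[0],
                                     block[1] - window[1]) + min_overhang)
            else:
                opposing += 1
    elif m.kind == "private_snp":
        for rec in _iter_records(alignments):
            if rec.reference_name != m.reference:
                continue
            if not _touches(rec, m.position, m.position + 1):
                continue
            base = _base_at(rec, m.position)
            if base is None:
                continue
            if base.upper() == m.expected_state.upper():
                supporting += 1
            else:
                opposing += 1
    elif m.kind == "absence_region":
        start, end = m.interval
        for rec in _iter_records(alignments):
            if rec.reference_name != m.reference:
                continue
            if _touches(rec, start, end):
                opposing += 1
            if _touches(rec, start - m.flank, start):
                left_cov += 1
            if _touches(rec, end, end + m.flank):
                right_cov += 1
        if opposing == 0:
            supporting = min(left_cov, right_cov)
    return ReadEvidence(m.id, supporting, opposing,
                        float(sum(overhangs) / len(overhangs))
                        if overhangs else 0.0)


def collect_evidence(alignments, markers: Sequence[DiagnosticMarker],
                     min_overhang: int = 20) -> dict[str, ReadEvidence]:
    """Evidence for a whole marker panel.

    Loads the alignment once and scans each marker over the in-memory
    records (markers are many, files are read-once).
    """
    records = list(_iter_records(alignments))
    return {m.id: scan_marker(records, m, min_overhang) for m in markers}


# ---------------------------------------------------------------------------
# Decision rule
# ---------------------------------------------------------------------------

def detect_hapF(evidence: ReadEvidence, min_reads: int = 3) -> HapFDetection:
    """HapF presence from the intron-2 33-bp insertion evidence."""
    n = evidence.supporting_reads
    detected = n >= min_reads
    low = (not detected) and n > 0
    if low:
        logger.warning("HapF insertion support %d below min_reads %d: "
                       "low evidence", n, min_reads)
    return HapFDetection(detected, low, n)


#: marker ids the default decision rule requires
REQUIRED_MARKERS = {
    "hapf_ins33": "33-bp intron-2 insertion of VvMybA1_SUB",
    "f2_tandem_junction": "junction of the two VvMybA4 tandem copies",
    "f2_ins213": "213-bp insertion in VvMybA4a",
    "f2_rlg_junction": "RLG retrotransposon / VvMybA4b junction",
    "fdel_absence_1": "HapF-specific segment in the deleted interval",
    "fdel_absence_2": "HapF-specific segment in the deleted interval",
}


def classify_subhaplotype(evidence: Mapping[str, ReadEvidence] |
                          Iterable[ReadEvidence],
                          thresholds: Thresholds = Thresholds(),
                          accession_id: str = "sample") -> HaplotypeCall:
    """Call the F subhaplotype from collected marker evidence.

    Pure function of evidence + thresholds.  Decision rule: no 33-bp
    insertion support -> no_HapF (sub-threshold support -> ambiguous);
    confirmed absence of the HapF-specific interval with no HapF2 marker
    support -> HapF_DEL; tandem-junction support with at least one
    corroborating HapF2 marker -> HapF2; no HapF2 marker support and
    absence not confirmed -> HapF1; anything conflicting -> ambiguous.
    """
    if not isinstance(evidence, Mapping):
        evidence = {e.marker_id: e for e in evidence}
    for mid, what in REQUIRED_MARKERS.items():
        if mid not in evidence:
            raise IncompleteEvidenceError(
                f"missing evidence for marker {mid!r} ({what})")
    thr = thresholds
    notes: list[str] = []
    det = detect_hapF(evidence["hapf_ins33"], thr.min_reads)

    f2_ids = ("f2_tandem_junction", "f2_ins213", "f2_rlg_junction")
    f2_sup = {mid: evidence[mid].supporting_reads >= thr.min_reads
              for mid in f2_ids}
    absence_ids = [mid for mid in evidence if mid.startswith("fdel_absence")]
    absence_ok = all(evidence[mid].supporting_reads >= thr.min_reads
                     and evidence[mid].opposing_reads == 0
                     for mid in absence_ids)

    if not det.detected:
        if det.low_evidence:
            call = "ambiguous"
            notes.append(f"sub-threshold HapF support "
                         f"({det.supporting_reads} reads)")
        else:
            call = "no_HapF"
    elif absence_ok and not any(f2_sup.values()):
        call = "HapF_DEL"
    elif absence_ok:
        call = "ambiguous"
        notes.append("deletion confirmed but HapF2 markers also supported")
    elif f2_sup["f2_tandem_junction"] and (f2_sup["f2_ins213"]
                                           or f2_sup["f2_rlg_junction"]):
        call = "HapF2"
    elif not any(f2_sup.values()):
        call = "HapF1"
    else:
        call = "ambiguous"
        notes.append("HapF2 marker evidence incomplete: "
                     + ", ".join(f"{k}={evidence[k].supporting_reads}"
                                 for k in f2_ids))
    return HaplotypeCall(accession_id, call, list(evidence.values()),
                         thr, notes)


def diagnose(alignments, markers: Sequence[DiagnosticMarker],
             thresholds: Thresholds = Thresholds(),
             accession_id: str = "sample") -> HaplotypeCall:
    """collect_evidence + classify_subhaplotype in one step."""
    ev = collect_evidence(alignments, markers, thresholds.min_overhang)
    return classify_subhaplotype(ev, thresholds, accession_id)


# ---------------------------------------------------------------------------
# Default marker panel built from the synthetic HapF2 reference
# ---------------------------------------------------------------------------

def _edit_span(model: HaplotypeModel, gene: str, label: str):
    g = model.gene(gene)
    for e in g.allele.edits:
        if e.label == label:
            return (g.offset + e.start, g.offset + e.end)
    raise KeyError(f"{gene} has no edit {label!r}")


def default_marker_panel(f2: HaplotypeModel,
                         absence_margin: int = 50,
                         flank: int = 1500) -> list[DiagnosticMarker]:
    """Diagnostic markers on the HapF2 haplotype used as mapping reference.

    The two absence markers sit on HapF-specific intergenic spacers inside
    the deleted interval; their flank windows reach into the neighbouring
    gene bodies, which attract reads from any haplotype (the genes are
    shared), so flanking coverage distinguishes a true deletion from
    missing data even in a HapF_DEL/HapA heterozygote.
    """
    ref = f2.name
    ins33 = _edit_span(f2, "VvMybA1", "ins33")
    snp_pos = _edit_span(f2, "VvMybA1", "snp_intron2_99")[0]
    ins213 = _edit_span(f2, "VvMybA4a", "ins213")
    rlg = next(t for t in f2.te_features if t.name == "RLG_2")
    a4b = f2.gene("VvMybA4b")
    a11, a10 = f2.gene("VvMybA11"), f2.gene("VvMybA10")
    a2, a4a = f2.gene("VvMybA2"), f2.gene("VvMybA4a")
    return [
        DiagnosticMarker("hapf_ins33", "insertion_span", ref,
                         interval=ins33, supports="HapF"),
        DiagnosticMarker("sub_snp_intron2_99", "private_snp", ref,
                         position=snp_pos,
                         expected_state=f2.sequence[snp_pos],
                         supports="HapF"),
        DiagnosticMarker("f2_tandem_junction", "junction", ref,
                         position=a4b.start, supports="HapF2"),
        DiagnosticMarker("f2_ins213", "insertion_span", ref,
                         interval=ins213, supports="HapF2"),
        DiagnosticMarker("f2_rlg_junction", "junction", ref,
                         position=rlg.start, supports="HapF2"),
        DiagnosticMarker("fdel_absence_1", "absence_region", ref,
                         interval=(a11.end + absence_margin,
                                   a10.start - absence_margin),
                         supports="HapF_DEL", flank=flank),
        DiagnosticMarker("fdel_absence_2", "absence_region", ref,
                         interval=(a2.end + absence_margin,
                                   a4a.start - absence_margin),
                         supports="HapF_DEL", flank=flank),
    ]


def markers_to_yaml(markers: Sequence[DiagnosticMarker], path) -> None:
    data = [{k: v for k, v in vars(m).items() if v is not None}
            for m in markers]
    for row in data:
        if "interval" in row:
            row["interval"] = list(row["interval"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def markers_from_yaml(path) -> list[DiagnosticMarker]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    out = []
    for row in data:
        if "interval" in row and row["interval"] is not None:
            row["interval"] = tuple(row["interval"])
        out.append(DiagnosticMarker(**row))
    return out


# ---------------------------------------------------------------------------
# Read mapping (external: minimap2)
# ---------------------------------------------------------------------------

def align_reads(reads: SimulatedReadSet | str | Path,
                reference: HaplotypeModel | str | Path,
                out_sam: str | Path | None = None,
                workdir: str | Path | None = None) -> Path:
    """Map short reads to a reference with minimap2 (short-read preset),
    returning the SAM path.  Mapping itself is out of scope here; this is
    a convenience wrapper for simulated data."""
    if shutil.which("minimap2") is None:
        raise RuntimeError("minimap2 not found on PATH")
    tmp = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="bcl_"))
    tmp.mkdir(parents=True, exist_ok=True)
    if isinstance(reference, HaplotypeModel):
        ref_path = tmp / "ref.fa"
        write_fasta(reference, ref_path)
    else:
        ref_path = Path(reference)
    if isinstance(reads, SimulatedReadSet):
        reads_path = tmp / "reads.fq"
        reads.to_fastq(reads_path)
    else:
        reads_path = Path(reads)
    sam = Path(out_sam) if out_sam else tmp / "aln.sam"
    cmd = ["minimap2", "-ax", "sr", "--secondary=no", "-t", "1",
           str(ref_path), str(reads_path)]
    with open(sam, "w") as fh:
        subprocess.run(cmd, stdout=fh, stderr=subprocess.DEVNULL, check=True)
    return sam


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def insilico_pcr(sequence: str, forward_primer: str, reverse_primer: str,
                 max_product: int = 5000) -> list[tuple[int, tuple[int, int]]]:
    """Exact-match PCR products: (length, (start, end)) for every pair of a
    forward site and a downstream reverse-complement reverse-primer site
    within ``max_product``.  Both template orientations are considered, so
    the product set is invariant under reverse-complementing the input.
    """
    for p in (forward_primer, reverse_primer):
        if len(p) < 15:
            raise ValueError("primers must be at least 15 bp")
    seq = sequence.upper()
    products: set[tuple[int, tuple[int, int]]] = set()
    for p1, p2 in ((forward_primer, reverse_primer),
                   (reverse_primer, forward_primer)):
        starts = _find_all(seq, p1.upper())
        site2 = revcomp(p2).upper()
        ends = [(j, j + len(site2)) for j in _find_all(seq, site2)]
        for s in starts:
            for j, e in ends:
                if j >= s + len(p1) and 0 < e - s <= max_product:
                    products.add((e - s, (s, e)))
    return sorted(products)


@dataclass(frozen=True)
class PcrAssay:
    """An INDEL-typing PCR assay: primers plus the diagnostic product
    length expected from the targeted allele."""
    forward: str
    reverse: str
    diagnostic_length: int
    max_product: int = 2000
    tolerance: int = 0


def assay_vvmyba3_hapF(hap_pair: Sequence[HaplotypeModel],
                       assay: PcrAssay) -> bool:
    """Positive iff either haplotype of a diploid yields the product length
    diagnostic for VvMybA3_HapF (the allele without the 209-bp exon-3
    deletion)."""
    for hap in hap_pair:
        for length, _span in insilico_pcr(hap.sequence, assay.forward,
                                          assay.reverse, assay.max_product):
            if abs(length - assay.diagnostic_length) <= assay.tolerance:
                return True
    return False


def vvmyba3_hapf_assay(f_model: HaplotypeModel,
                       primer_len: int = 22) -> PcrAssay:
    """Design the VvMybA3_HapF INDEL assay on a HapF model.

    The forward primer sits in intron 2 (identical across alleles) and the
    reverse primer in the distal part of exon 3, past the 209-bp deletion
    of the non-F alleles and clear of the HapF-private SNPs, so both
    alleles amplify but with a 209-bp product-length difference; the long
    product is diagnostic for HapF.
    """
    g = f_model.gene("VvMybA3")
    allele = g.allele
    i2_start, i2_end = allele.exons[1][1], allele.exons[2][0]
    e3_start, e3_end = allele.exons[2]
    fwd = allele.sequence[i2_start + 40:i2_start + 40 + primer_len]
    snp_positions = {e.start for e in allele.edits
                     if e.kind == "substitution"}
    rev_start = None
    for cand in range(e3_start + 300, e3_end - primer_len):
        if not any(cand <= p < cand + primer_len for p in snp_positions):
            rev_start = cand
            break
    if rev_start is None:
        raise RuntimeError("no SNP-free reverse-primer window in exon 3")
    site = allele.sequence[rev_start:rev_start + primer_len]
    rev = revcomp(site)
    products = insilico_pcr(allele.sequence, fwd, rev)
    if len(products) != 1:
        raise RuntimeError("assay design did not yield a unique product")
    return PcrAssay(fwd, rev, diagnostic_length=products[0][0])
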