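"""Structural analysis of MybA gene clusters.

Gene discovery by approximate matching of the conserved R2R3 probe,
dotplot comparison, annotation-based structural differencing with
sequence-refined breakpoints, CDS translation, and LTR-retrotransposon
insertion dating from LTR-pair divergence (T = K / 2mu).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import numpy as np
from Bio.Seq import Seq

from .synthetic_locus import GeneTemplate, HaplotypeModel, revcomp

logger = logging.getLogger(__name__)

DEFAULT_MU = 1.3e-8  # substitutions / site / year


class UnreliableLtrPairError(ValueError):
    """LTR pair too divergent to be a credible insertion-time clock."""


# ---------------------------------------------------------------------------
# Gene discovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneHit:
    contig: str
    start: int
    end: int
    strand: str
    identity: float
    label: str = ""


def _scan_strand(contig: str, probe: str, min_identity: float,
                 strand: str, contig_len: int) -> list[tuple[int, int, float]]:
    """All non-overlapping approximate occurrences of the probe on one
    strand, by iterative best-hit masking with edlib infix alignment."""
    max_dist = int((1.0 - min_identity) * len(probe))
    work = bytearray(contig.encode())
    hits: list[tuple[int, int, float]] = []
    for _ in range(200):  # generous bound on cluster size
        res = edlib.align(probe, work.decode(), mode="HW", task="locations",
                          k=max_dist)
        if res["editDistance"] < 0:
            break
        identity = 1.0 - res["editDistance"] / len(probe)
        # co-optimal locations of the same occurrence cluster together;
        # take one representative per cluster, then mask
        locs = sorted((s, e + 1) for s, e in res["locations"])
        merged = [list(locs[0])]
        for s, e in locs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            mid = (s + e) // 2
            half = len(probe) // 2
            start, end = max(0, mid - half), min(len(work), mid + half)
            hits.append((start, end, identity))
            work[start:end] = b"N" * (end - start)
    if strand == "-":
        hits = [(contig_len - e, contig_len - s, ident)
                for s, e, ident in hits]
    return hits


def find_myba_genes(contig: str, probe: str, min_identity: float = 0.6,
                    min_coverage: float = 0.9,
                    contig_id: str = "contig") -> list[GeneHit]:
    """Locate MybA-like genes on both strands of a contig.

    The probe is aligned as an infix (edlib), so every reported hit covers
    the full probe; ``min_coverage`` is kept for interface compatibility
    with partial-hit searches and is trivially satisfied here.
    """
    if len(probe) < 100:
        raise ValueError("probe must be at least 100 bp")
    if not contig:
        return []
    tagged = ([(s, e, i, "+") for s, e, i in
               _scan_strand(contig, probe, min_identity, "+", len(contig))]
              + [(s, e, i, "-") for s, e, i in
                 _scan_strand(revcomp(contig), probe, min_identity, "-",
                              len(contig))])
    tagged.sort()
    merged: list[list] = []
    for s, e, ident, strand in tagged:
        if merged and s < merged[-1][1]:  # overlapping hits: keep the better
            if ident > merged[-1][2]:
                merged[-1] = [s, e, ident, strand]
        else:
            merged.append([s, e, ident, strand])
    return [GeneHit(contig_id, s, e, strand, round(ident, 4), f"hit{k+1}")
            for k, (s, e, ident, strand) in enumerate(merged)]


# ---------------------------------------------------------------------------
# Dotplot
# ---------------------------------------------------------------------------

def dotplot(seq_a: str, seq_b: str, word_size: int = 12
            ) -> list[tuple[int, int, str]]:
    """Exact shared words between two sequences, both strands.

    Returns (position in A, position in B, strand) triples; strand '-'
    means the word in A matches the reverse complement of B at that
    position (anti-diagonal structure).
    """
    if word_size < 8:
        raise ValueError("word_size must be >= 8")
    index: dict[str, list[int]] = {}
    for i in range(len(seq_a) - word_size + 1):
        index.setdefault(seq_a[i:i + word_size], []).append(i)
    out: list[tuple[int, int, str]] = []
    for j in range(len(seq_b) - word_size + 1):
        word = seq_b[j:j + word_size]
        for i in index.get(word, ()):
            out.append((i, j, "+"))
        for i in index.get(revcomp(word), ()):
            out.append((i, j, "-"))
    return out


def save_dotplot(matches, path, title="dotplot") -> None:
    """Render dotplot matches to an image file (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for strand, color in (("+", "tab:blue"), ("-", "tab:red")):
        pts = [(i, j) for i, j, s in matches if s == strand]
        if pts:
            xs, ys = zip(*pts)
            ax.plot(xs, ys, ".", ms=1, color=color)
    ax.set_xlabel("sequence A")
    ax.set_ylabel("sequence B")
    ax.set_title(title)
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Structural differencing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffInterval:
    """A segment present in one model and absent in the other.

    ``upstream_flank`` is the distance from the segment start to the first
    contained gene; ``downstream_flank`` from the last contained gene to the
    segment end.
    """

    start: int
    end: int
    genes: tuple[str, ...]
    upstream_flank: int
    downstream_flank: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class StructuralDiff:
    deletions: list[DiffInterval]
    insertions: list[DiffInterval]
    order_changes: list[tuple[str, str]]


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _missing_runs(a: HaplotypeModel, b: HaplotypeModel) -> list[DiffInterval]:
    """Maximal runs of genes of ``a`` absent from ``b``, with breakpoints
    refined by comparing the inter-anchor sequence of both models."""
    b_names = set(b.gene_names())
    runs: list[list] = []
    for idx, g in enumerate(a.genes):
        if g.name in b_names:
            continue
        if runs and runs[-1][-1] == idx - 1:
            runs[-1].append(idx)
        else:
            runs.append([idx])
    out: list[DiffInterval] = []
    for run in runs:
        left = next((a.genes[i] for i in range(run[0] - 1, -1, -1)
                     if a.genes[i].name in b_names), None)
        right = next((a.genes[i] for i in range(run[-1] + 1, len(a.genes))
                      if a.genes[i].name in b_names), None)
        la_start = left.end if left else 0
        la_end = right.start if right else len(a.sequence)
        lb_start = b.gene(left.name).end if left else 0
        lb_end = b.gene(right.name).start if right else len(b.sequence)
        seg_a = a.sequence[la_start:la_end]
        seg_b = b.sequence[lb_start:lb_end]
        extra = len(seg_a) - len(seg_b)
        if extra <= 0:
            # annotation says genes are missing but no net length gain;
            # fall back to the span of the missing genes themselves
            start = a.genes[run[0]].start
            end = a.genes[run[-1]].end
        else:
            p = min(_common_prefix(seg_a, seg_b), len(seg_b))
            start = la_start + p
            end = start + extra
        contained = tuple(g.name for g in a.genes
                          if start <= g.start and g.end <= end)
        if contained:
            first = a.gene(contained[0])
            last = a.gene(contained[-1])
            up, down = first.start - start, end - last.end
        else:
            up = down = 0
        out.append(DiffInterval(start, end, contained, up, down))
    return out


def detect_structural_diff(model_a: HaplotypeModel,
                           model_b: HaplotypeModel) -> StructuralDiff:
    """Deletions (in A, absent from B), insertions (the converse) and gene
    order changes between two annotated haplotype models."""
    deletions = _missing_runs(model_a, model_b)
    insertions = _missing_runs(model_b, model_a)
    shared = [n for n in model_a.gene_names() if n in set(model_b.gene_names())]
    order_b = [n for n in model_b.gene_names() if n in set(shared)]
    order_changes = [(x, y) for x, y in zip(shared, order_b) if x != y]
    return StructuralDiff(deletions, insertions, order_changes)


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinResult:
    protein: str
    length: int
    premature_stop: bool
    frameshift: bool
    stop_found: bool


def translate_gene(gene: GeneTemplate) -> ProteinResult:
    """Translate a gene's spliced CDS; flag frameshifts and premature stops.

    A healthy CDS starts with ATG, has length divisible by 3 and ends at
    its single terminal stop; anything else is reported, not raised, except
    a missing start codon or ambiguous bases, which are hard errors.
    """
    cds = gene.spliced().upper()
    if not cds.startswith("ATG"):
        raise ValueError(f"{gene.name}: CDS does not start with ATG")
    if "N" in cds:
        raise ValueError(f"{gene.name}: CDS contains ambiguous bases")
    frameshift = len(cds) % 3 != 0
    usable = cds[:len(cds) - len(cds) % 3]
    full = str(Seq(usable).translate())
    stop_index = full.find("*")
    stop_found = stop_index != -1
    protein = full[:stop_index] if stop_found else full
    # premature: a stop before the final codon, or a frame-broken CDS
    premature = frameshift or (stop_found and stop_index < len(full) - 1)
    return ProteinResult(protein, len(protein), premature, frameshift,
                         stop_found)


# ---------------------------------------------------------------------------
# Pairwise identity and allele comparison
# ---------------------------------------------------------------------------

def _global_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    # affine gaps: a substitution is always cheaper than an indel pair, so
    # substitution-only divergence aligns gaplessly (unit-cost edit paths
    # would otherwise trade adjacent mismatches for gap pairs and deflate
    # the mismatch fraction)
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _global_aligner()


def _global_alignment_columns(seq_a: str, seq_b: str):
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Matches over aligned columns, terminal gaps excluded, after global
    alignment."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    qa, ta = _global_alignment_columns(seq_a, seq_b)
    lo = 0
    hi = len(qa)
    while lo < hi and (qa[lo] == "-" or ta[lo] == "-"):
        lo += 1
    while hi > lo and (qa[hi - 1] == "-" or ta[hi - 1] == "-"):
        hi -= 1
    cols = hi - lo
    if cols == 0:
        return 0.0
    matches = sum(qa[i] == ta[i] for i in range(lo, hi))
    return matches / cols


@dataclass(frozen=True)
class IndelEvent:
    kind: str  # "insertion" (in A relative to B) or "deletion"
    position: int  # on B
    length: int


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def allele_indel_events(seq_a: str, seq_b: str,
                        min_anchor: int = 15) -> list[IndelEvent]:
    """Indel events distinguishing two allele sequences, from a global
    alignment (A as query, B as reference).

    Optimal edit paths split a long insertion wherever inserted bases
    coincidentally match the reference, so gap runs separated by exact
    anchors shorter than ``min_anchor`` are merged into one event of the
    net length; real inter-event anchors are orders of magnitude longer.
    """
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    events: list[IndelEvent] = []
    ins = dele = 0
    event_start = 0
    pos_b = 0

    def flush():
        nonlocal ins, dele
        net = ins - dele
        if net > 0:
            events.append(IndelEvent("insertion", event_start, net))
        elif net < 0:
            events.append(IndelEvent("deletion", event_start, -net))
        ins = dele = 0

    in_event = False
    for n, op in _parse_cigar(res["cigar"]):
        if op == "I":
            if not in_event:
                event_start, in_event = pos_b, True
            ins += n
        elif op == "D":
            if not in_event:
                event_start, in_event = pos_b, True
            dele += n
            pos_b += n
        else:  # '=', 'X' or 'M' consume both sequences
            if in_event and op == "=" and n >= min_anchor:
                flush()
                in_event = False
            pos_b += n
    if in_event:
        flush()
    return events


# ---------------------------------------------------------------------------
# LTR insertion dating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TeAgeEstimate:
    te_name: str
    p_distance: float          # raw mismatch fraction between the LTRs
    divergence: float          # corrected K, substitutions / site
    mu: float
    age: float                 # years, K / (2 mu)
    correction: str


def _ltr_column_counts(ltr_a: str, ltr_b: str):
    qa, ta = _global_alignment_columns(ltr_a, ltr_b)
    lo, hi = 0, len(qa)
    while lo < hi and (qa[lo] == "-" or ta[lo] == "-"):
        lo += 1
    while hi > lo and (qa[hi - 1] == "-" or ta[hi - 1] == "-"):
        hi -= 1
    transitions = transversions = matches = cols = all_cols = 0
    purines = {"A", "G"}
    for i in range(lo, hi):
        x, y = qa[i], ta[i]
        all_cols += 1
        if x == "-" or y == "-":
            continue
        cols += 1
        if x == y:
            matches += 1
        elif (x in purines) == (y in purines):
            transitions += 1
        else:
            transversions += 1
    return matches, transitions, transversions, cols, all_cols


def ltr_age(te_seq: str, ltr5: tuple[int, int], ltr3: tuple[int, int],
            mu: float = DEFAULT_MU, correction: str = "jc",
            te_name: str = "") -> TeAgeEstimate:
    """Insertion age of an LTR retrotransposon from its LTR-pair divergence.

    The two LTRs are identical at insertion time; their accumulated
    divergence K (default Jukes-Cantor corrected, Kimura 2-parameter behind
    the ``correction='k2p'`` flag) dates the insertion as ``T = K / (2 mu)``.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    a = te_seq[ltr5[0]:ltr5[1]]
    b = te_seq[ltr3[0]:ltr3[1]]
    if len(a) < 100 or len(b) < 100:
        raise ValueError("both LTRs must be at least 100 bp")
    matches, ts, tv, cols, all_cols = _ltr_column_counts(a, b)
    # identity over all non-terminal columns (gaps included) screens out
    # sequence pairs that are not genuinely homologous LTR copies
    identity = matches / all_cols if all_cols else 0.0
    if identity < 0.6:
        raise UnreliableLtrPairError(
            f"LTR pair identity {identity:.2f} < 0.60; not a reliable clock")
    p = (ts + tv) / cols
    if correction == "jc":
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            raise UnreliableLtrPairError("saturated LTR divergence")
        k = -0.75 * np.log(arg)
    elif correction == "k2p":
        pp, q = ts / cols, tv / cols
        a1, a2 = 1.0 - 2.0 * pp - q, 1.0 - 2.0 * q
        if a1 <= 0 or a2 <= 0:
            raise UnreliableLtrPairError("saturated LTR divergence")
        k = -0.5 * np.log(a1) - 0.25 * np.log(a2)
    else:
        raise ValueError("correction must be 'jc' or 'k2p'")
    return TeAgeEstimate(te_name, p, float(k), mu, float(k) / (2.0 * mu),
                         correction)


def date_te(model: HaplotypeModel, te_name: str,
            mu: float = DEFAULT_MU, correction: str = "jc") -> TeAgeEstimate:
    """Convenience wrapper: date an annotated TE on a haplotype model."""
    te = next(t for t in model.te_features if t.name == te_name)
    local5 = (te.ltr5[0] - te.start, te.ltr5[1] - te.start)
    local3 = (te.ltr3[0] - te.start, te.ltr3[1] - te.start)
    return ltr_age(model.sequence[te.start:te.end], local5, local3,
                   mu, correction, te_name)
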