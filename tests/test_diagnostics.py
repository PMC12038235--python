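"""Marker scanning, the subhaplotype decision rule, and in-silico PCR."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bcltools.diagnostics as dx
import bcltools.synthetic_locus as sl
from bcltools.diagnostics import (DiagnosticMarker, ReadEvidence, Thresholds,
                                  classify_subhaplotype, detect_hapF,
                                  insilico_pcr, scan_marker)

from conftest import write_sam

REF = "ref"
REF_LEN = 2000
BP = 1000  # breakpoint used by hand-built alignments


def junction_marker(**kw):
    return DiagnosticMarker("j1", "junction", REF, position=BP,
                            supports="HapF2", **kw)


class TestScanMarkerJunction:
    def test_supporting_counts_match_bruteforce_overhang_rule(self, tmp_path):
        """Reads support the junction iff they align gaplessly with >= 20
        matched bases on each side of the breakpoint."""
        starts = [BP - 150, BP - 100, BP - 80, BP - 30, BP - 21, BP - 20,
                  BP - 19, BP - 10, BP, BP - 140]
        recs = [(f"r{i}", s, "100M", "A" * 100) for i, s in enumerate(starts)]
        sam = write_sam(tmp_path / "a.sam", REF, REF_LEN, recs)
        oracle = sum(s <= BP - 20 and s + 100 >= BP + 20 for s in starts)
        ev = scan_marker(str(sam), junction_marker(), min_overhang=20)
        assert ev.supporting_reads == oracle
        assert ev.supporting_reads + ev.opposing_reads == sum(
            s + 100 > BP - 20 and s < BP + 20 for s in starts)

    def test_empty_alignment_gives_zero_zero(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", REF, REF_LEN, [])
        ev = scan_marker(str(sam), junction_marker())
        assert (ev.supporting_reads, ev.opposing_reads) == (0, 0)

    def test_read_ending_exactly_at_breakpoint_does_not_support(
            self, tmp_path):
        recs = [("r1", BP - 100, "100M", "A" * 100),   # ends at breakpoint
                ("r2", BP, "100M", "A" * 100)]          # starts at breakpoint
        sam = write_sam(tmp_path / "a.sam", REF, REF_LEN, recs)
        ev = scan_marker(str(sam), junction_marker())
        assert ev.supporting_reads == 0

    def test_gapped_read_does_not_support(self, tmp_path):
        # a 30-bp deletion right at the breakpoint splits the block
        recs = [("r1", BP - 50, "50M30D50M", "A" * 100)]
        sam = write_sam(tmp_path / "a.sam", REF, REF_LEN, recs)
        ev = scan_marker(str(sam), junction_marker())
        assert ev.supporting_reads == 0
        assert ev.opposing_reads == 1

    def test_unknown_reference_rejected(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", "other", REF_LEN, [])
        with pytest.raises(ValueError, match="absent from alignment header"):
            scan_marker(str(sam), junction_marker())


class TestScanMarkerOtherKinds:
    def test_private_snp_counts_expected_vs_other_bases(self, tmp_path):
        marker = DiagnosticMarker("s1", "private_snp", REF, position=500,
                                  expected_state="G", supports="HapF")
        recs = ([(f"g{i}", 450, "100M", "A" * 50 + "G" + "A" * 49)
                 for i in range(6)]
                + [(f"t{i}", 450, "100M", "A" * 100) for i in range(4)]
                + [("far", 700, "100M", "A" * 100)])
        sam = write_sam(tmp_path / "a.sam", REF, REF_LEN, recs)
        ev = scan_marker(str(sam), marker)
        assert (ev.supporting_reads, ev.opposing_reads) == (6, 4)

    def test_insertion_span_requires_block_across_a_boundary(self, tmp_path):
        marker = DiagnosticMarker("i1", "insertion_span", REF,
                                  interval=(900, 933), supports="HapF")
        recs = [("span", 850, "150M", "A" * 150),      # crosses both edges
                ("left", 860, "60M", "A" * 60),        # crosses left edge
                ("inside", 905, "20M", "A" * 20),      # inside insert only
                ("del", 850, "50M33D67M", "A" * 117)]  # insert absent
        sam = write_sam(tmp_path / "a.sam", REF, REF_LEN, recs)
        ev = scan_marker(str(sam), marker, min_overhang=20)
        assert ev.supporting_reads == 2  # "span" and "left"
        assert ev.opposing_reads == 2

    def test_absence_region_confirmed_only_with_covered_flanks(
            self, tmp_path):
        marker = DiagnosticMarker("a1", "absence_region", REF,
                                  interval=(800, 1200), supports="HapF_DEL",
                                  flank=200)
        flanks = [("l1", 650, "100M", "A" * 100),
                  ("l2", 640, "100M", "A" * 100),
                  ("r1", 1210, "100M", "A" * 100),
                  ("r2", 1250, "100M", "A" * 100)]
        sam = write_sam(tmp_path / "good.sam", REF, REF_LEN, flanks)
        ev = scan_marker(str(sam), marker)
        assert ev.supporting_reads == 2 and ev.opposing_reads == 0
        # interior coverage breaks the absence call
        sam = write_sam(tmp_path / "bad.sam", REF, REF_LEN,
                        flanks + [("mid", 900, "100M", "A" * 100)])
        ev = scan_marker(str(sam), marker)
        assert ev.supporting_reads == 0 and ev.opposing_reads == 1
        # no flanking coverage: missing data, not a deletion
        sam = write_sam(tmp_path / "empty.sam", REF, REF_LEN, [])
        ev = scan_marker(str(sam), marker)
        assert ev.supporting_reads == 0


class TestDetectHapF:
    def test_threshold_rule(self):
        assert detect_hapF(ReadEvidence("m", 12, 0)).detected
        assert not detect_hapF(ReadEvidence("m", 0, 10)).detected

    def test_boundary_flags_low_evidence(self):
        det = detect_hapF(ReadEvidence("m", 2, 5), min_reads=3)
        assert not det.detected and det.low_evidence


def _evidence(ins33=0, tandem=0, ins213=0, rlg=0, abs1=(0, 1), abs2=(0, 1)):
    return {
        "hapf_ins33": ReadEvidence("hapf_ins33", ins33, 0),
        "f2_tandem_junction": ReadEvidence("f2_tandem_junction", tandem, 0),
        "f2_ins213": ReadEvidence("f2_ins213", ins213, 0),
        "f2_rlg_junction": ReadEvidence("f2_rlg_junction", rlg, 0),
        "fdel_absence_1": ReadEvidence("fdel_absence_1", *abs1),
        "fdel_absence_2": ReadEvidence("fdel_absence_2", *abs2),
    }


class TestClassify:
    def test_no_hapf_when_everything_zero_but_coverage_elsewhere(self):
        call = classify_subhaplotype(_evidence(abs1=(10, 0), abs2=(10, 0)))
        assert call.call == "no_HapF"

    def test_f1_f2_del_rules(self):
        assert classify_subhaplotype(
            _evidence(ins33=10, abs1=(0, 50), abs2=(0, 40))).call == "HapF1"
        assert classify_subhaplotype(
            _evidence(ins33=10, tandem=6, ins213=5, rlg=7,
                      abs1=(0, 50), abs2=(0, 40))).call == "HapF2"
        assert classify_subhaplotype(
            _evidence(ins33=10, abs1=(20, 0), abs2=(18, 0))).call == "HapF_DEL"

    def test_conflicting_evidence_is_ambiguous(self):
        call = classify_subhaplotype(
            _evidence(ins33=10, tandem=8, ins213=6, abs1=(20, 0),
                      abs2=(20, 0)))
        assert call.call == "ambiguous"

    def test_missing_marker_evidence_raises(self):
        ev = _evidence()
        del ev["f2_ins213"]
        with pytest.raises(dx.IncompleteEvidenceError, match="f2_ins213"):
            classify_subhaplotype(ev)

    def test_classification_is_pure(self):
        ev = _evidence(ins33=10, tandem=6, ins213=5, rlg=7,
                       abs1=(0, 50), abs2=(0, 40))
        a = classify_subhaplotype(ev)
        b = classify_subhaplotype(ev)
        assert a.call == b.call == "HapF2"


class TestEndToEnd:
    """Truth-label round trips through simulation + minimap2 + calling."""

    @pytest.mark.parametrize("truth,expected", [
        ("HapF2", "HapF2"), ("HapF_DEL", "HapF_DEL"), ("HapA", "no_HapF")])
    def test_diploid_with_hapa_recovers_truth(self, models, marker_panel,
                                              truth, expected, tmp_path):
        reads = sl.simulate_dna_reads([models[truth], models["HapA"]],
                                      depth=30, read_len=150,
                                      error_rate=0.005, seed=11)
        sam = dx.align_reads(reads, models["HapF2"], workdir=tmp_path)
        call = dx.diagnose(sam, marker_panel, accession_id=truth)
        assert call.call == expected


class TestInsilicoPcr:
    def test_deletion_shifts_product_length_by_209(self, models):
        """The VvMybA3 assay product is 209 bp longer on HapF (no exon-3
        deletion) than on HapA."""
        assay = dx.vvmyba3_hapf_assay(models["HapF2"])
        on_f = insilico_pcr(models["HapF2"].sequence, assay.forward,
                            assay.reverse)
        on_a = insilico_pcr(models["HapA"].sequence, assay.forward,
                            assay.reverse)
        assert len(on_f) == 1 and len(on_a) == 1
        assert on_f[0][0] - on_a[0][0] == 209

    def test_absent_primer_gives_empty(self):
        assert insilico_pcr("ACGT" * 100, "T" * 20, "G" * 20) == []

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError, match="at least 15"):
            insilico_pcr("ACGT" * 100, "ACGTACGTAC", "ACGTACGTACGTACG")

    @given(st.integers(0, 2 ** 31 - 1))
    def test_product_lengths_invariant_under_revcomp(self, seed):
        rng = np.random.default_rng(seed)
        seq = sl.random_seq(rng, 600)
        fwd, rev = seq[50:70], sl.revcomp(seq[400:420])
        forward = [L for L, _ in insilico_pcr(seq, fwd, rev)]
        reverse = [L for L, _ in insilico_pcr(sl.revcomp(seq), fwd, rev)]
        assert forward == reverse


class TestVvMybA3Assay:
    def test_presence_absence_matrix(self, models):
        assay = dx.vvmyba3_hapf_assay(models["HapF2"])
        assert dx.assay_vvmyba3_hapF([models["HapF1"], models["HapA"]], assay)
        assert not dx.assay_vvmyba3_hapF([models["HapF_DEL"], models["HapA"]],
                                         assay)
        assert not dx.assay_vvmyba3_hapF([models["HapA"], models["HapA"]],
                                         assay)


class TestMarkerIO:
    def test_yaml_round_trip(self, marker_panel, tmp_path):
        path = tmp_path / "markers.yaml"
        dx.markers_to_yaml(marker_panel, path)
        again = dx.markers_from_yaml(path)
        assert again == list(marker_panel)
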