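"""TN93 distances, UPGMA, bootstrap consensus, Newick round trips."""

import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bcltools.phylo as ph
import bcltools.synthetic_locus as sl


def random_alignment(rng, n=4, length=300, divergence=0.1):
    base = sl.random_seq(rng, length)
    return {f"s{i}": sl.mutate_sequence(base, divergence * (i + 1) / n, rng)
            for i in range(n)}


class TestTamuraNei:
    def test_identical_sequences_distance_zero(self):
        dm = ph.tamura_nei_distance({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert dm[("a", "b")] == 0.0

    def test_symmetry_on_random_pairs(self, rng):
        dm = ph.tamura_nei_distance(random_alignment(rng, n=5))
        assert np.array_equal(dm.values, dm.values.T)

    def test_closed_form_matches_hand_counted_pair(self):
        """A toy pair with counted transitions/transversions equals the
        independently evaluated TN93 closed form to 1e-9."""
        rng = np.random.default_rng(21)
        a = sl.random_seq(rng, 600)
        b = sl.mutate_sequence(a, 0.12, rng)
        # independent evaluation from raw counts
        n = len(a)
        pur = {"A", "G"}
        p1 = sum(x != y and x in pur and y in pur
                 for x, y in zip(a, b)) / n
        p2 = sum(x != y and x not in pur and y not in pur
                 for x, y in zip(a, b)) / n
        q = sum(x != y and (x in pur) != (y in pur)
                for x, y in zip(a, b)) / n
        freqs = {c: (a + b).count(c) / (2 * n) for c in "ACGT"}
        gA, gC, gG, gT = (freqs[c] for c in "ACGT")
        gR, gY = gA + gG, gC + gT
        k1 = 2 * gA * gG / gR
        k2 = 2 * gC * gT / gY
        k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
        expected = (-k1 * np.log(1 - p1 / k1 - q / (2 * gR))
                    - k2 * np.log(1 - p2 / k2 - q / (2 * gY))
                    - k3 * np.log(1 - q / (2 * gR * gY)))
        dm = ph.tamura_nei_distance({"a": a, "b": b})
        assert dm[("a", "b")] == pytest.approx(expected, abs=1e-9)

    def test_agrees_with_ape_reference_implementation(self, rng, tmp_path):
        """Cross-check against ape::dist.dna(model='TN93') via Rscript."""
        aln = random_alignment(rng, n=3, length=500, divergence=0.25)
        fa = tmp_path / "aln.fa"
        fa.write_text("".join(f">{k}\n{v}\n" for k, v in aln.items()))
        script = (f'suppressMessages(library(ape));'
                  f'a<-read.dna("{fa}",format="fasta");'
                  f'write.csv(as.matrix(dist.dna(a,model="TN93")),'
                  f'"{tmp_path}/d.csv")')
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        import pandas as pd

        ref = pd.read_csv(tmp_path / "d.csv", index_col=0)
        dm = ph.tamura_nei_distance(aln)
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                assert dm.values[i, j] == pytest.approx(
                    ref.loc[a, b], rel=5e-3, abs=1e-6)

    def test_reduces_to_jukes_cantor_for_equal_rates(self, rng):
        """With near-uniform base frequencies and unbiased substitutions
        (the generator's model), TN93 ~ JC."""
        a = sl.random_seq(rng, 4000, gc=0.5)
        b = sl.mutate_sequence(a, 0.1, rng)
        p = sum(x != y for x, y in zip(a, b)) / len(a)
        jc = -0.75 * np.log(1 - 4 * p / 3)
        dm = ph.tamura_nei_distance({"a": a, "b": b})
        assert dm[("a", "b")] == pytest.approx(jc, rel=0.02)

    def test_gapped_columns_dropped_per_pair(self):
        dm = ph.tamura_nei_distance({"a": "ACGT-CGT", "b": "ACGTACGT"})
        assert dm[("a", "b")] == 0.0

    def test_saturated_pair_is_infinite(self, caplog):
        # complementary sequences: all transversions, far beyond saturation
        a = "A" * 50 + "C" * 50
        b = "C" * 50 + "A" * 50
        dm = ph.tamura_nei_distance({"a": a, "b": b})
        assert np.isinf(dm[("a", "b")])


class TestUpgma:
    def test_two_leaves_split_distance(self):
        dm = ph.DistanceMatrix(["A", "B"], np.array([[0, 1.0], [1.0, 0]]))
        tree = ph.upgma(dm)
        assert ph.write_newick(tree) in ("(A:0.5,B:0.5);", "(B:0.5,A:0.5);")

    def test_three_leaf_hand_agglomeration(self):
        dm = ph.DistanceMatrix(["A", "B", "C"],
                               np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]],
                                        float))
        tree = ph.upgma(dm)
        ab = next(n for n in tree.non_tips()
                  if {t.name for t in n.tips()} == {"A", "B"})
        assert ab.length == pytest.approx(2.0)
        assert all(c.length == pytest.approx(1.0) for c in ab.children)
        c_leaf = next(t for t in tree.tips() if t.name == "C")
        assert c_leaf.length == pytest.approx(3.0)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(3, 9))
    def test_output_always_ultrametric(self, seed, n):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0.1, 2.0, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        tree = ph.upgma(ph.DistanceMatrix([f"t{i}" for i in range(n)], m))
        assert ph.is_ultrametric(tree, tol=1e-9)
        assert sum(1 for _ in tree.non_tips(include_self=True)) == n - 1

    def test_nonfinite_matrix_rejected(self):
        m = np.array([[0, np.inf], [np.inf, 0]])
        with pytest.raises(ValueError, match="finite"):
            ph.upgma(ph.DistanceMatrix(["a", "b"], m))

    def test_deterministic_under_ties(self):
        m = np.ones((4, 4)) - np.eye(4)
        dm = ph.DistanceMatrix(list("ABCD"), m)
        assert ph.write_newick(ph.upgma(dm)) == \
            ph.write_newick(ph.upgma(dm))


class TestBootstrapConsensus:
    def _two_clade_alignment(self, seed=42):
        """Two clearly divergent clades, nearly identical within, with an
        outgroup distant but well below TN93 saturation."""
        rng = np.random.default_rng(seed)
        a = sl.random_seq(rng, 400)
        b = sl.mutate_sequence(a, 0.25, rng)
        return {
            "a1": a, "a2": sl.mutate_sequence(a, 0.01, rng),
            "b1": b, "b2": sl.mutate_sequence(b, 0.01, rng),
            "out": sl.mutate_sequence(a, 0.4, rng),
        }

    def test_strong_clades_get_full_support(self):
        aln = self._two_clade_alignment()
        tree = ph.bootstrap_consensus(aln, n_reps=200, outgroup_label="out",
                                      seed=3)
        clades = {frozenset(t.name for t in n.tips()): n.support
                  for n in tree.non_tips(include_self=False)}
        assert clades.get(frozenset({"a1", "a2"})) >= 95
        assert clades.get(frozenset({"b1", "b2"})) >= 95

    def test_threshold_zero_keeps_point_topology(self):
        aln = self._two_clade_alignment()
        point = ph.upgma(ph.tamura_nei_distance(aln))
        tree = ph.bootstrap_consensus(aln, n_reps=50, collapse_threshold=0,
                                      outgroup_label="out", seed=1)
        assert {frozenset(t.name for t in n.tips())
                for n in tree.non_tips()} == \
            {frozenset(t.name for t in n.tips()) for n in point.non_tips()}

    def test_fixed_seed_reproducible(self):
        aln = self._two_clade_alignment()
        t1 = ph.bootstrap_consensus(aln, n_reps=100, seed=5,
                                    outgroup_label="out")
        t2 = ph.bootstrap_consensus(aln, n_reps=100, seed=5,
                                    outgroup_label="out")
        assert ph.write_newick(t1) == ph.write_newick(t2)

    def test_missing_outgroup_rejected(self):
        with pytest.raises(ValueError, match="outgroup"):
            ph.bootstrap_consensus(self._two_clade_alignment(),
                                   n_reps=10, outgroup_label="nope")

    def test_outgroup_sits_at_root(self):
        tree = ph.bootstrap_consensus(self._two_clade_alignment(),
                                      n_reps=100, outgroup_label="out",
                                      seed=2)
        out_tip = next(t for t in tree.tips() if t.name == "out")
        assert out_tip.parent is tree

    def test_weak_branches_collapse_to_polytomy(self):
        """Leaves at equal distances carry no support; the consensus
        collapses them rather than keeping arbitrary resolution."""
        rng = np.random.default_rng(8)
        base = sl.random_seq(rng, 300)
        aln = {f"t{i}": sl.mutate_sequence(base, 0.10, rng)
               for i in range(5)}
        aln["out"] = sl.mutate_sequence(base, 0.5, rng)
        tree = ph.bootstrap_consensus(aln, n_reps=100, outgroup_label="out",
                                      seed=4)
        for node in tree.non_tips(include_self=False):
            assert node.support >= 90

    def test_paralog_groups_recovered_with_high_support(self):
        """On the synthetic MybA paralogs the A1/A2/A3 group, the A4/A11
        group and the distant A13 are resolved with >= 90% support."""
        aln = sl.paralog_probe_alignment()
        tree = ph.bootstrap_consensus(aln, n_reps=300,
                                      outgroup_label=sl.OUTGROUP_NAME,
                                      seed=7)
        clades = {frozenset(t.name for t in n.tips())
                  for n in tree.non_tips(include_self=False)}
        assert frozenset({"VvMybA1", "VvMybA2", "VvMybA3"}) in clades
        assert frozenset({"VvMybA4a", "VvMybA4b", "VvMybA11"}) in clades
        ingroup = frozenset(n for n in aln if n != sl.OUTGROUP_NAME)
        assert frozenset(ingroup - {"VvMybA13"}) in clades


class TestNewick:
    def test_two_leaf_pattern(self):
        dm = ph.DistanceMatrix(["A", "B"], np.array([[0, 1.0], [1.0, 0]]))
        assert ph.write_newick(ph.upgma(dm)).endswith(":0.5);")

    @given(st.integers(0, 2 ** 31 - 1))
    def test_round_trip_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        m = rng.uniform(0.5, 3.0, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        tree = ph.upgma(ph.DistanceMatrix([f"t{i}" for i in range(n)], m))
        again = ph.read_newick(ph.write_newick(tree))
        assert ph.trees_equal(tree, again)

    def test_polytomy_survives_round_trip(self):
        tree = ph.read_newick("((A:1,B:1,C:1)95:2,D:3);")
        again = ph.read_newick(ph.write_newick(tree))
        assert ph.trees_equal(tree, again)
        poly = next(n for n in again.non_tips(include_self=False))
        assert len(poly.children) == 3 and poly.support == 95
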