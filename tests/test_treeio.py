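"""Tree/character I/O, validation, and terminal cropping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syndive.treeio import (CharacterData, SamplingFractions, TreeError,
                            crop_tree, read_newick, read_states, total_length,
                            tree_height, write_newick)

from conftest import random_ultrametric


class TestReadNewick:
    def test_two_tip(self, two_tip):
        assert two_tip.n_tips == 2
        assert tree_height(two_tip) == pytest.approx(1.0)

    def test_three_tip_ultrametric(self, three_tip):
        assert three_tip.n_tips == 3
        assert tree_height(three_tip) == pytest.approx(2.0)
        assert total_length(three_tip) == pytest.approx(5.0)
        assert three_tip.is_ultrametric()

    def test_malformed_raises(self):
        with pytest.raises(TreeError):
            read_newick("(a:1,b:1")

    def test_duplicate_labels_raise(self):
        with pytest.raises(TreeError):
            read_newick("(a:1,a:1):0;")

    def test_nonbifurcating_raises(self):
        with pytest.raises(TreeError):
            read_newick("(a:1,b:1,c:1):0;")

    def test_quoted_label_roundtrip(self):
        t = read_newick("('P. bicolor':1,'P. barbatus':1):0;")
        assert "P. bicolor" in t.tip_labels
        t2 = read_newick(write_newick(t))
        assert sorted(t2.tip_labels) == sorted(t.tip_labels)


class TestNewickRoundTrip:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=40), st.integers(0, 10 ** 6))
    def test_roundtrip_preserves_topology_and_lengths(self, n, seed):
        rng = np.random.default_rng(seed)
        t = random_ultrametric(n, rng)
        t2 = read_newick(write_newick(t))
        assert t2.n_tips == t.n_tips
        d1 = dict(zip(t.tip_labels, t.depths()[: t.n_tips]))
        d2 = dict(zip(t2.tip_labels, t2.depths()[: t2.n_tips]))
        for lb in d1:
            assert d2[lb] == pytest.approx(d1[lb], rel=1e-11)
        assert t2.total_length() == pytest.approx(t.total_length(), rel=1e-11)
        # topology: every clade's tip set is preserved under the MRCA structure
        assert _clade_sets(t) == _clade_sets(t2)


def _clade_sets(tree):
    return {frozenset(tree.tip_labels[i] for i in tree.subtree_tips(v))
            for v in range(tree.n_tips, tree.n_nodes)}


class TestReadStates:
    def test_csv_with_header_and_counts(self):
        rows = ["taxon,state"] + [f"sp{i},{1 if i < 19 else 0}" for i in range(104)]
        cd = read_states("\n".join(rows))
        n0, n1 = cd.counts()
        assert (n0, n1) == (85, 19)
        assert cd.proportion_state1() == pytest.approx(19 / 104, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(TreeError):
            read_states("taxon,state\n")

    def test_bad_symbol_raises(self):
        with pytest.raises(TreeError):
            read_states("a,0\nb,2\n")

    def test_nexus_block(self):
        nex = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=3 NCHAR=1;
FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;
MATRIX
a 0
b 1
c 0
;
END;
"""
        cd = read_states(nex)
        assert cd.states == {"a": 0, "b": 1, "c": 0}

    def test_missing_tip_detected(self, three_tip):
        cd = read_states("a,0\nb,1\n")
        with pytest.raises(TreeError, match="missing"):
            cd.as_array(three_tip)


class TestSamplingFractions:
    def test_defaults_and_bounds(self):
        f = SamplingFractions()
        assert (f.f0, f.f1) == (0.83, 0.79)
        with pytest.raises(ValueError):
            SamplingFractions(0.0, 0.5)
        with pytest.raises(ValueError):
            SamplingFractions(0.5, 1.2)


class TestCropTree:
    def test_identity_at_zero(self, three_tip):
        cd = CharacterData({"a": 0, "b": 0, "c": 1})
        t2, cd2 = crop_tree(three_tip, 0.0, cd)
        assert t2.total_length() == pytest.approx(5.0)
        assert cd2.states == cd.states

    def test_two_tip_closed_form(self, two_tip):
        cd = CharacterData({"a": 0, "b": 1})
        t2, _ = crop_tree(two_tip, 0.10, cd)
        assert t2.total_length() == pytest.approx(1.8, rel=1e-9)
        np.testing.assert_allclose(t2.terminal_lengths(), [0.9, 0.9], rtol=1e-9)

    def test_cherry_collapses_to_shared_state(self):
        # cherry (a,b) with crown age 0.1; deep slice removes it
        t = read_newick("((a:0.1,b:0.1):0.9,c:1):0;")
        cd = CharacterData({"a": 0, "b": 0, "c": 1})
        target = 0.5  # slice well above the cherry's crown
        red = 1 - (2 * 0.5) / t.total_length()
        t2, cd2 = crop_tree(t, red, cd)
        assert t2.n_tips == 2
        assert cd2[t2.tip_labels[0]] in (0, 1)
        assert set(cd2.states.values()) == {0, 1}
        assert "a" in cd2.states and cd2["a"] == 0  # collapsed tip keeps first member

    def test_mixed_state_collapse_raises(self):
        t = read_newick("((a:0.1,b:0.1):0.9,c:1):0;")
        cd = CharacterData({"a": 0, "b": 1, "c": 1})
        red = 1 - (2 * 0.5) / t.total_length()
        with pytest.raises(TreeError, match="mixes states"):
            crop_tree(t, red, cd)

    @pytest.mark.parametrize("reduction", [0.05, 0.075, 0.10])
    def test_random_trees_exact_reduction(self, reduction):
        rng = np.random.default_rng(17)
        for _ in range(5):
            t = random_ultrametric(30, rng)
            cd = CharacterData({lb: 0 for lb in t.tip_labels})  # collapse-safe
            L0 = t.total_length()
            t2, cd2 = crop_tree(t, reduction, cd)
            assert t2.total_length() == pytest.approx((1 - reduction) * L0, rel=1e-9)
            assert t2.is_ultrametric()
            # tip count bookkeeping: removed tips = sum over collapses (members-1)
            assert t2.n_tips <= t.n_tips
            assert len(cd2) == t2.n_tips

    def test_infeasible_reduction(self, two_tip):
        cd = CharacterData({"a": 0, "b": 1})
        with pytest.raises(TreeError):
            crop_tree(two_tip, 1.5, cd)
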