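"""Site-selection tests: trees, parsimony counts, consensus, subsampling."""

import numpy as np
import pytest

from mhcamp import selection, simdata
from mhcamp.selection import SiteSelectionResult


def test_build_tree_validates_input():
    with pytest.raises(ValueError):
        selection.build_tree({"a": "AAA", "b": "AAA"})
    with pytest.raises(ValueError):
        selection.build_tree({"a": "AAA", "b": "AAA", "c": "AA"})
    with pytest.raises(ValueError):
        selection.build_tree({"a": "AAA", "b": "AAA", "c": "AAA"},
                             distance_model="wrong")


def test_build_tree_groups_obvious_clades():
    aln = {
        "a1": "AAAAAAAACC",
        "a2": "AAAAAAAAGG",
        "b1": "TTTTTTTTCC",
        "b2": "TTTTTTTTGG",
    }
    tree = selection.build_tree(aln)
    # the (a1,a2) vs (b1,b2) quartet must be resolved
    tips = {t.name for t in tree.tips()}
    assert tips == set(aln)
    a1 = next(t for t in tree.tips() if t.name == "a1")
    dist_a2 = a1.distance(next(t for t in tree.tips() if t.name == "a2"))
    dist_b1 = a1.distance(next(t for t in tree.tips() if t.name == "b1"))
    assert dist_a2 < dist_b1
    for node in tree.traverse(include_self=False):
        assert node.length is None or node.length >= 0


def test_codon_columns_masks_stops_and_frames():
    aln = {"a": "A" + "ATGTAA", "b": "A" + "ATGGCC"}
    cols = selection.codon_columns(aln, frame_offset=1)
    assert len(cols) == 2
    assert cols[0] == {"a": "ATG", "b": "ATG"}
    assert cols[1]["a"] is None  # stop codon treated as missing
    assert cols[1]["b"] == "GCC"


def test_fitch_changes_counts_minimum_events():
    aln = {
        "a1": "AAAAAAAAAGCC",
        "a2": "AAAAAAAAAGCC",
        "b1": "TTTTTTTTTGCA",
        "b2": "TTTTTTTTTGCA",
    }
    tree = selection.build_tree(aln)
    cols = selection.codon_columns(aln, frame_offset=0)
    changes = selection._fitch_changes(tree, cols[3])
    assert len(changes) == 1  # one codon change on the internal edge
    assert sorted(changes[0]) == ["GCA", "GCC"]
    assert selection._fitch_changes(tree, cols[0]) != []


def test_counting_test_invariant_site_null():
    aln = {f"t{i}": "ATGATGATG" for i in range(4)}
    res = selection.counting_site_test(aln, frame_offset=0)
    assert all(r.p_value == 1.0 and not r.positive for r in res)


def test_counting_test_binomial_tail_example():
    # all-nonsynonymous changes with f = 0.7 gives the upper-tail 0.7**10
    from scipy import stats

    assert float(stats.binom.sf(9, 10, 0.7)) == pytest.approx(0.7 ** 10)


def test_counting_flags_planted_nonsynonymous_hotspot():
    aln = simdata.simulate_codon_alignment(
        60, 12, omega_map={5: 8.0}, omega_background=0.05,
        tree_length=30.0, seed=11)
    res = selection.counting_site_test(aln, frame_offset=0)
    assert res[5].positive
    assert res[5].dn_excess
    negatives = [r for r in res if r.site != 5]
    assert sum(r.positive for r in negatives) <= 1


def test_likelihood_test_agrees_on_planted_hotspot():
    aln = simdata.simulate_codon_alignment(
        40, 8, omega_map={2: 8.0}, omega_background=0.05,
        tree_length=25.0, seed=3)
    tree = selection.build_tree(aln)
    res = selection.likelihood_site_test(aln, tree, frame_offset=0)
    assert res[2].positive
    assert res[2].detail["beta_s"] > res[2].detail["alpha_s"]
    assert sum(r.positive for r in res if r.site != 2) <= 1


def test_consensus_pss_k_of_m():
    def r(site, positive):
        return SiteSelectionResult(site, 1.0, 0.01 if positive else 0.9,
                                   positive, positive)

    res = {
        "counting": [r(0, True), r(1, True), r(2, False)],
        "likelihood": [r(0, True), r(1, False), r(2, False)],
    }
    assert selection.consensus_pss(res) == {0}
    assert selection.consensus_pss(res, k=1) == {0, 1}
    with pytest.raises(ValueError):
        selection.consensus_pss(res, k=3)
    with pytest.raises(ValueError):
        selection.consensus_pss({})


def test_subsample_selection_shape_and_determinism():
    aln = simdata.simulate_codon_alignment(
        20, 10, omega_map={1: 6.0}, omega_background=0.2,
        tree_length=25.0, seed=2)
    d1 = selection.subsample_selection(aln, subset_size=10, n_reps=5, seed=4,
                                       frame_offset=0, length_class="demo")
    d2 = selection.subsample_selection(aln, subset_size=10, n_reps=5, seed=4,
                                       frame_offset=0)
    assert d1.pss_counts == d2.pss_counts
    assert len(d1.pss_counts) == 5
    assert d1.length_class == "demo"
    with pytest.raises(ValueError):
        selection.subsample_selection(aln, subset_size=50, n_reps=2, frame_offset=0)
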