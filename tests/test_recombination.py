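"""Recombination scans: statistics, permutation tests, consensus."""

import numpy as np
import pytest

from mhcamp import recombination as rec


def test_max_chi2_hand_example():
    vec = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=np.int8)
    stat, k = rec._max_chi2_binary(vec)
    assert k == 4
    assert stat == pytest.approx(8.0)  # perfect 4/4 split of 8 observations


def test_max_chi2_uniform_vector_degenerate():
    stat, _ = rec._max_chi2_binary(np.ones(6, dtype=np.int8))
    assert stat == 0.0


def test_maxchi_requires_variable_sites():
    res = rec.maxchi_scan("AAAA" * 10, "AAAT" * 10 )
    # 10 mismatches uniformly spread: testable but not necessarily significant
    assert res.status == "ok"
    res2 = rec.maxchi_scan("A" * 40, "A" * 39 + "T")
    assert res2.status == "untestable"
    with pytest.raises(ValueError):
        rec.maxchi_scan("AAA", "AAAA")


def test_maxchi_detects_abrupt_rate_change():
    left = "A" * 40
    right = "C" * 40
    a = left + right
    b = left + "A" * 40  # b matches a on the left, diverges on the right
    res = rec.maxchi_scan(a, b, n_permutations=499, seed=0)
    assert res.status == "ok"
    assert res.p_value < 0.01
    assert res.breakpoint == 40


def test_chimaera_planted_breakpoint(default_pool):
    alleles = [a.sequence for a in default_pool.class_alleles("no_del")]
    pa, pb = alleles[0], alleles[1]
    bp = 120
    chim = pa[:bp] + pb[bp:]
    res = rec.chimaera_scan(chim, pa, pb, n_permutations=999, seed=1)
    assert res.status == "ok"
    assert res.p_value < 0.01
    sites = [i for i, (x, y) in enumerate(zip(pa, pb)) if x != y]
    true_idx = sum(1 for s in sites if s < bp)
    assert abs(res.breakpoint_site_index - true_idx) <= 2


def test_chimaera_untestable_cases():
    assert rec.chimaera_scan("AAAA", "AAAA", "AAAA").status == "untestable"
    with pytest.raises(ValueError):
        rec.chimaera_scan("AAA", "AAAA", "AAAA")


def test_permutation_p_lower_bound():
    left, right = "A" * 30, "C" * 30
    res = rec.maxchi_scan(left + right, left + "A" * 30,
                          n_permutations=99, seed=0)
    assert res.p_value >= 1 / 100


def test_phi_recombination_signal():
    rng = np.random.default_rng(8)
    bases = "ACGT"
    n, L = 14, 120
    # two clonal halves -> nearby sites compatible, distant ones incompatible
    left_types = ["".join(rng.choice(list(bases), L // 2)) for _ in range(3)]
    right_types = ["".join(rng.choice(list(bases), L // 2)) for _ in range(3)]
    aln = {}
    for i in range(n):
        aln[f"s{i}"] = left_types[rng.integers(3)] + right_types[rng.integers(3)]
    res = rec.phi_test(aln, window=30, n_permutations=499, seed=2)
    assert res.status == "ok"
    assert res.p_value < 0.05

    # clonal data: no recombination signal
    base = "".join(rng.choice(list(bases), L))
    clonal = {}
    for i in range(n):
        s = list(base)
        for p in rng.choice(L, 6, replace=False):
            s[p] = bases[(bases.index(s[p]) + 1) % 4]
        clonal[f"c{i}"] = "".join(s)
    res2 = rec.phi_test(clonal, window=30, n_permutations=199, seed=2)
    assert res2.p_value > 0.05


def test_phi_untestable_small():
    assert rec.phi_test({"a": "AC", "b": "AC"}).status == "untestable"


def test_refined_incompatibility():
    # compatible pair: one site's split nests in the other's
    a = np.array(list("AAACCC"))
    b = np.array(list("GGGGTT"))
    assert rec._refined_incompatibility(a, b) == 0.0
    # all four joint states -> one extra homoplasy step
    a2 = np.array(list("AACC"))
    b2 = np.array(list("GTGT"))
    assert rec._refined_incompatibility(a2, b2) == 1.0


def test_consensus_events_rule():
    cands = [
        {"recombinant_id": "r1", "parent_ids": ("a", "b"), "best_breakpoint": 5,
         "p_values": {"chimaera": 0.01, "maxchi": 0.02, "phi": 0.5}},
        {"recombinant_id": "r2", "parent_ids": ("a", "c"), "best_breakpoint": 9,
         "p_values": {"chimaera": 0.01, "maxchi": 0.6, "phi": np.nan}},
    ]
    cons, reported = rec.consensus_events(cands, k=2, alpha=0.05)
    assert [e.recombinant_id for e in cons] == ["r1"]
    assert [e.recombinant_id for e in reported] == ["r2"]
    assert reported[0].n_significant == 1
    with pytest.raises(ValueError):
        rec.consensus_events(cands, k=4)


def test_scan_triplets_finds_planted_recombinant(default_pool):
    alleles = sorted(a.sequence for a in default_pool.class_alleles("no_del"))[:12]
    aln = {f"a{i:02d}": s for i, s in enumerate(alleles)}
    chim = alleles[0][:120] + alleles[1][120:]
    aln["rec"] = chim
    cons, reported = rec.scan_triplets(aln, n_permutations=199, seed=0,
                                       max_candidates=5)
    assert any(e.recombinant_id == "rec" and e.consensus for e in cons)
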