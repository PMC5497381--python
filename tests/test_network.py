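"""NeighborNet distances, ordering, split weights, bootstrap, NEXUS."""

import numpy as np
import pytest

from mhcamp import network


def tree_metric(n, seed):
    """Random binary tree metric; returns (distance matrix, split weights)."""
    rng = np.random.default_rng(seed)
    d = np.zeros((n, n))
    clusters = [{i: 0.0} for i in range(n)]
    blens: dict[frozenset, float] = {}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        cj = clusters.pop(j)
        ci = clusters.pop(i)
        bi, bj = rng.uniform(0.05, 1.0, 2)
        blens[frozenset(ci)] = blens.get(frozenset(ci), 0.0) + bi
        blens[frozenset(cj)] = blens.get(frozenset(cj), 0.0) + bj
        for a, da in ci.items():
            for b, db in cj.items():
                d[a, b] = d[b, a] = da + bi + db + bj
        merged = {l: x + bi for l, x in ci.items()}
        merged.update({l: x + bj for l, x in cj.items()})
        clusters.append(merged)
    return d, blens


def test_k2p_distance_formula():
    # 100 sites, 10 transitions (A<->G), 5 transversions (A<->T)
    a = "A" * 100
    b = "G" * 10 + "T" * 5 + "A" * 85
    d = network.k2p_gamma_distance({"a": a, "b": b}, alpha=None)
    P, Q = 0.10, 0.05
    expected = -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)
    assert d[0, 1] == pytest.approx(expected)
    dg = network.k2p_gamma_distance({"a": a, "b": b}, alpha=0.29)
    al = 0.29
    eg = (al / 2) * ((1 - 2 * P - Q) ** (-1 / al) - 1) + (al / 4) * (
        (1 - 2 * Q) ** (-1 / al) - 1
    )
    assert dg[0, 1] == pytest.approx(eg)
    assert dg[0, 1] > d[0, 1]  # gamma correction inflates distances


def test_k2p_gap_exclusion_and_saturation():
    d = network.k2p_gamma_distance({"a": "A-CT", "b": "AGCT"}, alpha=None)
    assert d[0, 1] == 0.0
    sat = network.k2p_gamma_distance({"a": "ACACAC", "b": "CACACA"}, alpha=None)
    assert sat[0, 1] == 5.0  # saturated pair hits the ceiling


def test_ordering_respects_tree_structure():
    d, _ = tree_metric(8, 1)
    taxa = [f"t{i}" for i in range(8)]
    ordering = network.neighbornet_ordering(d, taxa)
    assert sorted(ordering) == sorted(taxa)
    small = network.neighbornet_ordering(d[:3, :3], taxa[:3])
    assert small == taxa[:3]
    with pytest.raises(ValueError):
        network.neighbornet_ordering(d[:4, :5], taxa[:4])


def test_splits_recover_tree_exactly():
    for seed in (0, 1):
        n = 10
        d, blens = tree_metric(n, seed)
        taxa = [f"t{i}" for i in range(n)]
        net = network.neighbornet_from_distances(d, taxa)
        assert np.abs(net.induced_distance() - d).max() < 1e-6
        full = frozenset(taxa)

        def canon(s):
            return s if "t0" not in s else full - s

        true = {}
        for ls, w in blens.items():
            side = frozenset(f"t{i}" for i in ls)
            if 0 < len(side) < n:
                true[canon(side)] = true.get(canon(side), 0.0) + w
        got = {canon(s): w for s, w in net.splits}
        assert set(got) == set(true)
        for s in true:
            assert got[s] == pytest.approx(true[s], abs=1e-6)


def test_split_threshold_drops_tiny_weights():
    d, _ = tree_metric(6, 3)
    taxa = [f"t{i}" for i in range(6)]
    ordering = network.neighbornet_ordering(d, taxa)
    net_all = network.fit_split_weights(d, ordering, threshold=0.0, taxa=taxa)
    net_cut = network.fit_split_weights(d, ordering, threshold=1e-6, taxa=taxa)
    assert len(net_cut.splits) <= len(net_all.splits)
    assert all(w >= 1e-6 for _, w in net_cut.splits)


def test_bootstrap_supports_deterministic(default_pool):
    alleles = sorted(a.sequence for a in default_pool.class_alleles("no_del"))[:10]
    aln = {f"a{i}": s for i, s in enumerate(alleles)}
    net = network.neighbornet(aln)
    s1 = network.bootstrap_supports(aln, net, n_replicates=20, seed=5)
    s2 = network.bootstrap_supports(aln, net, n_replicates=20, seed=5)
    assert s1 == s2
    assert all(0.0 <= v <= 100.0 for v in s1.values())
    with pytest.raises(ValueError):
        network.bootstrap_supports(aln, net, n_replicates=0)


def test_write_nexus_structure(tmp_path, default_pool):
    alleles = sorted(a.sequence for a in default_pool.class_alleles("no_del"))[:8]
    aln = {f"a{i}": s for i, s in enumerate(alleles)}
    net = network.neighbornet(aln)
    out = tmp_path / "net.nex"
    network.write_nexus(net, out)
    text = out.read_text()
    assert text.startswith("#nexus")
    assert "BEGIN Taxa;" in text and "BEGIN Splits;" in text
    assert f"ntax={len(aln)}" in text
    assert f"nsplits={len(net.splits)}" in text
    assert "CYCLE" in text
    matrix = text.split("MATRIX")[1].split(";")[0]
    assert len([l for l in matrix.strip().splitlines()]) == len(net.splits)
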