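"""Recombination detection by sliding-breakpoint scans and permutation tests.

Three complementary tests with a k-of-m consensus:

* :func:`maxchi_scan` — pairwise MaxChi: the mismatch pattern between two
  aligned sequences is split at every candidate breakpoint and scored by a
  2x2 chi-square (left/right x match/mismatch); significance by permuting
  the column order.
* :func:`chimaera_scan` — triplet Chimaera: a putative recombinant is encoded
  as a binary match-to-parent-A vector over parent-informative sites and the
  2x2 chi-square is maximized over breakpoints; significance by permuting
  the binary vector.
* :func:`phi_test` — pairwise homoplasy index: mean refined incompatibility
  of nearby informative site pairs; recombination makes nearby sites more
  compatible than a random site order, detected by permutation.

All permutation p-values are seeded, reproducible, and bounded below by
1/(n_permutations + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ScanResult:
    status: str  # ok | untestable
    breakpoint: int | None  # alignment column of the inferred junction
    breakpoint_site_index: int | None  # index among informative sites
    statistic: float
    p_value: float


@dataclass
class RecombinationEvent:
    recombinant_id: str
    parent_ids: tuple[str, str]
    best_breakpoint: int | None
    p_values: dict
    consensus: bool
    n_significant: int


def _max_chi2_binary(vec: np.ndarray) -> tuple[float, int]:
    """Maximum 2x2 chi-square over breakpoints of a binary vector.

    The table at breakpoint k is (left/right segment) x (ones/zeros);
    chi-square without continuity correction, degenerate tables (an empty
    row or column) score zero.  Returns (chi2_max, index of the first
    element of the right segment).
    """
    n = len(vec)
    total = float(vec.sum())
    k = np.arange(1, n, dtype=float)
    ones_left = np.cumsum(vec)[:-1].astype(float)
    a = ones_left  # ones, left
    b = k - ones_left  # zeros, left
    c = total - ones_left  # ones, right
    d = (n - k) - c  # zeros, right
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    best = int(np.argmax(chi2))
    return float(chi2[best]), best + 1


def _perm_p(rng: np.random.Generator, vec: np.ndarray, observed: float, n_perm: int) -> float:
    hits = 0
    work = vec.copy()
    for _ in range(n_perm):
        rng.shuffle(work)
        stat, _ = _max_chi2_binary(work)
        if stat >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def maxchi_scan(
    seq_a: str, seq_b: str, n_permutations: int = 1000, seed: int = 0
) -> ScanResult:
    """MaxChi on one aligned pair: does the mismatch rate change abruptly at
    some breakpoint?  Requires >= 4 variable (differing) sites."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    mism = np.array([1 if a != b else 0 for a, b in zip(seq_a, seq_b)], dtype=np.int8)
    if mism.sum() < 4:
        return ScanResult("untestable", None, None, 0.0, 1.0)
    stat, k = _max_chi2_binary(mism)
    if stat <= 0:
        return ScanResult("ok", None, None, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    p = _perm_p(rng, mism, stat, n_permutations)
    return ScanResult("ok", k, None, stat, p)


def chimaera_scan(
    recombinant: str,
    parent_a: str,
    parent_b: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ScanResult:
    """Chimaera on one triplet: encode the recombinant as match-to-A over
    parent-informative sites and maximize the 2x2 chi-square over
    breakpoints."""
    if not (len(recombinant) == len(parent_a) == len(parent_b)):
        raise ValueError("triplet must be aligned to equal length")
    sites = []
    matches = []
    for i, (r, a, b) in enumerate(zip(recombinant, parent_a, parent_b)):
        if a == b:
            continue
        if r == a:
            sites.append(i)
            matches.append(1)
        elif r == b:
            sites.append(i)
            matches.append(0)
        # sites matching neither parent carry no parent signal and are dropped
    if len(sites) < 4 or len(set(matches)) < 2:
        return ScanResult("untestable", None, None, 0.0, 1.0)
    vec = np.array(matches, dtype=np.int8)
    stat, k = _max_chi2_binary(vec)
    if stat <= 0:
        return ScanResult("ok", None, None, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    p = _perm_p(rng, vec, stat, n_permutations)
    return ScanResult("ok", sites[k], k, stat, p)


# ---------------------------------------------------------------------------
# PHI


def _informative_columns(alignment: dict[str, str]) -> tuple[np.ndarray, np.ndarray]:
    names = sorted(alignment)
    arr = np.array([list(alignment[n]) for n in names])
    keep = []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        vals, counts = np.unique(col, return_counts=True)
        if (counts >= 2).sum() >= 2:
            keep.append(j)
    return arr[:, keep], np.array(keep, dtype=int)


def _refined_incompatibility(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Minimum extra homoplasy steps for a site pair: joint states minus
    connected components of the state bipartite graph, versus the tree-
    compatible minimum."""
    pairs = set(zip(col_a.tolist(), col_b.tolist()))
    states_a = {p[0] for p in pairs}
    states_b = {p[1] for p in pairs}
    # connected components of the bipartite graph on states_a x states_b
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in states_a:
        parent[("a", a)] = ("a", a)
    for b in states_b:
        parent[("b", b)] = ("b", b)
    for a, b in pairs:
        ra, rb = find(("a", a)), find(("b", b))
        if ra != rb:
            parent[ra] = rb
    comps = {find(k) for k in parent}
    return float(len(pairs) - len(states_a) - len(states_b) + len(comps))


def phi_test(
    alignment: dict[str, str],
    window: int = 100,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ScanResult:
    """Pairwise homoplasy index over informative sites.

    The statistic is the mean refined incompatibility of site pairs within
    ``window`` alignment columns of each other; the permutation null shuffles
    site positions, so recombination (nearby sites more compatible than
    random) gives small p.
    """
    if len(alignment) < 4:
        return ScanResult("untestable", None, None, 0.0, 1.0)
    cols, positions = _informative_columns(alignment)
    k = cols.shape[1]
    if k < 2:
        return ScanResult("untestable", None, None, 0.0, 1.0)
    inc = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            inc[i, j] = inc[j, i] = _refined_incompatibility(cols[:, i], cols[:, j])

    triu = np.triu_indices(k, 1)

    def mean_nearby(pos: np.ndarray) -> float:
        gaps = np.abs(pos[:, None] - pos[None, :])[triu]
        near = gaps <= window
        if not near.any():
            return 0.0
        return float(inc[triu][near].mean())

    observed = mean_nearby(positions)
    rng = np.random.default_rng(seed)
    hits = 0
    perm_pos = positions.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm_pos)
        if mean_nearby(perm_pos) <= observed + 1e-12:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return ScanResult("ok", None, None, observed, p)


# ---------------------------------------------------------------------------
# consensus


def consensus_events(
    candidates: list[dict],
    k: int = 2,
    alpha: float = 0.05,
) -> tuple[list[RecombinationEvent], list[RecombinationEvent]]:
    """Partition candidate events into consensus (significant in >= k enabled
    tests) and sub-threshold (reported with their test tally).

    Each candidate is a dict with keys ``recombinant_id``, ``parent_ids``,
    ``best_breakpoint`` and ``p_values`` (test name -> p, NaN/None for
    untestable).
    """
    consensus, reported = [], []
    for cand in candidates:
        pvals = {
            t: p
            for t, p in cand["p_values"].items()
            if p is not None and not np.isnan(p)
        }
        if k > len(cand["p_values"]):
            raise ValueError("consensus k exceeds number of enabled tests")
        n_sig = sum(1 for p in pvals.values() if p < alpha)
        event = RecombinationEvent(
            recombinant_id=cand["recombinant_id"],
            parent_ids=tuple(cand["parent_ids"]),
            best_breakpoint=cand.get("best_breakpoint"),
            p_values=dict(cand["p_values"]),
            consensus=n_sig >= k,
            n_significant=n_sig,
        )
        (consensus if event.consensus else reported).append(event)
    return consensus, reported


def scan_triplets(
    alignment: dict[str, str],
    frequencies: dict[str, int] | None = None,
    top: int = 50,
    n_permutations: int = 200,
    k: int = 2,
    alpha: float = 0.05,
    seed: int = 0,
    max_candidates: int = 20,
) -> tuple[list[RecombinationEvent], list[RecombinationEvent]]:
    """Driver: scan the ``top`` most frequent alleles for recombinants.

    Triplets are pre-ranked by the raw Chimaera chi-square (no permutations),
    the strongest ``max_candidates`` get full permutation tests (Chimaera,
    pairwise MaxChi against the 5' parent, and the alignment-wide PHI test),
    and events are split by the k-of-m consensus rule.
    """
    names = sorted(alignment)
    if frequencies:
        names.sort(key=lambda n: (-frequencies.get(n, 0), n))
    names = names[:top]
    sub = {n: alignment[n] for n in names}
    scored = []
    for r in names:
        for i, a in enumerate(names):
            if a == r:
                continue
            for b in names[i + 1 :]:
                if b == r:
                    continue
                quick = chimaera_scan(sub[r], sub[a], sub[b], n_permutations=0, seed=0)
                if quick.status == "ok" and quick.statistic > 0:
                    scored.append((quick.statistic, r, a, b))
    scored.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    phi = phi_test(sub, n_permutations=n_permutations, seed=seed)
    candidates = []
    for rank, (_, r, a, b) in enumerate(scored[:max_candidates]):
        chim = chimaera_scan(sub[r], sub[a], sub[b], n_permutations, seed + rank)
        maxchi = maxchi_scan(sub[r], sub[a], n_permutations, seed + 1000 + rank)
        candidates.append(
            {
                "recombinant_id": r,
                "parent_ids": (a, b),
                "best_breakpoint": chim.breakpoint,
                "p_values": {
                    "chimaera": chim.p_value if chim.status == "ok" else np.nan,
                    "maxchi": maxchi.p_value if maxchi.status == "ok" else np.nan,
                    "phi": phi.p_value if phi.status == "ok" else np.nan,
                },
            }
        )
    return consensus_events(candidates, k=k, alpha=alpha)
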