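"""NeighborNet split networks of alleles.

Pipeline: Kimura two-parameter distances with gamma rate heterogeneity
(default shape 0.29), agglomerative NeighborNet circular ordering, split
weights fitted by non-negative least squares over all circular splits with a
small-weight threshold (default 1e-6), and column-bootstrap supports.
Networks serialize to a SplitsTree-readable NEXUS file.

The NeighborNet agglomeration follows Bryant & Moulton: taxa start as
singleton components; pairs of components are selected by the neighbor-
joining Q criterion on component-average distances, the concrete node pair
by the same criterion with the two chosen components' nodes kept separate;
components are linked into paths and every three consecutive active nodes
are reduced to two with the (2/3, 1/3) distance reduction, recorded on an
expansion stack that is unwound into the final circular ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import nnls


@dataclass
class SplitsNetwork:
    """A circular split system: taxa, ordering, weighted splits, supports."""

    taxa: list[str]
    circular_ordering: list[str]
    splits: list[tuple[frozenset, float]]
    supports: dict = field(default_factory=dict)

    def split_side(self, split: frozenset) -> frozenset:
        return split

    def induced_distance(self) -> np.ndarray:
        """Distance matrix implied by the split weights (taxa order =
        self.taxa)."""
        idx = {t: i for i, t in enumerate(self.taxa)}
        n = len(self.taxa)
        d = np.zeros((n, n))
        for side, w in self.splits:
            inside = np.array([t in side for t in self.taxa])
            sep = np.logical_xor.outer(inside, inside)
            d += w * sep
        return d


# ---------------------------------------------------------------------------
# distances

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def k2p_gamma_distance(
    alignment: dict[str, str],
    alpha: float | None = 0.29,
    saturation_ceiling: float = 5.0,
) -> np.ndarray:
    """Kimura two-parameter distances with gamma rate correction.

    ``alpha`` is the gamma shape (None for the classical no-gamma limit).
    Gapped or ambiguous columns are excluded pairwise; saturated pairs (log or
    power argument non-positive) are set to ``saturation_ceiling``.  Taxa
    order of the returned matrix is ``sorted(alignment)``.
    """
    names = sorted(alignment)
    seqs = [alignment[n].upper() for n in names]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("alignment sequences must have equal length")
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[i], seqs[j]
            compared = ts = tv = 0
            for x, y in zip(a, b):
                if x not in "ACGT" or y not in "ACGT":
                    continue
                compared += 1
                if x == y:
                    continue
                same_class = (x in _PURINES) == (y in _PURINES)
                if same_class:
                    ts += 1
                else:
                    tv += 1
            if compared == 0:
                raise ValueError(f"no comparable sites between {names[i]} and {names[j]}")
            P, Q = ts / compared, tv / compared
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            if w1 <= 0 or w2 <= 0:
                d = saturation_ceiling
            elif alpha is None or np.isinf(alpha):
                d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
            else:
                d = (alpha / 2.0) * (w1 ** (-1.0 / alpha) - 1.0) + (
                    alpha / 4.0
                ) * (w2 ** (-1.0 / alpha) - 1.0)
            out[i, j] = out[j, i] = min(d, saturation_ceiling)
    return out


# ---------------------------------------------------------------------------
# NeighborNet circular ordering


class _NNetState:
    def __init__(self, dist: np.ndarray):
        n = dist.shape[0]
        size = 3 * n + 3  # room for reduction nodes
        self.d = np.zeros((size, size))
        self.d[:n, :n] = dist
        self.next_id = n
        self.components: list[list[int]] = [[i] for i in range(n)]
        self.expansions: list[tuple[int, int, int, int, int]] = []

    def new_node(self) -> int:
        if self.next_id >= self.d.shape[0]:
            grown = np.zeros((self.d.shape[0] * 2, self.d.shape[0] * 2))
            grown[: self.d.shape[0], : self.d.shape[0]] = self.d
            self.d = grown
        i = self.next_id
        self.next_id += 1
        return i

    def active_nodes(self) -> list[int]:
        return [x for comp in self.components for x in comp]

    def comp_dist(self, ci: list[int], cj: list[int]) -> float:
        return float(np.mean([[self.d[x, y] for y in cj] for x in ci]))

    def reduce_triple(self, w: int, x: int, y: int) -> tuple[int, int]:
        u, v = self.new_node(), self.new_node()
        active = self.active_nodes()
        for z in active:
            if z in (w, x, y):
                continue
            self.d[u, z] = self.d[z, u] = (2 * self.d[w, z] + self.d[x, z]) / 3.0
            self.d[v, z] = self.d[z, v] = (2 * self.d[y, z] + self.d[x, z]) / 3.0
        self.d[u, v] = self.d[v, u] = (
            self.d[w, x] + self.d[x, y] + self.d[w, y]
        ) / 3.0
        self.expansions.append((u, v, w, x, y))
        return u, v


def _select_components(state: _NNetState) -> tuple[int, int]:
    comps = state.components
    m = len(comps)
    if m == 2:
        return 0, 1
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = state.comp_dist(comps[i], comps[j])
    row = D.sum(axis=1)
    best = None
    for i in range(m):
        for j in range(i + 1, m):
            q = (m - 2) * D[i, j] - row[i] - row[j]
            if best is None or q < best[0] - 1e-12:
                best = (q, i, j)
    return best[1], best[2]


def _select_nodes(state: _NNetState, ci: int, cj: int) -> tuple[int, int]:
    comps = state.components
    a, b = comps[ci], comps[cj]
    others = [comps[k] for k in range(len(comps)) if k not in (ci, cj)]
    entities: list[list[int]] = [[x] for x in a] + [[y] for y in b] + others
    ne = len(entities)
    if len(a) == 1 and len(b) == 1:
        return a[0], b[0]
    dmat = np.zeros((ne, ne))
    for i in range(ne):
        for j in range(i + 1, ne):
            dmat[i, j] = dmat[j, i] = state.comp_dist(entities[i], entities[j])
    row = dmat.sum(axis=1)
    best = None
    for i, x in enumerate(a):
        for j0, y in enumerate(b):
            j = len(a) + j0
            q = (ne - 2) * dmat[i, j] - row[i] - row[j]
            if best is None or q < best[0] - 1e-12:
                best = (q, x, y)
    return best[1], best[2]


def neighbornet_ordering(dist: np.ndarray, taxa: list[str]) -> list[str]:
    """Circular taxon ordering by NeighborNet agglomeration.

    Deterministic: ties resolve to the first candidate in the (sorted) taxa
    order.  Requires a symmetric matrix; with fewer than 4 taxa the input
    order is returned.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] != dist.shape[1] or not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    n = len(taxa)
    if dist.shape[0] != n:
        raise ValueError("matrix size does not match taxa")
    if n <= 3:
        return list(taxa)

    state = _NNetState(dist)
    while len(state.components) > 1:
        ci, cj = _select_components(state)
        x, y = _select_nodes(state, ci, cj)
        a = list(state.components[ci])
        b = list(state.components[cj])
        if a[-1] != x:
            a.reverse()
        if b[0] != y:
            b.reverse()
        path = a + b
        comps = [
            state.components[k]
            for k in range(len(state.components))
            if k not in (ci, cj)
        ]
        state.components = comps + [path]
        while len(path) > 2:
            u, v = state.reduce_triple(path[0], path[1], path[2])
            path[:3] = [u, v]

    cycle = list(state.components[0])
    for u, v, w, x, y in reversed(state.expansions):
        if u in cycle and v in cycle:
            iu, iv = cycle.index(u), cycle.index(v)
            if (iu + 1) % len(cycle) == iv:
                cycle[iu : iu + 1] = [w, x]
                cycle[cycle.index(v)] = y
            elif (iv + 1) % len(cycle) == iu:
                cycle[iv : iv + 1] = [y, x]
                cycle[cycle.index(u)] = w
            else:  # pragma: no cover - expansion nodes are always adjacent
                raise AssertionError("non-adjacent expansion nodes")
    return [taxa[i] for i in cycle]


# ---------------------------------------------------------------------------
# split weights


def _circular_splits(ordering: list[str]) -> list[frozenset]:
    n = len(ordering)
    seen = set()
    splits = []
    anchor = ordering[0]
    for start in range(n):
        for length in range(1, n):
            side = frozenset(
                ordering[(start + k) % n] for k in range(length)
            )
            canon = side if anchor not in side else frozenset(ordering) - side
            if canon and canon not in seen:
                seen.add(canon)
                splits.append(canon)
    return splits


def fit_split_weights(
    dist: np.ndarray,
    ordering: list[str],
    threshold: float = 1e-6,
    taxa: list[str] | None = None,
) -> SplitsNetwork:
    """Non-negative least squares fit of circular split weights to the
    distance matrix; splits with weight below ``threshold`` are dropped.

    ``dist`` rows/columns follow ``taxa`` (default: sorted ordering).
    """
    taxa = sorted(ordering) if taxa is None else list(taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    candidates = _circular_splits(ordering)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    A = np.zeros((len(pairs), len(candidates)))
    for c, side in enumerate(candidates):
        inside = np.array([t in side for t in taxa])
        for r, (i, j) in enumerate(pairs):
            if inside[i] != inside[j]:
                A[r, c] = 1.0
    dvec = np.array([dist[i, j] for i, j in pairs])
    weights, _ = nnls(A, dvec)
    splits = [
        (side, float(w))
        for side, w in zip(candidates, weights)
        if w >= threshold
    ]
    splits.sort(key=lambda sw: (-sw[1], sorted(sw[0])))
    return SplitsNetwork(taxa=taxa, circular_ordering=list(ordering), splits=splits)


def neighbornet(
    alignment: dict[str, str],
    alpha: float | None = 0.29,
    threshold: float = 1e-6,
) -> SplitsNetwork:
    """Distances -> circular ordering -> fitted split weights."""
    taxa = sorted(alignment)
    dist = k2p_gamma_distance(alignment, alpha=alpha)
    ordering = neighbornet_ordering(dist, taxa)
    return fit_split_weights(dist, ordering, threshold=threshold, taxa=taxa)


def neighbornet_from_distances(
    dist: np.ndarray, taxa: list[str], threshold: float = 1e-6
) -> SplitsNetwork:
    ordering = neighbornet_ordering(dist, list(taxa))
    return fit_split_weights(dist, ordering, threshold=threshold, taxa=list(taxa))


# ---------------------------------------------------------------------------
# bootstrap


def _canonical(side: frozenset, taxa: list[str]) -> frozenset:
    anchor = taxa[0]
    return side if anchor not in side else frozenset(taxa) - side


def bootstrap_supports(
    alignment: dict[str, str],
    network: SplitsNetwork | None = None,
    n_replicates: int = 1000,
    support_display_min: float = 70.0,
    seed: int = 0,
    alpha: float | None = 0.29,
    threshold: float = 1e-6,
) -> dict:
    """Column-bootstrap supports (percent of replicates containing each
    bipartition) for the splits of the base network.

    ``support_display_min`` is a presentation filter only; all supports are
    returned, the display threshold is recorded by callers.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if network is None:
        network = neighbornet(alignment, alpha=alpha, threshold=threshold)
    taxa = network.taxa
    names = sorted(alignment)
    cols = np.array([list(alignment[n]) for n in names]).T  # sites x taxa
    n_sites = cols.shape[0]
    rng = np.random.default_rng(seed)
    hits = {
        _canonical(side, taxa): 0 for side, _ in network.splits if 0 < len(side) < len(taxa)
    }
    for _ in range(n_replicates):
        take = rng.integers(0, n_sites, size=n_sites)
        boot = {
            name: "".join(cols[take, k]) for k, name in enumerate(names)
        }
        try:
            bnet = neighbornet(boot, alpha=alpha, threshold=threshold)
        except ValueError:
            continue
        present = {_canonical(side, taxa) for side, _ in bnet.splits}
        for split in hits:
            if split in present:
                hits[split] += 1
    supports = {s: 100.0 * h / n_replicates for s, h in hits.items()}
    network.supports = supports
    return supports


# ---------------------------------------------------------------------------
# NEXUS


def write_nexus(network: SplitsNetwork, path: str | Path, support_display_min: float = 70.0) -> None:
    """SplitsTree-readable NEXUS with Taxa and Splits blocks; bootstrap
    supports above the display threshold go into a comment column."""
    taxa = network.taxa
    idx = {t: i + 1 for i, t in enumerate(taxa)}
    order_idx = [idx[t] for t in network.circular_ordering]
    lines = ["#nexus", "", "BEGIN Taxa;", f"DIMENSIONS ntax={len(taxa)};", "TAXLABELS"]
    for i, t in enumerate(taxa, start=1):
        lines.append(f"[{i}] '{t}'")
    lines.append(";")
    lines.append("END; [Taxa]")
    lines.append("")
    lines.append("BEGIN Splits;")
    lines.append(
        f"DIMENSIONS ntax={len(taxa)} nsplits={len(network.splits)};"
    )
    lines.append("FORMAT labels=no weights=yes confidences=yes;")
    lines.append("PROPERTIES fit=-1.0 cyclic;")
    lines.append("CYCLE " + " ".join(str(i) for i in order_idx) + ";")
    lines.append("MATRIX")
    for side, w in network.splits:
        canon = _canonical(side, taxa)
        support = network.supports.get(canon)
        conf = (
            f"{support:.1f}"
            if support is not None and support >= support_display_min
            else "0"
        )
        members = " ".join(str(idx[t]) for t in sorted(side, key=lambda t: idx[t]))
        lines.append(f"\t{w:.8f}\t{conf}\t{members},")
    lines.append(";")
    lines.append("END; [Splits]")
    Path(path).write_text("\n".join(lines) + "\n")
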