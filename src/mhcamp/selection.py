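"""Site-wise positive-selection detection with a k-of-m consensus.

Two independent in-repo site tests are provided, mirroring the counting and
fixed-effects likelihood families of codon selection tests:

* :func:`counting_site_test` — SLAC-style: Fitch parsimony reconstructs
  ancestral codons per site on a neighbor-joining tree, observed changes on
  every edge are decomposed into synonymous and nonsynonymous counts
  (Nei–Gojobori pathway averaging), and the nonsynonymous excess over the
  potential-site expectation is scored by a binomial tail.
* :func:`likelihood_site_test` — FEL-style: per site, synonymous and
  nonsynonymous rates are maximum-likelihood fitted under an MG94-style
  codon model (uniform codon frequencies, single-nucleotide exchanges) with
  branch lengths fixed from the tree, and beta = alpha is tested by a
  chi-square(1) likelihood-ratio test.

A site is called positively selected by consensus when at least k of the m
enabled tests report a significant nonsynonymous excess.  The subsampling
driver re-runs a designated single test on random allele subsets to compare
classes of very different sample size on equal footing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from ._codon import (
    SENSE_CODONS,
    CODON_INDEX,
    codon_neighbors,
    is_synonymous,
    pathway_changes,
    potential_sites,
)

__all__ = [
    "SiteSelectionResult",
    "SubsampleDistribution",
    "build_tree",
    "counting_site_test",
    "likelihood_site_test",
    "consensus_pss",
    "subsample_selection",
]


@dataclass
class SiteSelectionResult:
    site: int  # exon-local codon index
    statistic: float
    p_value: float
    dn_excess: bool  # nonsynonymous rate/count above expectation
    positive: bool  # significant and dn_excess
    tested: bool = True
    detail: dict | None = None


@dataclass
class SubsampleDistribution:
    length_class: str
    subset_size: int
    n_reps: int
    pss_counts: list[int]
    seed: int


# ---------------------------------------------------------------------------
# trees


def _pdist_matrix(names: list[str], seqs: list[str]) -> np.ndarray:
    arr = np.array([list(s) for s in seqs])
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        diff = (arr != arr[i]).mean(axis=1)
        d[i] = diff
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def build_tree(alignment: dict[str, str], distance_model: str = "p") -> TreeNode:
    """Neighbor-joining tree from p-distances (or K2P), negative branch
    lengths clamped to zero."""
    names = sorted(alignment)
    if len(names) != len(set(names)):
        raise ValueError("duplicate taxa labels")
    if len(names) < 3:
        raise ValueError("need at least 3 sequences")
    seqs = [alignment[n] for n in names]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("alignment sequences must have equal length")
    if distance_model == "p":
        mat = _pdist_matrix(names, seqs)
    elif distance_model == "k2p":
        from .network import k2p_gamma_distance

        mat = k2p_gamma_distance(dict(zip(names, seqs)), alpha=None)
    else:
        raise ValueError(f"unknown distance model {distance_model!r}")
    dm = DistanceMatrix(mat, ids=names)
    tree = nj(dm)
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# codon columns


def codon_columns(alignment: dict[str, str], frame_offset: int = 1):
    """Per-site codon strings per taxon; stop-containing or ambiguous codons
    are treated as missing (None)."""
    names = sorted(alignment)
    length = len(next(iter(alignment.values())))
    n_sites = (length - frame_offset) // 3
    cols = []
    for s in range(n_sites):
        col = {}
        for name in names:
            codon = alignment[name][frame_offset + 3 * s : frame_offset + 3 * s + 3]
            col[name] = codon if codon in CODON_INDEX else None
        cols.append(col)
    return cols


# ---------------------------------------------------------------------------
# counting (SLAC-style) test


def _fitch_changes(tree: TreeNode, column: dict[str, str | None]):
    """Fitch parsimony over one codon column; returns inferred (codon_from,
    codon_to) changes over edges."""
    observed = sorted({c for c in column.values() if c is not None})
    if len(observed) <= 1:
        return []
    all_states = frozenset(observed)
    downsets: dict[int, frozenset] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            c = column.get(node.name)
            downsets[id(node)] = frozenset([c]) if c is not None else all_states
        else:
            sets = [downsets[id(ch)] for ch in node.children]
            inter = frozenset.intersection(*sets)
            downsets[id(node)] = inter if inter else frozenset.union(*sets)
    changes = []
    states: dict[int, str] = {}
    for node in tree.preorder(include_self=True):
        own = downsets[id(node)]
        if node.parent is None:
            states[id(node)] = min(own)
        else:
            parent_state = states[id(node.parent)]
            if parent_state in own:
                states[id(node)] = parent_state
            else:
                state = min(own)
                states[id(node)] = state
                if node.is_tip() and column.get(node.name) is None:
                    continue  # missing tip: no inferred change
                changes.append((parent_state, state))
    return changes


def counting_site_test(
    alignment: dict[str, str],
    tree: TreeNode | None = None,
    alpha: float = 0.05,
    frame_offset: int = 1,
) -> list[SiteSelectionResult]:
    """Per-site counting test of positive selection.

    Observed nonsynonymous (n) and synonymous (s) changes are inferred by
    Fitch parsimony; the expected nonsynonymous fraction f comes from the
    Nei–Gojobori potential-site decomposition of the codons at the site.  The
    reported p is the binomial tail in the direction of the deviation, and a
    positive call requires an observed nonsynonymous excess (n/(n+s) > f).
    """
    if tree is None:
        tree = build_tree(alignment)
    results = []
    for site, column in enumerate(codon_columns(alignment, frame_offset)):
        changes = _fitch_changes(tree, column)
        n_obs = s_obs = 0.0
        for a, b in changes:
            s_i, n_i = pathway_changes(a, b)
            s_obs += s_i
            n_obs += n_i
        codons = [c for c in column.values() if c is not None]
        pot = np.array([potential_sites(c) for c in codons]) if codons else np.zeros((1, 2))
        s_pot, n_pot = pot.mean(axis=0)
        f = n_pot / (s_pot + n_pot) if (s_pot + n_pot) > 0 else 0.75
        total = int(round(n_obs + s_obs))
        k = int(round(n_obs))
        if total == 0:
            results.append(
                SiteSelectionResult(site, 0.0, 1.0, False, False,
                                    detail={"n": n_obs, "s": s_obs, "f": f})
            )
            continue
        excess = (n_obs / (n_obs + s_obs)) > f
        if excess:
            p = float(stats.binom.sf(k - 1, total, f))  # P(X >= k)
        else:
            p = float(stats.binom.cdf(k, total, f))  # P(X <= k)
        p = min(1.0, p)
        results.append(
            SiteSelectionResult(
                site,
                statistic=float(n_obs - s_obs),
                p_value=p,
                dn_excess=excess,
                positive=excess and p < alpha,
                detail={"n": n_obs, "s": s_obs, "f": f, "changes": len(changes)},
            )
        )
    return results


# ---------------------------------------------------------------------------
# likelihood (FEL-style) test

_N_SENSE = len(SENSE_CODONS)


def _rate_components():
    S = np.zeros((_N_SENSE, _N_SENSE))
    N = np.zeros((_N_SENSE, _N_SENSE))
    for i, ca in enumerate(SENSE_CODONS):
        for cb, _pos, syn in codon_neighbors(ca):
            j = CODON_INDEX[cb]
            if syn:
                S[i, j] = 1.0
            else:
                N[i, j] = 1.0
    # normalize so a=b=1 gives one expected substitution per codon per unit t
    scale = (S + N).sum() / _N_SENSE
    return S / scale, N / scale


_S_MAT, _N_MAT = _rate_components()


class _SiteLikelihood:
    """Felsenstein pruning for one codon site with site-specific synonymous
    and nonsynonymous rates; transition matrices via symmetric
    eigendecomposition (uniform codon frequencies make Q symmetric)."""

    def __init__(self, tree: TreeNode):
        self.post = list(tree.postorder(include_self=True))
        self.index = {id(n): i for i, n in enumerate(self.post)}
        self.children = [
            [self.index[id(c)] for c in n.children] for n in self.post
        ]
        self.lengths = np.array(
            [max(n.length or 0.0, 0.0) for n in self.post]
        )
        self.is_tip = [n.is_tip() for n in self.post]
        self.names = [n.name for n in self.post]

    def loglik(self, column: dict[str, str | None], a: float, b: float) -> float:
        Q = a * _S_MAT + b * _N_MAT
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        w, U = np.linalg.eigh(Q)
        n_nodes = len(self.post)
        msgs = np.empty((n_nodes, _N_SENSE))
        logscale = 0.0
        for i in range(n_nodes):
            if self.is_tip[i]:
                codon = column.get(self.names[i])
                vec = np.full(_N_SENSE, 1.0)
                if codon is not None:
                    vec = np.zeros(_N_SENSE)
                    vec[CODON_INDEX[codon]] = 1.0
                msgs[i] = vec
            else:
                vec = np.ones(_N_SENSE)
                for c in self.children[i]:
                    t = self.lengths[c]
                    P = (U * np.exp(w * t)) @ U.T
                    np.maximum(P, 1e-12, out=P)
                    vec = vec * (P @ msgs[c])
                m = vec.max()
                if m <= 0:
                    return -np.inf
                logscale += np.log(m)
                vec = vec / m
                msgs[i] = vec
        root = msgs[-1]
        return float(np.log(root.mean()) + logscale)


def likelihood_site_test(
    alignment: dict[str, str],
    tree: TreeNode | None = None,
    alpha: float = 0.05,
    frame_offset: int = 1,
) -> list[SiteSelectionResult]:
    """Per-site likelihood-ratio test of beta (nonsynonymous rate) = alpha_s
    (synonymous rate), branch lengths fixed from the tree."""
    if tree is None:
        tree = build_tree(alignment)
    engine = _SiteLikelihood(tree)
    results = []
    log_lo, log_hi = -8.0, 4.0
    for site, column in enumerate(codon_columns(alignment, frame_offset)):
        observed = {c for c in column.values() if c is not None}
        if len(observed) <= 1:
            results.append(SiteSelectionResult(site, 0.0, 1.0, False, False))
            continue
        try:
            res0 = optimize.minimize_scalar(
                lambda lr: -engine.loglik(column, np.exp(lr), np.exp(lr)),
                bounds=(log_lo, log_hi),
                method="bounded",
                options={"xatol": 1e-3},
            )
            ll0, r0 = -res0.fun, res0.x
            res1 = optimize.minimize(
                lambda v: -engine.loglik(column, np.exp(v[0]), np.exp(v[1])),
                x0=np.array([r0, r0]),
                method="L-BFGS-B",
                bounds=[(log_lo, log_hi)] * 2,
                options={"maxiter": 60, "ftol": 1e-8},
            )
            ll1 = -res1.fun
            a_hat, b_hat = np.exp(res1.x)
        except (ValueError, FloatingPointError):
            results.append(
                SiteSelectionResult(site, np.nan, np.nan, False, False, tested=False)
            )
            continue
        lrt = max(0.0, 2.0 * (ll1 - ll0))
        p = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
        excess = b_hat > a_hat
        results.append(
            SiteSelectionResult(
                site,
                statistic=lrt,
                p_value=p,
                dn_excess=excess,
                positive=excess and p < alpha,
                detail={"alpha_s": float(a_hat), "beta_s": float(b_hat)},
            )
        )
    return results


# ---------------------------------------------------------------------------
# consensus and subsampling


def consensus_pss(
    results_per_test: dict[str, list[SiteSelectionResult]], k: int | None = None
) -> set[int]:
    """Sites positive in at least k of the enabled tests (default: all)."""
    m = len(results_per_test)
    if m < 1:
        raise ValueError("at least one test required")
    if k is None:
        k = m
    if k > m or k < 1:
        raise ValueError(f"consensus k={k} incompatible with m={m} tests")
    tally: dict[int, int] = {}
    for results in results_per_test.values():
        for r in results:
            if r.tested and r.positive:
                tally[r.site] = tally.get(r.site, 0) + 1
    return {site for site, votes in tally.items() if votes >= k}


def subsample_selection(
    alignment: dict[str, str],
    subset_size: int = 47,
    n_reps: int = 100,
    test: str = "counting",
    seed: int = 0,
    alpha: float = 0.05,
    frame_offset: int = 1,
    length_class: str = "",
) -> SubsampleDistribution:
    """Randomized subsampling: repeatedly draw ``subset_size`` alleles without
    replacement, run the designated single site test, and record the number
    of positively selected sites per replicate."""
    names = sorted(alignment)
    if subset_size > len(names):
        raise ValueError("subset_size exceeds number of sequences")
    runner = {"counting": counting_site_test, "likelihood": likelihood_site_test}[test]
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_reps):
        chosen = rng.choice(names, size=subset_size, replace=False)
        sub = {n: alignment[n] for n in chosen}
        results = runner(sub, alpha=alpha, frame_offset=frame_offset)
        counts.append(sum(1 for r in results if r.positive))
    return SubsampleDistribution(length_class, subset_size, n_reps, counts, seed)
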