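"""Standard genetic code utilities shared by the simulator and selection tests.

Everything here is pure table lookup on the standard (vertebrate nuclear)
genetic code: codon translation, single-nucleotide codon neighbourhoods,
synonymous/nonsynonymous classification and the Nei–Gojobori decomposition of
codons into potential synonymous and nonsynonymous sites.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations, product

from Bio.Seq import Seq

BASES = "ACGT"

_CODON_TABLE = {
    "".join(c): str(Seq("".join(c)).translate()) for c in product(BASES, repeat=3)
}

STOP_CODONS = frozenset(c for c, a in _CODON_TABLE.items() if a == "*")
SENSE_CODONS = tuple(sorted(c for c in _CODON_TABLE if c not in STOP_CODONS))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


def translate_codon(codon: str) -> str:
    """Amino acid (one letter, '*' for stop) for a codon; 'X' if ambiguous."""
    return _CODON_TABLE.get(codon.upper(), "X")


def translate(seq: str, frame_offset: int = 0) -> str:
    """Translate ``seq`` starting at ``frame_offset``, ignoring a trailing
    partial codon."""
    seq = seq.upper()
    aas = []
    for i in range(frame_offset, len(seq) - 2, 3):
        aas.append(translate_codon(seq[i : i + 3]))
    return "".join(aas)


def is_synonymous(codon_a: str, codon_b: str) -> bool:
    return translate_codon(codon_a) == translate_codon(codon_b)


@lru_cache(maxsize=None)
def codon_neighbors(codon: str, exclude_stops: bool = True):
    """All codons one nucleotide substitution away from ``codon``.

    Returns a tuple of (neighbor, position, synonymous_flag).
    """
    out = []
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1 :]
            if exclude_stops and nb in STOP_CODONS:
                continue
            out.append((nb, pos, is_synonymous(codon, nb)))
    return tuple(out)


@lru_cache(maxsize=None)
def potential_sites(codon: str):
    """Nei–Gojobori potential (synonymous, nonsynonymous) site counts.

    Each codon position contributes fractionally according to the fraction of
    possible single-base changes that are synonymous; changes to stop codons
    are excluded from the denominator.
    """
    s = n = 0.0
    for pos in range(3):
        changes = []
        for b in BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1 :]
            if nb in STOP_CODONS:
                continue
            changes.append(is_synonymous(codon, nb))
        if not changes:
            continue
        syn_frac = sum(changes) / len(changes)
        s += syn_frac
        n += 1.0 - syn_frac
    return s, n


@lru_cache(maxsize=None)
def pathway_changes(codon_a: str, codon_b: str):
    """Nei–Gojobori pathway-averaged (synonymous, nonsynonymous) change counts
    between two codons.

    Averages over all orderings of the differing positions; pathways passing
    through a stop codon are skipped (if all pathways hit a stop they are used
    anyway, weighting each step equally, so the count never degenerates).
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in permutations(diff):
        cur = codon_a
        s = n = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon_b:
                through_stop = True
            if is_synonymous(cur, nxt):
                s += 1.0
            else:
                n += 1.0
            cur = nxt
        totals.append((s, n, through_stop))
    valid = [(s, n) for s, n, bad in totals if not bad]
    if not valid:
        valid = [(s, n) for s, n, _ in totals]
    s_mean = sum(v[0] for v in valid) / len(valid)
    n_mean = sum(v[1] for v in valid) / len(valid)
    return s_mean, n_mean
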