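"""Diversity and divergence statistics for allele sets and genotypes.

Implements the population summaries used to characterise an extremely
duplicated gene family: mean pairwise p-distances at nucleotide and amino
acid level, nucleotide diversity over unique alleles, per-individual allele
count summaries, the minimum-locus bound implied by the maximal per-bird
allele count under heterozygosity, and between-method genotype
repeatability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._codon import translate
from .length_classes import LengthClassedAllele

GAP_CHARS = frozenset("-.")


@dataclass
class DiversityReport:
    """Per-class diversity and divergence summary (one Table-style row)."""

    length_class: str
    n_nt_alleles: int
    n_aa_alleles: int
    pi: float
    mean_aa_pdist: float
    sd_aa_pdist: float
    aa_per_nt_ratio: float


@dataclass
class IndividualSummary:
    individual_id: str
    total_alleles: int
    per_class: dict
    transcribed_fraction: float | None


def _pairwise_p(a: str, b: str) -> float:
    """p-distance of one pair with pairwise deletion of gapped columns."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    compared = mismatch = 0
    for x, y in zip(a, b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        compared += 1
        if x != y:
            mismatch += 1
    if compared == 0:
        raise ValueError("no comparable sites in pair")
    return mismatch / compared


def p_distance(sequences: list[str], level: str = "nt"):
    """Mean, SD and matrix of pairwise p-distances over aligned sequences.

    ``level`` records whether the inputs are nucleotide or amino acid
    sequences; the arithmetic (mismatches / compared sites with pairwise
    deletion of gapped columns) is identical.  Requires >= 2 sequences.
    """
    if level not in ("nt", "aa"):
        raise ValueError("level must be 'nt' or 'aa'")
    n = len(sequences)
    if n < 2:
        raise ValueError("p-distance needs at least two sequences")
    mat = np.zeros((n, n))
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            d = _pairwise_p(sequences[i], sequences[j])
            mat[i, j] = mat[j, i] = d
            vals.append(d)
    vals = np.array(vals)
    return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0, mat


def nucleotide_diversity(sequences: list[str], unique: bool = True) -> float:
    """π: mean pairwise nucleotide p-distance, by default over unique alleles
    (unweighted by population frequency)."""
    seqs = sorted(set(sequences)) if unique else list(sequences)
    mean, _, _ = p_distance(seqs, level="nt")
    return mean


def min_locus_bound(max_alleles_per_individual: int) -> int:
    """Minimum number of loci implied by the largest per-individual allele
    count, assuming full heterozygosity: ceil(max / 2)."""
    if max_alleles_per_individual < 1:
        raise ValueError("allele count must be positive")
    return math.ceil(max_alleles_per_individual / 2)


def repeatability(set_a: set, set_b: set, mode: str = "jaccard") -> float:
    """Between-method genotype agreement for one individual.

    'jaccard' -> |A∩B| / |A∪B|; 'recall_vs_A' -> |A∩B| / |A|.
    """
    set_a, set_b = set(set_a), set(set_b)
    if not set_a and not set_b:
        raise ValueError("both allele sets empty")
    inter = len(set_a & set_b)
    if mode == "jaccard":
        return inter / len(set_a | set_b)
    if mode == "recall_vs_A":
        if not set_a:
            raise ValueError("reference set A is empty")
        return inter / len(set_a)
    raise ValueError(f"unknown mode {mode!r}")


def mean_transcribed_fraction(counts: list[tuple[int, int]]) -> float:
    """Mean per-individual transcribed fraction from (gdna_alleles,
    cdna_alleles) count pairs — the average of cdna/gdna ratios."""
    if not counts:
        raise ValueError("no count pairs supplied")
    fractions = []
    for gdna, cdna in counts:
        if gdna < 1 or cdna < 0:
            raise ValueError("allele counts must be positive")
        fractions.append(cdna / gdna)
    return float(np.mean(fractions))


def diversity_report(
    sequences: list[str], length_class: str = "", frame_offset: int = 1
) -> DiversityReport:
    """Table-style per-class summary over a set of alleles of equal length."""
    nt = sorted(set(sequences))
    aa = sorted({translate(s, frame_offset) for s in nt})
    pi = nucleotide_diversity(nt)
    if len(aa) >= 2:
        aa_mean, aa_sd, _ = p_distance(aa, level="aa")
    else:
        aa_mean = aa_sd = 0.0
    return DiversityReport(
        length_class=length_class,
        n_nt_alleles=len(nt),
        n_aa_alleles=len(aa),
        pi=pi,
        mean_aa_pdist=aa_mean,
        sd_aa_pdist=aa_sd,
        aa_per_nt_ratio=round(len(aa) / len(nt), 2),
    )


def aa_per_nt_ratio(n_aa: int, n_nt: int) -> float:
    """Display ratio of unique amino acid to unique nucleotide alleles,
    rounded to two decimals."""
    if n_nt < 1:
        raise ValueError("nucleotide allele count must be positive")
    return round(n_aa / n_nt, 2)


def summarize_population(
    genotypes: dict[str, list[LengthClassedAllele]],
    transcribed: dict[str, float] | None = None,
):
    """Per-individual summaries plus aggregate mean / SD (sample, n-1) /
    inclusive range, overall and per class."""
    if not genotypes:
        raise ValueError("empty population")
    classes = ["no_del", "del3", "del6", "other"]
    summaries = []
    for ind in sorted(genotypes):
        per_class = {c: 0 for c in classes}
        for a in genotypes[ind]:
            per_class[a.length_class] += 1
        summaries.append(
            IndividualSummary(
                individual_id=ind,
                total_alleles=sum(per_class.values()),
                per_class=per_class,
                transcribed_fraction=(transcribed or {}).get(ind),
            )
        )

    def agg(values):
        arr = np.array(values, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        return {
            "mean": float(arr.mean()),
            "sd": sd,
            "min": float(arr.min()),
            "max": float(arr.max()),
        }

    aggregate = {"total": agg([s.total_alleles for s in summaries])}
    for c in classes:
        carriers = [s.per_class[c] for s in summaries if s.per_class[c] > 0]
        if carriers:
            aggregate[c] = agg(carriers)
            aggregate[c]["carrier_fraction"] = len(carriers) / len(summaries)
    return summaries, aggregate


def summaries_to_frame(summaries: list[IndividualSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"individual_id": s.individual_id, "total": s.total_alleles}
        row.update(s.per_class)
        if s.transcribed_fraction is not None:
            row["transcribed_fraction"] = s.transcribed_fraction
        rows.append(row)
    return pd.DataFrame(rows)
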