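"""Partition of exon-3 alleles into deletion length classes.

Alleles of a 241 bp reference-length exon fall into three in-frame classes —
no deletion (241 bp, 80 aa), a one-codon deletion (238 bp, 79 aa) and a
two-adjacent-codon deletion (235 bp, 78 aa) — plus an "other" bin for
anything frame-breaking (e.g. 11 bp deletion pseudogenes) or longer than the
reference.  Deletion placement is found by a codon-aware comparison against
the reference: every codon-boundary contiguous gap placement of the right
length is scored by mismatches to the reference and the leftmost
best-scoring placement wins, which for in-frame deletion classes enumerates
exactly the alignments a codon-gap-preferring global aligner could prefer.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._codon import translate

CLASS_OTHER = "other"


@dataclass
class LengthClassedAllele:
    allele_id: str
    length_class: str  # no_del | del3 | del6 | other
    deleted_codons: tuple[int, ...]  # reference codon indices, exon-local
    aa_sequence: str
    mismatches: int  # vs reference under the chosen gap placement


def _codons(seq: str, frame_offset: int) -> list[str]:
    return [
        seq[i : i + 3] for i in range(frame_offset, len(seq) - 2, 3)
    ]


def classify_allele(
    sequence: str,
    reference: str,
    allele_id: str = "",
    frame_offset: int = 1,
) -> LengthClassedAllele:
    """Assign a deletion length class and deletion placement to one allele.

    ``reference`` is the configured 241 bp no-deletion representative.  All
    coordinates are exon-local 0-based codon indices.
    """
    sequence = sequence.upper()
    if not set(sequence) <= set("ACGT"):
        raise ValueError(f"non-ACGT characters in allele {allele_id!r}")
    d = len(reference) - len(sequence)
    aa = translate(sequence, frame_offset) if (len(sequence) - frame_offset) % 3 == 0 else ""
    if d == 0:
        mism = sum(1 for a, b in zip(sequence, reference) if a != b)
        return LengthClassedAllele(allele_id, "no_del", (), aa, mism)
    if d not in (3, 6) or (len(sequence) - frame_offset) % 3 != 0:
        return LengthClassedAllele(allele_id, CLASS_OTHER, (), aa, -1)

    n_gap_codons = d // 3
    ref_codons = _codons(reference, frame_offset)
    seq_codons = _codons(sequence, frame_offset)
    lead_mism = sum(
        1 for a, b in zip(sequence[:frame_offset], reference[:frame_offset]) if a != b
    )
    best = None  # (mismatches, start_codon)
    for start in range(len(ref_codons) - n_gap_codons + 1):
        gapped = ref_codons[:start] + ref_codons[start + n_gap_codons :]
        mism = lead_mism + sum(
            1
            for rc, sc in zip(gapped, seq_codons)
            for a, b in zip(rc, sc)
            if a != b
        )
        if best is None or mism < best[0]:
            best = (mism, start)
    mism, start = best
    deleted = tuple(range(start, start + n_gap_codons))
    cls = "del3" if d == 3 else "del6"
    return LengthClassedAllele(allele_id, cls, deleted, aa, mism)


def classify_alleles(
    sequences: dict[str, str], reference: str, frame_offset: int = 1
) -> dict[str, LengthClassedAllele]:
    return {
        aid: classify_allele(seq, reference, aid, frame_offset)
        for aid, seq in sequences.items()
    }


def class_census(
    genotypes: dict[str, list[LengthClassedAllele]]
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Per-individual class counts, population carrier fractions and the
    class frequency spectrum (how many individuals carry each allele count).

    Returns (per_individual, carrier_fractions, spectra).
    """
    classes = ["no_del", "del3", "del6", CLASS_OTHER]
    rows = []
    for ind in sorted(genotypes):
        counts = {c: 0 for c in classes}
        for a in genotypes[ind]:
            counts[a.length_class] += 1
        counts["individual_id"] = ind
        counts["total"] = sum(counts[c] for c in classes)
        rows.append(counts)
    per_ind = pd.DataFrame(rows).set_index("individual_id")
    carrier = (per_ind[classes] > 0).mean()
    spectra = pd.DataFrame(
        {c: per_ind[c].value_counts().sort_index() for c in classes}
    ).fillna(0).astype(int)
    return per_ind, carrier, spectra
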