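"""Dual-tag demultiplexing and per-amplicon variant tables.

Reads are assigned to amplicons only when both 6 bp tags match exactly and
both primers match within a configurable mismatch allowance (IUPAC degenerate
primer positions match any of their expansions).  Assigned reads are trimmed
to the insert between the primers; everything else is counted as discarded,
so assigned + discarded always equals the input read count.

The variant table is the unit all downstream artifact filters act on: unique
insert sequences with read counts, ordered by descending count (ties broken
lexicographically), after dropping reads with ambiguous bases and capping
each amplicon at a seeded uniform subsample of ``read_cap`` reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .simdata import ConfigurationError

_IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


@dataclass
class VariantTable:
    """Unique insert sequences of one amplicon with read counts, sorted by
    count (descending) then sequence (lexicographic)."""

    amplicon_id: str
    variants: list[tuple[str, int]]
    total_reads_used: int

    def __post_init__(self):
        self.variants = sorted(self.variants, key=lambda v: (-v[1], v[0]))
        seqs = [s for s, _ in self.variants]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate sequences in variant table")
        if any(c <= 0 for _, c in self.variants):
            raise ValueError("variant counts must be positive")

    @property
    def sequences(self) -> list[str]:
        return [s for s, _ in self.variants]

    def count(self, seq: str) -> int:
        for s, c in self.variants:
            if s == seq:
                return c
        return 0


@dataclass
class DemuxResult:
    assignments: dict[str, list[str]]  # amplicon_id -> trimmed inserts
    n_assigned: int
    n_discarded: int
    discard_reasons: Counter = field(default_factory=Counter)

    @property
    def n_input(self) -> int:
        return self.n_assigned + self.n_discarded


def primer_mismatches(segment: str, primer: str) -> int:
    """Mismatch count of a read segment against a possibly degenerate primer."""
    if len(segment) != len(primer):
        return max(len(segment), len(primer))
    return sum(
        1 for s, p in zip(segment, primer) if s not in _IUPAC.get(p, frozenset())
    )


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def demultiplex(
    reads,
    tag_sheet: pd.DataFrame,
    primer_pair: tuple[str, str],
    max_primer_mismatches: int = 0,
    tag_length: int | None = None,
) -> DemuxResult:
    """Assign reads to amplicons by exact dual tags and near-exact primers.

    ``reads`` is an iterable of Bio.SeqRecord or plain strings.  Both read
    orientations are tried.  Returns trimmed inserts per amplicon plus
    conservation counts.
    """
    if len(tag_sheet) == 0:
        raise ConfigurationError("empty tag sheet")
    fwd_primer, rev_primer = primer_pair
    tag_len = tag_length or len(tag_sheet.iloc[0]["fwd_tag"])
    lookup = {
        (r.fwd_tag, r.rev_tag): r.amplicon_id
        for r in tag_sheet.itertuples(index=False)
    }
    if len(lookup) != len(tag_sheet):
        raise ConfigurationError("duplicate (fwd_tag, rev_tag) pair in tag sheet")

    rc_rev_primer = _revcomp(rev_primer)
    flen, rlen = len(fwd_primer), len(rev_primer)
    assignments: dict[str, list[str]] = {aid: [] for aid in tag_sheet["amplicon_id"]}
    n_assigned = 0
    reasons: Counter = Counter()

    def try_assign(seq: str):
        if len(seq) < 2 * tag_len + flen + rlen + 1:
            return None, "too_short"
        fwd_tag = seq[:tag_len]
        rev_tag = _revcomp(seq[-tag_len:])
        aid = lookup.get((fwd_tag, rev_tag))
        if aid is None:
            return None, "tag_mismatch"
        fseg = seq[tag_len : tag_len + flen]
        rseg = seq[-(tag_len + rlen) : -tag_len]
        if primer_mismatches(fseg, fwd_primer) > max_primer_mismatches:
            return None, "primer_mismatch"
        # the reverse primer appears reverse-complemented on this strand
        if primer_mismatches(_revcomp(rseg), rev_primer) > max_primer_mismatches:
            return None, "primer_mismatch"
        insert = seq[tag_len + flen : -(tag_len + rlen)]
        return (aid, insert), None

    _ = rc_rev_primer  # orientation handled via per-read reverse complement

    n_discarded = 0
    for rec in reads:
        seq = str(rec.seq) if hasattr(rec, "seq") else str(rec)
        seq = seq.upper()
        hit, reason = try_assign(seq)
        if hit is None:
            hit, reason2 = try_assign(_revcomp(seq))
            reason = reason if hit is None else None
        if hit is None:
            n_discarded += 1
            reasons[reason] += 1
        else:
            aid, insert = hit
            assignments[aid].append(insert)
            n_assigned += 1
    return DemuxResult(assignments, n_assigned, n_discarded, reasons)


def build_variant_table(
    reads: list[str],
    amplicon_id: str = "",
    read_cap: int = 20_000,
    seed: int = 0,
) -> VariantTable:
    """Collapse trimmed inserts into a variant table.

    Reads containing non-ACGT characters are dropped; if more than
    ``read_cap`` reads remain, a seeded uniform subsample of ``read_cap`` is
    used (the study capped amplicons at 20,000 reads).
    """
    if read_cap < 1:
        raise ConfigurationError("read_cap must be >= 1")
    clean = [r for r in reads if set(r) <= set("ACGT") and r]
    if len(clean) > read_cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(clean), size=read_cap, replace=False)
        clean = [clean[i] for i in sorted(idx)]
    counts = Counter(clean)
    variants = [(s, c) for s, c in counts.items()]
    return VariantTable(amplicon_id, variants, total_reads_used=len(clean))


def read_fastq(path: str | Path):
    fmt = "fasta" if str(path).endswith((".fa", ".fasta")) else "fastq"
    return list(SeqIO.parse(str(path), fmt))


def tables_from_demux(
    result: DemuxResult, read_cap: int = 20_000, seed: int = 0
) -> dict[str, VariantTable]:
    return {
        aid: build_variant_table(reads, aid, read_cap=read_cap, seed=seed)
        for aid, reads in result.assignments.items()
    }


def tables_to_frame(tables: dict[str, VariantTable]) -> pd.DataFrame:
    rows = []
    for aid in sorted(tables):
        for rank, (seq, count) in enumerate(tables[aid].variants, start=1):
            rows.append(
                {"amplicon_id": aid, "rank": rank, "sequence": seq, "count": count}
            )
    return pd.DataFrame(rows)
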