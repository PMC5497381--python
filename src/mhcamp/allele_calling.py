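"""Artifact filtering and replicate-verified allele calling.

The filters reproduce the amplicon-genotyping artifact rules for extremely
duplicated genes: variants under a copy-number floor are dropped, variants
explicable as single-breakpoint chimeras of two more abundant same-length
variants are flagged and removed, and variants within 1-2 edits of a strictly
more abundant variant are collapsed onto it.  An allele is *verified* for an
individual and template (gDNA or cDNA) only when it survives filtering in
both independent PCR replicates; alleles verified in both gDNA and cDNA are
classed as transcribed, gDNA-only alleles as putatively non-expressed.

All removals are logged so alternative filter orders can be audited.  The
composed filter is contractive and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd

from ._codon import translate
from .demux import VariantTable
from .simdata import ConfigurationError


@dataclass
class ChimeraFlag:
    sequence: str
    count: int
    parent_a: str
    parent_b: str
    breakpoint: int  # first position attributed to parent B


@dataclass
class CollapseRecord:
    sequence: str
    count: int
    parent: str
    edit_distance: int


@dataclass
class FilterLog:
    low_copy: list[tuple[str, int]] = field(default_factory=list)
    chimeras: list[ChimeraFlag] = field(default_factory=list)
    collapsed: list[CollapseRecord] = field(default_factory=list)


@dataclass
class AlleleCall:
    """A replicate-verified allele of one individual."""

    allele_id: str
    sequence: str
    individual_id: str
    support: dict  # {"gDNA": (rep1_count, rep2_count), "cDNA": ...}
    orf_status: str  # orf | stop_codon | frameshift
    expression: str  # transcribed | gdna_only | cdna_only


def filter_low_copy(table: VariantTable, min_copies: int = 10) -> VariantTable:
    """Drop variants with fewer than ``min_copies`` reads (boundary kept)."""
    if min_copies < 1:
        raise ConfigurationError("min_copies must be >= 1")
    kept = [(s, c) for s, c in table.variants if c >= min_copies]
    return VariantTable(table.amplicon_id, kept, table.total_reads_used)


def _prefix_len(seq: str, other: str) -> int:
    for i, (a, b) in enumerate(zip(seq, other)):
        if a != b:
            return i
    return len(seq)


def _suffix_start(seq: str, other: str) -> int:
    for i in range(len(seq) - 1, -1, -1):
        if seq[i] != other[i]:
            return i + 1
    return 0


def _chimera_parents(
    seq: str, candidates: list[tuple[str, int]], count: int
) -> ChimeraFlag | None:
    """Find parents A, B (each strictly more abundant, same length, distinct
    from ``seq``) such that ``seq`` equals A exactly left of a breakpoint and
    B exactly right of it — which implies >= 1 A/B-differing site on each
    side.

    Equivalent to the exhaustive breakpoint scan: ``seq`` is a chimera of
    (A, B) iff prefix_agreement(seq, A) >= suffix_agreement_start(seq, B),
    so only the best prefix parent and best suffix parent need checking.
    """
    pool = [(s, c) for s, c in candidates if c > count and len(s) == len(seq) and s != seq]
    if len(pool) < 2:
        return None
    best_prefix = max(pool, key=lambda sc: _prefix_len(seq, sc[0]))
    best_suffix = min(pool, key=lambda sc: _suffix_start(seq, sc[0]))
    p_len = _prefix_len(seq, best_prefix[0])
    s_start = _suffix_start(seq, best_suffix[0])
    if p_len >= s_start:
        # same parent on both sides would mean seq == parent, excluded above
        return ChimeraFlag(
            seq, count, best_prefix[0], best_suffix[0], breakpoint=s_start
        )
    return None


def flag_chimeras(
    table: VariantTable, log: FilterLog | None = None
) -> VariantTable:
    """Remove variants explicable as two-parent single-breakpoint chimeras.

    Parents must be strictly more abundant, same-length variants of the same
    table; the chimera must agree with one parent at every parent-differing
    site left of a breakpoint and with the other right of it, with at least
    one differing site on each side.
    """
    kept: list[tuple[str, int]] = []
    flags: list[ChimeraFlag] = []
    for seq, count in table.variants:
        flag = _chimera_parents(seq, table.variants, count)
        if flag is None:
            kept.append((seq, count))
        else:
            flags.append(flag)
    if log is not None:
        log.chimeras.extend(flags)
    return VariantTable(table.amplicon_id, kept, table.total_reads_used)


def collapse_errors(
    table: VariantTable,
    max_edit: int = 2,
    max_count_ratio: float = 0.5,
    log: FilterLog | None = None,
) -> VariantTable:
    """Remove variants within ``max_edit`` edits (substitutions or indels) of
    an already retained, more abundant variant.

    "More abundant" is read as substantially more abundant: a variant is
    collapsed only when its count is at most ``max_count_ratio`` of the
    parent's, since a PCR/sequencing error derivative is expected at a small
    fraction of its template's reads, whereas two true alleles amplify at
    comparable depth.  ``max_count_ratio=1.0`` recovers the strict
    any-count-difference rule.
    """
    retained: list[tuple[str, int]] = []
    for seq, count in table.variants:
        parent = None
        dist = None
        for rseq, rcount in retained:
            if rcount <= count or count > max_count_ratio * rcount:
                continue
            res = edlib.align(seq, rseq, task="distance", k=max_edit)
            if res["editDistance"] != -1:
                parent, dist = rseq, res["editDistance"]
                break
        if parent is None:
            retained.append((seq, count))
        elif log is not None:
            log.collapsed.append(CollapseRecord(seq, count, parent, dist))
    return VariantTable(table.amplicon_id, retained, table.total_reads_used)


def apply_filters(
    table: VariantTable,
    min_copies: int = 10,
    max_edit: int = 2,
) -> tuple[VariantTable, FilterLog]:
    """Composed artifact filter: copy floor, then chimera flagging, then 1-2
    edit collapse.  Contractive and idempotent."""
    log = FilterLog()
    before = {s: c for s, c in table.variants}
    t = filter_low_copy(table, min_copies=min_copies)
    log.low_copy = [(s, c) for s, c in before.items() if c < min_copies]
    t = flag_chimeras(t, log=log)
    t = collapse_errors(t, max_edit=max_edit, log=log)
    return t, log


def verify_replicates(
    replicate_tables: dict[int, VariantTable], min_replicates: int | None = None
) -> set[str]:
    """Alleles verified for one individual x template: present in the retained
    set of at least ``min_replicates`` replicate PCRs (default: all).

    Raises if a replicate table is missing (None) so a failed PCR can never
    silently verify alleles.
    """
    if not replicate_tables:
        raise ConfigurationError("no replicate tables supplied")
    if any(t is None for t in replicate_tables.values()):
        raise ConfigurationError("missing replicate table; amplicon unscored")
    need = len(replicate_tables) if min_replicates is None else min_replicates
    if need > len(replicate_tables):
        raise ConfigurationError("min_replicates exceeds available replicates")
    tally: dict[str, int] = {}
    for t in replicate_tables.values():
        for s in t.sequences:
            tally[s] = tally.get(s, 0) + 1
    return {s for s, n in tally.items() if n >= need}


def orf_status(sequence: str, frame_offset: int = 1) -> str:
    """ORF classification of an insert: in-frame open reading frame, in-frame
    stop codon, or frameshifting length."""
    if (len(sequence) - frame_offset) % 3 != 0:
        return "frameshift"
    aa = translate(sequence, frame_offset)
    return "stop_codon" if "*" in aa else "orf"


def classify_expression(
    individual_id: str,
    gdna_verified: set[str],
    cdna_verified: set[str],
    replicate_counts: dict | None = None,
    frame_offset: int = 1,
    allele_prefix: str = "all",
) -> list[AlleleCall]:
    """Partition one individual's verified alleles by template evidence.

    gDNA-and-cDNA -> transcribed; gDNA-only -> putatively non-expressed;
    cDNA-only alleles are reported (possible gDNA dropout) but the genotype
    source remains gDNA.
    """
    calls = []
    ordered = sorted(gdna_verified | cdna_verified)
    for i, seq in enumerate(ordered):
        in_g = seq in gdna_verified
        in_c = seq in cdna_verified
        expression = "transcribed" if (in_g and in_c) else (
            "gdna_only" if in_g else "cdna_only"
        )
        support = {}
        if replicate_counts:
            for tpl, by_rep in replicate_counts.items():
                support[tpl] = tuple(t.count(seq) for t in by_rep.values())
        calls.append(
            AlleleCall(
                allele_id=f"{individual_id}.{allele_prefix}{i:03d}",
                sequence=seq,
                individual_id=individual_id,
                support=support,
                orf_status=orf_status(seq, frame_offset),
                expression=expression,
            )
        )
    return calls


def transcribed_fraction(calls: list[AlleleCall]) -> float:
    """Fraction of an individual's gDNA-verified ORF alleles that are also in
    cDNA (the per-individual transcribed fraction)."""
    gdna = [c for c in calls if c.expression in ("transcribed", "gdna_only")]
    if not gdna:
        raise ValueError("no gDNA-verified alleles")
    return sum(1 for c in gdna if c.expression == "transcribed") / len(gdna)


def call_genotypes(
    tables: dict[str, VariantTable],
    tag_sheet: pd.DataFrame,
    min_copies: int = 10,
    max_edit: int = 2,
    frame_offset: int = 1,
) -> tuple[dict[str, list[AlleleCall]], dict[str, FilterLog]]:
    """Full calling pass over demultiplexed variant tables.

    Groups amplicons by individual and template via the tag sheet, filters
    each replicate table, verifies across replicates and classifies
    expression.  Individuals with only gDNA amplicons get calls with
    expression 'gdna_only' semantics left to downstream interpretation.
    """
    logs: dict[str, FilterLog] = {}
    filtered: dict[str, VariantTable] = {}
    for aid, table in tables.items():
        filtered[aid], logs[aid] = apply_filters(
            table, min_copies=min_copies, max_edit=max_edit
        )
    sheet = tag_sheet[~tag_sheet["is_negative_control"]]
    out: dict[str, list[AlleleCall]] = {}
    for ind, group in sheet.groupby("individual_id", sort=True):
        verified: dict[str, set[str]] = {}
        counts: dict[str, dict[int, VariantTable]] = {}
        for tpl, tgroup in group.groupby("template", sort=True):
            reps = {
                int(r.replicate): filtered[r.amplicon_id]
                for r in tgroup.itertuples(index=False)
            }
            verified[tpl] = verify_replicates(reps)
            counts[tpl] = reps
        gdna = verified.get("gDNA", set())
        cdna = verified.get("cDNA", set())
        if "cDNA" not in verified:
            # no expression evidence: report gDNA alleles without cDNA claims
            out[ind] = [
                c
                for c in classify_expression(
                    ind, gdna, set(), counts, frame_offset=frame_offset
                )
            ]
        else:
            out[ind] = classify_expression(
                ind, gdna, cdna, counts, frame_offset=frame_offset
            )
    return out, logs


def calls_to_frame(calls: dict[str, list[AlleleCall]]) -> pd.DataFrame:
    rows = []
    for ind in sorted(calls):
        for c in calls[ind]:
            rows.append(
                {
                    "individual_id": ind,
                    "allele_id": c.allele_id,
                    "sequence": c.sequence,
                    "orf_status": c.orf_status,
                    "expression": c.expression,
                }
            )
    return pd.DataFrame(rows)
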