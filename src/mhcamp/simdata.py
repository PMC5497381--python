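"""Synthetic amplicon-read generator for highly duplicated MHC class I exon 3.

The generator emulates the statistical structure of dual-tagged amplicon
sequencing of a multigene family with extreme copy-number variation:

* an allele pool of exon-3 sequences in three length classes — no deletion
  (241 bp), an in-frame 3 bp deletion (238 bp) and an in-frame 6 bp deletion
  (235 bp) — with class-specific nucleotide diversity and class-specific maps
  of codon sites under elevated nonsynonymous substitution;
* per-individual genotypes of tens of alleles drawn per class, with
  class-specific carrier probabilities;
* tagged, primered reads with i.i.d. per-base substitution errors and PCR
  chimeras joining two co-amplified templates at a uniform internal
  breakpoint;
* two PCR replicates per individual x template (gDNA / cDNA) and
  template-free negative controls.

Every read is logged with its provenance (source template(s), chimera
breakpoint, error positions) so downstream filters can be scored against
truth.  All randomness flows from a single :class:`numpy.random.Generator`
seeded by ``config.seed``; identical configs give byte-identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._codon import BASES, SENSE_CODONS, STOP_CODONS, codon_neighbors

CLASSES = ("no_del", "del3", "del6")

# IUPAC expansions used when emitting a concrete base for degenerate primer
# positions.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class ConfigurationError(ValueError):
    """Raised for contradictory simulation or pipeline configuration."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated study.

    Defaults mirror a passerine MHC class I study system: exon-3
    alleles of 241/238/235 bp, per-class diversity (mean pairwise p-distance)
    of 0.128 / 0.016 / 0.111, tens of alleles per individual for the
    no-deletion class, 6 bp sample tags and six negative controls per plate.
    """

    seed: int = 1
    n_individuals: int = 20
    reference_length_bp: int = 241
    frame_offset: int = 1  # first base completes an upstream codon
    del3_codon: int = 41
    del6_codons: tuple[int, int] = (48, 49)
    class_pool_sizes: dict = field(
        default_factory=lambda: {"no_del": 80, "del3": 5, "del6": 11}
    )
    class_target_pi: dict = field(
        default_factory=lambda: {"no_del": 0.128, "del3": 0.016, "del6": 0.111}
    )
    # codon sites (exon-local, 0-based in reference coordinates) with elevated
    # nonsynonymous substitution, per class
    class_pss_sites: dict = field(
        default_factory=lambda: {
            "no_del": frozenset(
                {3, 7, 9, 13, 17, 21, 24, 28, 33, 37, 44, 52, 56, 61, 65, 69, 72, 76}
            ),
            "del3": frozenset(),
            "del6": frozenset({3, 7, 13, 21, 33, 44, 56, 65}),
        }
    )
    omega_background: float = 0.2
    omega_pss: float = 5.0
    copy_number_range: dict = field(
        default_factory=lambda: {"no_del": (8, 59), "del3": (1, 3), "del6": (1, 8)}
    )
    class_carrier_prob: dict = field(
        default_factory=lambda: {"no_del": 1.0, "del3": 0.99, "del6": 0.93}
    )
    transcribed_prob: dict = field(
        default_factory=lambda: {"no_del": 0.60, "del3": 0.80, "del6": 0.73}
    )
    coverage: int = 1000
    coverage_per_allele: bool = False  # if True, reads per amplicon = coverage x alleles
    error_rate: float = 0.005
    chimera_rate: float = 0.02
    stop_codon_fraction: float = 0.03
    tag_length: int = 6
    n_negative_controls: int = 6
    cdna_individuals: int | None = None  # None -> all individuals get cDNA
    fwd_primer: str = "GAGYGGGGGTCTCCACAC"
    rev_primer: str = "TGCGMTCCAGYTCCTTCTGCCC"

    def __post_init__(self):
        if (self.reference_length_bp - self.frame_offset) % 3 != 0:
            raise ConfigurationError(
                "reference length minus frame offset must be a codon multiple"
            )
        n_codons = self.n_codons
        if not (0 <= self.del3_codon < n_codons):
            raise ConfigurationError("del3_codon outside the reference")
        a, b = self.del6_codons
        if abs(a - b) != 1 or not (0 <= min(a, b) and max(a, b) < n_codons):
            raise ConfigurationError("del6_codons must be an adjacent in-range pair")
        for name, p in [
            ("error_rate", self.error_rate),
            ("chimera_rate", self.chimera_rate),
            ("stop_codon_fraction", self.stop_codon_fraction),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for cls, (lo, hi) in self.copy_number_range.items():
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"copy_number_range[{cls}] must be positive")
        for cls, pi in self.class_target_pi.items():
            if not 0.0 <= pi < 0.5:
                raise ConfigurationError(f"class_target_pi[{cls}] must be in [0, 0.5)")

    @property
    def n_codons(self) -> int:
        return (self.reference_length_bp - self.frame_offset) // 3

    def class_length(self, cls: str) -> int:
        return self.reference_length_bp - {"no_del": 0, "del3": 3, "del6": 6}[cls]


@dataclass
class AlleleRecord:
    allele_id: str
    sequence: str
    length_class: str
    transcribed: bool
    has_stop: bool
    deleted_codons: tuple[int, ...]


class SimRead(NamedTuple):
    """One simulated read; ``seq`` is the full tagged, primered sequence."""

    id: str
    seq: str


@dataclass
class TruthSet:
    """Ground truth of a simulation: pool, genotypes and read provenance.

    ``provenance`` has one row per emitted read with columns read_id,
    amplicon_id, template_id, chimera_parent (3' parent or None), breakpoint
    (insert position of the join or None) and error_positions (tuple of
    insert positions hit by substitution errors).
    """

    config: SimulationConfig
    reference: str
    pool: dict[str, AlleleRecord]
    genotypes: dict[str, set[str]]
    provenance: pd.DataFrame | None = None

    def class_alleles(self, cls: str) -> list[AlleleRecord]:
        return [a for a in self.pool.values() if a.length_class == cls]

    def pool_to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "allele_id": a.allele_id,
                "length_class": a.length_class,
                "transcribed": a.transcribed,
                "has_stop": a.has_stop,
                "sequence": a.sequence,
            }
            for a in self.pool.values()
        ]
        return pd.DataFrame(rows)

    def genotypes_to_frame(self) -> pd.DataFrame:
        rows = [
            {"individual_id": ind, "allele_id": aid}
            for ind, ids in sorted(self.genotypes.items())
            for aid in sorted(ids)
        ]
        return pd.DataFrame(rows)


def _random_reference(rng: np.random.Generator, config: SimulationConfig) -> str:
    lead = "".join(rng.choice(list(BASES), size=config.frame_offset))
    codons = rng.choice(len(SENSE_CODONS), size=config.n_codons)
    return lead + "".join(SENSE_CODONS[i] for i in codons)


def _attempt_prob(target_pi: float) -> float:
    # per-site divergence-from-reference q with 2q(1-q) = target pairwise pi
    if target_pi <= 0:
        return 0.0
    return (1.0 - np.sqrt(1.0 - 2.0 * target_pi)) / 2.0


def _mutate_codon(rng: np.random.Generator, codon: str, omega: float) -> str:
    """One substitution step: pick a single-base neighbour, weighting
    nonsynonymous changes by omega relative to synonymous ones."""
    neighbors = codon_neighbors(codon)
    if not neighbors:
        return codon
    weights = np.array([omega if not syn else 1.0 for _, _, syn in neighbors])
    total = weights.sum()
    if total <= 0:
        return codon
    idx = rng.choice(len(neighbors), p=weights / total)
    return neighbors[idx][0]


def generate_allele_pool(config: SimulationConfig) -> TruthSet:
    """Draw the allele pool and per-individual genotypes.

    Each class starts from the shared reference (with its deletion applied)
    and accumulates codon-level substitutions: at every codon site a
    substitution is attempted with a per-site probability tuned so the
    realized mean pairwise p-distance approximates ``class_target_pi``;
    the substituted codon is drawn among single-base neighbours with
    nonsynonymous changes weighted by the site's omega.  Sites in the class
    PSS map use ``omega_pss`` and a mildly elevated attempt rate, emulating
    balancing selection hotspots.
    """
    rng = np.random.default_rng(config.seed)
    reference = _random_reference(rng, config)
    off = config.frame_offset
    ref_codons = [reference[off + 3 * i : off + 3 * i + 3] for i in range(config.n_codons)]

    pool: dict[str, AlleleRecord] = {}
    prefix = {"no_del": "nd", "del3": "d3", "del6": "d6"}
    for cls in CLASSES:
        size = int(config.class_pool_sizes.get(cls, 0))
        if size < 0:
            raise ConfigurationError(f"class_pool_sizes[{cls}] must be >= 0")
        if size == 0:
            continue
        if cls == "del3":
            deleted = (config.del3_codon,)
        elif cls == "del6":
            deleted = tuple(sorted(config.del6_codons))
        else:
            deleted = ()
        kept = [i for i in range(config.n_codons) if i not in deleted]
        pss = config.class_pss_sites.get(cls, frozenset())
        q = _attempt_prob(config.class_target_pi.get(cls, 0.0))
        p_codon = 1.0 - (1.0 - q) ** 3
        lead = reference[:off]
        for k in range(size):
            codons = []
            for ref_idx in kept:
                codon = ref_codons[ref_idx]
                is_pss = ref_idx in pss
                omega = config.omega_pss if is_pss else config.omega_background
                p_site = min(1.0, p_codon * (1.5 if is_pss else 1.0))
                if p_site > 0 and rng.random() < p_site:
                    codon = _mutate_codon(rng, codon, omega)
                codons.append(codon)
            has_stop = False
            if config.stop_codon_fraction > 0 and rng.random() < config.stop_codon_fraction:
                pos = int(rng.integers(0, len(codons)))
                codons[pos] = sorted(STOP_CODONS)[int(rng.integers(0, 3))]
                has_stop = True
            seq = lead + "".join(codons)
            transcribed = (not has_stop) and rng.random() < config.transcribed_prob.get(
                cls, 1.0
            )
            aid = f"{prefix[cls]}-{k:04d}"
            pool[aid] = AlleleRecord(aid, seq, cls, transcribed, has_stop, deleted)
            assert len(seq) == config.class_length(cls)

    genotypes: dict[str, set[str]] = {}
    for i in range(config.n_individuals):
        ind = f"ind{i:03d}"
        alleles: set[str] = set()
        for cls in CLASSES:
            class_ids = [a.allele_id for a in pool.values() if a.length_class == cls]
            if not class_ids:
                continue
            if rng.random() >= config.class_carrier_prob.get(cls, 1.0):
                continue
            lo, hi = config.copy_number_range.get(cls, (1, 1))
            k = int(rng.integers(lo, hi + 1))
            k = min(k, len(class_ids))
            chosen = rng.choice(class_ids, size=k, replace=False)
            alleles.update(chosen.tolist())
        genotypes[ind] = alleles
    return TruthSet(config=config, reference=reference, pool=pool, genotypes=genotypes)


def make_tag_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Dual-barcode plate sheet: one unique (fwd_tag, rev_tag) pair per
    amplicon; two PCR replicates per individual x template plus negative
    controls."""
    rng = np.random.default_rng(config.seed + 10_007)
    n_cdna = (
        config.n_individuals
        if config.cdna_individuals is None
        else min(config.cdna_individuals, config.n_individuals)
    )
    amplicons = []
    for i in range(config.n_individuals):
        ind = f"ind{i:03d}"
        templates = ["gDNA"] + (["cDNA"] if i < n_cdna else [])
        for tpl in templates:
            for rep in (1, 2):
                amplicons.append((f"{ind}.{tpl}.r{rep}", ind, tpl, rep, False))
    for j in range(config.n_negative_controls):
        amplicons.append((f"neg{j:02d}.gDNA.r1", f"neg{j:02d}", "gDNA", 1, True))

    tags: set[str] = set()
    while len(tags) < 2 * len(amplicons):
        tags.add("".join(rng.choice(list(BASES), size=config.tag_length)))
    tag_list = sorted(tags)
    rng.shuffle(tag_list)
    rows = []
    for k, (aid, ind, tpl, rep, neg) in enumerate(amplicons):
        rows.append(
            {
                "amplicon_id": aid,
                "individual_id": ind,
                "template": tpl,
                "replicate": rep,
                "fwd_tag": tag_list[2 * k],
                "rev_tag": tag_list[2 * k + 1],
                "is_negative_control": neg,
            }
        )
    return pd.DataFrame(rows)


def _primer_expansions(primer: str) -> list[str]:
    return ["".join(p) for p in itertools.product(*(_IUPAC[b] for b in primer))]


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


_OTHER_BASES = {b: [c for c in BASES if c != b] for b in BASES}


def simulate_reads(
    truth: TruthSet, config: SimulationConfig, tag_sheet: pd.DataFrame
) -> list[SimRead]:
    """Emit tagged amplicon reads with substitution errors and PCR chimeras.

    Read layout: ``fwd_tag + fwd_primer + insert + revcomp(rev_primer) +
    revcomp(rev_tag)``; degenerate primer positions are realized per read.
    With probability ``chimera_rate`` the insert joins two distinct
    co-amplified templates at a uniform internal breakpoint.  Each amplicon
    gets ``coverage`` reads (``coverage`` per template when
    ``coverage_per_allele`` is set); negative-control amplicons emit none.
    Per-read provenance is stored on ``truth.provenance``.
    """
    pairs = list(zip(tag_sheet["fwd_tag"], tag_sheet["rev_tag"]))
    if len(set(pairs)) != len(pairs):
        raise ConfigurationError("duplicate (fwd_tag, rev_tag) pair in tag sheet")
    rng = np.random.default_rng(config.seed + 20_011)
    fwd_variants = _primer_expansions(config.fwd_primer)
    rc_rev_variants = [_revcomp(v) for v in _primer_expansions(config.rev_primer)]
    reads: list[SimRead] = []
    prov: dict[str, list] = {
        "read_id": [], "amplicon_id": [], "template_id": [],
        "chimera_parent": [], "breakpoint": [], "error_positions": [],
    }
    for row in tag_sheet.itertuples(index=False):
        if row.is_negative_control:
            continue
        genotype = sorted(truth.genotypes.get(row.individual_id, set()))
        if row.template == "cDNA":
            genotype = [a for a in genotype if truth.pool[a].transcribed]
        if not genotype:
            continue
        seqs = [truth.pool[a].sequence for a in genotype]
        lens = np.array([len(s) for s in seqs])
        k = len(genotype)
        n_reads = config.coverage * (k if config.coverage_per_allele else 1)
        prefixes = [row.fwd_tag + v for v in fwd_variants]
        rc_rev_tag = _revcomp(row.rev_tag)
        suffixes = [v + rc_rev_tag for v in rc_rev_variants]

        tidx = rng.integers(0, k, size=n_reads)
        if k >= 2 and config.chimera_rate > 0:
            chim = rng.random(n_reads) < config.chimera_rate
            partner = rng.integers(0, k - 1, size=n_reads)
            partner = partner + (partner >= tidx)
            limits = np.minimum(lens[tidx], lens[partner])
            bps = rng.integers(1, limits)
        else:
            chim = np.zeros(n_reads, dtype=bool)
            partner = tidx
            bps = np.zeros(n_reads, dtype=int)
        # a chimeric insert inherits the 3' parent's length
        read_lens = np.where(chim, lens[partner], lens[tidx])
        fsel = rng.integers(0, len(prefixes), size=n_reads)
        rsel = rng.integers(0, len(suffixes), size=n_reads)
        if config.error_rate > 0:
            mask = rng.random((n_reads, int(lens.max()))) < config.error_rate
            mask &= np.arange(int(lens.max()))[None, :] < read_lens[:, None]
            err_rows, err_cols = np.nonzero(mask)
            repl = rng.integers(0, 3, size=len(err_rows))
            starts = np.searchsorted(err_rows, np.arange(n_reads))
            ends = np.searchsorted(err_rows, np.arange(n_reads) + 1)
        else:
            starts = ends = np.zeros(n_reads, dtype=int)
            err_cols = repl = np.zeros(0, dtype=int)

        for n in range(n_reads):
            t = int(tidx[n])
            template_id = genotype[t]
            insert = seqs[t]
            parent2 = None
            breakpoint_ = None
            if chim[n]:
                p2 = int(partner[n])
                parent2 = genotype[p2]
                breakpoint_ = int(bps[n])
                insert = insert[:breakpoint_] + seqs[p2][breakpoint_:]
            a, b = int(starts[n]), int(ends[n])
            if b > a:
                err_pos = tuple(int(p) for p in err_cols[a:b])
                chars = list(insert)
                for j in range(a, b):
                    p = int(err_cols[j])
                    chars[p] = _OTHER_BASES[chars[p]][int(repl[j])]
                insert = "".join(chars)
            else:
                err_pos = ()
            read_id = f"{row.amplicon_id}:{n:06d}"
            reads.append(
                SimRead(read_id, prefixes[fsel[n]] + insert + suffixes[rsel[n]])
            )
            prov["read_id"].append(read_id)
            prov["amplicon_id"].append(row.amplicon_id)
            prov["template_id"].append(template_id)
            prov["chimera_parent"].append(parent2)
            prov["breakpoint"].append(breakpoint_)
            prov["error_positions"].append(err_pos)
    truth.provenance = pd.DataFrame(prov)
    return reads


def write_fastq(reads: list[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_truth(truth: TruthSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.pool_to_frame().to_csv(directory / "pool.tsv", sep="\t", index=False)
    truth.genotypes_to_frame().to_csv(
        directory / "genotypes.tsv", sep="\t", index=False
    )
    if truth.provenance is not None:
        prov = truth.provenance.copy()
        prov["error_positions"] = [
            ";".join(map(str, t)) for t in prov["error_positions"]
        ]
        prov.to_csv(directory / "provenance.tsv", sep="\t", index=False)


def simulate_codon_alignment(
    n_taxa: int,
    n_sites: int,
    omega_map: dict[int, float] | None = None,
    omega_background: float = 1.0,
    tree_length: float = 10.0,
    frame_offset: int = 0,
    seed: int = 0,
) -> dict[str, str]:
    """Codon alignment evolved along a random bifurcating tree.

    A random topology is drawn by iterative pair joining; every branch gets
    length ``tree_length / (2 n_taxa - 2)`` expected substitution steps per
    codon site.  Each step moves the codon to a single-base sense neighbour,
    weighting nonsynonymous moves by the site's omega (``omega_map`` keyed by
    codon site, default ``omega_background``).  Useful as a controlled regime
    for site-test calibration and power studies.
    """
    if n_taxa < 3:
        raise ConfigurationError("n_taxa must be >= 3")
    rng = np.random.default_rng(seed)
    omega_map = omega_map or {}
    root = [SENSE_CODONS[i] for i in rng.choice(len(SENSE_CODONS), size=n_sites)]
    branch_len = tree_length / (2 * n_taxa - 2)

    # random topology: (children, ...) tuples; leaves are taxon indices
    nodes: list = list(range(n_taxa))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    topology = nodes[0]

    lead = "".join(rng.choice(list(BASES), size=frame_offset))
    out: dict[str, str] = {}

    def evolve(codons: list[str]) -> list[str]:
        codons = list(codons)
        n_steps = rng.poisson(branch_len, size=n_sites)
        for s in np.flatnonzero(n_steps):
            omega = omega_map.get(int(s), omega_background)
            for _ in range(int(n_steps[s])):
                codons[s] = _mutate_codon(rng, codons[s], omega)
        return codons

    def descend(node, codons: list[str]) -> None:
        codons = evolve(codons)
        if isinstance(node, tuple):
            for child in node:
                descend(child, codons)
        else:
            out[f"t{node:04d}"] = lead + "".join(codons)

    for child in topology:
        descend(child, root)
    return out


def simulate_study(config: SimulationConfig):
    """Convenience wrapper: pool + genotypes + tag sheet + reads."""
    truth = generate_allele_pool(config)
    sheet = make_tag_sheet(config)
    reads = simulate_reads(truth, config, sheet)
    return truth, sheet, reads
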