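# mhcamp

Amplicon genotyping and comparative evolutionary analysis of highly duplicated
MHC class I genes.

`mhcamp` is a self-contained toolkit for studying MHC class I diversity in
species where the locus has undergone extensive duplication, so that a single
PCR amplifies dozens of co-amplifying alleles per individual. It covers the
full workflow: simulating tagged-amplicon sequencing studies, demultiplexing
and genotyping with replicate-based artifact filtering, partitioning alleles
into exon-length classes, population-genetic summaries, phylogeny-based tests
for positively selected sites, recombination/chimera detection, and
NeighborNet split networks with bootstrap support.

## Quick start

Run the whole pipeline on a simulated study:

```bash
mhcamp all --seed 1 --out-dir run1
```

or stage by stage:

```bash
mhcamp simulate --out sim --seed 4 --individuals 20 --coverage 300 --coverage-per-allele
mhcamp demux    --reads sim/reads.fastq --tags sim/tags.tsv --out tables.tsv
mhcamp call     --tables tables.tsv --tags sim/tags.tsv --out calls.tsv
mhcamp stats    --alleles alleles.fasta
mhcamp select   --alleles alleles.fasta --out selection.json
mhcamp recomb   --alleles alleles.fasta --out recombination.json
mhcamp network  --alleles alleles.fasta --boot 200 --out net.nex
```

From Python:

```python
from mhcamp import simdata, demux, allele_calling

cfg = simdata.SimulationConfig(seed=11, coverage=300, coverage_per_allele=True)
truth, tag_sheet, reads = simdata.simulate_study(cfg)
result = demux.demultiplex(reads, tag_sheet, (cfg.fwd_primer, cfg.rev_primer))
tables = demux.tables_from_demux(result)
calls, logs = allele_calling.call_genotypes(tables, tag_sheet)
```

## Modules

| Module | Purpose |
| --- | --- |
| `simdata` | Simulated study generator: allele pools in three exon-length classes, genotypes, tagged amplicons, reads with substitution errors and PCR chimeras, plus a codon-level sequence evolution simulator for validating the selection tests. |
| `demux` | Tag/primer demultiplexing with IUPAC-aware primer matching and per-amplicon variant tables. |
| `allele_calling` | Copy-number floor, chimera flagging, 1–2 bp error collapse, replicate verification, ORF status, transcribed/gDNA-only/cDNA-only expression classes. |
| `length_classes` | Assignment of alleles to the full-length, 3 bp-deletion and 6 bp-deletion exon classes. |
| `popgen_stats` | Pairwise p-distances, nucleotide diversity, minimum-locus bounds, transcribed fractions, amino-acid/nucleotide ratios, repeatability. |
| `selection` | Neighbor-joining trees, counting-based and likelihood-ratio site tests for positive selection, consensus PSS, subsampling analyses. |
| `recombination` | MaxChi and Chimaera sliding scans with permutation p-values, PHI test, triplet scanning. |
| `network` | Distance corrections (p, K2P, gamma), NeighborNet split networks, bootstrap supports, NEXUS export. |
| `pipeline` / `cli` | Deterministic end-to-end orchestration with per-stage seeds, run logs and a `mhcamp` command-line interface. |

## Validation

`scripts/acceptance.py` recomputes the package's headline quantities — exact
arithmetic reproductions plus simulation-based recovery studies (genotyping
precision/recall, site-test calibration and power, chimera detection,
split-network tree-metric recovery):

```bash
python scripts/acceptance.py --seed 1 --out acceptance.json
```

The test suite mirrors these checks and adds module-level unit tests:

```bash
python -m pytest -q tests/
```

See `docs/methods.md` for the statistical methods and the design rationale
behind the simulation defaults.
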