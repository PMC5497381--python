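# Methods

This note documents the statistical methods implemented in `mhcamp` and the
rationale for the simulation defaults used in the validation studies.

## Study model

The package models a tagged-amplicon sequencing study of a highly duplicated
MHC class I locus. One primer pair amplifies a single exon from many
co-amplifying loci at once, so an individual's "genotype" is a set of tens of
alleles rather than two. Each individual contributes both a genomic DNA (gDNA)
and a complementary DNA (cDNA) template, each amplified in two independent PCR
replicates distinguished by unique forward/reverse tag combinations.

Alleles fall into three exon-length classes: full-length (no deletion), a
3 bp deletion removing one codon, and a 6 bp deletion removing two adjacent
codons. Deletions are in-frame, so all classes translate without frameshifts.

## Simulated data (`simdata`)

`generate_allele_pool` derives each class from a shared random reference:
class membership fixes the deleted codon positions, and per-allele point
mutations create the within-class diversity. `simulate_study` then draws
per-individual genotypes (class-specific copy-number ranges), marks a fraction
of alleles as untranscribed (absent from cDNA), assigns unique tag pairs to
every individual × template × replicate amplicon, and generates reads.

The read model applies, per read: optional PCR chimerism (a single crossover
between two alleles of the same genotype at a uniform breakpoint, the read
inheriting the 3′ parent's length) and independent per-base substitution
errors. Primer degeneracy is realized by sampling among the expanded primer
variants. A provenance table records, for every read, its template, chimera
parent/breakpoint, and error positions, which the genotyping validation uses
as ground truth.

Coverage can be specified per amplicon or per allele
(`coverage_per_allele=True`). The per-allele mode is the study-like regime:
with ~30 alleles per amplicon and a 0.5 %/base error rate on ~240 bp reads,
only ~30 % of reads are error-free, so per-amplicon coverage of a few hundred
leaves individual alleles below any sensible copy-number floor. Deep
per-template coverage (hundreds of reads per allele, i.e. tens of thousands
per amplicon) is what makes replicate-verified genotyping reliable, and is the
default in the pipeline.

`simulate_codon_alignment` is a separate codon-level evolution simulator used
to validate the selection tests: a random bifurcating topology with equal
branch lengths, Poisson-distributed substitution events per branch and site,
and single-base codon moves accepted with probability proportional to ω for
nonsynonymous changes (stop codons rejected). Per-site ω maps let validation
studies plant selected sites at known positions.

## Genotyping (`demux`, `allele_calling`)

Demultiplexing matches exact tags plus IUPAC-aware primers (configurable
mismatch allowance) in both orientations and trims reads to the insert.
Variant tables count unique insert sequences per amplicon.

Artifact filtering applies, in order:

1. **Copy-number floor** — variants below `min_copies` (default 10) are
   dropped.
2. **Chimera flagging** — a variant is removed if it can be written as a
   prefix of one strictly more abundant same-length variant joined to the
   suffix of another, with supporting signal on both sides of the crossover.
3. **1–2 bp collapse** — a variant within edit distance 2 of a more abundant
   variant is collapsed into it when its count is at most `max_count_ratio`
   (default 0.5) of the parent's. The ratio guard keeps genuinely distinct
   alleles that differ by 1–2 bp but amplify at comparable depth; true
   single-codon-deletion alleles can sit 1–3 edits from full-length alleles,
   so an unconditional collapse would delete real diversity.

Only variants present in both PCR replicates of a template are accepted
(`verify_replicates`). Expression classes compare gDNA and cDNA calls:
`transcribed` (both), `gdna_only`, `cdna_only`. ORF status distinguishes
intact reading frames from stop-codon and frameshift variants.

## Population statistics (`popgen_stats`)

Pairwise p-distances use pairwise gap deletion at the nucleotide or amino
acid level; nucleotide diversity averages over unique sequences by default.
The minimum number of loci implied by a maximum per-individual allele count
is ⌈n/2⌉. Per-individual transcribed fractions and amino-acid-per-nucleotide
allele ratios reproduce the standard descriptive summaries for this kind of
dataset.

## Selection tests (`selection`)

Trees are neighbor-joining on p- or K2P distances (scikit-bio). Two site
tests are provided, both operating on codon columns with stop codons masked:

- **Counting test.** Minimum substitution events per site via Fitch parsimony
  on the tree; each event's synonymous/nonsynonymous weight via averaged
  mutational pathways. The per-site expected nonsynonymous fraction comes
  from the alignment-wide mean of potential sites, and a one-tailed binomial
  test (in the direction of the observed deviation) flags sites with a
  nonsynonymous excess.
- **Likelihood-ratio test.** A per-site codon likelihood under an
  ω-parameterized rate matrix, maximized over a bounded log-rate, compared
  between ω free and ω = 1 via χ²(1).

`consensus_pss` intersects site lists k-of-m across methods;
`subsample_selection` repeats the counting test on random allele subsets to
measure the stability of PSS counts with sample size.

Validation (acceptance script and suite) checks: type-I error within 1.6× the
nominal α under neutrality (500 sites, 24 taxa); recovery of ≥7/10 planted
ω = 5 sites with ≤2 false positives among 100 alleles; a strong > moderate >
none ordering of PSS counts across three regimes proportioned like the three
length classes (planted 18/8/0 sites); and non-overlapping subsampled PSS
distributions between the strong and no-selection regimes. The powered
regimes use deep total tree lengths because parsimony-based counting needs
many observable substitution events per site; these settings were fixed as
part of the study design, before running the validations.

## Recombination (`recombination`)

`maxchi_scan` and `chimaera_scan` slide a window over the informative sites
of a sequence triplet and maximize a 2×2 χ² of parental-origin composition
before/after a candidate breakpoint; significance comes from permuting site
order. `phi_test` computes the pairwise homoplasy index from refined
incompatibility scores with a permutation null. `scan_triplets` ranks triplet
candidates and `consensus_events` merges per-method calls.

Validation plants single-crossover chimeras between full-length alleles and
requires detection at p < 0.01 with the breakpoint located within ±2
informative sites, and a type-I rate ≤ 1.5× nominal on recombination-free
triplets.

## Split networks (`network`)

Distances support p, K2P and gamma-corrected K2P (saturation-ceiling guard).
`neighbornet_from_distances` implements NeighborNet agglomeration with
non-negative least-squares split weights; on additive (tree) distances it
reproduces the tree's splits and branch lengths to machine precision and the
induced distances match the input. `bootstrap_supports` resamples alignment
columns and reports the percentage of replicate networks containing each
split. Networks export to NEXUS (SplitsTree-compatible).

## Pipeline (`pipeline`, `cli`)

`run_pipeline` chains simulate → demux → call → classify → stats → selection →
recombination → network. Each stage gets an independent seed derived from the
run seed via `numpy.random.SeedSequence([seed, stage_index])`, outputs are
content-hashed into `run_log.json`, and the run is fully reproducible: two
runs with the same seed and configuration produce byte-identical genotype
tables and equal summaries.
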