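"""Simulated-study generator: structure, determinism, noise model."""

import numpy as np
import pytest

from mhcamp import simdata
from mhcamp.simdata import ConfigurationError, SimulationConfig


def test_config_rejects_bad_frame():
    with pytest.raises(ConfigurationError):
        SimulationConfig(reference_length_bp=240, frame_offset=1)


def test_config_rejects_bad_rates():
    with pytest.raises(ConfigurationError):
        SimulationConfig(error_rate=1.5)
    with pytest.raises(ConfigurationError):
        SimulationConfig(chimera_rate=-0.1)


def test_config_rejects_non_adjacent_del6():
    with pytest.raises(ConfigurationError):
        SimulationConfig(del6_codons=(10, 12))


def test_class_lengths():
    cfg = SimulationConfig()
    assert cfg.class_length("no_del") == 241
    assert cfg.class_length("del3") == 238
    assert cfg.class_length("del6") == 235
    assert cfg.n_codons == 80


def test_pool_sizes_and_lengths(default_pool):
    cfg = default_pool.config
    for cls in ("no_del", "del3", "del6"):
        alleles = default_pool.class_alleles(cls)
        assert len(alleles) == cfg.class_pool_sizes[cls]
        assert all(len(a.sequence) == cfg.class_length(cls) for a in alleles)
    # all pool sequences unique
    seqs = [a.sequence for a in default_pool.pool.values()]
    assert len(set(seqs)) == len(seqs)


def test_deleted_codons_recorded(default_pool):
    cfg = default_pool.config
    for a in default_pool.class_alleles("del3"):
        assert a.deleted_codons == (cfg.del3_codon,)
    for a in default_pool.class_alleles("del6"):
        assert a.deleted_codons == tuple(sorted(cfg.del6_codons))


def test_generation_deterministic():
    cfg = SimulationConfig(seed=3, n_individuals=3, coverage=30,
                           class_pool_sizes={"no_del": 8, "del3": 2, "del6": 3})
    t1, s1, r1 = simdata.simulate_study(cfg)
    t2, s2, r2 = simdata.simulate_study(cfg)
    assert [a.sequence for a in t1.pool.values()] == [a.sequence for a in t2.pool.values()]
    assert t1.genotypes == t2.genotypes
    assert s1.equals(s2)
    assert r1 == r2


def test_tag_sheet_structure(small_study):
    cfg, _, sheet, _ = small_study
    pairs = list(zip(sheet["fwd_tag"], sheet["rev_tag"]))
    assert len(set(pairs)) == len(pairs)
    assert set(sheet["template"]) == {"gDNA", "cDNA"}
    real = sheet[~sheet["is_negative_control"]]
    # two replicates per individual x template
    assert (real.groupby(["individual_id", "template"]).size() == 2).all()
    assert sheet["is_negative_control"].sum() == cfg.n_negative_controls
    assert all(len(t) == cfg.tag_length for t in sheet["fwd_tag"])


def test_read_layout_and_negative_controls(small_study):
    cfg, truth, sheet, reads = small_study
    by_amp = {}
    for r in reads:
        by_amp.setdefault(r.id.rsplit(":", 1)[0], []).append(r)
    negatives = sheet[sheet["is_negative_control"]]["amplicon_id"]
    assert not any(aid in by_amp for aid in negatives)
    row = sheet[~sheet["is_negative_control"]].iloc[0]
    for r in by_amp[row.amplicon_id][:20]:
        assert r.seq.startswith(row.fwd_tag)
        assert r.seq.endswith(simdata._revcomp(row.rev_tag))
        insert = r.seq[cfg.tag_length + len(cfg.fwd_primer):
                       -(cfg.tag_length + len(cfg.rev_primer))]
        assert insert in {a.sequence for a in truth.pool.values()}


def test_coverage_per_allele_read_counts(small_study):
    cfg, truth, sheet, reads = small_study
    counts = {}
    for r in reads:
        aid = r.id.rsplit(":", 1)[0]
        counts[aid] = counts.get(aid, 0) + 1
    for row in sheet[~sheet["is_negative_control"]].itertuples(index=False):
        genotype = truth.genotypes[row.individual_id]
        if row.template == "cDNA":
            genotype = {a for a in genotype if truth.pool[a].transcribed}
        assert counts.get(row.amplicon_id, 0) == cfg.coverage * len(genotype)


def test_chimera_and_error_provenance():
    cfg = SimulationConfig(seed=9, n_individuals=2, coverage=4000,
                           error_rate=0.002, chimera_rate=0.05,
                           class_pool_sizes={"no_del": 10, "del3": 2, "del6": 3})
    truth, sheet, reads = simdata.simulate_study(cfg)
    prov = truth.provenance
    assert len(prov) == len(reads)
    chim_frac = prov["chimera_parent"].notna().mean()
    assert 0.03 < chim_frac < 0.07
    per_base_err = np.mean([len(t) for t in prov["error_positions"]]) / 241
    assert 0.001 < per_base_err < 0.003
    chim = prov[prov["chimera_parent"].notna()]
    assert (chim["template_id"] != chim["chimera_parent"]).all()
    assert (chim["breakpoint"] >= 1).all()


def test_duplicate_tag_pair_rejected(small_study):
    cfg, truth, sheet, _ = small_study
    bad = sheet.copy()
    bad.loc[bad.index[1], ["fwd_tag", "rev_tag"]] = bad.iloc[0][["fwd_tag", "rev_tag"]].values
    with pytest.raises(ConfigurationError):
        simdata.simulate_reads(truth, cfg, bad)


def test_codon_alignment_shapes_and_determinism():
    aln = simdata.simulate_codon_alignment(8, 20, seed=4, tree_length=5.0)
    assert len(aln) == 8
    assert all(len(s) == 60 for s in aln.values())
    assert aln == simdata.simulate_codon_alignment(8, 20, seed=4, tree_length=5.0)


def test_codon_alignment_omega_shifts_nonsynonymous_fraction():
    from Bio.Seq import Seq

    def aa_variability(aln, sites):
        tot = 0
        for s in sites:
            aas = {str(Seq(seq[3 * s:3 * s + 3]).translate()) for seq in aln.values()}
            tot += len(aas) - 1
        return tot

    high = simdata.simulate_codon_alignment(
        40, 30, omega_map={s: 5.0 for s in range(15)},
        omega_background=0.05, tree_length=15.0, seed=2)
    assert aa_variability(high, range(15)) > aa_variability(high, range(15, 30))
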