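"""Artifact filters, replicate verification and expression classes."""

import pytest

from mhcamp import allele_calling as ac
from mhcamp.demux import VariantTable
from mhcamp.simdata import ConfigurationError


def vt(variants, aid="amp"):
    return VariantTable(aid, variants, sum(c for _, c in variants))


# --- copy-number floor ------------------------------------------------------


def test_low_copy_floor_boundary():
    t = vt([("AAAA", 10), ("CCCC", 9), ("GGGG", 300)])
    out = ac.filter_low_copy(t, min_copies=10)
    assert out.sequences == ["GGGG", "AAAA"]


def test_low_copy_rejects_bad_threshold():
    with pytest.raises(ConfigurationError):
        ac.filter_low_copy(vt([("AAAA", 5)]), min_copies=0)


# --- chimeras ---------------------------------------------------------------


def test_chimera_of_two_more_abundant_parents_removed():
    a = "AAAAAAAAAA"
    b = "CCCCCCCCCC"
    chim = a[:4] + b[4:]
    t = vt([(a, 500), (b, 400), (chim, 50)])
    log = ac.FilterLog()
    out = ac.flag_chimeras(t, log=log)
    assert chim not in out.sequences
    assert a in out.sequences and b in out.sequences
    flag = log.chimeras[0]
    assert {flag.parent_a, flag.parent_b} == {a, b}
    assert flag.breakpoint == 4


def test_chimera_requires_strictly_more_abundant_parents():
    a = "AAAAAAAAAA"
    b = "CCCCCCCCCC"
    chim = a[:4] + b[4:]
    # chimera as abundant as one parent: kept
    t = vt([(a, 500), (chim, 400), (b, 400)])
    out = ac.flag_chimeras(t)
    assert chim in out.sequences


def test_chimera_needs_signal_on_both_sides():
    a = "AAAAAAAAAA"
    b = "AAAAAAAACC"  # differs only near the 3' end
    hybrid = b  # any crossover reproduces a parent, not a new variant
    t = vt([(a, 500), (b, 400), ("GGGGGGGGGG", 300)])
    out = ac.flag_chimeras(t)
    assert set(out.sequences) == {a, b, "GGGGGGGGGG"}


def test_chimera_parents_must_match_length():
    a = "AAAAAAAAAA"
    b = "CCCCCCCCCC"
    short = a[:4] + b[4:8]
    t = vt([(a, 500), (b, 400), (short, 50)])
    out = ac.flag_chimeras(t)
    assert short in out.sequences


# --- 1-2 bp collapse --------------------------------------------------------


def test_collapse_small_variant_onto_abundant_parent():
    a = "ACGTACGTACGT"
    near = "ACGTACGAACGT"  # one substitution
    t = vt([(a, 1000), (near, 30)])
    log = ac.FilterLog()
    out = ac.collapse_errors(t, log=log)
    assert out.sequences == [a]
    rec = log.collapsed[0]
    assert rec.parent == a and rec.edit_distance == 1


def test_collapse_handles_indels_within_two_edits():
    a = "ACGTACGTACGT"
    near = "ACGTACGTACG"  # one deletion
    out = ac.collapse_errors(vt([(a, 900), (near, 12)]))
    assert out.sequences == [a]


def test_equal_count_near_variants_both_kept():
    a = "ACGTACGTACGT"
    near = "ACGTACGAACGT"
    out = ac.collapse_errors(vt([(a, 400), (near, 400)]))
    assert set(out.sequences) == {a, near}


def test_comparable_abundance_not_collapsed():
    # two true alleles amplify at comparable depth: ratio above the cutoff
    a = "ACGTACGTACGT"
    near = "ACGTACGAACGT"
    out = ac.collapse_errors(vt([(a, 500), (near, 400)]))
    assert set(out.sequences) == {a, near}
    strict = ac.collapse_errors(vt([(a, 500), (near, 400)]), max_count_ratio=1.0)
    assert strict.sequences == [a]


def test_distant_variants_not_collapsed():
    a = "ACGTACGTACGT"
    far = "ACGTTTTAACGT"
    out = ac.collapse_errors(vt([(a, 1000), (far, 30)]))
    assert set(out.sequences) == {a, far}


# --- composition ------------------------------------------------------------


def test_apply_filters_contractive_and_idempotent():
    a = "AAAAAAAAAA"
    b = "CCCCCCCCCC"
    chim = a[:5] + b[5:]
    err = "AAAAAAATAA"  # internal 1 bp error: not explicable as a crossover
    t = vt([(a, 900), (b, 800), (chim, 60), (err, 25), ("GGGGGGGGGG", 4)])
    out, log = ac.apply_filters(t)
    assert set(out.sequences) <= set(t.sequences)
    assert set(out.sequences) == {a, b}
    assert [s for s, _ in log.low_copy] == ["GGGGGGGGGG"]
    assert [f.sequence for f in log.chimeras] == [chim]
    assert [c.sequence for c in log.collapsed] == [err]
    again, _ = ac.apply_filters(out)
    assert again.variants == out.variants


# --- replicate verification -------------------------------------------------


def test_verify_replicates_intersection():
    r1 = vt([("AAAA", 50), ("CCCC", 40)])
    r2 = vt([("AAAA", 60), ("GGGG", 30)])
    assert ac.verify_replicates({1: r1, 2: r2}) == {"AAAA"}
    assert ac.verify_replicates({1: r1, 2: r2}, min_replicates=1) == {
        "AAAA", "CCCC", "GGGG"
    }


def test_verify_replicates_missing_table_errors():
    r1 = vt([("AAAA", 50)])
    with pytest.raises(ConfigurationError):
        ac.verify_replicates({1: r1, 2: None})
    with pytest.raises(ConfigurationError):
        ac.verify_replicates({})
    with pytest.raises(ConfigurationError):
        ac.verify_replicates({1: r1}, min_replicates=2)


# --- ORF and expression -----------------------------------------------------


def test_orf_status():
    orf = "A" + "ATGGCCGCC"
    stop = "A" + "ATGTAAGCC"
    shifted = "A" + "ATGGCCGC"
    assert ac.orf_status(orf) == "orf"
    assert ac.orf_status(stop) == "stop_codon"
    assert ac.orf_status(shifted) == "frameshift"


def test_classify_expression_partition():
    g = {"A" + "ATGGCCGCC", "A" + "ATGGCCGCT"}
    c = {"A" + "ATGGCCGCC", "A" + "ATGGCCACC"}
    calls = ac.classify_expression("ind0", g, c)
    by_seq = {x.sequence: x.expression for x in calls}
    assert by_seq["A" + "ATGGCCGCC"] == "transcribed"
    assert by_seq["A" + "ATGGCCGCT"] == "gdna_only"
    assert by_seq["A" + "ATGGCCACC"] == "cdna_only"
    assert all(x.individual_id == "ind0" for x in calls)


def test_transcribed_fraction():
    g = {"A" + "ATGGCCGCC", "A" + "ATGGCCGCT"}
    c = {"A" + "ATGGCCGCC"}
    calls = ac.classify_expression("ind0", g, c)
    assert ac.transcribed_fraction(calls) == 0.5
    with pytest.raises(ValueError):
        ac.transcribed_fraction([])


# --- end-to-end zero noise --------------------------------------------------


def test_zero_noise_calls_match_truth_exactly(small_calls):
    truth, calls, _ = small_calls
    for ind, ind_calls in calls.items():
        true_seqs = {truth.pool[a].sequence for a in truth.genotypes[ind]}
        called = {c.sequence for c in ind_calls
                  if c.expression in ("transcribed", "gdna_only")}
        assert called == true_seqs
        # expression matches the simulated transcription flags
        transcribed_truth = {
            truth.pool[a].sequence
            for a in truth.genotypes[ind]
            if truth.pool[a].transcribed
        }
        called_transcribed = {c.sequence for c in ind_calls
                              if c.expression == "transcribed"}
        assert called_transcribed == transcribed_truth
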