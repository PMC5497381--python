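"""End-to-end pipeline: simulate -> demux -> call -> classify -> stats ->
selection -> recombination -> network.

One structured config drives every stage; numeric defaults are the study
constants (copy floor 10, 1-2 bp collapse, 20,000-read cap, 47-allele
subsampling with 100 replicates, K2P gamma shape 0.29, split threshold 1e-6,
1000 bootstrap replicates with a 70% display threshold).  A single global
seed fans out to per-stage seeds through numpy SeedSequence spawning keyed by
stage index, so stages can be rerun independently yet reproducibly.  Every
stage's outputs are content-hashed into the run log.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import allele_calling, demux, length_classes, network, popgen_stats, recombination
from . import selection as selection_mod
from . import simdata
from .io_utils import read_fasta, read_tag_sheet, write_fasta
from .simdata import ConfigurationError, SimulationConfig

STAGES = [
    "simulate",
    "demux",
    "call",
    "classify",
    "stats",
    "selection",
    "recombination",
    "network",
]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "mhcamp_run",
    "paths": {
        "reads": None,
        "tags": None,
        "reference": None,
    },
    "simulate": {
        "enabled": True,
        "n_individuals": 20,
        "coverage": 300,
        "coverage_per_allele": True,
        "error_rate": 0.005,
        "chimera_rate": 0.02,
        "class_pool_sizes": {"no_del": 80, "del3": 5, "del6": 11},
    },
    "demux": {"read_cap": 20000, "max_primer_mismatches": 0},
    "call": {"min_copies": 10, "max_edit": 2},
    "classify": {"frame_offset": 1},
    "stats": {},
    "selection": {
        "enabled": True,
        "tests": ["counting"],
        "consensus_k": None,
        "alpha": 0.05,
        "subset_size": 47,
        "n_reps": 100,
        "run_subsampling": False,
        "min_alleles": 8,
    },
    "recombination": {
        "enabled": True,
        "top": 50,
        "n_permutations": 200,
        "k": 2,
        "alpha": 0.05,
    },
    "network": {
        "enabled": True,
        "alpha": 0.29,
        "threshold": 1e-6,
        "bootstrap": 1000,
        "support_display_min": 70,
        "max_taxa": 96,
    },
}


def _merge_config(user: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if not user:
        return cfg

    def merge(base: dict, upd: dict, path: str):
        for key, val in upd.items():
            if key not in base:
                raise ConfigurationError(f"unknown config key {path}{key}")
            if isinstance(base[key], dict) and isinstance(val, dict) and key not in (
                "class_pool_sizes",
            ):
                merge(base[key], val, f"{path}{key}.")
            else:
                base[key] = val

    merge(cfg, user, "")
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: SeedSequence spawned from (global_seed, stage index)."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict | None = None) -> dict:
    """Run all enabled stages in fixed order; returns the machine-readable
    summary (also written to ``summary.json`` in the run directory)."""
    cfg = _merge_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    summary: dict = {"seed": cfg["seed"], "stages": []}

    def log_stage(name: str, files: list[Path]):
        entry = {
            "stage": name,
            "outputs": {str(f.name): _hash_file(f) for f in files if f.exists()},
        }
        log.append(entry)
        summary["stages"].append(name)

    # --- simulate -----------------------------------------------------------
    sim_cfg = cfg["simulate"]
    truth = None
    if sim_cfg["enabled"]:
        sc = SimulationConfig(
            seed=stage_seed(cfg["seed"], "simulate"),
            n_individuals=sim_cfg["n_individuals"],
            coverage=sim_cfg["coverage"],
            coverage_per_allele=sim_cfg["coverage_per_allele"],
            error_rate=sim_cfg["error_rate"],
            chimera_rate=sim_cfg["chimera_rate"],
            class_pool_sizes=dict(sim_cfg["class_pool_sizes"]),
        )
        truth, sheet, reads = simdata.simulate_study(sc)
        reads_path = out / "reads.fastq"
        tags_path = out / "tags.tsv"
        simdata.write_fastq(reads, reads_path)
        sheet.to_csv(tags_path, sep="\t", index=False)
        simdata.write_truth(truth, out / "truth")
        write_fasta({"reference": truth.reference}, out / "reference.fasta")
        cfg["paths"]["reads"] = str(reads_path)
        cfg["paths"]["tags"] = str(tags_path)
        cfg["paths"]["reference"] = str(out / "reference.fasta")
        primers = (sc.fwd_primer, sc.rev_primer)
        log_stage("simulate", [reads_path, tags_path])
    else:
        primers = (
            SimulationConfig().fwd_primer,
            SimulationConfig().rev_primer,
        )
    if not cfg["paths"]["reads"] or not cfg["paths"]["tags"]:
        raise ConfigurationError("reads and tags paths required when simulate disabled")

    # --- demux --------------------------------------------------------------
    sheet = read_tag_sheet(cfg["paths"]["tags"])
    reads = demux.read_fastq(cfg["paths"]["reads"])
    result = demux.demultiplex(
        reads, sheet, primers, max_primer_mismatches=cfg["demux"]["max_primer_mismatches"]
    )
    tables = demux.tables_from_demux(
        result,
        read_cap=cfg["demux"]["read_cap"],
        seed=stage_seed(cfg["seed"], "demux"),
    )
    tables_path = out / "variant_tables.tsv"
    demux.tables_to_frame(tables).to_csv(tables_path, sep="\t", index=False)
    summary["demux"] = {
        "n_assigned": result.n_assigned,
        "n_discarded": result.n_discarded,
    }
    log_stage("demux", [tables_path])

    # --- call ---------------------------------------------------------------
    calls, _logs = allele_calling.call_genotypes(
        tables,
        sheet,
        min_copies=cfg["call"]["min_copies"],
        max_edit=cfg["call"]["max_edit"],
        frame_offset=cfg["classify"]["frame_offset"],
    )
    calls_path = out / "genotypes.tsv"
    allele_calling.calls_to_frame(calls).to_csv(calls_path, sep="\t", index=False)
    log_stage("call", [calls_path])

    # --- classify -----------------------------------------------------------
    if truth is not None:
        reference = truth.reference
    elif cfg["paths"]["reference"]:
        reference = next(iter(read_fasta(cfg["paths"]["reference"]).values()))
    else:
        raise ConfigurationError("reference path required when simulate disabled")
    frame_offset = cfg["classify"]["frame_offset"]
    genotype_classes: dict[str, list] = {}
    allele_seqs: dict[str, str] = {}
    class_of: dict[str, str] = {}
    for ind, ind_calls in calls.items():
        classed = []
        for c in ind_calls:
            if c.expression == "cdna_only":
                continue  # genotype source is gDNA
            lc = length_classes.classify_allele(
                c.sequence, reference, c.allele_id, frame_offset
            )
            classed.append(lc)
            allele_seqs[c.sequence] = c.sequence
            class_of[c.sequence] = lc.length_class
        genotype_classes[ind] = classed
    per_ind, carrier, spectra = length_classes.class_census(genotype_classes)
    census_path = out / "class_census.tsv"
    per_ind.to_csv(census_path, sep="\t")
    summary["classes"] = {
        "carrier_fractions": carrier.to_dict(),
        "population_counts": {
            c: int(sum(1 for s in class_of.values() if s == c))
            for c in ("no_del", "del3", "del6", "other")
        },
    }
    log_stage("classify", [census_path])

    # --- stats --------------------------------------------------------------
    summaries, aggregate = popgen_stats.summarize_population(genotype_classes)
    by_class: dict[str, list[str]] = {}
    for seq, cls in class_of.items():
        by_class.setdefault(cls, []).append(seq)
    reports = {}
    for cls, seqs in sorted(by_class.items()):
        uniq = sorted(set(seqs))
        if len(uniq) >= 2 and cls != "other":
            rep = popgen_stats.diversity_report(uniq, cls, frame_offset)
            reports[cls] = {
                "n_nt_alleles": rep.n_nt_alleles,
                "n_aa_alleles": rep.n_aa_alleles,
                "pi": round(rep.pi, 3),
                "mean_aa_pdist": round(rep.mean_aa_pdist, 3),
                "aa_per_nt_ratio": rep.aa_per_nt_ratio,
            }
    stats_path = out / "population_summary.tsv"
    popgen_stats.summaries_to_frame(summaries).to_csv(stats_path, sep="\t", index=False)
    max_total = max(s.total_alleles for s in summaries)
    summary["stats"] = {
        "per_class": reports,
        "total_alleles_mean": aggregate["total"]["mean"],
        "total_alleles_sd": aggregate["total"]["sd"],
        "total_alleles_range": [aggregate["total"]["min"], aggregate["total"]["max"]],
        "min_locus_bound": popgen_stats.min_locus_bound(max_total),
    }
    log_stage("stats", [stats_path])

    # --- selection ----------------------------------------------------------
    sel_cfg = cfg["selection"]
    if sel_cfg["enabled"]:
        pss_block = {}
        for cls, seqs in sorted(by_class.items()):
            if cls == "other":
                continue
            orf = sorted(
                {
                    s
                    for s in set(seqs)
                    if allele_calling.orf_status(s, frame_offset) == "orf"
                }
            )
            if len(orf) < sel_cfg["min_alleles"]:
                pss_block[cls] = {"n_alleles": len(orf), "consensus_pss": None}
                continue
            aln = {f"{cls}-{i:04d}": s for i, s in enumerate(orf)}
            tree = selection_mod.build_tree(aln)
            results = {}
            for test in sel_cfg["tests"]:
                runner = {
                    "counting": selection_mod.counting_site_test,
                    "likelihood": selection_mod.likelihood_site_test,
                }[test]
                results[test] = runner(
                    aln, tree, alpha=sel_cfg["alpha"], frame_offset=frame_offset
                )
            pss = selection_mod.consensus_pss(results, k=sel_cfg["consensus_k"])
            pss_block[cls] = {
                "n_alleles": len(orf),
                "consensus_pss": sorted(pss),
                "n_pss": len(pss),
            }
        summary["selection"] = pss_block
        sel_path = out / "selection.json"
        sel_path.write_text(json.dumps(pss_block, indent=2))
        log_stage("selection", [sel_path])

    # --- recombination ------------------------------------------------------
    rec_cfg = cfg["recombination"]
    if rec_cfg["enabled"]:
        carriers: dict[str, int] = {}
        for ind, ind_calls in calls.items():
            for c in ind_calls:
                if c.expression != "cdna_only":
                    carriers[c.sequence] = carriers.get(c.sequence, 0) + 1
        aln_all: dict[str, str] = {}
        freq: dict[str, int] = {}
        for i, seq in enumerate(sorted(class_of)):
            name = f"a{i:04d}"
            aln_all[name] = seq
            freq[name] = carriers.get(seq, 0)
        # scans need equal-length input: use the dominant length class
        lens = [len(s) for s in aln_all.values()]
        main_len = max(set(lens), key=lens.count)
        aln_rec = {n: s for n, s in aln_all.items() if len(s) == main_len}
        cons, reported = recombination.scan_triplets(
            aln_rec,
            frequencies=freq,
            top=rec_cfg["top"],
            n_permutations=rec_cfg["n_permutations"],
            k=rec_cfg["k"],
            alpha=rec_cfg["alpha"],
            seed=stage_seed(cfg["seed"], "recombination"),
        )
        summary["recombination"] = {
            "n_consensus": len(cons),
            "n_subthreshold": len(reported),
        }
        rec_path = out / "recombination.json"
        rec_path.write_text(
            json.dumps(
                [
                    {
                        "recombinant": e.recombinant_id,
                        "parents": list(e.parent_ids),
                        "breakpoint": e.best_breakpoint,
                        "p_values": {k_: (None if v is None or (isinstance(v, float) and np.isnan(v)) else v) for k_, v in e.p_values.items()},
                        "consensus": e.consensus,
                    }
                    for e in cons + reported
                ],
                indent=2,
            )
        )
        log_stage("recombination", [rec_path])

    # --- network ------------------------------------------------------------
    net_cfg = cfg["network"]
    if net_cfg["enabled"]:
        uniq = sorted(set(class_of))
        names = [f"a{i:04d}" for i in range(len(uniq))]
        lens = [len(s) for s in uniq]
        main_len = max(set(lens), key=lens.count)
        aln_net = {
            n: s for n, s in zip(names, uniq) if len(s) == main_len
        }
        if len(aln_net) > net_cfg["max_taxa"]:
            aln_net = dict(sorted(aln_net.items())[: net_cfg["max_taxa"]])
        net = network.neighbornet(
            aln_net, alpha=net_cfg["alpha"], threshold=net_cfg["threshold"]
        )
        if net_cfg["bootstrap"] > 0:
            network.bootstrap_supports(
                aln_net,
                net,
                n_replicates=net_cfg["bootstrap"],
                support_display_min=net_cfg["support_display_min"],
                seed=stage_seed(cfg["seed"], "network"),
                alpha=net_cfg["alpha"],
                threshold=net_cfg["threshold"],
            )
        net_path = out / "network.nex"
        network.write_nexus(net, net_path, net_cfg["support_display_min"])
        summary["network"] = {
            "n_taxa": len(net.taxa),
            "n_splits": len(net.splits),
            "file": str(net_path),
        }
        log_stage("network", [net_path])

    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
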