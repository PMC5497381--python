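"""Shared fixtures: small deterministic simulated studies."""

from __future__ import annotations

import pytest

from mhcamp import allele_calling, demux, simdata


@pytest.fixture(scope="session")
def small_cfg():
    return simdata.SimulationConfig(
        seed=7,
        n_individuals=4,
        coverage=120,
        coverage_per_allele=True,
        error_rate=0.0,
        chimera_rate=0.0,
        stop_codon_fraction=0.0,
        class_pool_sizes={"no_del": 12, "del3": 3, "del6": 5},
        copy_number_range={"no_del": (4, 8), "del3": (1, 2), "del6": (1, 3)},
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    truth, sheet, reads = simdata.simulate_study(small_cfg)
    return small_cfg, truth, sheet, reads


@pytest.fixture(scope="session")
def small_calls(small_study):
    cfg, truth, sheet, reads = small_study
    result = demux.demultiplex(reads, sheet, (cfg.fwd_primer, cfg.rev_primer))
    tables = demux.tables_from_demux(result)
    calls, logs = allele_calling.call_genotypes(tables, sheet)
    return truth, calls, logs


@pytest.fixture(scope="session")
def default_pool():
    return simdata.generate_allele_pool(simdata.SimulationConfig(seed=5))
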