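"""Shared fixtures: synthetic runs reused across test modules.

The heavier end-to-end simulations are session-scoped so the mapping work
is paid once; every fixture is fully seeded and deterministic.
"""

from __future__ import annotations

import pytest

from covloss import alignment, coverage
from covloss.pipeline import PipelineConfig, run_pipeline
from covloss.synthetic import SimConfig, simulate_reads, simulate_truth_set

# Study conditions: 200 families, 25% lost, 0.10 subs/site/branch,
# 100 bp PE reads at 15x with 1% error (the calibrated operating regime).
DEFAULT_SIM = SimConfig(
    n_families=200,
    loss_fraction=0.25,
    divergence_per_branch=0.10,
    coverage=15.0,
    seq_error_rate=0.01,
    rng_seed=1,
)

ZERO_DIV_SIM = SimConfig(
    n_families=60,
    loss_fraction=0.25,
    divergence_per_branch=0.0,
    coverage=15.0,
    seq_error_rate=0.0,
    rng_seed=2,
)


@pytest.fixture(scope="session")
def zero_div_data():
    """Simulation at divergence 0 with error-free reads, plus mapped hits."""
    cds_sets, genome, truth = simulate_truth_set(ZERO_DIV_SIM)
    reads1, reads2 = simulate_reads(genome, ZERO_DIV_SIM)
    reads = reads1 + reads2
    best = alignment.best_hit_filter(
        alignment.map_reads_to_cds(reads, cds_sets["ath"])
    )
    return {
        "cfg": ZERO_DIV_SIM,
        "cds_sets": cds_sets,
        "genome": genome,
        "truth": truth,
        "reads": reads,
        "best_hits_ath": best,
    }


@pytest.fixture(scope="session")
def zero_div_report(tmp_path_factory):
    """Full pipeline on the zero-divergence simulation."""
    out = tmp_path_factory.mktemp("zero_div_pipeline")
    return run_pipeline(PipelineConfig(sim=ZERO_DIV_SIM), out)


@pytest.fixture(scope="session")
def default_report(tmp_path_factory):
    """Full pipeline at the default study conditions (ground truth known)."""
    out = tmp_path_factory.mktemp("default_pipeline")
    return run_pipeline(PipelineConfig(sim=DEFAULT_SIM), out)


@pytest.fixture(scope="session")
def diverged_small():
    """Small two-species simulation at 0.06 subs/site/branch, error-free.

    Used for oracle comparisons (Smith-Waterman best-subject agreement) and
    RBB parameter-recovery checks at realistic divergence.
    """
    cfg = SimConfig(
        n_families=60,
        loss_fraction=0.0,
        divergence_per_branch=0.06,
        seq_error_rate=0.0,
        coverage=15.0,
        species=("ath", "osa"),
        monocot_species=("osa",),
        rng_seed=3,
    )
    cds_sets, genome, truth = simulate_truth_set(cfg)
    reads1, reads2 = simulate_reads(genome, cfg)
    return {
        "cfg": cfg,
        "cds_sets": cds_sets,
        "genome": genome,
        "truth": truth,
        "reads": reads1 + reads2,
    }
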