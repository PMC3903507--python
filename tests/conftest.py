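"""Shared fixtures: synthetic study runs are expensive (each folds a few
hundred 250-nt windows), so full-pipeline results are session-scoped and
shared between the pipeline tests and the acceptance suite."""

from __future__ import annotations

import pytest

from mircot.pipeline import run_from_raw_reads
from mircot.synthetic_data import (
    SyntheticConfig,
    evaluate_against_truth,
    generate_genome,
    simulate_dicer_reads,
)

RECOVERY_SEEDS = (11, 12, 13, 14, 15)


def scaled_config(seed: int) -> SyntheticConfig:
    """Study conditions at reduced problem size (8 hairpins on 2 x 40 kb
    chromosomes) so a run folds in well under a minute."""
    return SyntheticConfig(seed=seed, n_hairpins=8, chrom_length=40_000)


def run_study(cfg: SyntheticConfig):
    genome, truth = generate_genome(cfg)
    reads = simulate_dicer_reads(genome, truth, cfg)
    result, collapsed, tally = run_from_raw_reads(genome, reads, cfg.adaptor)
    evaluation = evaluate_against_truth(result.accepted, truth)
    return {
        "config": cfg,
        "genome": genome,
        "truth": truth,
        "reads": reads,
        "result": result,
        "collapsed": collapsed,
        "tally": tally,
        "evaluation": evaluation,
    }


@pytest.fixture(scope="session")
def study_runs():
    """Full pipeline runs on five independent seeds (scaled problem size)."""
    return [run_study(scaled_config(seed)) for seed in RECOVERY_SEEDS]


@pytest.fixture(scope="session")
def study_run(study_runs):
    return study_runs[0]
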