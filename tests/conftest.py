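"""Shared fixtures: one default-scale synthetic study, computed once.

The ``study`` fixture runs the full discovery analysis (generation, block
building, filtering, normalisation, age scan, interaction scan, a-DMR
calling, blood-trait EWAS, replication) at the generator's default study
conditions and is shared by the calibration and acceptance tests.  The
``demo_runs`` fixture runs the end-to-end pipeline twice at a small scale
for determinism checks.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from agewas import cells, dmr, ewas, regions, simdata
from agewas.pipeline import PipelineConfig, run_pipeline
from agewas.simdata import SimConfig

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")

STUDY_SEED = 0


@pytest.fixture(scope="session")
def study():
    """Full discovery + replication analysis at default study conditions."""
    cfg = SimConfig(seed=STUDY_SEED)
    genome = simdata.generate_genome(cfg)
    blocks = regions.build_ld_blocks(genome.genetic_map)
    gblocks, snps, block_stats = regions.assign_snps(
        blocks, genome.gwas_snps, genome.chrom_sizes
    )
    windows, _ = regions.windows_in_blocks(gblocks, blacklist=genome.blacklist)
    cohort = simdata.generate_cohort(cfg, gblocks)
    truth = simdata.generate_truth(cfg, windows)
    matrix = simdata.generate_methylome(cfg, cohort, truth, windows, genome)
    keep = cells.window_nonzero_filter(matrix, 0.9)
    normed, flagged = ewas.normalise(matrix.loc[keep])
    results = ewas.run_ewas(normed, windows, cohort.samples, cohort.genotypes)
    threshold = ewas.bonferroni_threshold(len(results))
    admrs, members = dmr.call_admrs(results, threshold, genome.cpg_positions)
    interaction = ewas.run_interaction(normed, windows, cohort.samples, cohort.genotypes)
    blood = pd.DataFrame(index=keep)
    for trait in simdata.BLOOD_TRAITS:
        blood[trait] = cells.mz_discordance_test(matrix.loc[keep], cohort.samples, trait)["p"]
    # replication: independent cohort, reduced covariates, significant windows
    sig = results[results["p"] < threshold]
    rep_cohort = simdata.generate_cohort(cfg, gblocks, seed=cfg.seed + 10007)
    sub_windows = windows[windows["window_id"].isin(sig["window_id"])].reset_index(drop=True)
    sub_truth = truth[truth["window_id"].isin(sub_windows["window_id"])]
    rep_matrix = simdata.generate_methylome(
        cfg, rep_cohort, sub_truth, sub_windows, genome, seed=cfg.seed + 10008
    )
    rep_normed, _ = ewas.normalise(rep_matrix)
    rep_results = ewas.run_ewas(rep_normed, sub_windows, rep_cohort.samples, covariates="reduced")
    merged = results.merge(truth, on="window_id")
    return dict(
        config=cfg, genome=genome, blocks=gblocks, snps=snps, block_stats=block_stats,
        windows=windows, cohort=cohort, truth=truth, matrix=matrix, keep=keep,
        normed=normed, results=results, merged=merged, threshold=threshold,
        admrs=admrs, members=members, interaction=interaction, blood=blood,
        sig=sig, rep_results=rep_results,
    )


def _demo_config(outdir, seed=11) -> PipelineConfig:
    sim = SimConfig(
        seed=seed, n_chromosomes=2, chrom_length=60_000, n_families=50,
        n_age_windows=12, n_geno_windows=6, n_interaction_windows=5,
        n_cell_windows=6, age_slope_range=(0.04, 0.06),
    )
    return PipelineConfig(sim=sim, outdir=str(outdir), n_permutations=200)


@pytest.fixture(scope="session")
def demo_runs(tmp_path_factory):
    """The small end-to-end pipeline run twice with one seed."""
    d1 = tmp_path_factory.mktemp("demo_run1")
    d2 = tmp_path_factory.mktemp("demo_run2")
    s1 = run_pipeline(_demo_config(d1), "all")
    s2 = run_pipeline(_demo_config(d2), "all")
    return dict(summary1=s1, summary2=s2, dir1=d1, dir2=d2)
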