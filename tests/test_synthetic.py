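"""Synthetic-cohort generator: determinism, structure, planted effects."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from agewas import regions, simdata
from agewas.simdata import SimConfig

SMALL = dict(n_chromosomes=2, chrom_length=40_000, n_families=40,
             n_age_windows=4, n_geno_windows=2, n_interaction_windows=2,
             n_cell_windows=2)


def small_cfg(**kw):
    return SimConfig(**{**SMALL, **kw})


def build(cfg):
    genome = simdata.generate_genome(cfg)
    blocks = regions.build_ld_blocks(genome.genetic_map)
    gblocks, _, _ = regions.assign_snps(blocks, genome.gwas_snps, genome.chrom_sizes)
    windows, _ = regions.windows_in_blocks(gblocks, blacklist=genome.blacklist)
    cohort = simdata.generate_cohort(cfg, gblocks)
    truth = simdata.generate_truth(cfg, windows)
    matrix = simdata.generate_methylome(cfg, cohort, truth, windows, genome)
    return genome, gblocks, windows, cohort, truth, matrix


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(window_slide=600), dict(mz_fraction=1.5), dict(n_families=-1),
        dict(age_range=(60.0, 30.0)), dict(chrom_length=1000),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**{**SMALL, **bad})


class TestDeterminism:
    def test_same_seed_gives_identical_outputs(self):
        a = build(small_cfg(seed=42))
        b = build(small_cfg(seed=42))
        pd.testing.assert_frame_equal(a[0].genetic_map, b[0].genetic_map)
        pd.testing.assert_frame_equal(a[0].gwas_snps, b[0].gwas_snps)
        pd.testing.assert_frame_equal(a[3].samples, b[3].samples)
        pd.testing.assert_frame_equal(a[5], b[5])

    def test_different_seeds_differ(self):
        a = build(small_cfg(seed=1))[5]
        b = build(small_cfg(seed=2))[5]
        assert not a.equals(b)


class TestGenome:
    def test_zero_hotspot_rate_gives_one_block_per_chromosome(self):
        cfg = small_cfg(hotspot_rate_per_mb=0.0)
        genome = simdata.generate_genome(cfg)
        blocks = regions.build_ld_blocks(genome.genetic_map)
        assert len(blocks) == cfg.n_chromosomes

    def test_gwas_pvalues_straddle_catalogue_threshold(self):
        genome = simdata.generate_genome(small_cfg(seed=5))
        p = genome.gwas_snps["p"]
        assert (p < 1e-7).any() and (p >= 1e-7).any()

    def test_chromatin_states_partition_each_chromosome(self):
        genome = simdata.generate_genome(small_cfg(seed=5))
        for chrom, grp in genome.chromatin_states.groupby("chrom"):
            grp = grp.sort_values("start")
            assert grp["start"].iloc[0] == 0
            assert (grp["start"].iloc[1:].to_numpy() == grp["end"].iloc[:-1].to_numpy()).all()
            assert grp["end"].iloc[-1] == genome.chrom_sizes[chrom]

    def test_block_count_matches_poisson_hotspot_expectation(self):
        # hotspots hit each map interval independently with prob 1-exp(-lam*l);
        # expected runs of cold intervals = q + (m-1) p q, q = exp(-lam*l)
        lam = 2.0 / 1e6  # 2 hotspots per Mb
        cfg = small_cfg(n_chromosomes=1, chrom_length=1_000_000,
                        map_interval=5_000, hotspot_rate_per_mb=2.0)
        counts = []
        for seed in range(200):
            genome = simdata.generate_genome(dataclasses.replace(cfg, seed=seed))
            gm = genome.genetic_map
            counts.append(len(regions.build_ld_blocks(gm, max_size=10**9)))
        m = 1_000_000 // 5_000
        q = np.exp(-lam * 5_000)
        expected = q + (m - 1) * (1 - q) * q
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se + 0.05


class TestCohort:
    def test_all_mz_pairs_share_genotypes(self):
        _, gblocks, _, cohort, _, _ = build(small_cfg(mz_fraction=1.0, singleton_fraction=0.0))
        first = cohort.samples.drop_duplicates("individual_id")
        for pid, grp in first.groupby("pair_id"):
            g = cohort.genotypes.loc[grp["sample_id"]]
            assert (g.nunique() == 1).all()

    def test_dz_cotwins_share_half_their_alleles(self):
        cfg = small_cfg(mz_fraction=0.0, singleton_fraction=0.0, n_families=300,
                        longitudinal_fraction=0.0)
        _, gblocks, _, cohort, _, _ = build(cfg)
        sam = cohort.samples
        corrs = []
        for block in cohort.genotypes.columns:
            g = cohort.genotypes[block]
            t1, t2 = [], []
            for pid, grp in sam.groupby("pair_id"):
                ids = grp["sample_id"].tolist()
                t1.append(g[ids[0]])
                t2.append(g[ids[1]])
            corrs.append(np.corrcoef(t1, t2)[0, 1])
        assert np.mean(corrs) == pytest.approx(0.5, abs=0.06)

    def test_no_longitudinal_means_one_sample_per_individual(self):
        _, _, _, cohort, _, _ = build(small_cfg(longitudinal_fraction=0.0))
        assert cohort.samples["individual_id"].is_unique

    def test_longitudinal_repeats_reuse_identifiers_with_age_gap(self):
        cfg = small_cfg(longitudinal_fraction=1.0)
        _, _, _, cohort, _, _ = build(cfg)
        per_ind = cohort.samples.groupby("individual_id")
        assert (per_ind.size() == 2).all()
        gaps = per_ind["age"].agg(lambda a: a.max() - a.min())
        assert np.allclose(gaps, cfg.longitudinal_gap)

    def test_cell_fractions_are_proportions(self):
        _, _, _, cohort, _, _ = build(small_cfg())
        cf = cohort.samples[["lymphocyte", "monocyte", "neutrophil", "eosinophil"]]
        assert ((cf >= 0) & (cf <= 1)).all().all()
        assert (cf.sum(axis=1) < 1).all()  # an unmodelled remainder exists


class TestMethylome:
    def test_noise_free_null_window_equals_cpg_baseline(self):
        cfg = small_cfg(noise_sd=0.0, family_sd=0.0, pair_sd=0.0, depth_sdlog=0.0,
                        smoking_effect=0.0, batch_effect=0.0,
                        low_coverage_window_fraction=0.0,
                        n_age_windows=0, n_geno_windows=0,
                        n_interaction_windows=0, n_cell_windows=0)
        genome, gblocks, windows, cohort, truth, matrix = build(cfg)
        assert (truth["effect_class"] == "null").all()
        arr = matrix.to_numpy()
        assert np.allclose(arr, arr[:, :1])  # constant across samples
        win = windows.set_index("window_id")
        for wid in matrix.index[:20]:
            chrom, span = wid.split(":")
            pos = genome.cpg_positions.query("chrom == @chrom")["pos"].to_numpy()
            s, e = win.loc[wid, ["start", "end"]]
            ncpg = int(((pos >= s) & (pos < e)).sum())
            assert matrix.loc[wid].iloc[0] == pytest.approx(cfg.baseline_per_cpg * ncpg)

    def test_truth_covers_all_windows_or_rejects(self):
        genome, gblocks, windows, cohort, truth, _ = build(small_cfg())
        with pytest.raises(ValueError, match="cover"):
            simdata.generate_methylome(small_cfg(), cohort, truth.iloc[:5], windows, genome)

    def test_ols_recovers_planted_age_slope(self):
        cfg = small_cfg(n_families=150)
        genome, gblocks, windows, cohort, truth, matrix = build(cfg)
        aged = truth[truth["effect_class"] == "age"]
        ages = cohort.samples["age"].to_numpy()
        for _, row in aged.iterrows():
            y = matrix.loc[row["window_id"]].to_numpy()
            res = st.linregress(ages, y)
            assert abs(res.slope - row["planted_age_slope"]) < 2.5 * res.stderr

    def test_cell_windows_track_their_driving_trait(self):
        cfg = small_cfg(n_families=150, n_cell_windows=4)
        genome, gblocks, windows, cohort, truth, matrix = build(cfg)
        ages = cohort.samples["age"].to_numpy()
        def partial_r(y, t):
            ry = y - np.polyval(np.polyfit(ages, y, 1), ages)
            rt = t - np.polyval(np.polyfit(ages, t, 1), ages)
            return abs(np.corrcoef(ry, rt)[0, 1])
        cell = truth[truth["effect_class"] == "cell"]
        nulls = truth[truth["effect_class"] == "null"].head(30)
        for _, row in cell.iterrows():
            t = cohort.samples[row["driving_cell_type"]].to_numpy()
            r_cell = partial_r(matrix.loc[row["window_id"]].to_numpy(), t)
            r_null = np.median([
                partial_r(matrix.loc[w].to_numpy(), t) for w in nulls["window_id"]
            ])
            assert r_cell > r_null

    def test_low_coverage_windows_fail_the_nonzero_filter(self):
        from agewas.cells import window_nonzero_filter
        cfg = small_cfg(low_coverage_window_fraction=0.2, low_coverage_zero_rate=0.5)
        *_, matrix = build(cfg)
        keep = window_nonzero_filter(matrix, 0.9)
        assert len(keep) < len(matrix)


class TestTruth:
    def test_exactly_one_class_per_window_and_consistent_slopes(self):
        _, _, windows, _, truth, _ = build(small_cfg())
        assert truth["window_id"].is_unique
        assert set(truth["effect_class"]) <= {"null", "age", "genotype", "interaction", "cell"}
        nulls = truth[truth["effect_class"] == "null"]
        assert (nulls["planted_age_slope"] == 0).all()
        assert (nulls["planted_geno_beta"] == 0).all()
        aged = truth[truth["effect_class"] == "age"]
        assert (aged["planted_age_slope"] != 0).all()
        assert (aged["planted_geno_beta"] == 0).all()
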