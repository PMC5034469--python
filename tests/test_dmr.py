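"""a-DMR merging, summaries, concordance and probe validation."""

import numpy as np
import pandas as pd
import pytest

from agewas import dmr

THRESH = 1e-6


def win(chrom, start, end, beta, p, wid=None, block="B0"):
    return dict(chrom=chrom, start=start, end=end,
                window_id=wid or f"{chrom}:{start}-{end}",
                block_id=block, beta_age=beta, p=p)


def results(*rows):
    return pd.DataFrame(list(rows))


class TestCallAdmrs:
    def test_overlapping_same_sign_windows_merge(self):
        res = results(win("chr1", 0, 500, 1.0, 1e-9), win("chr1", 250, 750, 0.5, 1e-8))
        admrs, members = dmr.call_admrs(res, THRESH)
        assert len(admrs) == 1
        a = admrs.iloc[0]
        assert (a["start"], a["end"], a["direction"], a["n_windows"]) == (0, 750, "hyper", 2)
        assert a["peak_p"] == pytest.approx(1e-9)

    def test_gap_between_windows_splits_regions(self):
        res = results(win("chr1", 0, 500, 1.0, 1e-9), win("chr1", 750, 1250, 1.0, 1e-9))
        admrs, _ = dmr.call_admrs(res, THRESH)
        assert len(admrs) == 2

    def test_book_ended_windows_merge(self):
        res = results(win("chr1", 0, 500, 1.0, 1e-9), win("chr1", 500, 1000, 1.0, 1e-9))
        admrs, _ = dmr.call_admrs(res, THRESH)
        assert len(admrs) == 1 and admrs.iloc[0]["end"] == 1000

    def test_sign_split_produces_separate_regions(self):
        res = results(win("chr1", 0, 500, 1.0, 1e-9), win("chr1", 250, 750, -0.5, 1e-8))
        admrs, _ = dmr.call_admrs(res, THRESH)
        assert len(admrs) == 2
        assert set(admrs["direction"]) == {"hyper", "hypo"}

    def test_non_significant_windows_ignored(self):
        res = results(win("chr1", 0, 500, 1.0, 1e-9), win("chr1", 250, 750, 1.0, 0.5))
        admrs, members = dmr.call_admrs(res, THRESH)
        assert len(admrs) == 1 and admrs.iloc[0]["end"] == 500
        assert len(members) == 1

    def test_merging_is_order_independent(self):
        rows = [win("chr1", 0, 500, 1.0, 1e-9), win("chr1", 250, 750, 0.5, 1e-8),
                win("chr1", 1500, 2000, -1.0, 1e-10), win("chr2", 0, 500, 1.0, 1e-9)]
        base, _ = dmr.call_admrs(results(*rows), THRESH)
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = results(*[rows[i] for i in rng.permutation(len(rows))])
            again, _ = dmr.call_admrs(shuffled, THRESH)
            pd.testing.assert_frame_equal(base, again)

    def test_cpg_counting_inside_regions(self):
        cpgs = pd.DataFrame({"chrom": ["chr1"] * 4, "pos": [10, 499, 500, 760]})
        res = results(win("chr1", 0, 500, 1.0, 1e-9), win("chr1", 250, 750, 1.0, 1e-9))
        admrs, _ = dmr.call_admrs(res, THRESH, cpgs)
        assert admrs.iloc[0]["n_cpgs"] == 3  # 760 outside [0, 750)

    def test_empty_input_gives_empty_output(self):
        admrs, members = dmr.call_admrs(results(), THRESH)
        assert len(admrs) == 0 and len(members) == 0

    def test_failed_fits_never_significant(self):
        row = win("chr1", 0, 500, np.nan, np.nan)
        admrs, _ = dmr.call_admrs(results(row), THRESH)
        assert len(admrs) == 0


class TestSummarise:
    def test_direction_split(self):
        admrs = pd.DataFrame({
            "chrom": "chr1", "start": [0, 1000, 2000, 3000],
            "end": [500, 1500, 2500, 3500],
            "direction": ["hyper", "hyper", "hypo", "hypo"],
            "n_cpgs": [3, 2, 1, 4],
        })
        s = dmr.summarise_admrs(admrs)
        assert s["frac_hyper"] == 0.5 and s["frac_hypo"] == 0.5
        assert s["total_cpgs"] == 10

    def test_mean_size_in_kb(self):
        admrs = pd.DataFrame({"chrom": "chr1", "start": [0, 1000],
                              "end": [500, 1800], "direction": ["hyper", "hypo"],
                              "n_cpgs": [0, 0]})
        assert dmr.summarise_admrs(admrs)["mean_size_kb"] == pytest.approx(0.65)

    def test_empty_set_gives_zeros(self):
        s = dmr.summarise_admrs(pd.DataFrame(columns=["chrom", "start", "end",
                                                      "direction", "n_cpgs"]))
        assert s["n_admrs"] == 0 and s["mean_size_kb"] == 0.0


def conc_frames(n=115, n_same=111, n_nom=97, n_bonf=70):
    disc = pd.DataFrame({
        "window_id": [f"w{i}" for i in range(n)],
        "beta_age": 1.0, "p": 1e-10,
    })
    beta, p = [], []
    for i in range(n):
        if i < n_bonf:
            beta.append(1.0); p.append(1e-9)
        elif i < n_nom:
            beta.append(1.0); p.append(0.01)
        elif i < n_same:
            beta.append(1.0); p.append(0.5)
        else:
            beta.append(-1.0); p.append(0.5)
    rep = pd.DataFrame({"window_id": disc["window_id"], "beta_age": beta, "p": p})
    return disc, rep


class TestConcordance:
    def test_tier_counting_matches_hand_construction(self):
        disc, rep = conc_frames()
        out = dmr.concordance(disc, rep, pd.DataFrame(columns=["admr_id", "window_id"]),
                              threshold=1.85e-8)
        assert out["n_discovery_windows"] == 115
        assert out["n_same_direction"] == 111
        assert out["frac_same_direction"] == pytest.approx(111 / 115)
        assert round(100 * out["frac_same_direction"], 1) == 96.5
        assert out["n_nominal"] == 97 and out["n_bonferroni"] == 70

    def test_tiers_are_nested(self):
        disc, rep = conc_frames(40, 30, 20, 5)
        out = dmr.concordance(disc, rep, pd.DataFrame(columns=["admr_id", "window_id"]),
                              threshold=1e-8)
        assert (out["n_bonferroni"] <= out["n_nominal"]
                <= out["n_same_direction"] <= out["n_discovery_windows"])

    def test_fully_concordant_set_scores_100_percent(self):
        disc, rep = conc_frames(10, 10, 10, 10)
        out = dmr.concordance(disc, rep, pd.DataFrame(columns=["admr_id", "window_id"]),
                              threshold=1e-8)
        assert out["frac_same_direction"] == out["frac_nominal"] == out["frac_bonferroni"] == 1.0

    def test_missing_replication_window_stays_in_denominator(self):
        disc, rep = conc_frames(10, 10, 10, 10)
        out = dmr.concordance(disc, rep.iloc[:-1], pd.DataFrame(columns=["admr_id", "window_id"]),
                              threshold=1e-8)
        assert out["n_missing"] == 1 and out["n_discovery_windows"] == 10
        assert out["n_same_direction"] == 9

    def test_dmr_level_qualifies_when_any_window_does(self):
        disc, rep = conc_frames(4, 4, 2, 1)
        members = pd.DataFrame({"admr_id": ["d1", "d1", "d2", "d2"],
                                "window_id": ["w0", "w1", "w2", "w3"]})
        out = dmr.concordance(disc, rep, members, threshold=1e-8)
        assert out["n_admrs"] == 2
        assert out["n_admr_bonferroni"] == 1      # only d1 holds w0
        assert out["n_admr_nominal"] == 1         # w0, w1 both in d1
        assert out["n_admr_same_direction"] == 2
        assert out["n_admr_bonferroni"] <= out["n_admr_nominal"] <= out["n_admr_same_direction"]

    def test_empty_discovery_set_rejected(self):
        with pytest.raises(ValueError):
            dmr.concordance(pd.DataFrame(columns=["window_id", "beta_age", "p"]),
                            pd.DataFrame(columns=["window_id", "beta_age", "p"]),
                            pd.DataFrame(columns=["admr_id", "window_id"]), 1e-8)


class TestProbeValidation:
    admrs = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"], "start": [0, 1000, 0],
        "end": [500, 1500, 500], "admr_id": ["d1", "d2", "d3"],
        "direction": ["hyper", "hypo", "hyper"],
    })

    def probes(self, *rows):
        return pd.DataFrame(list(rows), columns=["chrom", "pos", "beta_age", "p"])

    def test_no_probe_means_no_coverage(self):
        out = dmr.probe_validation(self.admrs, self.probes(("chr1", 100, 1.0, 1e-9)))
        assert out.set_index("admr_id").loc["d3", "status"] == "no_coverage"

    def test_strict_validation_requires_direction_and_p(self):
        out = dmr.probe_validation(self.admrs, self.probes(("chr1", 100, 0.5, 1e-9)))
        assert out.set_index("admr_id").loc["d1", "status"] == "validated_strict"

    def test_opposite_direction_probe_does_not_validate(self):
        out = dmr.probe_validation(self.admrs, self.probes(("chr1", 100, -0.5, 1e-9)))
        assert out.set_index("admr_id").loc["d1", "status"] == "not_validated"

    def test_nominal_tier(self):
        out = dmr.probe_validation(self.admrs, self.probes(("chr1", 1200, -0.5, 0.01)))
        assert out.set_index("admr_id").loc["d2", "status"] == "validated_nominal"

    def test_probe_at_end_coordinate_outside_half_open_region(self):
        out = dmr.probe_validation(self.admrs, self.probes(("chr1", 500, 1.0, 1e-9)))
        assert out.set_index("admr_id").loc["d1", "status"] == "no_coverage"


class TestOnStudy:
    def test_planted_age_regions_recovered_with_matching_direction(self, study):
        """At default effects, called a-DMRs cover planted age windows."""
        truth = study["truth"].set_index("window_id")
        got = study["members"].copy()
        classes = truth.loc[got["window_id"], "effect_class"]
        # no cell- or genotype-driven window is ever called
        assert not (classes == "cell").any()
        assert not (classes == "genotype").any()
        # direction matches the planted slope sign for every member age window
        admr_dir = study["admrs"].set_index("admr_id")["direction"]
        for _, row in got.iterrows():
            if truth.loc[row["window_id"], "effect_class"] == "age":
                planted = truth.loc[row["window_id"], "planted_age_slope"]
                want = "hyper" if planted > 0 else "hypo"
                assert admr_dir[row["admr_id"]] == want
        # recall: the large majority of planted age windows are covered
        age_ids = set(truth.index[truth["effect_class"] == "age"])
        covered = len(age_ids & set(got["window_id"])) / len(age_ids)
        assert covered > 0.9

    def test_recall_is_one_at_large_effect(self):
        import dataclasses
        from agewas import cells, ewas, regions, simdata
        cfg = simdata.SimConfig(
            seed=4, n_chromosomes=2, chrom_length=60_000, n_families=150,
            n_age_windows=20, n_geno_windows=0, n_interaction_windows=0,
            n_cell_windows=0, age_slope_range=(0.04, 0.05),
        )
        genome = simdata.generate_genome(cfg)
        blocks = regions.build_ld_blocks(genome.genetic_map)
        gblocks, _, _ = regions.assign_snps(blocks, genome.gwas_snps, genome.chrom_sizes)
        windows, _ = regions.windows_in_blocks(gblocks, blacklist=genome.blacklist)
        cohort = simdata.generate_cohort(cfg, gblocks)
        truth = simdata.generate_truth(cfg, windows)
        matrix = simdata.generate_methylome(cfg, cohort, truth, windows, genome)
        keep = cells.window_nonzero_filter(matrix, 0.9)
        normed, _ = ewas.normalise(matrix.loc[keep])
        res = ewas.run_ewas(normed, windows, cohort.samples, cohort.genotypes)
        thr = ewas.bonferroni_threshold(len(res))
        admrs, members = dmr.call_admrs(res, thr)
        # recall among analysed windows (a window that drew the random
        # low-coverage label is removed by the filter before any testing)
        planted = truth[truth["effect_class"] == "age"]
        analysed = planted[planted["window_id"].isin(keep)]
        called = set(members["window_id"])
        assert len(analysed) >= 15
        recall = analysed["window_id"].isin(called).mean()
        assert recall == 1.0
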