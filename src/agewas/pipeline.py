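"""End-to-end orchestration of the synthetic-cohort age-EWAS.

Stage order (the `all` mode): simulate -> blocks -> ewas -> dmr ->
interaction -> cells -> enrichment -> replication -> summary.  Each stage
reads its inputs from the run directory and writes its outputs there, so
stages can also be run one at a time from the CLI; a JSON summary collates
the headline numbers at the end.  All randomness derives from the single
config seed, so a re-run of any stage on unchanged inputs reproduces its
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cells as cells_mod
from . import dmr as dmr_mod
from . import enrich as enrich_mod
from . import ewas as ewas_mod
from . import regions as regions_mod
from . import simdata
from .io import config_hash, read_bed, read_table, write_bed, write_table

__all__ = ["PipelineConfig", "Run", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One config drives every stage; see docs/methods.md for the knobs."""

    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    outdir: str = "results/run"
    alpha: float = 0.05
    overlap_fraction: float = 0.1
    rate_threshold: float = 10.0
    max_block_size: int = 10_000_000
    n_permutations: int = 1000
    normalisation: str = "zscore"
    nonzero_fraction: float = 0.9
    replication_seed_offset: int = 10007

    @property
    def seed(self) -> int:
        return self.sim.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim.get("age_range"), list):
            sim["age_range"] = tuple(sim["age_range"])
        for k in ("age_slope_range", "geno_beta_range", "interaction_slope_range",
                  "cell_beta_range"):
            if isinstance(sim.get(k), list):
                sim[k] = tuple(sim[k])
        return cls(sim=simdata.SimConfig(**sim), **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def content_hash(self) -> str:
        """Config hash over analysis parameters only (paths excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        return config_hash(d)

    def header(self, stage: str) -> dict:
        return {
            "tool": f"agewas {__version__}",
            "stage": stage,
            "seed": self.seed,
            "config": self.content_hash(),
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None  # NaN/inf are not valid JSON
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


class Run:
    """A run directory with lazily-loaded stage inputs."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.dir = Path(config.outdir)

    # ------------------------------------------------------------------ io
    def path(self, name: str) -> Path:
        return self.dir / name

    def _require(self, name: str) -> Path:
        p = self.path(name)
        if not p.exists():
            raise FileNotFoundError(f"missing pipeline input: {p} (run earlier stages first)")
        return p

    # --------------------------------------------------------------- stages
    def simulate(self) -> dict:
        """Generate the toy study: genome, annotations, cohort, methylome."""
        cfg = self.cfg
        genome = simdata.generate_genome(cfg.sim)
        blocks = regions_mod.build_ld_blocks(
            genome.genetic_map, cfg.rate_threshold, cfg.max_block_size
        )
        gwas_blocks, snps, stats = regions_mod.assign_snps(
            blocks, genome.gwas_snps, genome.chrom_sizes
        )
        windows, _ = regions_mod.windows_in_blocks(
            gwas_blocks, cfg.sim.window_size, cfg.sim.window_slide, genome.blacklist
        )
        cohort = simdata.generate_cohort(cfg.sim, gwas_blocks)
        truth = simdata.generate_truth(cfg.sim, windows)
        matrix = simdata.generate_methylome(cfg.sim, cohort, truth, windows, genome)
        ldmp = simdata.ldmp_positions(truth, windows)

        h = self.cfg.header("simulate")
        write_table(genome.genetic_map, self.path("genetic_map.tsv"), h)
        write_table(genome.gwas_snps, self.path("gwas_snps.tsv"), h)
        write_table(genome.cpg_positions, self.path("cpg_positions.tsv"), h)
        write_table(
            pd.DataFrame(genome.chrom_sizes.items(), columns=["chrom", "size"]),
            self.path("chrom_sizes.tsv"), h,
        )
        write_bed(genome.blacklist, self.path("tracks/blacklist.bed"), h)
        write_bed(genome.cgi, self.path("tracks/cgi.bed"), h)
        write_bed(
            genome.chromatin_states.rename(columns={"state": "name"}),
            self.path("tracks/chromatin_states.bed"), h,
        )
        manifest = []
        for name, feats in genome.dhs_tracks.items():
            write_bed(feats, self.path(f"tracks/dhs/{name}.bed"), h)
            manifest.append(
                dict(name=name, path=f"tracks/dhs/{name}.bed", category="dhs",
                     is_blood=name in genome.blood_tissues)
            )
        write_table(pd.DataFrame(manifest), self.path("tracks/manifest.tsv"), h)
        write_table(cohort.samples, self.path("cohort.tsv"), h)
        write_table(
            cohort.genotypes.reset_index().rename(columns={"index": "sample_id"}),
            self.path("genotypes.tsv"), h,
        )
        write_table(truth, self.path("truth.tsv"), h)
        write_table(matrix.reset_index(), self.path("matrix.tsv"), h)
        write_bed(
            ldmp.assign(start=ldmp["pos"], end=ldmp["pos"] + 1)[["chrom", "start", "end"]],
            self.path("ldmp.bed"), h,
        )
        return {
            "n_samples": int(len(cohort.samples)),
            "n_families": int(cohort.samples["family_id"].nunique()),
            "n_windows_simulated": int(len(matrix)),
            "n_planted": {
                cls: int((truth["effect_class"] == cls).sum())
                for cls in ("age", "genotype", "interaction", "cell", "null")
            },
        }

    def blocks(self) -> dict:
        """LD blocks from the map, SNP assignment, analysis windows."""
        cfg = self.cfg
        gmap = read_table(self._require("genetic_map.tsv"))
        gwas = read_table(self._require("gwas_snps.tsv"))
        sizes = read_table(self._require("chrom_sizes.tsv"))
        blacklist = read_bed(self._require("tracks/blacklist.bed"))
        blocks = regions_mod.build_ld_blocks(gmap, cfg.rate_threshold, cfg.max_block_size)
        gwas_blocks, snps, stats = regions_mod.assign_snps(
            blocks, gwas, dict(zip(sizes["chrom"], sizes["size"]))
        )
        windows, n_black = regions_mod.windows_in_blocks(
            gwas_blocks, cfg.sim.window_size, cfg.sim.window_slide, blacklist
        )
        h = self.cfg.header("blocks")
        write_table(gwas_blocks, self.path("blocks.tsv"), h)
        write_table(snps, self.path("snps_in_blocks.tsv"), h)
        write_table(windows, self.path("windows.tsv"), h)
        return dict(stats, n_windows=int(len(windows)), n_blacklist_removed=n_black)

    def _load_matrix(self):
        m = read_table(self._require("matrix.tsv"), index_col=0)
        m.index.name = "window_id"
        return m

    def _load_cohort(self):
        return read_table(self._require("cohort.tsv"))

    def _load_genotypes(self):
        return read_table(self._require("genotypes.tsv"), index_col=0)

    def ewas(self) -> dict:
        """Normalise and scan every analysis window for an age effect."""
        cfg = self.cfg
        matrix = self._load_matrix()
        windows = read_table(self._require("windows.tsv"))
        matrix = matrix.loc[matrix.index.intersection(windows["window_id"])]
        keep = cells_mod.window_nonzero_filter(matrix, cfg.nonzero_fraction)
        normed, flagged = ewas_mod.normalise(matrix.loc[keep], cfg.normalisation)
        results = ewas_mod.run_ewas(
            normed, windows, self._load_cohort(), self._load_genotypes(), covariates="full"
        )
        n_tests = len(results)
        threshold = ewas_mod.bonferroni_threshold(n_tests, cfg.alpha)
        h = self.cfg.header("ewas")
        h["bonferroni_threshold"] = threshold
        write_table(results, self.path("ewas.tsv"), h)
        return dict(
            n_windows_tested=n_tests,
            n_nonzero_filtered=int(len(matrix) - len(keep)),
            n_zero_variance=len(flagged),
            bonferroni_threshold=threshold,
            n_significant=int((results["p"] < threshold).sum()),
            n_failed=int((results["status"] == "failed").sum()),
        )

    def call_dmrs(self) -> dict:
        """Merge significant windows into a-DMRs and summarise them."""
        cfg = self.cfg
        results = read_table(self._require("ewas.tsv"))
        threshold = ewas_mod.bonferroni_threshold(len(results), cfg.alpha)
        cpgs = read_table(self._require("cpg_positions.tsv"))
        admrs, members = dmr_mod.call_admrs(results, threshold, cpgs)
        h = self.cfg.header("call-dmrs")
        write_table(admrs, self.path("admrs.tsv"), h)
        write_table(members, self.path("admr_windows.tsv"), h)
        if len(admrs):
            bed = admrs.assign(
                name=admrs["direction"],
                score=(-np.log10(admrs["peak_p"].clip(lower=1e-300))).round(2),
            )[["chrom", "start", "end", "name", "score"]]
            write_bed(bed, self.path("admrs.bed"), h)
        return dmr_mod.summarise_admrs(admrs)

    def interaction(self) -> dict:
        """Genotype x age interaction scan, intersected with the a-DMRs."""
        matrix = self._load_matrix()
        windows = read_table(self._require("windows.tsv"))
        keep = cells_mod.window_nonzero_filter(
            matrix.loc[matrix.index.intersection(windows["window_id"])],
            self.cfg.nonzero_fraction,
        )
        normed, _ = ewas_mod.normalise(matrix.loc[keep], self.cfg.normalisation)
        res = ewas_mod.run_interaction(
            normed, windows, self._load_cohort(), self._load_genotypes()
        )
        members = read_table(self._require("admr_windows.tsv"))
        sig_inter = set(res.loc[res["p"] < 0.05, "window_id"])
        admr_hits = members[members["window_id"].isin(sig_inter)]["admr_id"].nunique() if len(members) else 0
        h = self.cfg.header("interaction")
        write_table(res, self.path("interaction.tsv"), h)
        return dict(
            n_windows=int(len(res)),
            n_nominal_interaction=int(len(sig_inter)),
            n_admrs_with_interaction=int(admr_hits),
        )

    def cell_composition(self) -> dict:
        """MZ blood-trait EWAS, a-DMR enrichment check, L-DMP overlap."""
        matrix = self._load_matrix()
        cohort = self._load_cohort()
        windows = read_table(self._require("windows.tsv"))
        matrix = matrix.loc[matrix.index.intersection(windows["window_id"])]
        keep = cells_mod.window_nonzero_filter(matrix, self.cfg.nonzero_fraction)
        pvals = pd.DataFrame(index=keep)
        for trait in simdata.BLOOD_TRAITS:
            pvals[trait] = cells_mod.mz_discordance_test(matrix.loc[keep], cohort, trait)["p"]
        members = read_table(self._require("admr_windows.tsv"))
        admrs = read_table(self._require("admrs.tsv"))
        summary = cells_mod.admr_bloodtrait_enrichment(pvals, members["window_id"])
        ldmp = read_bed(self._require("ldmp.bed"))
        ldmp = pd.DataFrame({"chrom": ldmp["chrom"], "pos": ldmp["start"]})
        summary["n_admrs_overlapping_ldmp"] = cells_mod.ldmp_overlap(admrs, ldmp)
        h = self.cfg.header("cells")
        write_table(pvals.reset_index().rename(columns={"index": "window_id"}),
                    self.path("cells_pvals.tsv"), h)
        return summary

    def enrichment(self) -> dict:
        """Fold enrichments, chromatin-state composition, DHS and disease."""
        cfg = self.cfg
        admrs = read_table(self._require("admrs.tsv"))
        blocks = read_table(self._require("blocks.tsv"))
        snps = read_table(self._require("snps_in_blocks.tsv"))
        background = enrich_mod.background_windows(blocks, cfg.sim.window_size)
        out: dict = {}
        h = self.cfg.header("enrichment")
        if len(admrs) == 0:
            return {"note": "no a-DMRs called; enrichment skipped"}
        query = admrs[["chrom", "start", "end"]]

        cgi = read_bed(self._require("tracks/cgi.bed"))
        folds = [enrich_mod.fold_enrichment(query, background, cgi, "CGI", cfg.overlap_fraction)]
        states = read_bed(self._require("tracks/chromatin_states.bed"),
                          ["chrom", "start", "end", "state"])
        comp = enrich_mod.state_composition(query, background, states, cfg.overlap_fraction)
        manifest = read_table(self._require("tracks/manifest.tsv"))
        tracks = {
            r["name"]: read_bed(self.path(r["path"]))
            for _, r in manifest.iterrows()
        }
        blood = list(manifest.loc[manifest["is_blood"], "name"])
        dhs_table, per_query = enrich_mod.dhs_multitissue(
            query, background, tracks, blood, cfg.overlap_fraction
        )
        write_table(pd.DataFrame(folds), self.path("enrichment_folds.tsv"), h)
        write_table(comp, self.path("enrichment_states.tsv"), h)
        write_table(dhs_table, self.path("enrichment_dhs.tsv"), h)
        write_table(per_query, self.path("admr_blood_dhs.tsv"), h)

        assoc, assoc_summary = enrich_mod.map_disease_classes(admrs, snps)
        write_table(assoc, self.path("admr_disease_classes.tsv"), h)
        age_blocks = snps.groupby("block_id")["age_related"].any()
        block_flags = pd.DataFrame(
            {
                "block_id": blocks["block_id"],
                "is_admr": blocks["block_id"].isin(admrs["block_id"]),
                "age_related": blocks["block_id"].map(age_blocks).fillna(False),
            }
        )
        fisher = enrich_mod.age_disease_fisher(block_flags)
        perm = enrich_mod.age_disease_permutation(
            n_total=len(block_flags),
            age_related_ids=block_flags.loc[block_flags["age_related"], "block_id"],
            admr_block_ids=block_flags.loc[block_flags["is_admr"], "block_id"],
            n_perm=cfg.n_permutations,
            seed=cfg.seed,
        )
        perm.pop("perm_stats")
        out.update(
            cgi_fold=folds[0]["fold"],
            disease_classes=assoc_summary,
            age_disease=dict(fisher, **perm),
            n_blood_enriched_admrs=int(per_query["blood_enriched"].sum()),
        )
        return out

    def replicate(self) -> dict:
        """Refit the significant windows in an independent synthetic cohort.

        The replication model mirrors the reduced covariate situation:
        batch as the only additional fixed effect, family and pair random.
        """
        cfg = self.cfg
        results = read_table(self._require("ewas.tsv"))
        threshold = ewas_mod.bonferroni_threshold(len(results), cfg.alpha)
        sig = results[results["p"] < threshold]
        members = read_table(self._require("admr_windows.tsv"))
        if len(sig) == 0:
            return {"note": "no significant discovery windows; replication skipped"}
        windows = read_table(self._require("windows.tsv"))
        # keep_default_na guards the literal class label "null"
        truth = read_table(self._require("truth.tsv"), keep_default_na=False, na_values=[""])
        blocks = read_table(self._require("blocks.tsv"))
        genome = simdata.generate_genome(cfg.sim)

        rep_seed = cfg.seed + cfg.replication_seed_offset
        rep_cohort = simdata.generate_cohort(cfg.sim, blocks, seed=rep_seed)
        sub_windows = windows[windows["window_id"].isin(sig["window_id"])].reset_index(drop=True)
        sub_truth = truth[truth["window_id"].isin(sub_windows["window_id"])]
        rep_matrix = simdata.generate_methylome(
            cfg.sim, rep_cohort, sub_truth, sub_windows, genome, seed=rep_seed + 1
        )
        keep = cells_mod.window_nonzero_filter(rep_matrix, cfg.nonzero_fraction)
        normed, _ = ewas_mod.normalise(rep_matrix.loc[keep], cfg.normalisation)
        rep_results = ewas_mod.run_ewas(
            normed, sub_windows, rep_cohort.samples, covariates="reduced"
        )
        conc = dmr_mod.concordance(sig, rep_results, members, threshold)
        h = self.cfg.header("replicate")
        write_table(rep_results, self.path("replication.tsv"), h)
        write_table(pd.DataFrame([conc]), self.path("concordance.tsv"), h)
        return conc


def run_pipeline(config: PipelineConfig, mode: str = "all") -> dict:
    """Run one stage or the whole pipeline; returns (and writes) the summary."""
    run = Run(config)
    stages = {
        "simulate": run.simulate,
        "blocks": run.blocks,
        "ewas": run.ewas,
        "call-dmrs": run.call_dmrs,
        "interact": run.interaction,
        "cells": run.cell_composition,
        "enrich": run.enrichment,
        "replicate": run.replicate,
    }
    if mode != "all" and mode not in stages:
        raise ValueError(f"unknown mode: {mode}")
    run.dir.mkdir(parents=True, exist_ok=True)
    if mode != "all":
        return _jsonable({mode: stages[mode]()})
    summary = {"seed": config.seed, "config": config.content_hash(),
               "version": __version__}
    for name, fn in stages.items():
        summary[name.replace("-", "_")] = fn()
    summary = _jsonable(summary)
    with open(run.path("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
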