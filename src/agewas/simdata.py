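"""Synthetic twin-cohort MeDIP-seq study generator.

Everything downstream of raw-read processing is emulated here on a toy
genome: a recombination map with hotspots (so LD blocks of varied size
exist), a GWAS SNP catalogue with disease classes, annotation tracks
(blacklist, CpG islands, chromatin states, per-tissue DHS), a twin cohort
with MZ/DZ pairs, singletons and longitudinal repeats, and a windows x
samples RPM-scale methylation matrix with known planted truth.

The generative model for a window value mirrors the analysis model run
forwards:

    rpm = baseline(CpG count)
          + age-slope * (age - midpoint)            [class "age"]
          + geno-beta * allelic count               [class "genotype"]
          + int-slope * (age - midpoint) * count    [class "interaction"]
          + cell-beta * blood-trait z-score         [class "cell"]
          + smoking and batch shifts
          + family intercept + pair intercept
          + noise / sqrt(sample depth),             floored at 0.

MeDIP signal tracks CpG density, hence the CpG-count baseline.  RPM is
depth-normalised by construction, so sequencing depth cancels in the mean
and enters only through the sampling noise: samples with a lower lognormal
depth factor are noisier.  Blood-cell traits are generated as
lymphocyte-correlated subtype fractions with an idiosyncratic component,
so the full-blood-count covariates in the model do not absorb them
completely -- that residual is what the MZ-discordance EWAS detects.
Leukocyte fractions drift with age (myeloid skew), which is what makes
cell-driven windows an age confounder when left unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "ToyGenome",
    "Cohort",
    "generate_genome",
    "generate_cohort",
    "generate_truth",
    "generate_methylome",
    "ldmp_positions",
    "BLOOD_TRAITS",
    "DISEASE_CLASSES",
    "AGE_RELATED_CLASSES",
]

BLOOD_TRAITS = ["cd4t", "cd8t", "tcell", "nk", "cd34", "b"]
# weight of the lymphocyte component in each trait; the remainder is
# idiosyncratic and invisible to the four FBC fractions
_TRAIT_LYMPH_WEIGHT = {
    "cd4t": 0.6, "cd8t": 0.5, "tcell": 0.7, "nk": 0.4, "cd34": 0.1, "b": 0.4,
}

DISEASE_CLASSES = [
    "cancer", "cardiovascular", "neurological", "metabolic", "musculoskeletal",
    "autoimmune", "haematological", "renal", "respiratory", "ophthalmological",
    "psychiatric", "developmental", "infection", "reproductive", "anthropometric",
]
AGE_RELATED_CLASSES = {
    "cancer", "cardiovascular", "neurological", "metabolic", "musculoskeletal",
}

CHROMATIN_STATES = ["TSS", "PF", "PoisedProm", "E", "WE", "CTCF", "T", "R"]
_STATE_PROBS = [0.04, 0.04, 0.03, 0.08, 0.08, 0.05, 0.28, 0.40]

SMOKING_LEVELS = ["never", "former", "current"]
_SMOKING_PROBS = [0.5, 0.3, 0.2]


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults describe the desk-scale study conditions: a toy genome of
    3 x 150 kb, ~150 twin families (pairs, singletons and longitudinal
    repeats), 500-bp windows on a 250-bp slide, and enough planted and
    null windows for calibration checks (>=500 null, >=200 age windows).
    """

    seed: int = 0
    # genome
    n_chromosomes: int = 3
    chrom_length: int = 200_000
    map_interval: int = 2_500
    hotspot_rate_per_mb: float = 40.0
    background_rate: float = 1.0
    cpg_spacing: int = 60
    n_cgi_per_chrom: int = 6
    cgi_length: int = 1_200
    cgi_cpg_spacing: int = 12
    n_gwas_snps: int = 150
    gwas_p_below_fraction: float = 0.75
    n_blacklist_per_chrom: int = 2
    blacklist_length: int = 1_500
    n_dhs_tissues: int = 25
    n_blood_tissues: int = 8
    dhs_sites_per_tissue: int = 40
    dhs_length: int = 400
    mean_state_length: int = 1_500
    # cohort
    n_families: int = 150
    singleton_fraction: float = 0.15
    mz_fraction: float = 0.45
    longitudinal_fraction: float = 0.2
    longitudinal_gap: float = 2.2
    age_range: tuple = (19.0, 82.0)
    n_batches: int = 4
    cell_concentration: float = 200.0
    cell_age_trend: float = 0.0015  # neutrophil fraction gain per year
    # planted truth
    window_size: int = 500
    window_slide: int = 250
    n_age_windows: int = 210
    n_geno_windows: int = 60
    n_interaction_windows: int = 30
    n_cell_windows: int = 40
    age_slope_range: tuple = (0.02, 0.05)
    geno_beta_range: tuple = (0.4, 0.8)
    interaction_slope_range: tuple = (0.015, 0.03)
    cell_beta_range: tuple = (0.6, 1.0)
    # methylome
    baseline_per_cpg: float = 1.0
    depth_sdlog: float = 0.15
    noise_sd: float = 0.8
    family_sd: float = 0.3
    pair_sd: float = 0.4
    smoking_effect: float = 0.15
    batch_effect: float = 0.1
    zero_fraction: float = 0.0
    low_coverage_window_fraction: float = 0.03
    low_coverage_zero_rate: float = 0.3

    def __post_init__(self):
        if self.window_slide > self.window_size or self.window_slide <= 0:
            raise ValueError("window_slide must be in (0, window_size]")
        for name in ("mz_fraction", "longitudinal_fraction", "singleton_fraction",
                     "gwas_p_below_fraction", "zero_fraction",
                     "low_coverage_window_fraction", "low_coverage_zero_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_chromosomes", "n_families", "n_age_windows",
                     "n_geno_windows", "n_interaction_windows", "n_cell_windows"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if self.chrom_length < 3 * self.window_size:
            raise ValueError("chrom_length must be at least 3 window sizes")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ToyGenome:
    chrom_sizes: dict
    genetic_map: pd.DataFrame
    gwas_snps: pd.DataFrame
    cpg_positions: pd.DataFrame
    blacklist: pd.DataFrame
    cgi: pd.DataFrame
    chromatin_states: pd.DataFrame
    dhs_tracks: dict
    blood_tissues: list


@dataclass
class Cohort:
    samples: pd.DataFrame
    genotypes: pd.DataFrame  # sample_id x block_id allelic counts
    block_mafs: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _genetic_map_one_chrom(rng, chrom: str, length: int, cfg: SimConfig) -> pd.DataFrame:
    starts = np.arange(0, length, cfg.map_interval)
    ends = np.minimum(starts + cfg.map_interval, length)
    rates = np.minimum(
        rng.lognormal(np.log(cfg.background_rate), 0.4, size=len(starts)), 9.5
    )
    n_hot = rng.poisson(cfg.hotspot_rate_per_mb * length / 1e6)
    if n_hot > 0:
        pos = rng.integers(0, length, size=n_hot)
        idx = np.unique(np.searchsorted(starts, pos, side="right") - 1)
        rates[idx] = rng.uniform(15.0, 60.0, size=len(idx))
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "rate": rates})


def _random_intervals(rng, chrom, length, n, width):
    s = rng.integers(0, max(length - width, 1), size=n)
    return pd.DataFrame({"chrom": chrom, "start": np.sort(s), "end": np.sort(s) + width})


def generate_genome(config: SimConfig, seed: int | None = None) -> ToyGenome:
    """Build the toy genome, recombination map, SNP catalogue and tracks."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sizes = {c: config.chrom_length for c in chroms}

    gmap = pd.concat(
        [_genetic_map_one_chrom(rng, c, sizes[c], config) for c in chroms],
        ignore_index=True,
    )

    # GWAS SNP catalogue with p-values straddling 1e-7
    n = config.n_gwas_snps
    chrom_ix = rng.integers(0, len(chroms), size=n)
    pos = rng.integers(0, config.chrom_length, size=n)
    below = rng.random(n) < config.gwas_p_below_fraction
    logp = np.where(below, rng.uniform(-25, -7.05, n), rng.uniform(-6.95, -4, n))
    classes = rng.choice(DISEASE_CLASSES, size=n)
    gwas = pd.DataFrame(
        {
            "chrom": [chroms[i] for i in chrom_ix],
            "pos": pos,
            "rsid": [f"rs{i:06d}" for i in range(n)],
            "p": 10.0 ** logp,
            "trait": [f"{c}_trait_{rng.integers(1, 4)}" for c in classes],
            "disease_class": classes,
            "age_related": [c in AGE_RELATED_CLASSES for c in classes],
        }
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)

    # CpG islands and CpG positions (background + island clusters)
    cgi_frames, cpg_frames = [], []
    for c in chroms:
        cgi = _random_intervals(rng, c, sizes[c], config.n_cgi_per_chrom, config.cgi_length)
        cgi_frames.append(cgi)
        bg = np.cumsum(rng.exponential(config.cpg_spacing, size=int(2 * sizes[c] / config.cpg_spacing)))
        bg = bg[bg < sizes[c]].astype(int)
        island = []
        for _, row in cgi.iterrows():
            ipos = np.arange(row["start"], row["end"], config.cgi_cpg_spacing)
            island.append(ipos + rng.integers(0, config.cgi_cpg_spacing, size=len(ipos)))
        allpos = np.unique(np.concatenate([bg] + island)) if island else np.unique(bg)
        cpg_frames.append(pd.DataFrame({"chrom": c, "pos": allpos[allpos < sizes[c]]}))
    cgi = pd.concat(cgi_frames, ignore_index=True)
    cpgs = pd.concat(cpg_frames, ignore_index=True)

    blacklist = pd.concat(
        [
            _random_intervals(rng, c, sizes[c], config.n_blacklist_per_chrom, config.blacklist_length)
            for c in chroms
        ],
        ignore_index=True,
    )

    # chromatin-state segmentation: one labelled state per base
    seg_rows = []
    for c in chroms:
        pos = 0
        while pos < sizes[c]:
            seg_len = max(int(rng.exponential(config.mean_state_length)), 200)
            end = min(pos + seg_len, sizes[c])
            seg_rows.append((c, pos, end, rng.choice(CHROMATIN_STATES, p=_STATE_PROBS)))
            pos = end
    states = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "state"])

    blood = [f"blood_{i + 1}" for i in range(config.n_blood_tissues)]
    other = [f"tissue_{i + 1}" for i in range(config.n_dhs_tissues - config.n_blood_tissues)]
    dhs = {}
    for name in blood + other:
        per_chrom = [
            _random_intervals(
                rng, c, sizes[c],
                max(config.dhs_sites_per_tissue // len(chroms), 1), config.dhs_length,
            )
            for c in chroms
        ]
        dhs[name] = pd.concat(per_chrom, ignore_index=True)

    return ToyGenome(
        chrom_sizes=sizes,
        genetic_map=gmap,
        gwas_snps=gwas,
        cpg_positions=cpgs,
        blacklist=blacklist,
        cgi=cgi,
        chromatin_states=states,
        dhs_tracks=dhs,
        blood_tissues=blood,
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _block_genotypes(rng, maf, zygosity):
    """Allelic counts for a list of families under Mendelian transmission.

    Returns per-family (twin1, twin2) counts; MZ co-twins share one
    genotype, DZ co-twins each draw one allele per parent independently
    (expected allelic correlation 1/2).
    """
    n = len(zygosity)
    father = rng.random((n, 2)) < maf
    mother = rng.random((n, 2)) < maf
    pick1f = rng.integers(0, 2, n)
    pick1m = rng.integers(0, 2, n)
    twin1 = father[np.arange(n), pick1f].astype(int) + mother[np.arange(n), pick1m].astype(int)
    pick2f = rng.integers(0, 2, n)
    pick2m = rng.integers(0, 2, n)
    twin2_dz = father[np.arange(n), pick2f].astype(int) + mother[np.arange(n), pick2m].astype(int)
    twin2 = np.where(np.asarray(zygosity) == "MZ", twin1, twin2_dz)
    return twin1, twin2


def _cell_fractions(rng, ages, cfg: SimConfig):
    """Dirichlet leukocyte fractions with an age trend (myeloid skew)."""
    mid = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
    shift = cfg.cell_age_trend * (ages - mid)
    means = np.column_stack(
        [
            np.clip(0.30 - shift, 0.05, 0.6),   # lymphocyte
            np.full_like(ages, 0.08),            # monocyte
            np.clip(0.56 + shift, 0.2, 0.85),   # neutrophil
            np.full_like(ages, 0.03),            # eosinophil
            np.full_like(ages, 0.03),            # other (keeps the 4 modelled
        ]                                        # fractions off the simplex)
    )
    out = np.empty_like(means)
    for i in range(len(ages)):
        out[i] = rng.dirichlet(means[i] * cfg.cell_concentration)
    return out[:, :4]


def generate_cohort(config: SimConfig, blocks: pd.DataFrame, seed: int | None = None) -> Cohort:
    """Twin families with genotypes, covariates and blood-cell traits.

    Each family is a twin pair (MZ with probability ``mz_fraction``) or a
    singleton.  Co-twins share their age at draw; a ``longitudinal_fraction``
    of individuals contributes a second sample ``longitudinal_gap`` years
    later under the same individual/pair/family identifiers.
    """
    if blocks is None or len(blocks) == 0:
        raise ValueError("blocks must be non-empty")
    rng = np.random.default_rng((config.seed + 1) if seed is None else seed)
    lo, hi = config.age_range

    fam_ids = [f"F{i:04d}" for i in range(config.n_families)]
    is_pair = rng.random(config.n_families) >= config.singleton_fraction
    zygosity = np.where(
        is_pair,
        np.where(rng.random(config.n_families) < config.mz_fraction, "MZ", "DZ"),
        "singleton",
    )
    fam_age = rng.uniform(lo, hi - config.longitudinal_gap, size=config.n_families)

    # genotypes per block at the family level
    block_ids = list(blocks["block_id"])
    mafs = {b: rng.uniform(0.1, 0.5) for b in block_ids}
    twin_geno = {b: _block_genotypes(rng, mafs[b], zygosity) for b in block_ids}

    indiv_rows = []
    for i, fam in enumerate(fam_ids):
        n_tw = 2 if is_pair[i] else 1
        for t in range(n_tw):
            indiv_rows.append(
                dict(
                    individual_id=f"{fam}_I{t + 1}",
                    family_id=fam,
                    pair_id=f"{fam}_P" if is_pair[i] else f"{fam}_S{t + 1}",
                    zygosity=zygosity[i],
                    fam_index=i,
                    twin_index=t,
                    base_age=fam_age[i],
                    smoking=rng.choice(SMOKING_LEVELS, p=_SMOKING_PROBS),
                )
            )
    indiv = pd.DataFrame(indiv_rows)
    indiv["longitudinal"] = rng.random(len(indiv)) < config.longitudinal_fraction

    sample_rows = []
    for _, ind in indiv.iterrows():
        n_visits = 2 if ind["longitudinal"] else 1
        for v in range(n_visits):
            sample_rows.append(
                dict(
                    sample_id=f"{ind['individual_id']}_V{v + 1}",
                    individual_id=ind["individual_id"],
                    family_id=ind["family_id"],
                    pair_id=ind["pair_id"],
                    zygosity=ind["zygosity"],
                    age=ind["base_age"] + v * config.longitudinal_gap,
                    smoking=ind["smoking"],
                    batch=f"batch{rng.integers(1, config.n_batches + 1)}",
                    fam_index=ind["fam_index"],
                    twin_index=ind["twin_index"],
                )
            )
    samples = pd.DataFrame(sample_rows)

    cells = _cell_fractions(rng, samples["age"].to_numpy(), config)
    for j, col in enumerate(["lymphocyte", "monocyte", "neutrophil", "eosinophil"]):
        samples[col] = cells[:, j]

    # blood-cell subtype traits: lymphocyte-correlated plus idiosyncratic part
    lymph = samples["lymphocyte"].to_numpy()
    z_lymph = (lymph - lymph.mean()) / lymph.std(ddof=0)
    for trait in BLOOD_TRAITS:
        w = _TRAIT_LYMPH_WEIGHT[trait]
        eps = rng.standard_normal(len(samples))
        samples[trait] = w * z_lymph + np.sqrt(1.0 - w * w) * eps

    geno = pd.DataFrame(index=samples["sample_id"], columns=block_ids, dtype=int)
    fi = samples["fam_index"].to_numpy()
    ti = samples["twin_index"].to_numpy()
    for b in block_ids:
        t1, t2 = twin_geno[b]
        geno[b] = np.where(ti == 0, t1[fi], t2[fi])
    samples = samples.drop(columns=["fam_index", "twin_index"])
    return Cohort(samples=samples, genotypes=geno, block_mafs=mafs)


# ---------------------------------------------------------------------------
# planted truth
# ---------------------------------------------------------------------------

def generate_truth(config: SimConfig, windows: pd.DataFrame, seed: int | None = None) -> pd.DataFrame:
    """Assign one effect class per window and draw the planted effect sizes.

    Age effects are planted in runs of 1-3 consecutive grid windows (these
    overlap, so the called a-DMRs exercise the merge step); all planted
    sites are separated by at least two untouched grid slots so classes
    never share signal.  Windows left over are class ``null``.
    """
    rng = np.random.default_rng((config.seed + 2) if seed is None else seed)
    win = windows.sort_values(["chrom", "start"]).reset_index(drop=True)
    n = len(win)
    starts = win["start"].to_numpy()
    blocks = win["block_id"].to_numpy()
    contiguous = np.zeros(n, dtype=bool)
    contiguous[:-1] = (np.diff(starts) == config.window_slide) & (blocks[:-1] == blocks[1:])

    occupied = np.zeros(n, dtype=bool)

    def take(run_len: int):
        cand = rng.permutation(n)
        for i in cand:
            j = i + run_len
            if j > n:
                continue
            if run_len > 1 and not contiguous[i: j - 1].all():
                continue
            lo_g, hi_g = max(i - 2, 0), min(j + 2, n)
            if occupied[lo_g:hi_g].any():
                continue
            occupied[lo_g:hi_g] = True
            return list(range(i, j))
        return None

    cls = np.array(["null"] * n, dtype=object)
    age_slope = np.zeros(n)
    geno_beta = np.zeros(n)
    inter_slope = np.zeros(n)
    cell_type = np.array([""] * n, dtype=object)

    remaining = config.n_age_windows
    while remaining > 0:
        run = min(int(rng.integers(1, 4)), remaining)
        idx = take(run)
        if idx is None:
            break
        lo, hi = config.age_slope_range
        slope = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        for k in idx:
            cls[k] = "age"
            age_slope[k] = slope
        remaining -= len(idx)

    for count, (label, rng_range, target) in {
        0: ("genotype", config.geno_beta_range, geno_beta),
        1: ("interaction", config.interaction_slope_range, inter_slope),
    }.items():
        need = config.n_geno_windows if label == "genotype" else config.n_interaction_windows
        for _ in range(need):
            idx = take(1)
            if idx is None:
                break
            lo, hi = rng_range
            val = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
            cls[idx[0]] = label
            target[idx[0]] = val

    for _ in range(config.n_cell_windows):
        idx = take(1)
        if idx is None:
            break
        lo, hi = config.cell_beta_range
        cls[idx[0]] = "cell"
        geno_b = rng.uniform(lo, hi)
        cell_type[idx[0]] = rng.choice(BLOOD_TRAITS)
        age_slope[idx[0]] = 0.0
        inter_slope[idx[0]] = 0.0
        geno_beta[idx[0]] = 0.0
        # store the cell effect in its own column
        win.loc[idx[0], "_cell_beta"] = geno_b

    truth = pd.DataFrame(
        {
            "window_id": win["window_id"],
            "effect_class": cls,
            "planted_age_slope": age_slope,
            "planted_geno_beta": geno_beta,
            "planted_interaction_slope": inter_slope,
            "driving_cell_type": cell_type,
            "planted_cell_beta": win.get("_cell_beta", pd.Series(0.0, index=win.index)).fillna(0.0),
        }
    )
    return truth.reset_index(drop=True)


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def generate_methylome(
    config: SimConfig,
    cohort: Cohort,
    truth: pd.DataFrame,
    windows: pd.DataFrame,
    genome: ToyGenome,
    seed: int | None = None,
) -> pd.DataFrame:
    """Raw RPM-scale windows x samples matrix with the planted effects."""
    missing = set(windows["window_id"]) - set(truth["window_id"])
    if missing:
        raise ValueError("truth table must cover all windows")
    rng = np.random.default_rng((config.seed + 3) if seed is None else seed)
    samples = cohort.samples
    n_s = len(samples)
    win = windows.merge(truth, on="window_id").reset_index(drop=True)
    n_w = len(win)

    # CpG counts per window
    ncpg = np.zeros(n_w)
    for chrom, grp in win.groupby("chrom"):
        pos = np.sort(
            genome.cpg_positions.loc[genome.cpg_positions["chrom"] == chrom, "pos"].to_numpy()
        )
        lo = np.searchsorted(pos, grp["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, grp["end"].to_numpy(), side="left")
        ncpg[grp.index] = hi - lo

    ages = samples["age"].to_numpy()
    mid = 0.5 * (config.age_range[0] + config.age_range[1])
    age_c = ages - mid
    # RPM is depth-normalised, so sequencing depth cancels in the mean and
    # survives only as per-sample noise scaling (shallower -> noisier)
    depth = rng.lognormal(0.0, config.depth_sdlog, size=n_s)

    values = np.broadcast_to(
        (config.baseline_per_cpg * ncpg)[:, None], (n_w, n_s)
    ).copy()

    # planted fixed effects
    values += np.outer(win["planted_age_slope"].to_numpy(), age_c)
    blocks_arr = win["block_id"].to_numpy()
    geno_all = cohort.genotypes.loc[samples["sample_id"]]
    need_geno = (win["planted_geno_beta"] != 0) | (win["planted_interaction_slope"] != 0)
    for i in np.flatnonzero(need_geno.to_numpy()):
        g = geno_all[blocks_arr[i]].to_numpy(dtype=float)
        maf = cohort.block_mafs.get(blocks_arr[i], 0.0)
        gc = g - 2.0 * maf
        values[i] += win.at[i, "planted_geno_beta"] * gc
        values[i] += win.at[i, "planted_interaction_slope"] * age_c * g
    for i in np.flatnonzero((win["effect_class"] == "cell").to_numpy()):
        trait = win.at[i, "driving_cell_type"]
        z = samples[trait].to_numpy()
        values[i] += win.at[i, "planted_cell_beta"] * (z - z.mean()) / z.std(ddof=0)

    # nuisance covariate shifts: per-window coefficients on smoking level
    # and batch identity, so omitting them detectably inflates error
    smoke_level = samples["smoking"].map({s: i for i, s in enumerate(SMOKING_LEVELS)}).to_numpy()
    smoke_coef = rng.normal(0.0, config.smoking_effect, size=n_w)
    values += np.outer(smoke_coef, smoke_level)
    batch_codes, batch_idx = np.unique(samples["batch"], return_inverse=True)
    batch_eff = rng.normal(0.0, config.batch_effect, size=(n_w, len(batch_codes)))
    values += batch_eff[:, batch_idx]

    # random intercepts and noise
    fam_codes, fam_idx = np.unique(samples["family_id"], return_inverse=True)
    pair_codes, pair_idx = np.unique(samples["pair_id"], return_inverse=True)
    values += rng.normal(0.0, config.family_sd, size=(n_w, len(fam_codes)))[:, fam_idx]
    values += rng.normal(0.0, config.pair_sd, size=(n_w, len(pair_codes)))[:, pair_idx]
    values += rng.normal(0.0, config.noise_sd, size=(n_w, n_s)) / np.sqrt(depth)[None, :]

    values = np.maximum(values, 0.0)
    # zero-inflation: rare background dropouts everywhere, plus a small set
    # of poorly covered windows with many zeros -- the latter is what the
    # >=90%-non-zero filter exists to remove
    if config.zero_fraction > 0:
        values[rng.random((n_w, n_s)) < config.zero_fraction] = 0.0
    if config.low_coverage_window_fraction > 0 and config.low_coverage_zero_rate > 0:
        low = rng.random(n_w) < config.low_coverage_window_fraction
        mask = rng.random((int(low.sum()), n_s)) < config.low_coverage_zero_rate
        vals_low = values[low]
        vals_low[mask] = 0.0
        values[low] = vals_low

    return pd.DataFrame(values, index=win["window_id"], columns=samples["sample_id"])


def ldmp_positions(truth: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Leukocyte-DMP stand-in list: centres of the cell-driven windows."""
    cell_ids = truth.loc[truth["effect_class"] == "cell", "window_id"]
    sub = windows[windows["window_id"].isin(cell_ids)]
    return pd.DataFrame(
        {"chrom": sub["chrom"], "pos": ((sub["start"] + sub["end"]) // 2).astype(int)}
    ).reset_index(drop=True)
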