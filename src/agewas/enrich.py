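"""Region-set enrichment statistics for a-DMRs.

Every comparison uses the windows inside the GWAS LD blocks as background
(non-overlapping 500-bp windows, stride = window size), never the whole
genome: the LD blocks are already functionally enriched, so genome-wide
backgrounds would overstate every fold.  Overlap uses the moderate
fractional criterion (>=10% of the query covered), matching
``intersectBed -f 0.1``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .regions import overlap

__all__ = [
    "fold_enrichment",
    "state_composition",
    "dhs_multitissue",
    "map_disease_classes",
    "age_disease_fisher",
    "age_disease_permutation",
    "background_windows",
    "reconstruct_block_instance",
]


def reconstruct_block_instance(
    n_total: int,
    frac_age_total: float,
    n_admr_blocks: int,
    frac_age_admr: float,
) -> pd.DataFrame:
    """Block flags from published summary fractions.

    For permutation/Fisher analyses only the four cell counts matter, so a
    block-flag table can be reconstructed from a study's printed totals and
    percentages: ``n_total`` LD blocks of which ``frac_age_total`` carry an
    age-related disease association, and ``n_admr_blocks`` a-DMR blocks of
    which ``frac_age_admr`` do (fractions rounded to whole blocks).
    """
    n_age = round(frac_age_total * n_total)
    n_overlap = round(frac_age_admr * n_admr_blocks)
    if not (0 <= n_overlap <= min(n_age, n_admr_blocks) and n_admr_blocks <= n_total):
        raise ValueError("inconsistent summary counts")
    ids = [f"B{i:04d}" for i in range(n_total)]
    is_admr = np.zeros(n_total, bool)
    is_admr[:n_admr_blocks] = True
    age = np.zeros(n_total, bool)
    age[:n_overlap] = True                                # a-DMR & age-related
    age[n_admr_blocks:n_admr_blocks + n_age - n_overlap] = True
    return pd.DataFrame({"block_id": ids, "is_admr": is_admr, "age_related": age})


def background_windows(blocks: pd.DataFrame, window_size: int = 500) -> pd.DataFrame:
    """Non-overlapping windows tiling the LD blocks (enrichment background)."""
    rows = []
    for _, b in blocks.iterrows():
        start = int(b["start"])
        while start + window_size <= b["end"]:
            rows.append((b["chrom"], start, start + window_size))
            start += window_size
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _chi2_2x2(a, b, c, d, correction=False):
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)[:4]
    return float(stat), float(p)


def fold_enrichment(
    query: pd.DataFrame,
    background: pd.DataFrame,
    features: pd.DataFrame,
    feature_name: str = "feature",
    f: float = 0.1,
    correction: bool = False,
) -> dict:
    """Hit-proportion fold of query regions vs background windows.

    A region hits when >= ``f`` of its length is covered by the feature
    union.  The chi-square on the 2x2 hit table is Pearson without Yates
    correction by default (the comparisons live in a large-count regime).
    """
    if len(features) == 0:
        q_hit = np.zeros(len(query), dtype=bool)
        b_hit = np.zeros(len(background), dtype=bool)
    else:
        q_hit = overlap(query, features, f)
        b_hit = overlap(background, features, f)
    nq, nb = len(query), len(background)
    hq, hb = int(q_hit.sum()), int(b_hit.sum())
    pq = hq / nq if nq else 0.0
    pb = hb / nb if nb else 0.0
    fold = np.inf if (pq > 0 and pb == 0) else (pq / pb if pb > 0 else (1.0 if pq == 0 else np.inf))
    chi2_stat, chi2_p = _chi2_2x2(hq, nq - hq, hb, nb - hb, correction=correction)
    return dict(
        feature_name=feature_name, n_query_hits=hq, n_query=nq,
        n_background_hits=hb, n_background=nb, fold=float(fold),
        chi2_stat=chi2_stat, chi2_p=chi2_p,
    )


def state_composition(
    query: pd.DataFrame,
    background: pd.DataFrame,
    segmentation: pd.DataFrame,
    f: float = 0.1,
) -> pd.DataFrame:
    """Per-chromatin-state hit fractions for query vs background.

    A region counts toward every state covering >= ``f`` of it, so the
    fractions are per state and may sum above 1 for multi-state regions.
    """
    rows = []
    for state, feats in segmentation.groupby("state"):
        res = fold_enrichment(query, background, feats[["chrom", "start", "end"]],
                              feature_name=str(state), f=f)
        res["frac_query"] = res["n_query_hits"] / res["n_query"] if res["n_query"] else 0.0
        res["frac_background"] = (
            res["n_background_hits"] / res["n_background"] if res["n_background"] else 0.0
        )
        rows.append(res)
    return pd.DataFrame(rows)


def dhs_multitissue(
    query: pd.DataFrame,
    background: pd.DataFrame,
    dhs_tracks: dict,
    blood_names: list,
    f: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue DHS log2 fold enrichments and per-query blood status.

    Returns the per-track enrichment table (with ``log2_fold`` and an
    ``is_blood`` flag) and a per-query table marking regions that hit at
    least 50% of the blood-tissue tracks.
    """
    unknown = set(blood_names) - set(dhs_tracks)
    if unknown:
        raise ValueError(f"blood tracks not in the track set: {sorted(unknown)}")
    rows = []
    blood_hits = np.zeros(len(query), dtype=int)
    for name, feats in dhs_tracks.items():
        res = fold_enrichment(query, background, feats, feature_name=name, f=f)
        with np.errstate(divide="ignore"):
            res["log2_fold"] = float(np.log2(res["fold"])) if res["fold"] > 0 else -np.inf
        res["is_blood"] = name in blood_names
        rows.append(res)
        if name in blood_names and len(feats):
            blood_hits += overlap(query, feats, f).astype(int)
    per_track = pd.DataFrame(rows)
    need = 0.5 * len(blood_names)
    per_query = query.copy()
    per_query["n_blood_hits"] = blood_hits
    per_query["blood_enriched"] = blood_hits >= need
    return per_track, per_query


def map_disease_classes(
    admrs: pd.DataFrame,
    snps: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Traits and disease classes of the LD blocks the a-DMRs occupy.

    a-DMRs map to their enclosing block (every a-DMR lies inside a GWAS LD
    block by construction), blocks to their unique SNPs, SNPs to their
    trait associations (counted with multiplicity).  Returns the per-DMR
    association table and deduplicated summary counts.
    """
    if not set(admrs["block_id"]).issubset(set(snps["block_id"])):
        raise AssertionError("a-DMR in a SNP-free block: blocks are only retained with SNPs")
    table = admrs[["admr_id", "block_id"]].merge(
        snps[["block_id", "rsid", "p", "trait", "disease_class", "age_related"]],
        on="block_id",
    )
    summary = dict(
        n_admrs=int(admrs["admr_id"].nunique()),
        n_blocks=int(admrs["block_id"].nunique()),
        n_unique_snps=int(table["rsid"].nunique()),
        n_associations=int(len(table)),
        class_counts=table.groupby("disease_class")["trait"].count().to_dict(),
    )
    return table, summary


def age_disease_fisher(block_flags: pd.DataFrame) -> dict:
    """Fisher's exact test: are a-DMR blocks enriched for age-related disease?

    ``block_flags`` has one row per GWAS LD block with boolean columns
    ``is_admr`` and ``age_related``.  Reports the cross-product (sample)
    odds ratio (Haldane-corrected and flagged on zero cells), the
    conditional-MLE odds ratio with its exact CI, and the two-sided exact p.
    """
    a = int((block_flags["is_admr"] & block_flags["age_related"]).sum())
    b = int((block_flags["is_admr"] & ~block_flags["age_related"]).sum())
    c = int((~block_flags["is_admr"] & block_flags["age_related"]).sum())
    d = int((~block_flags["is_admr"] & ~block_flags["age_related"]).sum())
    table = np.array([[a, b], [c, d]])
    haldane = (table == 0).any()
    t = table + 0.5 if haldane else table
    sample_or = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    res = stats.contingency.odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(0.95)
    return dict(
        n_blocks_total=int(len(block_flags)),
        n_admr_blocks=a + b,
        n_age_related_total=a + c,
        n_age_related_admr=a,
        odds_ratio=float(sample_or),
        odds_ratio_cmle=float(res.statistic),
        haldane_corrected=bool(haldane),
        fisher_p=float(fisher_p),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


def age_disease_permutation(
    n_total: int,
    age_related_ids,
    admr_block_ids,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation null for the age-related-disease overlap.

    Each permutation draws ``len(age_related_ids)`` blocks uniformly
    without replacement from the full set of ``n_total`` blocks and counts
    the overlap with the observed a-DMR blocks.  The empirical p is the
    add-one-smoothed upper-tail fraction, so it can never be exactly zero
    from a finite number of draws.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    age_ids = list(age_related_ids)
    admr_ids = set(admr_block_ids)
    if len(age_ids) > n_total:
        raise ValueError("more age-related blocks than blocks in total")
    universe = np.arange(n_total)
    rng = np.random.default_rng(seed)
    observed = len(admr_ids & set(age_ids))
    k = len(age_ids)
    n_admr = len(admr_ids)
    # under uniform draws the block labels are exchangeable, so any fixed
    # set of n_admr labels represents the observed a-DMR blocks
    admr_mask = np.zeros(n_total, dtype=bool)
    admr_mask[:n_admr] = True
    stats_perm = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        draw = rng.choice(universe, size=k, replace=False)
        stats_perm[i] = int(admr_mask[draw].sum())
    emp_p = (1 + int((stats_perm >= observed).sum())) / (n_perm + 1)
    return dict(
        observed=observed,
        empirical_p=float(emp_p),
        n_permutations=int(n_perm),
        perm_mean=float(stats_perm.mean()),
        perm_stats=stats_perm,
    )
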