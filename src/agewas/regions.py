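"""LD-block construction, analysis-window enumeration and interval overlap.

Genomic intervals are 0-based half-open throughout, as in BED.  LD blocks
are maximal runs of genetic-map intervals whose recombination rate stays
below a hotspot threshold (default 10 cM/Mb); runs longer than a maximum
size are pruned.  Analysis windows are fixed-size sliding windows laid on a
global grid (start a multiple of the slide) and kept only when fully
contained in a block.

The fractional-overlap predicate mirrors ``intersectBed -f``: a query
interval hits a feature set when at least a fraction ``f`` of the query is
covered by the union of the features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "build_ld_blocks",
    "assign_snps",
    "windows_in_blocks",
    "merge_intervals",
    "coverage_fraction",
    "overlap",
]

_EPS = 1e-9


def _check_intervals(df: pd.DataFrame, what: str = "interval") -> None:
    if len(df) and not (df["end"].to_numpy() > df["start"].to_numpy()).all():
        raise ValueError(f"malformed {what}: end must be > start")


def build_ld_blocks(
    genetic_map: pd.DataFrame,
    rate_threshold: float = 10.0,
    max_size: int = 10_000_000,
) -> pd.DataFrame:
    """Partition each chromosome into LD blocks from a recombination map.

    Parameters
    ----------
    genetic_map : DataFrame with columns chrom, start, end, rate (cM/Mb).
        Intervals on a chromosome must not overlap.
    rate_threshold : intervals with ``rate >= rate_threshold`` are hotspot
        boundaries; they separate blocks and belong to no block.
    max_size : blocks longer than this many bp are dropped.

    Returns
    -------
    DataFrame with columns chrom, start, end, block_id.
    """
    _check_intervals(genetic_map, "genetic map interval")
    rows = []
    for chrom, grp in genetic_map.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping genetic-map intervals on {chrom}")
        below = grp["rate"].to_numpy() < rate_threshold
        # maximal runs of below-threshold intervals
        i = 0
        n = len(grp)
        while i < n:
            if not below[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            rows.append((chrom, int(starts[i]), int(ends[j])))
            i = j + 1
    blocks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if len(blocks):
        blocks = blocks[(blocks["end"] - blocks["start"]) <= max_size]
        blocks = blocks.sort_values(["chrom", "start"]).reset_index(drop=True)
    blocks["block_id"] = [
        f"B{i:05d}" for i in range(len(blocks))
    ]
    return blocks


def assign_snps(
    blocks: pd.DataFrame,
    gwas_table: pd.DataFrame,
    chrom_sizes: dict[str, int],
    p_cut: float = 1e-7,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Assign catalogue SNPs to LD blocks and retain blocks with >=1 SNP.

    SNPs failing the association-p cut-off or falling outside every block
    are discarded.  Returns ``(gwas_blocks, snps, stats)`` where
    ``gwas_blocks`` is the subset of ``blocks`` holding at least one
    retained SNP (with an ``n_snps`` column), ``snps`` is the retained SNP
    table with a ``block_id`` column, and ``stats`` reports the distinct
    block count and the genome fraction the retained blocks cover.
    """
    snps = gwas_table[gwas_table["p"] < p_cut].copy() if len(gwas_table) else gwas_table.copy()
    assignments = []
    for _, s in snps.iterrows():
        hit = blocks[
            (blocks["chrom"] == s["chrom"])
            & (blocks["start"] <= s["pos"])
            & (s["pos"] < blocks["end"])
        ]
        assignments.append(hit["block_id"].iloc[0] if len(hit) else None)
    snps["block_id"] = assignments if len(snps) else pd.Series(dtype=object)
    snps = snps[snps["block_id"].notna()].reset_index(drop=True)
    gwas_blocks = blocks[blocks["block_id"].isin(snps["block_id"])].copy()
    counts = snps.groupby("block_id").size()
    gwas_blocks["n_snps"] = gwas_blocks["block_id"].map(counts).astype(int) if len(gwas_blocks) else 0
    total = sum(chrom_sizes.values())
    covered = int((gwas_blocks["end"] - gwas_blocks["start"]).sum()) if len(gwas_blocks) else 0
    stats = {
        "n_snps_retained": int(len(snps)),
        "n_distinct_blocks": int(len(gwas_blocks)),
        "genome_fraction": covered / total if total else 0.0,
    }
    return gwas_blocks.reset_index(drop=True), snps, stats


def windows_in_blocks(
    blocks: pd.DataFrame,
    window_size: int = 500,
    window_slide: int = 250,
    blacklist: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, int]:
    """Enumerate grid windows fully contained in blocks; drop blacklisted.

    Window starts sit on the global slide grid (multiples of
    ``window_slide``).  A window overlapping any blacklist interval by >=1 bp
    is removed.  Returns the window table (chrom, start, end, window_id,
    block_id) and the number of windows the blacklist removed.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if window_slide <= 0 or window_slide > window_size:
        raise ValueError("window_slide must be in (0, window_size]")
    rows = []
    for _, b in blocks.iterrows():
        start = -(-int(b["start"]) // window_slide) * window_slide
        while start + window_size <= b["end"]:
            rows.append((b["chrom"], start, start + window_size, b["block_id"]))
            start += window_slide
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "block_id"])
    windows["window_id"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(windows["chrom"], windows["start"], windows["end"])
    ]
    windows = windows[["chrom", "start", "end", "window_id", "block_id"]]
    n_removed = 0
    if blacklist is not None and len(blacklist) and len(windows):
        cov = coverage_fraction(windows, blacklist)
        keep = cov <= 0.0
        n_removed = int((~keep).sum())
        windows = windows[keep].reset_index(drop=True)
    return windows.reset_index(drop=True), n_removed


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals per chromosome (sorted, disjoint output)."""
    _check_intervals(df)
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def coverage_fraction(query: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Fraction of each query interval covered by the union of features."""
    _check_intervals(query, "query interval")
    _check_intervals(features, "feature interval")
    merged = merge_intervals(features)
    frac = np.zeros(len(query), dtype=float)
    for chrom, grp in merged.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        cum = np.concatenate([[0], np.cumsum(e - s)])
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        qs = query.loc[mask, "start"].to_numpy()
        qe = query.loc[mask, "end"].to_numpy()
        i = np.searchsorted(e, qs, side="right")   # first feature ending after qs
        j = np.searchsorted(s, qe, side="left")    # features starting before qe
        cov = cum[j] - cum[i]
        has = j > i
        # clip the partially-overlapping first/last merged feature
        left = np.where(has, np.maximum(0, qs - s[np.minimum(i, len(s) - 1)]), 0)
        right = np.where(has, np.maximum(0, e[np.maximum(j - 1, 0)] - qe), 0)
        cov = np.maximum(cov - left - right, 0)
        frac[mask] = cov / (qe - qs)
    return frac


def overlap(query: pd.DataFrame, features: pd.DataFrame, min_fraction: float) -> np.ndarray:
    """Boolean per query: covered fraction >= ``min_fraction`` (half-open).

    Boundary equality counts as a hit (e.g. a 50/500 bp overlap at f=0.1).
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    return coverage_fraction(query, features) >= min_fraction - _EPS
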