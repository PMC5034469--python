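"""a-DMR calling, summaries, replication concordance and probe validation.

Bonferroni-significant windows that overlap or are book-ended (0-bp gap)
AND share the sign of the age coefficient merge into discrete
age-associated differentially methylated regions (a-DMRs).  Mixed-sign
adjacency splits regions, so every a-DMR is purely hyper- or
hypomethylated with age.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["call_admrs", "summarise_admrs", "concordance", "probe_validation"]


def call_admrs(
    results: pd.DataFrame,
    threshold: float,
    cpg_positions: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge significant windows into a-DMRs.

    Parameters
    ----------
    results : per-window EWAS table with chrom, start, end, window_id,
        block_id, beta_age, p (and optionally status; failed fits are
        never significant because their p is NaN).
    threshold : Bonferroni p-value cut-off.
    cpg_positions : optional (chrom, pos) table used to count CpGs per region.

    Returns
    -------
    (admrs, members): the a-DMR table (chrom, start, end, admr_id,
    direction, n_windows, peak_p, n_cpgs, block_id) and the window
    membership map (admr_id, window_id).
    """
    cols = ["chrom", "start", "end", "admr_id", "direction", "n_windows",
            "peak_p", "n_cpgs", "block_id"]
    if len(results) == 0:
        return (pd.DataFrame(columns=cols),
                pd.DataFrame(columns=["admr_id", "window_id"]))
    sig = results[(results["p"] < threshold) & results["p"].notna()].copy()
    if len(sig) == 0:
        return (pd.DataFrame(columns=cols),
                pd.DataFrame(columns=["admr_id", "window_id"]))
    sig["direction"] = np.where(sig["beta_age"] > 0, "hyper", "hypo")
    sig = sig.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    regions = []
    cur = None
    for _, w in sig.iterrows():
        if (
            cur is not None
            and w["chrom"] == cur["chrom"]
            and w["start"] <= cur["end"]        # overlap or book-ended
            and w["direction"] == cur["direction"]
        ):
            cur["end"] = max(cur["end"], int(w["end"]))
            cur["windows"].append(w["window_id"])
            cur["peak_p"] = min(cur["peak_p"], float(w["p"]))
        else:
            if cur is not None:
                regions.append(cur)
            cur = dict(
                chrom=w["chrom"], start=int(w["start"]), end=int(w["end"]),
                direction=w["direction"], windows=[w["window_id"]],
                peak_p=float(w["p"]), block_id=w["block_id"],
            )
    regions.append(cur)

    rows, members = [], []
    for i, r in enumerate(regions):
        admr_id = f"aDMR{i + 1:03d}"
        n_cpgs = 0
        if cpg_positions is not None:
            pos = np.sort(
                cpg_positions.loc[cpg_positions["chrom"] == r["chrom"], "pos"].to_numpy()
            )
            n_cpgs = int(
                np.searchsorted(pos, r["end"], "left") - np.searchsorted(pos, r["start"], "left")
            )
        rows.append(
            dict(chrom=r["chrom"], start=r["start"], end=r["end"], admr_id=admr_id,
                 direction=r["direction"], n_windows=len(r["windows"]),
                 peak_p=r["peak_p"], n_cpgs=n_cpgs, block_id=r["block_id"])
        )
        members.extend({"admr_id": admr_id, "window_id": w} for w in r["windows"])
    return pd.DataFrame(rows, columns=cols), pd.DataFrame(members)


def summarise_admrs(admrs: pd.DataFrame) -> dict:
    """Counts, direction split, mean size (kb) and total CpGs."""
    n = len(admrs)
    if n == 0:
        return dict(n_admrs=0, n_hyper=0, n_hypo=0, frac_hyper=0.0, frac_hypo=0.0,
                    mean_size_kb=0.0, total_cpgs=0)
    n_hyper = int((admrs["direction"] == "hyper").sum())
    sizes = (admrs["end"] - admrs["start"]).to_numpy()
    return dict(
        n_admrs=n,
        n_hyper=n_hyper,
        n_hypo=n - n_hyper,
        frac_hyper=n_hyper / n,
        frac_hypo=(n - n_hyper) / n,
        mean_size_kb=float(sizes.mean() / 1000.0),
        total_cpgs=int(admrs["n_cpgs"].sum()),
    )


def concordance(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    members: pd.DataFrame,
    threshold: float,
    nominal_alpha: float = 0.05,
) -> dict:
    """Direction / nominal / Bonferroni concordance at window and DMR level.

    ``discovery`` holds only the Bonferroni-significant discovery windows;
    ``replication`` is matched by window_id.  A window missing from the
    replication set stays in the denominator and is flagged.  A DMR
    qualifies at a tier when at least one of its windows does.
    """
    if len(discovery) == 0:
        raise ValueError("empty discovery set")
    rep = replication.set_index("window_id")
    flags = []
    for _, w in discovery.iterrows():
        wid = w["window_id"]
        if wid not in rep.index or not np.isfinite(rep.loc[wid, "p"]):
            flags.append(dict(window_id=wid, missing=True, same_direction=False,
                              nominal=False, bonferroni=False))
            continue
        r = rep.loc[wid]
        same = np.sign(r["beta_age"]) == np.sign(w["beta_age"])
        flags.append(
            dict(window_id=wid, missing=False, same_direction=bool(same),
                 nominal=bool(same and r["p"] < nominal_alpha),
                 bonferroni=bool(same and r["p"] < threshold))
        )
    fl = pd.DataFrame(flags)
    out = dict(
        n_discovery_windows=int(len(fl)),
        n_missing=int(fl["missing"].sum()),
        n_same_direction=int(fl["same_direction"].sum()),
        n_nominal=int(fl["nominal"].sum()),
        n_bonferroni=int(fl["bonferroni"].sum()),
    )
    for tier in ("same_direction", "nominal", "bonferroni"):
        out[f"frac_{tier}"] = out[f"n_{tier}"] / out["n_discovery_windows"]
    if len(members):
        m = members.merge(fl, on="window_id", how="left").fillna(False)
        g = m.groupby("admr_id")
        out["n_admrs"] = int(g.ngroups)
        for tier in ("same_direction", "nominal", "bonferroni"):
            n_t = int(g[tier].any().sum())
            out[f"n_admr_{tier}"] = n_t
            out[f"frac_admr_{tier}"] = n_t / g.ngroups
    return out


def probe_validation(
    admrs: pd.DataFrame,
    probe_results: pd.DataFrame,
    nominal_alpha: float = 0.05,
    strict_p: float = 1e-7,
) -> pd.DataFrame:
    """Per-DMR validation against an independent per-site scan.

    ``probe_results`` carries chrom, pos, beta_age, p for array-style
    probes.  A DMR is ``validated_strict`` when a contained probe has the
    same direction and p < ``strict_p``, ``validated_nominal`` at
    p < ``nominal_alpha``, ``not_validated`` when probes exist but none
    qualifies, and ``no_coverage`` when no probe falls inside it.
    """
    rows = []
    for _, a in admrs.iterrows():
        inside = probe_results[
            (probe_results["chrom"] == a["chrom"])
            & (probe_results["pos"] >= a["start"])
            & (probe_results["pos"] < a["end"])
        ]
        sign = 1.0 if a["direction"] == "hyper" else -1.0
        same = inside[np.sign(inside["beta_age"]) == sign]
        if len(inside) == 0:
            status = "no_coverage"
        elif (same["p"] < strict_p).any():
            status = "validated_strict"
        elif (same["p"] < nominal_alpha).any():
            status = "validated_nominal"
        else:
            status = "not_validated"
        rows.append(dict(admr_id=a["admr_id"], n_probes=len(inside), status=status))
    return pd.DataFrame(rows)
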