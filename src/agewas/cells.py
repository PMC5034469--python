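"""Leukocyte-composition controls for the blood age-EWAS.

Peripheral blood is a mixture of cell types whose proportions drift with
age, so apparent methylation-age signal can be cell-composition artefact.
Two guards are implemented: (i) a monozygotic-twin blood-trait-discordance
EWAS (windows whose methylation tracks a blood-cell subtype trait within
genetically identical pairs), with the called a-DMRs then checked for
enrichment in such windows; and (ii) an overlap check of the a-DMRs
against a list of known leukocyte-subtype differentially methylated
positions (L-DMPs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import CELL_COLUMNS, inverse_normal

__all__ = [
    "window_nonzero_filter",
    "mz_discordance_test",
    "admr_bloodtrait_enrichment",
    "ldmp_overlap",
]


def window_nonzero_filter(values: pd.DataFrame, min_fraction: float = 0.9) -> pd.Index:
    """Window ids with >= ``min_fraction`` of samples non-zero (raw scale)."""
    arr = values.to_numpy()
    frac = (arr > 0).mean(axis=1)
    return values.index[frac >= min_fraction]


def _residual_design(cohort: pd.DataFrame) -> np.ndarray:
    """Intercept + smoking + leukocyte counts + age + batch (OLS adjustment)."""
    n = len(cohort)
    cols = [np.ones(n), cohort["age"].to_numpy(dtype=float)]
    for col in CELL_COLUMNS:
        cols.append(cohort[col].to_numpy(dtype=float))
    for col in ("smoking", "batch"):
        d = pd.get_dummies(cohort[col].astype(str), drop_first=True)
        cols.extend(d[c].to_numpy(dtype=float) for c in d.columns)
    return np.column_stack(cols)


def mz_discordance_test(
    values: pd.DataFrame,
    cohort: pd.DataFrame,
    trait: str,
) -> pd.DataFrame:
    """One-sided per-window test of methylation discordance in MZ pairs.

    For MZ pairs discordant for ``trait``: methylation is residualised on
    smoking, leukocyte counts, age and batch by OLS; residuals are
    rank-inverse-normal transformed per window (Blom offset 3/8); the
    high-minus-low twin differences are tested for positive mean with a
    paired one-sample one-sided t-test.

    One sample per individual is used (the first visit).  Pairs with zero
    trait discordance are dropped (the high/low ordering is undefined).
    """
    mz = cohort[cohort["zygosity"] == "MZ"].copy()
    mz = mz.sort_values(["pair_id", "individual_id", "sample_id"])
    mz = mz.drop_duplicates("individual_id", keep="first")
    sizes = mz.groupby("pair_id")["individual_id"].nunique()
    full_pairs = sizes[sizes == 2].index
    mz = mz[mz["pair_id"].isin(full_pairs)]

    hi_ids, lo_ids = [], []
    for _, grp in mz.groupby("pair_id"):
        t = grp[trait].to_numpy()
        if t[0] == t[1]:
            continue
        order = np.argsort(t)
        lo_ids.append(grp["sample_id"].iloc[order[0]])
        hi_ids.append(grp["sample_id"].iloc[order[1]])
    if len(hi_ids) < 3:
        raise ValueError("need >=3 discordant MZ pairs")

    used = hi_ids + lo_ids
    sub = cohort.set_index("sample_id").loc[used].reset_index()
    X = _residual_design(sub)
    Y = values[used].to_numpy(dtype=float).T        # samples x windows
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]
    resid = Y - X @ beta                             # samples x windows
    normed = np.apply_along_axis(inverse_normal, 0, resid)
    k = len(hi_ids)
    d = normed[:k] - normed[k:]                      # pairs x windows
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p = stats.ttest_1samp(d, 0.0, axis=0, alternative="greater")
    # degenerate windows: every pair difference exactly zero
    zero = (d == 0).all(axis=0)
    t_stat = np.where(zero, 0.0, t_stat)
    p = np.where(zero, 0.5, p)
    return pd.DataFrame({"t": t_stat, "p": p}, index=values.index)


def admr_bloodtrait_enrichment(
    blood_pvals: pd.DataFrame,
    admr_window_ids,
    alpha: float = 0.05,
) -> dict:
    """Are a-DMR windows enriched for blood-trait signal?

    A window counts as blood-associated when its minimum p over the six
    traits is below ``alpha``.  The 2x2 chi-square (continuity-corrected)
    compares a-DMR windows against all other tested windows.
    """
    admr_ids = pd.Index(admr_window_ids).intersection(blood_pvals.index)
    if len(admr_ids) == 0:
        raise ValueError("no a-DMR windows among the tested windows")
    hot = (blood_pvals.min(axis=1) < alpha)
    in_admr = blood_pvals.index.isin(admr_ids)
    a = int((hot & in_admr).sum())
    b = int((~hot & in_admr).sum())
    c = int((hot & ~in_admr).sum())
    d = int((~hot & ~in_admr).sum())
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        chi2_stat, chi2_p = 0.0, 1.0
    else:
        chi2_stat, chi2_p, _, _ = stats.chi2_contingency(table, correction=True)[:4]
    return dict(
        frac_all=float(hot.mean()),
        frac_admr=float(hot[in_admr].mean()),
        frac_background=float(hot[~in_admr].mean()) if (~in_admr).any() else float("nan"),
        n_admr_windows=int(in_admr.sum()),
        n_windows=int(len(hot)),
        chi2_stat=float(chi2_stat),
        chi2_p=float(chi2_p),
    )


def ldmp_overlap(admrs: pd.DataFrame, ldmp: pd.DataFrame) -> int:
    """Number of a-DMRs containing >=1 L-DMP position (half-open)."""
    if len(ldmp) == 0 or len(admrs) == 0:
        return 0
    count = 0
    for _, a in admrs.iterrows():
        inside = ldmp[
            (ldmp["chrom"] == a["chrom"])
            & (ldmp["pos"] >= a["start"])
            & (ldmp["pos"] < a["end"])
        ]
        count += int(len(inside) > 0)
    return count
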