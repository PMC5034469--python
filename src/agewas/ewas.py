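"""Per-window age EWAS with a nested-intercept linear mixed model.

Each 500-bp window's normalised methylation score is regressed on
chronological age with fixed-effect adjustment for the LD block's
haplotype-tagging SNP allelic count, smoking status, batch and four
leukocyte fractions, and random intercepts for family and twin pair.
Significance of the age term (and, separately, of an age x genotype
interaction) comes from a likelihood-ratio test between ML fits of the
full and the reduced model, referred to chi-square with 1 df.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import NestedStructure, fit_nested_lmm

__all__ = [
    "normalise",
    "bonferroni_threshold",
    "build_design",
    "run_ewas",
    "run_interaction",
    "CELL_COLUMNS",
]

CELL_COLUMNS = ["lymphocyte", "monocyte", "neutrophil", "eosinophil"]


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def inverse_normal(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom offset, average ties)."""
    v = np.asarray(values, dtype=float)
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - offset) / (len(v) - 2 * offset + 1))


def normalise(values: pd.DataFrame, method: str = "zscore"):
    """Per-window normalisation of a windows x samples score matrix.

    ``zscore`` centres and scales each window to mean 0, sd 1 (ddof=1, the
    R ``scale()`` convention); ``inverse_normal`` maps ranks to normal
    quantiles.  Zero-variance windows cannot be normalised: they are
    dropped from the returned matrix and reported in the flag list.

    Returns ``(normalised, flagged_window_ids)``.
    """
    if method not in ("zscore", "inverse_normal"):
        raise ValueError(f"unknown normalisation method: {method}")
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    flagged = values.index[sd == 0].tolist()
    keep = sd > 0
    if method == "zscore":
        out = (arr[keep] - arr[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    else:
        out = np.vstack([inverse_normal(row) for row in arr[keep]]) if keep.any() else arr[keep]
    normed = pd.DataFrame(out, index=values.index[keep], columns=values.columns)
    return normed, flagged


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance cut-off alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(
    cohort: pd.DataFrame,
    genotype: np.ndarray | None = None,
    covariates: str = "full",
    interaction: bool = False,
):
    """Fixed-effect design matrix for one window's model.

    ``covariates='full'`` gives intercept + age + SNP allelic count +
    smoking + batch + the four leukocyte fractions (the discovery model);
    ``'reduced'`` gives intercept + age + batch only (the replication
    model, which lacks genotype, smoking and leukocyte data).  With
    ``interaction=True`` an age x genotype column is appended.

    Age is mean-centred for conditioning; this leaves the age coefficient
    and every likelihood ratio unchanged.
    """
    n = len(cohort)
    age_c = cohort["age"].to_numpy(dtype=float)
    age_c = age_c - age_c.mean()
    cols = [np.ones(n), age_c]
    names = ["intercept", "age"]
    if covariates == "full":
        if genotype is not None:
            cols.append(np.asarray(genotype, dtype=float))
            names.append("snp")
        for col, prefix in (("smoking", "smoking"), ("batch", "batch")):
            dummies = pd.get_dummies(cohort[col].astype(str), prefix=prefix, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(c)
        for c in CELL_COLUMNS:
            cols.append(cohort[c].to_numpy(dtype=float))
            names.append(c)
    elif covariates == "reduced":
        dummies = pd.get_dummies(cohort["batch"].astype(str), prefix="batch", drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(c)
    else:
        raise ValueError(f"unknown covariate set: {covariates}")
    if interaction:
        if genotype is None:
            raise ValueError("interaction model requires genotype")
        cols.append(age_c * np.asarray(genotype, dtype=float))
        names.append("age_x_snp")
    return np.column_stack(cols), names


def _lrt(ll_full: float, ll_null: float) -> tuple[float, float]:
    stat = 2.0 * (ll_full - ll_null)
    if stat < -1e-6:
        stat = 0.0
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# per-window scans
# ---------------------------------------------------------------------------

def run_ewas(
    values: pd.DataFrame,
    windows: pd.DataFrame,
    cohort: pd.DataFrame,
    genotypes: pd.DataFrame | None = None,
    covariates: str = "full",
) -> pd.DataFrame:
    """Likelihood-ratio age scan over every window in ``values``.

    ``values`` is the normalised windows x samples matrix (columns must
    match ``cohort['sample_id']``), ``windows`` carries coordinates and the
    enclosing ``block_id`` per window, ``genotypes`` the samples x blocks
    allelic-count table used for the SNP covariate.

    Returns one row per window with the age coefficient, log-likelihoods,
    LRT statistic and p-value, variance components and a status flag.
    Failed fits are flagged but kept (they stay in the Bonferroni
    denominator).
    """
    cohort = cohort.set_index("sample_id").loc[list(values.columns)].reset_index()
    struct = NestedStructure(cohort["family_id"].to_numpy(), cohort["pair_id"].to_numpy())
    win = windows.set_index("window_id")
    designs: dict = {}
    rows = []
    for window_id, y in values.iterrows():
        info = win.loc[window_id]
        block = info["block_id"]
        if block not in designs:
            geno = (
                genotypes.loc[cohort["sample_id"], block].to_numpy()
                if (genotypes is not None and covariates == "full")
                else None
            )
            Xf, names_f = build_design(cohort, geno, covariates=covariates)
            age_ix = names_f.index("age")
            Xn = np.delete(Xf, age_ix, axis=1)
            designs[block] = (Xf, names_f, Xn)
        Xf, names_f, Xn = designs[block]
        yv = y.to_numpy(dtype=float)
        status = "ok"
        try:
            full = fit_nested_lmm(Xf, yv, struct, names=names_f)
            null = fit_nested_lmm(Xn, yv, struct)
            stat, p = _lrt(full.loglik, null.loglik)
            if not (full.converged and null.converged):
                status = "failed"
            rows.append(
                dict(
                    window_id=window_id,
                    chrom=info["chrom"],
                    start=int(info["start"]),
                    end=int(info["end"]),
                    block_id=block,
                    beta_age=full.coef("age"),
                    se_age=full.coef_se("age"),
                    ll_full=full.loglik,
                    ll_null=null.loglik,
                    lrt_stat=stat,
                    p=p,
                    vc_family=full.sigma2_family,
                    vc_pair=full.sigma2_pair,
                    vc_resid=full.sigma2_resid,
                    n=full.n,
                    status=status,
                )
            )
        except Exception:  # noqa: BLE001 - a bad window must not kill the scan
            rows.append(
                dict(
                    window_id=window_id,
                    chrom=info["chrom"],
                    start=int(info["start"]),
                    end=int(info["end"]),
                    block_id=block,
                    beta_age=np.nan,
                    se_age=np.nan,
                    ll_full=np.nan,
                    ll_null=np.nan,
                    lrt_stat=np.nan,
                    p=np.nan,
                    vc_family=np.nan,
                    vc_pair=np.nan,
                    vc_resid=np.nan,
                    n=struct.n,
                    status="failed",
                )
            )
    return pd.DataFrame(rows)


def run_interaction(
    values: pd.DataFrame,
    windows: pd.DataFrame,
    cohort: pd.DataFrame,
    genotypes: pd.DataFrame,
) -> pd.DataFrame:
    """Age x genotype interaction scan (1-df LRT vs the full model)."""
    cohort = cohort.set_index("sample_id").loc[list(values.columns)].reset_index()
    struct = NestedStructure(cohort["family_id"].to_numpy(), cohort["pair_id"].to_numpy())
    win = windows.set_index("window_id")
    designs: dict = {}
    rows = []
    for window_id, y in values.iterrows():
        info = win.loc[window_id]
        block = info["block_id"]
        if block not in designs:
            geno = genotypes.loc[cohort["sample_id"], block].to_numpy()
            if np.ptp(geno) == 0:
                designs[block] = None  # monomorphic: interaction inestimable
            else:
                Xf, names_f = build_design(cohort, geno, covariates="full")
                Xi, names_i = build_design(cohort, geno, covariates="full", interaction=True)
                designs[block] = (Xf, Xi, names_i)
        entry = designs[block]
        if entry is None:
            rows.append(
                dict(window_id=window_id, block_id=block, beta_interaction=np.nan,
                     lrt_stat=np.nan, p=np.nan, status="monomorphic")
            )
            continue
        Xf, Xi, names_i = entry
        yv = y.to_numpy(dtype=float)
        try:
            full = fit_nested_lmm(Xf, yv, struct)
            inter = fit_nested_lmm(Xi, yv, struct, names=names_i)
            stat, p = _lrt(inter.loglik, full.loglik)
            status = "ok" if (full.converged and inter.converged) else "failed"
            rows.append(
                dict(window_id=window_id, block_id=block,
                     beta_interaction=inter.coef("age_x_snp"),
                     lrt_stat=stat, p=p, status=status)
            )
        except Exception:  # noqa: BLE001
            rows.append(
                dict(window_id=window_id, block_id=block, beta_interaction=np.nan,
                     lrt_stat=np.nan, p=np.nan, status="failed")
            )
    return pd.DataFrame(rows)
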