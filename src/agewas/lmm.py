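"""Linear mixed model with nested family/pair random intercepts.

The model is

    y = X beta + a_family + b_pair + e,
    a ~ N(0, s2_f),  b ~ N(0, s2_p),  e ~ N(0, s2_e),

with twin pairs nested in families (singletons form their own pair).  This
is the per-window model of the age EWAS: twin resemblance enters through
the two random intercepts, and fixed-effect likelihood-ratio tests require
maximum-likelihood (not REML) fitting, which is what this module does.

Fitting profiles out beta and s2_e, leaving a 2-parameter problem in the
variance ratios gamma = (s2_f/s2_e, s2_p/s2_e).  For this nested structure
the marginal covariance has a closed-form inverse: within each pair the
compound-symmetry block inverts analytically, and the family intercept adds
a rank-one Woodbury correction.  Every objective evaluation is therefore
O(n p) with segment sums, which is what makes testing thousands of windows
per run affordable on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["NestedStructure", "LmmFit", "fit_nested_lmm", "drop_aliased"]

_LOG2PI = np.log(2.0 * np.pi)


class NestedStructure:
    """Precomputed grouping for samples with pair-within-family intercepts.

    Parameters are label arrays (one entry per sample).  Samples are
    internally re-ordered so that pairs and families are contiguous; use
    :attr:`order` to map design rows into the internal order.
    """

    def __init__(self, family, pair):
        family = np.asarray(family)
        pair = np.asarray(pair)
        if family.shape != pair.shape:
            raise ValueError("family and pair labels must align")
        order = np.lexsort((pair, family))
        self.order = order
        fam_sorted = family[order]
        pair_sorted = pair[order]
        # pair boundaries in sample space
        key = np.array([f"{f}\x00{p}" for f, p in zip(fam_sorted, pair_sorted)])
        new_pair = np.concatenate([[True], key[1:] != key[:-1]])
        self.pair_starts = np.flatnonzero(new_pair)
        self.pair_sizes = np.diff(np.append(self.pair_starts, len(key)))
        # family boundaries in pair space
        fam_of_pair = fam_sorted[self.pair_starts]
        new_fam = np.concatenate([[True], fam_of_pair[1:] != fam_of_pair[:-1]])
        self.fam_starts_pairspace = np.flatnonzero(new_fam)
        fam_sizes_pairs = np.diff(
            np.append(self.fam_starts_pairspace, len(fam_of_pair))
        )
        # family sizes in sample space, for broadcasting
        self.fam_sizes_samples = np.add.reduceat(
            self.pair_sizes, self.fam_starts_pairspace
        )
        self.n = len(key)
        self.n_pairs = len(self.pair_starts)
        self.n_families = len(self.fam_starts_pairspace)
        self._fam_sizes_pairs = fam_sizes_pairs

    # --- whitening -------------------------------------------------------
    def apply_vinv(self, M: np.ndarray, gamma_f: float, gamma_p: float):
        """Return (V^{-1} M, log|V|) for V = I + g_f Z_f Z_f' + g_p Z_p Z_p'.

        ``M`` must already be in the internal sample order.
        """
        m = self.pair_sizes.astype(float)
        c = gamma_p / (1.0 + m * gamma_p)          # per pair
        u = 1.0 / (1.0 + m * gamma_p)              # (A^{-1} 1)_i within pair
        ps = np.add.reduceat(M, self.pair_starts, axis=0)       # pair sums
        AinvM = M - np.repeat(c[:, None] * ps, self.pair_sizes, axis=0)
        # family-level rank-one correction
        t = np.add.reduceat(u[:, None] * ps, self.fam_starts_pairspace, axis=0)
        s = np.add.reduceat(m * u, self.fam_starts_pairspace)
        w = gamma_f / (1.0 + gamma_f * s)
        u_sample = np.repeat(u, self.pair_sizes)
        corr = np.repeat(w[:, None] * t, self.fam_sizes_samples, axis=0)
        VinvM = AinvM - u_sample[:, None] * corr
        logdet = float(
            np.sum(np.log1p(m * gamma_p)) + np.sum(np.log1p(gamma_f * s))
        )
        return VinvM, logdet


@dataclass
class LmmFit:
    """ML fit of the nested-intercept LMM."""

    beta: np.ndarray
    se: np.ndarray
    names: list
    loglik: float
    sigma2_resid: float
    sigma2_family: float
    sigma2_pair: float
    converged: bool
    n: int
    dropped: list = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.names.index(name)])


def drop_aliased(X: np.ndarray, names: list, tol: float = 1e-8):
    """Drop linearly dependent columns (pivoted QR); returns (X, names, dropped)."""
    if X.shape[1] == 0:
        return X, list(names), []
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    thresh = tol * max(diag[0], 1.0)
    rank = int((diag > thresh).sum())
    keep = np.sort(piv[:rank])
    dropped = [names[i] for i in piv[rank:]]
    return X[:, keep], [names[i] for i in keep], dropped


def _profiled_nll(gamma, X, y, struct):
    Z = np.column_stack([X, y])
    VZ, logdet = struct.apply_vinv(Z, gamma[0], gamma[1])
    p = X.shape[1]
    XtVX = X.T @ VZ[:, :p]
    XtVy = X.T @ VZ[:, p]
    ytVy = float(y @ VZ[:, p])
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtVX, XtVy, rcond=None)[0]
    rss = max(ytVy - float(beta @ XtVy), 1e-300)
    n = struct.n
    sigma2 = rss / n
    nll = 0.5 * (n * (_LOG2PI + np.log(sigma2)) + logdet + n)
    return nll, beta, sigma2, XtVX


def fit_nested_lmm(
    X: np.ndarray,
    y: np.ndarray,
    struct: NestedStructure,
    names: list | None = None,
    fix_gamma: tuple | None = None,
    gamma_bound: float = 100.0,
) -> LmmFit:
    """Fit the nested-intercept LMM by profiled maximum likelihood.

    Parameters
    ----------
    X, y : design matrix and response in the caller's sample order; they
        are re-ordered internally with ``struct.order``.
    struct : NestedStructure built from the same samples.
    names : column names for the coefficient table.
    fix_gamma : optionally pin the variance ratios (s2_f/s2_e, s2_p/s2_e)
        instead of estimating them; ``(0, 0)`` reduces the fit to OLS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    X, names, dropped = drop_aliased(X, list(names))
    Xo = X[struct.order]
    yo = y[struct.order]

    if fix_gamma is not None:
        gamma = np.asarray(fix_gamma, dtype=float)
        converged = True
    else:
        def obj(g):
            return _profiled_nll(g, Xo, yo, struct)[0]

        res = optimize.minimize(
            obj,
            x0=np.array([0.1, 0.1]),
            method="L-BFGS-B",
            bounds=[(0.0, gamma_bound)] * 2,
        )
        gamma = res.x
        converged = bool(res.success)
        if not converged:
            # the profiled likelihood has a flat ridge when families and
            # pairs nearly coincide; a derivative-free polish settles it
            res2 = optimize.minimize(
                obj, x0=np.clip(res.x, 0.0, gamma_bound), method="Nelder-Mead",
                bounds=[(0.0, gamma_bound)] * 2,
            )
            if res2.fun <= res.fun + 1e-8:
                gamma = res2.x
                converged = True
        # the boundary (0,0) is a kink of the parameterisation; accept it
        # whenever it is at least as good as the interior optimum
        nll0 = obj(np.zeros(2))
        if nll0 <= res.fun + 1e-10:
            gamma = np.zeros(2)
            converged = True

    nll, beta, sigma2, XtVX = _profiled_nll(gamma, Xo, yo, struct)
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return LmmFit(
        beta=beta,
        se=se,
        names=names,
        loglik=-nll,
        sigma2_resid=sigma2,
        sigma2_family=float(gamma[0] * sigma2),
        sigma2_pair=float(gamma[1] * sigma2),
        converged=converged,
        n=struct.n,
        dropped=dropped,
    )
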