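"""Phylogenetic signal statistics for continuous traits.

Blomberg's K compares the observed ratio of trait variance to phylogenetically
corrected mean squared error against its Brownian-motion expectation; K = 1
matches BM, K < 1 indicates less resemblance among relatives than BM predicts
(variance within clades), K > 1 more (variance between clades).  Significance
comes from a tip-label randomization test.

Pagel's lambda scales the off-diagonal phylogenetic covariances; it is
estimated by maximum likelihood on [0, 1] and tested against lambda = 0 with a
one-degree-of-freedom likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from ._gls import align_trait, gls_mean, ml_lnl
from .trees import Phylo, transform_vcv, vcv

__all__ = ["SignalResult", "blomberg_k", "pagel_lambda", "signal_table"]


@dataclass
class SignalResult:
    K: float
    p_K: float
    n_perm: int
    lambda_hat: float
    logL: float
    logL0: float
    p_lambda: float


def _k_stat(C: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Blomberg's K and the phylogenetic MSE for one trait vector."""
    n = len(x)
    a, cf = gls_mean(C, x)
    r = x - a
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ cho_solve(cf, r)) / (n - 1)
    one = np.ones(n)
    denom = float(one @ cho_solve(cf, one))
    expected = (np.trace(C) - n / denom) / (n - 1)
    return (mse0 / mse) / expected, mse


def blomberg_k(tree: Phylo, x, n_perm: int = 1000, seed=None) -> tuple[float, float]:
    """Blomberg's K with a tip-label permutation test.

    The permutation p-value is the lower-tail proportion of permuted datasets
    whose phylogenetic MSE is <= the observed MSE (true signal lowers the
    MSE); the observed dataset is counted in the null set.
    """
    xv = align_trait(tree, x)
    n = len(xv)
    if n < 4:
        raise ValueError("need at least 4 tips")
    C = vcv(tree).C
    K, mse_obs = _k_stat(C, xv)

    # MSE under permutation, vectorized: mse = (xp - a)' C^-1 (xp - a)
    a, cf = gls_mean(C, xv)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    X = xv[perms]                                 # (n_perm, n)
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    s11 = float(one @ Ci1)
    A = (X @ Ci1) / s11                            # GLS mean per permutation
    R = X - A[:, None]
    CiR = cho_solve(cf, R.T).T
    mses = np.einsum("ij,ij->i", R, CiR) / (n - 1)
    p = (1 + int(np.sum(mses <= mse_obs + 1e-12))) / (n_perm + 1)
    return float(K), float(p)


def pagel_lambda(tree: Phylo, x, lam_max: float = 1.0) -> tuple[float, float, float, float]:
    """ML estimate of Pagel's lambda with a likelihood-ratio test vs lambda=0.

    Returns ``(lambda_hat, logL, logL0, p)`` where p is the chi-square(1)
    upper tail of ``2 * (logL - logL0)``.
    """
    xv = align_trait(tree, x)
    C0 = vcv(tree)

    def negll(lam: float) -> float:
        Cl = transform_vcv(C0, "lambda", {"lam": lam}).C
        return -ml_lnl(Cl, xv)[0]

    # coarse grid to bracket, then bounded refinement (profile can be multimodal)
    grid = np.linspace(0.0, lam_max, 21)
    vals = [negll(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo == hi:
        lam_hat, fbest = grid[i], vals[i]
    else:
        res = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        lam_hat, fbest = float(res.x), float(res.fun)
        if vals[i] < fbest:  # guard against optimizer landing above a grid point
            lam_hat, fbest = float(grid[i]), float(vals[i])
    logl = -fbest
    logl0 = -negll(0.0)
    if logl < logl0:
        lam_hat, logl = 0.0, logl0
    lr = max(2.0 * (logl - logl0), 0.0)
    p = float(chi2.sf(lr, df=1)) if lr > 0 else 1.0
    return float(lam_hat), float(logl), float(logl0), p


def signal_table(tree: Phylo, traits, n_perm: int = 1000, seed=None):
    """Per-variable signal summary (one row per trait column).

    ``traits`` is a DataFrame (rows = species, columns = variables).  Returns
    a DataFrame with columns layer, K, p_K, lambda, logL, logL0, p_lambda.
    """
    import pandas as pd

    rows = []
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for col, sub in zip(traits.columns, ss.spawn(len(traits.columns))):
        x = traits[col]
        K, pK = blomberg_k(tree, x, n_perm=n_perm, seed=sub)
        lam, logl, logl0, pl = pagel_lambda(tree, x)
        rows.append({"layer": col, "K": K, "p_K": pK, "lambda": lam,
                     "logL": logl, "logL0": logl0, "p_lambda": pl})
    return pd.DataFrame(rows)
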