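"""Internal Gaussian/GLS helpers shared by signal, evomodels, pno and ppca."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .trees import Phylo


def align_trait(tree: Phylo, x) -> np.ndarray:
    """Coerce a trait vector (Series/dict/array) into tip order; validate labels."""
    if isinstance(x, pd.Series):
        x = x.to_dict()
    if isinstance(x, dict):
        missing = [t for t in tree.tip_labels if t not in x]
        if missing:
            raise ValueError(f"trait values missing for tips: {missing}")
        return np.array([float(x[t]) for t in tree.tip_labels])
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size != tree.n_tips:
        raise ValueError(f"trait length {arr.size} != number of tips {tree.n_tips}")
    return arr


def gls_mean(C: np.ndarray, x: np.ndarray):
    """GLS phylogenetic mean (1'C^-1 1)^-1 1'C^-1 x; also returns the solve factor."""
    try:
        cf = cho_factor(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance matrix is singular; jitter zero-length branches"
        ) from exc
    one = np.ones(len(x))
    Ci1 = cho_solve(cf, one)
    a = float(one @ cho_solve(cf, x)) / float(one @ Ci1)
    return a, cf


def ml_lnl(C: np.ndarray, x: np.ndarray):
    """Profiled ML log-likelihood of MVN(z0*1, sigma2*C) over z0 and sigma2.

    The rate uses the pure-ML (1/n) denominator so values are comparable
    across models.  Returns (lnL, z0_hat, sigma2_hat).
    """
    n = len(x)
    a, cf = gls_mean(C, x)
    r = x - a
    q = float(r @ cho_solve(cf, r))
    sigma2 = q / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    lnl = -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * logdet - 0.5 * n
    return float(lnl), float(a), float(sigma2)
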