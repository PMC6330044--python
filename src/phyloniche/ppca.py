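"""Phylogenetic and ordinary principal component analysis of niche traits.

Phylogenetic PCA eigendecomposes the evolutionary (GLS) covariance of the
species-by-variable matrix — data are centered on the phylogenetic mean and
the covariance is weighted by the inverse of the Brownian-motion phylogenetic
covariance — so scores are comparable under the assumption that all variables
evolved by multivariate BM.  With a star phylogeny it reduces exactly to
ordinary covariance PCA.  Ordinary PCA (correlation-mode by default, since
bioclimatic variables have incommensurate units) is provided for
non-phylogenetic ordination; the scores of either can be fed back to the
signal and model-fitting analyses as univariate traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .trees import Phylo, vcv

__all__ = ["PPCAResult", "phylo_pca", "ordinary_pca"]


@dataclass
class PPCAResult:
    mean: pd.Series                      # (phylogenetic) mean per variable
    R: pd.DataFrame = field(repr=False)  # (evolutionary) covariance
    eigenvalues: np.ndarray = field(repr=False)
    loadings: pd.DataFrame = field(repr=False)   # variables x components
    scores: pd.DataFrame = field(repr=False)     # species x components
    explained: np.ndarray = field(repr=False)    # variance fractions


def _eig_result(Xc: np.ndarray, R: np.ndarray, mean: np.ndarray,
                index, columns) -> PPCAResult:
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12
    if not pos.all():
        warnings.warn(f"rank-deficient covariance: keeping {int(pos.sum())} of "
                      f"{len(evals)} components", stacklevel=3)
        evals, evecs = evals[pos], evecs[:, pos]
    # orient each component so its largest-magnitude loading is positive
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    comp = [f"PC{j + 1}" for j in range(evecs.shape[1])]
    scores = Xc @ evecs
    return PPCAResult(
        mean=pd.Series(mean, index=columns),
        R=pd.DataFrame(R, index=columns, columns=columns),
        eigenvalues=evals,
        loadings=pd.DataFrame(evecs, index=columns, columns=comp),
        scores=pd.DataFrame(scores, index=index, columns=comp),
        explained=evals / evals.sum(),
    )


def phylo_pca(tree: Phylo, X: pd.DataFrame) -> PPCAResult:
    """Phylogenetic PCA of a species-by-variable matrix (covariance mode).

    The phylogenetic mean is ``a = (1'C^-1 1)^-1 1'C^-1 X`` and the
    evolutionary covariance ``R = (X-1a)' C^-1 (X-1a) / (n-1)`` with C the BM
    phylogenetic covariance; scores are the centered data projected on R's
    eigenvectors.
    """
    missing = [t for t in tree.tip_labels if t not in X.index]
    if missing:
        raise ValueError(f"trait matrix missing species: {missing}")
    X = X.loc[tree.tip_labels]
    if X.isna().any().any():
        raise ValueError("trait matrix contains missing values")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    Xv = X.to_numpy(dtype=float)
    n = len(Xv)
    C = vcv(tree).C
    cf = cho_factor(C)
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    a = (Xv.T @ Ci1) / (one @ Ci1)
    Xc = Xv - a
    R = Xc.T @ cho_solve(cf, Xc) / (n - 1)
    return _eig_result(Xc, R, a, X.index, X.columns)


def ordinary_pca(X: pd.DataFrame, standardize: bool = True) -> PPCAResult:
    """Ordinary PCA; correlation-mode (standardized variables) by default."""
    if X.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if X.isna().any().any():
        raise ValueError("trait matrix contains missing values")
    Xv = X.to_numpy(dtype=float)
    mean = Xv.mean(axis=0)
    Xc = Xv - mean
    if standardize:
        sd = Xv.std(axis=0, ddof=1)
        if np.any(sd == 0):
            degenerate = [c for c, s in zip(X.columns, sd) if s == 0]
            raise ValueError(f"constant variables cannot be standardized: {degenerate}")
        Xc = Xc / sd
    R = Xc.T @ Xc / (len(Xv) - 1)
    return _eig_result(Xc, R, mean, X.index, X.columns)
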