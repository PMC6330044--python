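"""Predicted niche occupancy (PNO) profiles and ancestral climatic tolerances.

A PNO profile is the unit-area histogram of an environmental variable weighted
by modeled suitability: the fraction of a species' total suitability that
falls in each climate bin.  Its weighted mean is the species' climatic trait
value used by the signal and model-fitting analyses.  Ancestral tolerances are
reconstructed by repeatedly drawing one climate value per species from its PNO
and applying the maximum-likelihood (GLS) Brownian-motion ancestral-state
estimator, giving per-node sampling distributions summarized by mean and 80%
central interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve

from ._gls import align_trait, gls_mean
from .grids import GridLayer
from .trees import Phylo, vcv

__all__ = ["PNOProfile", "AncestralTolerance", "compute_pno", "pno_weighted_mean",
           "ancestral_states_bm", "ancestral_tolerance"]


@dataclass
class PNOProfile:
    variable: str
    species: str
    centers: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if np.any(self.mass < 0) or not np.isclose(self.mass.sum(), 1.0, atol=1e-9):
            raise ValueError("mass must be non-negative and sum to 1")

    def quantile(self, q) -> np.ndarray:
        cdf = np.cumsum(self.mass)
        return self.centers[np.searchsorted(cdf, np.atleast_1d(q), side="left").clip(0, len(self.centers) - 1)]

    def central_interval(self, level: float = 0.8) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = self.quantile([a, 1.0 - a])
        return float(lo), float(hi)


@dataclass
class AncestralTolerance:
    node_ids: list[int]
    samples: np.ndarray = field(repr=False)   # (n_iter, n_internal)
    mean: np.ndarray = field(repr=False)
    lo80: np.ndarray = field(repr=False)
    hi80: np.ndarray = field(repr=False)
    tip_summary: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node_id": self.node_ids, "mean": self.mean,
                             "lo80": self.lo80, "hi80": self.hi80})


def compute_pno(climate: GridLayer, suitability: GridLayer, n_bins: int = 50,
                vmin: float | None = None, vmax: float | None = None,
                variable: str = "", species: str = "") -> PNOProfile:
    """PNO profile of ``climate`` weighted by ``suitability``.

    Bin centers are ``n_bins`` equally spaced evaluation points spanning
    [vmin, vmax] (default: the climate layer's valid range); each valid cell
    contributes its suitability to the nearest center.  Pass a common
    vmin/vmax per variable to make profiles comparable across species.
    """
    if not climate.aligned_with(suitability):
        raise ValueError("climate and suitability layers are not aligned")
    m = climate.valid_mask() & suitability.valid_mask()
    cvals = climate.values[m]
    svals = suitability.values[m]
    if np.any((svals < 0) | (svals > 1)):
        raise ValueError("suitability values must lie in [0, 1]")
    tot = svals.sum()
    if tot <= 0:
        raise ValueError("suitability is zero everywhere; PNO undefined")
    vmin = float(cvals.min()) if vmin is None else float(vmin)
    vmax = float(cvals.max()) if vmax is None else float(vmax)
    if vmax <= vmin:
        raise ValueError("degenerate climate range (vmax <= vmin)")
    centers = np.linspace(vmin, vmax, n_bins)
    width = centers[1] - centers[0]
    idx = np.clip(np.round((cvals - vmin) / width).astype(int), 0, n_bins - 1)
    mass = np.bincount(idx, weights=svals, minlength=n_bins) / tot
    return PNOProfile(variable=variable, species=species, centers=centers, mass=mass)


def pno_weighted_mean(profile: PNOProfile) -> float:
    """Suitability-weighted climatic mean: sum of center * mass."""
    return float(np.dot(profile.centers, profile.mass))


def _node_tip_cov(tree: Phylo) -> np.ndarray:
    """Shared path length between each internal node and each tip."""
    depths = tree.depths()
    n = tree.n_tips
    internal = tree.internal_nodes
    S = np.zeros((len(internal), n))
    for r, k in enumerate(internal):
        desc = set(tree.clade_tips(k))
        for i in range(n):
            if i in desc:
                S[r, i] = depths[k]
            else:
                S[r, i] = depths[tree.mrca([k, i])]
    return S


def ancestral_operator(tree: Phylo) -> np.ndarray:
    """Linear map A with ancestral states = A @ tip_values (BM/GLS estimator).

    a_hat = z0 + S C^-1 (x - z0*1) with z0 the GLS phylogenetic mean; both
    terms are linear in x, so the whole reconstruction is one matrix product.
    Rows follow ``tree.internal_nodes`` order (root last).
    """
    C = vcv(tree).C
    n = tree.n_tips
    one = np.ones(n)
    _, cf = gls_mean(C, one)  # factor only; mean of ones is 1
    Ci1 = cho_solve(cf, one)
    g = Ci1 / (one @ Ci1)                       # z0 = g' x
    S = _node_tip_cov(tree)
    SCi = cho_solve(cf, S.T).T
    A = np.outer(np.ones(S.shape[0]), g) + SCi @ (np.eye(n) - np.outer(one, g))
    return A


def ancestral_states_bm(tree: Phylo, x) -> dict[int, float]:
    """ML (GLS) ancestral states under Brownian motion, per internal node.

    Equals the conditional mean of the joint BM Gaussian given the tips, with
    the root state set to the GLS phylogenetic mean.
    """
    xv = align_trait(tree, x)
    A = ancestral_operator(tree)
    vals = A @ xv
    return {k: float(v) for k, v in zip(tree.internal_nodes, vals)}


def ancestral_tolerance(tree: Phylo, profiles: dict[str, PNOProfile],
                        n_iter: int = 1000, seed=None,
                        level: float = 0.8) -> AncestralTolerance:
    """Monte-Carlo ancestral tolerance reconstruction from PNO profiles.

    Each iteration draws one climate value per species from its PNO mass and
    reconstructs all internal-node states under BM; summaries are the
    per-node sample mean and central ``level`` interval.  Tips are summarized
    by their own PNO mean and central density.
    """
    missing = [t for t in tree.tip_labels if t not in profiles]
    if missing:
        raise ValueError(f"PNO profile missing for tips: {missing}")
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    draws = np.empty((n_iter, n))
    for i, t in enumerate(tree.tip_labels):
        prof = profiles[t]
        draws[:, i] = rng.choice(prof.centers, size=n_iter, p=prof.mass)
    A = ancestral_operator(tree)
    samples = draws @ A.T
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [a, 1.0 - a], axis=0)
    tip_rows = []
    for t in tree.tip_labels:
        prof = profiles[t]
        l, h = prof.central_interval(level)
        tip_rows.append({"species": t, "mean": pno_weighted_mean(prof),
                         "lo80": l, "hi80": h})
    return AncestralTolerance(node_ids=tree.internal_nodes, samples=samples,
                              mean=samples.mean(axis=0), lo80=lo, hi80=hi,
                              tip_summary=pd.DataFrame(tip_rows))
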