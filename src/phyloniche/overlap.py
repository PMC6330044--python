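"""Niche-overlap statistics and the age-range correlation (ARC) test.

Suitability surfaces are compared as probability distributions over shared
valid cells: Schoener's D is one minus half the L1 distance and Warren's I is
one minus half the squared Hellinger distance; both range from 0 (disjoint
niches) to 1 (identical), and I >= D for every pair.

ARC regresses the between-clade overlap at each internal node on node age;
overlaps are aggregated by nested averaging so each daughter clade contributes
one half regardless of its size (cross-pair weights (1/2)^d, d = number of
internal nodes on the path from the focal node down to the pair).  A joint
row/column Monte-Carlo permutation of the overlap matrix supplies the null
distribution of slope and intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridLayer
from .trees import Phylo, node_ages

__all__ = ["SuitabilityDist", "OverlapMatrix", "ARCResult", "suitability_dist",
           "schoener_d", "warren_i", "overlap_matrix", "age_range_correlation"]


@dataclass
class SuitabilityDist:
    """Suitability surface normalized to a probability distribution over cells."""

    species: str
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float).ravel()
        if np.any(self.p < 0):
            raise ValueError("suitability values must be >= 0")


@dataclass
class OverlapMatrix:
    labels: list[str]
    D: np.ndarray = field(repr=False)
    I: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Single table with D in the upper triangle and I in the lower."""
        n = len(self.labels)
        M = np.ones((n, n))
        iu, il = np.triu_indices(n, 1), np.tril_indices(n, -1)
        M[iu] = self.D[iu]
        M[il] = self.I[il]
        return pd.DataFrame(M, index=self.labels, columns=self.labels)


@dataclass
class ARCResult:
    nodes: pd.DataFrame            # node_id, age, overlap
    slope: float
    intercept: float
    p_slope: float
    p_intercept: float
    n_iter: int


def suitability_dist(layer: GridLayer, species: str,
                     mask: np.ndarray | None = None) -> SuitabilityDist:
    """Normalize a suitability layer over (shared) valid cells."""
    m = layer.valid_mask() if mask is None else mask
    return SuitabilityDist(species, _normalize(layer.values[m]))


def _normalize(p: np.ndarray) -> np.ndarray:
    tot = p.sum()
    if tot <= 0:
        raise ValueError("suitability sums to zero; cannot normalize")
    return p / tot


def _as_probs(p) -> np.ndarray:
    v = p.p if isinstance(p, SuitabilityDist) else np.asarray(p, dtype=float).ravel()
    if np.any(v < 0):
        raise ValueError("negative suitability values")
    if not np.isclose(v.sum(), 1.0, atol=1e-9):
        warnings.warn("input not normalized; normalizing to sum 1", stacklevel=3)
        v = _normalize(v)
    return v


def schoener_d(p, q) -> float:
    """Schoener's D = 1 - 0.5 * sum |p_i - q_i|."""
    pv, qv = _as_probs(p), _as_probs(q)
    if pv.shape != qv.shape:
        raise ValueError("distributions are not aligned (different cell counts)")
    return float(1.0 - 0.5 * np.abs(pv - qv).sum())


def warren_i(p, q) -> float:
    """Warren's I = 1 - 0.5 * sum (sqrt(p_i) - sqrt(q_i))^2 (Hellinger-based)."""
    pv, qv = _as_probs(p), _as_probs(q)
    if pv.shape != qv.shape:
        raise ValueError("distributions are not aligned (different cell counts)")
    return float(1.0 - 0.5 * ((np.sqrt(pv) - np.sqrt(qv)) ** 2).sum())


def overlap_matrix(dists: list[SuitabilityDist]) -> OverlapMatrix:
    """All pairwise D and I values, mirrored, with unit diagonal."""
    if len(dists) < 2:
        raise ValueError("need at least 2 species")
    n = len(dists)
    P = np.vstack([_as_probs(d) for d in dists])
    D = np.ones((n, n))
    I = np.ones((n, n))
    S = np.sqrt(P)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = 1.0 - 0.5 * np.abs(P[i] - P[j]).sum()
            I[i, j] = I[j, i] = 1.0 - 0.5 * ((S[i] - S[j]) ** 2).sum()
    return OverlapMatrix(labels=[d.species for d in dists], D=D, I=I)


def _clade_tip_weights(tree: Phylo, node: int, n: int) -> np.ndarray:
    """Tip weights of nested averaging within the clade at ``node`` (sum to 1)."""
    w = np.zeros(n)
    if node < tree.n_tips:
        w[node] = 1.0
        return w
    kids = tree.children[node]
    for c in kids:
        w += _clade_tip_weights(tree, c, n) / len(kids)
    return w


def node_overlap_weights(tree: Phylo) -> dict[int, np.ndarray]:
    """Per internal node, the matrix W with o_k = sum_ij W_ij * M_ij.

    W is the average over pairs of child clades of the outer product of their
    nested-averaging tip weights, so each daughter clade contributes equally.
    """
    n = tree.n_tips
    out = {}
    for k in tree.internal_nodes:
        kids = tree.children[k]
        ws = [_clade_tip_weights(tree, c, n) for c in kids]
        W = np.zeros((n, n))
        npairs = 0
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                W += np.outer(ws[a], ws[b])
                npairs += 1
        out[k] = W / npairs
    return out


def age_range_correlation(tree: Phylo, M: OverlapMatrix | pd.DataFrame,
                          stat: str = "I", n_iter: int = 1000,
                          seed=None) -> ARCResult:
    """Age-range correlation with a Monte-Carlo permutation null.

    Regresses per-node between-clade overlap on node age (OLS).  The null
    permutes species labels of the overlap matrix (joint row/column
    permutation) ``n_iter`` times; two-tailed p-values count null statistics
    at least as extreme as the observed, with the observed included.
    """
    if isinstance(M, OverlapMatrix):
        labels = M.labels
        mat = M.I if stat.upper() == "I" else M.D
    else:
        labels = list(M.index)
        mat = M.to_numpy(dtype=float)
    missing = [t for t in tree.tip_labels if t not in labels]
    if missing:
        raise ValueError(f"overlap matrix missing tips: {missing}")
    order = [labels.index(t) for t in tree.tip_labels]
    mat = np.asarray(mat)[np.ix_(order, order)]

    ages = node_ages(tree)
    internal = tree.internal_nodes
    age_vec = np.array([ages[k] for k in internal])
    weights = node_overlap_weights(tree)
    Wstack = np.vstack([weights[k].ravel() for k in internal])   # (n_nodes, n^2)

    def stats_for(m: np.ndarray) -> tuple[float, float, np.ndarray]:
        o = Wstack @ m.ravel()
        A = np.vstack([age_vec, np.ones_like(age_vec)]).T
        coef, *_ = np.linalg.lstsq(A, o, rcond=None)
        return float(coef[0]), float(coef[1]), o

    slope, intercept, o_obs = stats_for(mat)

    rng = np.random.default_rng(seed)
    n = len(order)
    null_s = np.empty(n_iter)
    null_i = np.empty(n_iter)
    for it in range(n_iter):
        p = rng.permutation(n)
        s, b, _ = stats_for(mat[np.ix_(p, p)])
        null_s[it] = s
        null_i[it] = b
    p_slope = (1 + int(np.sum(np.abs(null_s) >= abs(slope) - 1e-12))) / (n_iter + 1)
    p_int = (1 + int(np.sum(np.abs(null_i) >= abs(intercept) - 1e-12))) / (n_iter + 1)

    nodes = pd.DataFrame({"node_id": internal, "age": age_vec, "overlap": o_obs})
    return ARCResult(nodes=nodes, slope=slope, intercept=intercept,
                     p_slope=float(p_slope), p_intercept=float(p_int), n_iter=n_iter)
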