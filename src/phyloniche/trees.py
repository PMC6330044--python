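"""Rooted time-calibrated trees: Newick I/O, node ages, and phylogenetic covariance.

The central object is :class:`Phylo`, a lightweight array-backed rooted tree with
stable integer node ids (tips ``0..n-1`` in Newick order, internal nodes
``n..n_nodes-1`` in postorder).  Under Brownian motion the among-species
covariance of a trait is ``sigma2 * C`` where ``C[i, j]`` is the shared
root-to-MRCA path length of tips i and j; :func:`vcv` builds that matrix and
:func:`transform_vcv` applies the branch-length transforms that define the
Pagel-lambda, Pagel-delta, early-burst and Ornstein-Uhlenbeck models.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylo",
    "VCVMatrix",
    "TreeParseError",
    "read_newick",
    "write_newick",
    "is_ultrametric",
    "vcv",
    "transform_vcv",
    "node_ages",
    "simulate_bm_tips",
]


class TreeParseError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


@dataclass
class Phylo:
    """Rooted tree with branch lengths in time units (e.g. million years).

    Node ids: tips ``0..n_tips-1`` in Newick (left-to-right) order, internal
    nodes ``n_tips..n_nodes-1`` in postorder; the root is always the last id.
    ``parent[root] == -1`` and ``brlen[root]`` is the root edge length
    (0.0 if absent).
    """

    tip_labels: list[str]
    parent: np.ndarray          # (n_nodes,) int
    brlen: np.ndarray           # (n_nodes,) float
    children: list[list[int]]   # per node, empty for tips

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.brlen = np.asarray(self.brlen, dtype=float)
        if np.any(self.brlen < 0):
            raise TreeParseError("negative branch length")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise TreeParseError("duplicate tip labels")

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.nonzero(self.parent == -1)[0][0])

    @property
    def internal_nodes(self) -> list[int]:
        return list(range(self.n_tips, self.n_nodes))

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node (root edge excluded)."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder()[1:]:
            d[v] = d[self.parent[v]] + self.brlen[v]
        return d

    @property
    def depth(self) -> float:
        """Maximum root-to-tip distance T."""
        return float(self.depths()[: self.n_tips].max())

    def preorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def postorder(self) -> list[int]:
        return self.preorder()[::-1]

    def clade_tips(self, node: int) -> list[int]:
        """Tip ids in the clade rooted at ``node``."""
        if node < self.n_tips:
            return [node]
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < self.n_tips:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return sorted(out)

    def mrca(self, tips: list[int]) -> int:
        sets = []
        for t in tips:
            anc, v = [], t
            while v != -1:
                anc.append(v)
                v = self.parent[v]
            sets.append(anc)
        common = set(sets[0]).intersection(*map(set, sets[1:])) if len(sets) > 1 else set(sets[0])
        # deepest common ancestor = first on any root-ward path that is common
        for v in sets[0]:
            if v in common:
                return v
        raise RuntimeError("unrooted path")  # pragma: no cover

    def label_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    def subtree(self, tip_labels: list[str]) -> "Phylo":
        """Extract the clade spanned by ``tip_labels``.

        Raises ``ValueError`` naming intruding tips if the set is not
        monophyletic.
        """
        idx = self.label_index()
        tips = [idx[t] for t in tip_labels]
        node = self.mrca(tips)
        clade = self.clade_tips(node)
        if set(clade) != set(tips):
            intruders = [self.tip_labels[i] for i in sorted(set(clade) - set(tips))]
            raise ValueError(f"tip set not monophyletic; clade also contains: {intruders}")
        return read_newick(self._newick_of(node, digits=17) + ";")

    # -- Newick serialization ------------------------------------------------

    def _newick_of(self, node: int, digits: int = 6) -> str:
        if node < self.n_tips:
            return f"{self.tip_labels[node]}:{self.brlen[node]:.{digits}g}"
        inner = ",".join(self._newick_of(c, digits) for c in self.children[node])
        if node == self.root:
            return f"({inner})"
        return f"({inner}):{self.brlen[node]:.{digits}g}"

    def to_newick(self, digits: int = 6) -> str:
        return self._newick_of(self.root, digits) + ";"


@dataclass
class VCVMatrix:
    """Among-species covariance structure: shared root-to-MRCA path lengths."""

    labels: list[str]
    C: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.labels)
        if self.C.shape != (n, n):
            raise ValueError("C shape does not match labels")


def read_newick(text: str) -> Phylo:
    """Parse a Newick string into a :class:`Phylo`.

    Every non-root edge must carry a branch length; tips are numbered in
    file order and internal nodes in postorder.
    """
    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"malformed Newick: {exc}") from exc

    leaves = list(dt.leaf_node_iter())
    labels = []
    for lf in leaves:
        lab = lf.taxon.label if lf.taxon is not None else None
        if not lab:
            raise TreeParseError("empty tip label")
        labels.append(lab)
    if len(set(labels)) != len(labels):
        dups = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeParseError(f"duplicate tip labels: {dups}")

    tip_id = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    ids: dict[int, int] = {}
    next_internal = n
    for nd in dt.postorder_node_iter():
        if nd.is_leaf():
            ids[id(nd)] = tip_id[id(nd)]
        else:
            ids[id(nd)] = next_internal
            next_internal += 1

    n_nodes = next_internal
    parent = np.full(n_nodes, -1, dtype=int)
    brlen = np.zeros(n_nodes)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for nd in dt.preorder_node_iter():
        v = ids[id(nd)]
        if nd.parent_node is not None:
            parent[v] = ids[id(nd.parent_node)]
            children[parent[v]].append(v)
            if nd.edge.length is None:
                who = labels[v] if v < n else f"internal node {v}"
                raise TreeParseError(f"missing branch length on edge above {who}")
            brlen[v] = float(nd.edge.length)
        else:
            brlen[v] = float(nd.edge.length or 0.0)
    return Phylo(tip_labels=labels, parent=parent, brlen=brlen, children=children)


def read_newick_file(path) -> Phylo:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick(tree: Phylo, path=None) -> str:
    """Serialize to Newick (6 significant digits); optionally write to ``path``."""
    s = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def is_ultrametric(tree: Phylo, rel_tol: float = 1e-6) -> bool:
    """True iff all root-to-tip depths agree within ``rel_tol * T``."""
    if tree.n_tips < 2:
        raise ValueError("need at least 2 tips")
    d = tree.depths()[: tree.n_tips]
    T = d.max()
    return bool(d.max() - d.min() <= rel_tol * max(T, np.finfo(float).tiny))


def vcv(tree: Phylo) -> VCVMatrix:
    """Phylogenetic variance-covariance matrix: C_ij = depth of MRCA(i, j)."""
    n = tree.n_tips
    depths = tree.depths()
    C = np.zeros((n, n))
    C[np.diag_indices(n)] = depths[:n]
    for v in tree.internal_nodes:
        kids = tree.children[v]
        for a in range(len(kids)):
            ta = tree.clade_tips(kids[a])
            for b in range(a + 1, len(kids)):
                tb = tree.clade_tips(kids[b])
                for i in ta:
                    C[i, tb] = depths[v]
                    C[tb, i] = depths[v]
    return VCVMatrix(labels=list(tree.tip_labels), C=C)


def transform_vcv(C: VCVMatrix, model: str, params: dict, T: float | None = None) -> VCVMatrix:
    """Model transform of the BM covariance matrix.

    lambda : off-diagonals scaled by ``lam`` in [0, 1], diagonal unchanged.
    delta  : each entry t -> t**delta, delta > 0 (no height rescaling; a
             constant rescale is absorbed into the ML rate estimate and does
             not change likelihoods).
    eb     : t -> (exp(r*t) - 1)/r for rate-decay r <= 0; identity at r = 0.
    ou     : C'_ij = exp(-2*alpha*(T - t_ij)) * (1 - exp(-2*alpha*t_ij)) / (2*alpha)
             for attraction alpha > 0 on an ultrametric tree of depth T; the
             BM matrix is the alpha -> 0 limit.
    """
    M = np.asarray(C.C, dtype=float)
    if T is None:
        T = float(np.max(np.diag(M)))
    if model == "lambda":
        lam = float(params["lam"])
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {lam}")
        out = M * lam
        np.fill_diagonal(out, np.diag(M))
    elif model == "delta":
        delta = float(params["delta"])
        if delta <= 0:
            raise ValueError(f"delta must be > 0, got {delta}")
        out = M ** delta
    elif model == "eb":
        r = float(params["r"])
        if r > 0:
            raise ValueError(f"EB rate-decay r must be <= 0, got {r}")
        if r == 0:
            out = M.copy()
        else:
            out = np.expm1(r * M) / r
    elif model == "ou":
        alpha = float(params["alpha"])
        if alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {alpha}")
        if alpha == 0:
            out = M.copy()
        else:
            out = np.exp(-2.0 * alpha * (T - M)) * (-np.expm1(-2.0 * alpha * M)) / (2.0 * alpha)
    else:
        raise ValueError(f"unknown model {model!r}; expected lambda/delta/eb/ou")
    return VCVMatrix(labels=list(C.labels), C=out)


def node_ages(tree: Phylo, rel_tol: float = 1e-6) -> dict[int, float]:
    """Age (time before present) of every node on an ultrametric tree."""
    if not is_ultrametric(tree, rel_tol=rel_tol):
        raise ValueError("tree is not ultrametric; check with is_ultrametric()")
    d = tree.depths()
    T = d[: tree.n_tips].max()
    ages = {v: float(max(T - d[v], 0.0)) for v in range(tree.n_nodes)}
    for t in range(tree.n_tips):
        ages[t] = 0.0
    return ages


def simulate_bm_tips(tree: Phylo, sigma2: float, z0: float = 0.0,
                     seed=None, size: int = 1) -> np.ndarray:
    """Draw tip states under Brownian motion: MVN(z0*1, sigma2*C).

    Returns shape ``(n_tips,)`` for ``size=1`` else ``(size, n_tips)``.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    C = vcv(tree).C
    n = tree.n_tips
    if sigma2 == 0:
        out = np.full((size, n), z0)
    else:
        L = np.linalg.cholesky(sigma2 * C + 1e-12 * np.eye(n))
        out = z0 + rng.standard_normal((size, n)) @ L.T
    return out[0] if size == 1 else out
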