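"""Rooted phylogenies as index arrays, plus the covariance structures of
phylogenetic comparative methods.

Trees are parsed with dendropy and flattened to parent/branch-length
arrays so repeated linear-algebra operations (covariance construction,
ancestral-state solves, trait simulation) stay vectorised.  Node indexing
is preorder with the root at 0; every node identifies the branch above it.

Covariance structures over tips:

* Brownian motion: ``V_ij = t_ij``, the shared path length from the root
  to the most recent common ancestor of tips i and j.
* Ornstein-Uhlenbeck (root-conditioned): ``V_ij = exp(-alpha d_ij) *
  (1 - exp(-2 alpha t_ij)) / (2 alpha)`` with ``d_ij`` the patristic
  distance; as alpha -> 0 this converges to the Brownian covariance.
* Grafen: node heights set from descendant-tip counts, normalised to unit
  depth, raised to a power rho, with tip covariance the transformed height
  of the MRCA.
"""

from __future__ import annotations

import random as _random
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny", "bm_covariance", "ou_covariance", "grafen_covariance",
           "phylo_covariance", "pure_birth_tree"]


class Phylogeny:
    """A rooted tree with branch lengths, flattened to arrays.

    Attributes
    ----------
    parent : (m,) int array, parent index per node (-1 at the root)
    blen : (m,) float array, length of the branch above each node (0 at root)
    children : list of child-index lists
    tips : (n,) int array of tip node indices
    tip_labels : list of n tip names (order defines every tip-vector API)
    """

    def __init__(self, parent, blen, labels, tip_labels_order=None):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=float)
        m = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(m)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.labels = list(labels)
        self.tips = np.array(
            [i for i in range(m) if not self.children[i]], dtype=np.int64
        )
        self.tip_labels = [self.labels[i] for i in self.tips]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("tip labels are not unique")
        self.tip_index: dict[str, int] = {
            lab: k for k, lab in enumerate(self.tip_labels)
        }
        # preorder / postorder node sequences
        order: list[int] = []
        stack = [int(np.where(self.parent < 0)[0][0])]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        self.preorder = np.array(order, dtype=np.int64)
        self.postorder = self.preorder[::-1].copy()
        self.root = int(self.preorder[0])
        self._cache: dict = {}

    # ---------------------------------------------------------------- I/O
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = [-1] * len(nodes)
        blen = [0.0] * len(nodes)
        labels = [""] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                blen[i] = float(nd.edge.length or 0.0)
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label:
                labels[i] = nd.label
        return cls(parent, blen, labels)

    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        try:
            if isinstance(source, Path) or (
                isinstance(source, str) and "(" not in source
            ):
                tree = dendropy.Tree.get(path=str(source), schema="newick")
            else:
                tree = dendropy.Tree.get(data=source, schema="newick")
        except Exception as exc:
            raise ValueError(f"could not parse newick tree: {exc}") from exc
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if not self.children[v]:
                core = self.labels[v].replace(" ", "_")
            else:
                core = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if self.parent[v] >= 0:
                core += f":{self.blen[v]:.10g}"
            return core

        return rec(self.root) + ";"

    # ---------------------------------------------------------- geometry
    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def node_depths(self) -> np.ndarray:
        """Distance from the root to each node."""
        if "depths" not in self._cache:
            d = np.zeros(len(self.parent))
            for v in self.preorder[1:]:
                d[v] = d[self.parent[v]] + self.blen[v]
            self._cache["depths"] = d
        return self._cache["depths"]

    @property
    def depth(self) -> float:
        """Maximum root-to-tip distance."""
        return float(self.node_depths()[self.tips].max())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.node_depths()[self.tips]
        return bool((d.max() - d.min()) <= rel_tol * max(d.max(), 1e-300))

    def _pairwise(self) -> tuple[np.ndarray, np.ndarray]:
        """All-node MRCA index matrix and MRCA-depth (shared time) matrix."""
        if "mrca" not in self._cache:
            m = len(self.parent)
            depths = self.node_depths()
            mrca = np.zeros((m, m), dtype=np.int64)
            desc: list[np.ndarray | None] = [None] * m
            for v in self.postorder:
                if not self.children[v]:
                    desc[v] = np.array([v], dtype=np.int64)
                else:
                    groups = [desc[c] for c in self.children[v]]
                    for a_i in range(len(groups)):
                        for b_i in range(a_i + 1, len(groups)):
                            mrca[np.ix_(groups[a_i], groups[b_i])] = v
                            mrca[np.ix_(groups[b_i], groups[a_i])] = v
                    mine = np.concatenate(groups + [[v]])
                    mrca[v, mine] = v
                    mrca[mine, v] = v
                    desc[v] = mine
                if not self.children[v]:
                    mrca[v, v] = v
            self._cache["mrca"] = mrca
            self._cache["shared"] = depths[mrca]
        return self._cache["mrca"], self._cache["shared"]

    def mrca_matrix(self) -> np.ndarray:
        return self._pairwise()[0]

    def shared_times(self) -> np.ndarray:
        """Tip x tip matrix of shared root-to-MRCA path lengths (BM covariance)."""
        _, shared = self._pairwise()
        return shared[np.ix_(self.tips, self.tips)].copy()

    def shared_times_all(self) -> np.ndarray:
        """All-node x all-node shared-time matrix."""
        return self._pairwise()[1]

    def patristic(self) -> np.ndarray:
        """Tip x tip patristic distance matrix."""
        d = self.node_depths()[self.tips]
        return d[:, None] + d[None, :] - 2.0 * self.shared_times()

    def path_to_root(self, node: int) -> list[int]:
        """Nodes from `node` up to (and including) the root."""
        out = [int(node)]
        while self.parent[out[-1]] >= 0:
            out.append(int(self.parent[out[-1]]))
        return out

    def mrca(self, nodes: Sequence[int]) -> int:
        M = self.mrca_matrix()
        v = int(nodes[0])
        for w in nodes[1:]:
            v = int(M[v, int(w)])
        return v

    def clade_nodes(self, node: int) -> np.ndarray:
        """All descendants of `node`, including itself."""
        out = []
        stack = [int(node)]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return np.array(out, dtype=np.int64)

    def tip_nodes(self, labels: Sequence[str]) -> np.ndarray:
        missing = [l for l in labels if l not in self.tip_index]
        if missing:
            raise ValueError(f"labels not in tree: {missing}")
        return self.tips[[self.tip_index[l] for l in labels]]

    def n_descendant_tips(self) -> np.ndarray:
        if "ndesc" not in self._cache:
            nd = np.zeros(len(self.parent), dtype=np.int64)
            for v in self.postorder:
                nd[v] = 1 if not self.children[v] else sum(nd[c] for c in self.children[v])
            self._cache["ndesc"] = nd
        return self._cache["ndesc"]

    def rescaled(self, depth: float = 1.0) -> "Phylogeny":
        """Copy with branch lengths scaled so the deepest tip sits at `depth`."""
        k = depth / self.depth
        return Phylogeny(self.parent.copy(), self.blen * k, list(self.labels))


# ------------------------------------------------------- covariance models
def bm_covariance(tree: Phylogeny) -> np.ndarray:
    """Brownian covariance: shared root-to-MRCA path length per tip pair."""
    return tree.shared_times()


def ou_covariance(tree: Phylogeny, alpha: float) -> np.ndarray:
    """Root-conditioned Ornstein-Uhlenbeck covariance (unit sigma^2).

    ``V_ij = exp(-alpha d_ij) (1 - exp(-2 alpha t_ij)) / (2 alpha)``;
    converges to the Brownian covariance as alpha -> 0.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    t = tree.shared_times()
    if alpha == 0:
        return t
    d = tree.patristic()
    return np.exp(-alpha * d) * (-np.expm1(-2.0 * alpha * t)) / (2.0 * alpha)


def grafen_covariance(tree: Phylogeny, rho: float = 1.0) -> np.ndarray:
    """Grafen's arbitrary-branch-length covariance.

    Node heights are (descendant tip count - 1) normalised by (n - 1) so
    the root has height 1 and tips 0, then raised to rho; tip covariance is
    one minus the transformed height of the MRCA (a correlation matrix with
    unit diagonal).
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    n = tree.n_tips
    h = (tree.n_descendant_tips() - 1.0) / (n - 1.0)
    M = tree.mrca_matrix()[np.ix_(tree.tips, tree.tips)]
    V = 1.0 - h[M] ** rho
    np.fill_diagonal(V, 1.0)
    return V


def phylo_covariance(
    tree: Phylogeny, model: str, param: float | None = None
) -> np.ndarray:
    """Tip covariance for model in {none, BM, OU, Grafen}; checks PD."""
    model_l = model.lower()
    if model_l == "none":
        V = np.eye(tree.n_tips)
    elif model_l == "bm":
        V = bm_covariance(tree)
    elif model_l == "ou":
        if param is None:
            raise ValueError("OU covariance needs alpha")
        V = ou_covariance(tree, float(param))
    elif model_l == "grafen":
        V = grafen_covariance(tree, 1.0 if param is None else float(param))
    else:
        raise ValueError(f"unknown correlation model {model!r}")
    try:
        np.linalg.cholesky(V + 1e-12 * np.eye(len(V)) * np.trace(V) / len(V))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"covariance for model {model!r} is not positive definite") from exc
    return V


def pure_birth_tree(
    n_tips: int, seed: int, birth_rate: float = 1.0, depth: float | None = 1.0
) -> Phylogeny:
    """Simulate a pure-birth (Yule) ultrametric tree with `n_tips` tips.

    Pendant edges are extended by one extra exponential waiting time after
    the final speciation so no tip sits on a zero-length branch; tips are
    labelled sp01, sp02, ...  If `depth` is given the tree is rescaled to
    that root-to-tip depth.
    """
    rng = _random.Random(int(seed))
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips, rng=rng
    )
    extra = rng.expovariate(birth_rate * n_tips)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)):
        leaf.taxon.label = f"sp{i + 1:02d}"
    phy = Phylogeny.from_dendropy(tree)
    return phy.rescaled(depth) if depth is not None else phy
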