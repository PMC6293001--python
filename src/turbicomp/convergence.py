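"""Ancestral-state reconstruction and Stayton convergence indices.

Convergence between two lineages is declared when their tips are
phenotypically closer than their ancestors ever were.  With Dtip the
(Euclidean, possibly multivariate) phenotypic distance between two focal
tips and Dmax the maximum distance between any pair of states - tips or
reconstructed ancestors - taken one from each lineage back to their most
recent common ancestor:

* ``C1 = 1 - Dtip / Dmax`` in [0, 1]: the proportion of the maximum
  divergence that has been closed again (phylogeny-scaled, amount-free);
* ``C2 = Dmax - Dtip`` >= 0: the absolute amount of divergence closed;
* ``C3 = C2 / Ltot_clade``: C2 scaled by the summed ancestor-to-descendant
  phenotypic change over every branch of the clade spanned by the MRCA.

Ancestral states are Brownian-motion maximum-likelihood (GLS) estimates;
significance comes from re-measuring the indices on Brownian simulations
whose rate (co)variance is estimated from the observed data, with
``p = (1 + #{sim >= observed}) / (1 + nsim)``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .phylo import Phylogeny

__all__ = [
    "AncestralStates",
    "ConvergenceResult",
    "anc_states_ml",
    "cont_map",
    "stayton_c",
    "stayton_significance",
]


@dataclass
class AncestralStates:
    """BM-ML state estimates at every node (tips hold their observed values)."""

    tree: Phylogeny
    node_states: np.ndarray  # (n_nodes,) or (n_nodes, n_traits)
    edge_samples: pd.DataFrame | None = None  # interpolation along edges


class _TreeSolver:
    """Cached linear algebra for repeated reconstructions on one tree."""

    def __init__(self, tree: Phylogeny):
        self.tree = tree
        if (tree.blen[tree.preorder[1:]] <= 0).any():
            raise ValueError("ancestral reconstruction needs positive branch lengths")
        S_all = tree.shared_times_all()
        tips = tree.tips
        C = S_all[np.ix_(tips, tips)]
        cho = cho_factor(C)
        n = len(tips)
        ones = np.ones(n)
        Ci1 = cho_solve(cho, ones)
        self.mu_weights = Ci1 / (ones @ Ci1)  # GLS root-state weights
        internal = np.array(
            [v for v in range(len(tree.parent)) if tree.children[v]], dtype=np.int64
        )
        self.internal = internal
        S_nt = S_all[np.ix_(internal, tips)]
        self.A = cho_solve(cho, S_nt.T).T  # conditional-mean operator
        self.cho = cho
        self.C = C

    def reconstruct(self, Y: np.ndarray) -> np.ndarray:
        """Y: (n_tips, p) observed tip states -> (n_nodes, p) all-node states."""
        mu = self.mu_weights @ Y  # (p,)
        states = np.zeros((len(self.tree.parent), Y.shape[1]))
        states[self.tree.tips] = Y
        states[self.internal] = mu + self.A @ (Y - mu)
        return states

    def bm_rate(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """ML root mean vector and BM rate (co)variance matrix of the traits."""
        mu = self.mu_weights @ Y
        R = (Y - mu).T @ cho_solve(self.cho, Y - mu) / len(self.tree.tips)
        return mu, R


def _as_matrix(traits, tree: Phylogeny) -> tuple[np.ndarray, list[str]]:
    if isinstance(traits, pd.DataFrame):
        missing = [l for l in tree.tip_labels if l not in traits.index]
        if missing:
            raise ValueError(f"traits missing species {missing}")
        return traits.loc[tree.tip_labels].to_numpy(dtype=float), list(traits.columns)
    if isinstance(traits, pd.Series):
        return _as_matrix(traits.to_frame(), tree)
    arr = np.asarray(traits, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != tree.n_tips:
        raise ValueError("trait rows do not match tip count")
    return arr, [f"trait{i}" for i in range(arr.shape[1])]


def anc_states_ml(tree: Phylogeny, trait) -> AncestralStates:
    """Brownian-motion ML (GLS) ancestral states at every internal node.

    Equivalent to the re-rooted weighted-average construction: internal
    states are the conditional means given the tips under BM with the GLS
    root estimate plugged in.
    """
    Y, _ = _as_matrix(trait, tree)
    solver = _TreeSolver(tree)
    states = solver.reconstruct(Y)
    return AncestralStates(tree, states if states.shape[1] > 1 else states[:, 0])


def cont_map(tree: Phylogeny, trait, samples_per_edge: int = 10) -> AncestralStates:
    """Continuous trait map: linear interpolation of states along each edge.

    Returns the ancestral states plus a tidy frame (node, position in
    [0, 1] from parent to child, value) with ``samples_per_edge`` evenly
    spaced points per edge, endpoints included.
    """
    if samples_per_edge < 2:
        raise ValueError("need at least 2 samples per edge (the endpoints)")
    anc = anc_states_ml(tree, trait)
    states = np.atleast_2d(anc.node_states.T).T  # (nodes, p)
    rows = []
    frac = np.linspace(0.0, 1.0, samples_per_edge)
    for v in tree.preorder[1:]:
        pa = tree.parent[v]
        for f in frac:
            val = states[pa] + f * (states[v] - states[pa])
            rows.append({"node": int(v), "parent": int(pa), "position": float(f),
                         **{f"value{i}" if states.shape[1] > 1 else "value": float(x)
                            for i, x in enumerate(np.atleast_1d(val))}})
    anc.edge_samples = pd.DataFrame(rows)
    return anc


@dataclass
class ConvergenceResult:
    """Stayton C indices for a focal tip set (means over focal pairs)."""

    focal_tips: list[str]
    c1: float
    c2: float
    c3: float
    dtip: float
    dmax: float
    ltot_clade: float
    per_pair: pd.DataFrame
    p_values: dict[str, float] = field(default_factory=dict)
    nsim: int = 0


def _pair_indices(tree: Phylogeny, states: np.ndarray, t1: int, t2: int):
    """C1-C3 ingredients for one focal tip pair from all-node states."""
    mrca = tree.mrca([t1, t2])

    def lineage(tip: int) -> list[int]:
        out = [tip]
        while out[-1] != mrca:
            out.append(int(tree.parent[out[-1]]))
        return out

    lin1, lin2 = lineage(t1), lineage(t2)
    S = np.atleast_2d(states.T).T
    d = lambda a, b: float(np.linalg.norm(S[a] - S[b]))
    dtip = d(t1, t2)
    dmax = max(d(a, b) for a in lin1 for b in lin2)
    clade = tree.clade_nodes(mrca)
    ltot = sum(
        float(np.linalg.norm(S[v] - S[tree.parent[v]]))
        for v in clade if v != mrca
    )
    c2 = dmax - dtip
    c1 = 1.0 - dtip / dmax if dmax > 0 else 0.0
    c3 = c2 / ltot if ltot > 0 else 0.0
    return c1, c2, c3, dtip, dmax, ltot


def _stayton_from_states(tree, states, focal_nodes, focal_labels):
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(focal_nodes), 2):
        c1, c2, c3, dtip, dmax, ltot = _pair_indices(tree, states, int(a), int(b))
        rows.append({"tip_a": focal_labels[i], "tip_b": focal_labels[j],
                     "C1": c1, "C2": c2, "C3": c3,
                     "Dtip": dtip, "Dmax": dmax, "Ltot_clade": ltot})
    return pd.DataFrame(rows)


def stayton_c(tree: Phylogeny, traits, focal_tips: list[str]) -> ConvergenceResult:
    """Stayton C1/C2/C3 for a set of putatively convergent tips.

    Ancestral states are reconstructed by BM ML; indices are computed per
    focal pair and averaged (per-pair values are retained in the result).
    Multivariate traits use Euclidean distances, which reduce to absolute
    differences in the univariate case.
    """
    if len(focal_tips) < 2:
        raise ValueError("need at least two focal tips")
    Y, _ = _as_matrix(traits, tree)
    focal_nodes = tree.tip_nodes(focal_tips)
    solver = _TreeSolver(tree)
    states = solver.reconstruct(Y)
    per_pair = _stayton_from_states(tree, states, focal_nodes, focal_tips)
    return ConvergenceResult(
        focal_tips=list(focal_tips),
        c1=float(per_pair["C1"].mean()),
        c2=float(per_pair["C2"].mean()),
        c3=float(per_pair["C3"].mean()),
        dtip=float(per_pair["Dtip"].mean()),
        dmax=float(per_pair["Dmax"].mean()),
        ltot_clade=float(per_pair["Ltot_clade"].mean()),
        per_pair=per_pair,
    )


def stayton_significance(
    tree: Phylogeny,
    traits,
    focal_tips: list[str],
    nsim: int = 1000,
    seed: int | None = None,
    standardize: bool = False,
) -> ConvergenceResult:
    """Stayton indices with simulation p-values.

    Simulates ``nsim`` Brownian datasets with the rate (co)variance
    estimated from the observed traits, recomputes the mean indices on
    each, and reports ``p = (1 + #{sim >= obs}) / (1 + nsim)`` per index.
    ``standardize`` z-scores each trait column first (useful when mixing
    areas, complexity indices and linear measurements in one test).
    """
    Y, cols = _as_matrix(traits, tree)
    if standardize:
        Y = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
    if nsim < 100:
        warnings.warn(f"nsim={nsim} is small; p-value resolution is coarse")
    focal_nodes = tree.tip_nodes(focal_tips)
    solver = _TreeSolver(tree)
    states = solver.reconstruct(Y)
    obs = _stayton_from_states(tree, states, focal_nodes, list(focal_tips))
    obs_mean = obs[["C1", "C2", "C3"]].mean()

    mu, R = solver.bm_rate(Y)
    # symmetrise and factor the trait rate matrix
    R = (R + R.T) / 2.0
    w, U = np.linalg.eigh(R)
    R_half = U @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ U.T
    L_tree = np.linalg.cholesky(
        solver.C + 1e-12 * np.trace(solver.C) / len(solver.C) * np.eye(len(solver.C))
    )
    rng = np.random.default_rng(seed)
    n, p = Y.shape
    exceed = np.zeros(3)
    for _ in range(nsim):
        Z = rng.standard_normal((n, p))
        Ysim = mu + L_tree @ Z @ R_half.T
        sim_states = solver.reconstruct(Ysim)
        sim = _stayton_from_states(tree, sim_states, focal_nodes, list(focal_tips))
        sim_mean = sim[["C1", "C2", "C3"]].mean()
        exceed += (sim_mean.to_numpy() >= obs_mean.to_numpy() - 1e-12)
    pvals = (1.0 + exceed) / (1.0 + nsim)
    res = ConvergenceResult(
        focal_tips=list(focal_tips),
        c1=float(obs_mean["C1"]), c2=float(obs_mean["C2"]), c3=float(obs_mean["C3"]),
        dtip=float(obs["Dtip"].mean()), dmax=float(obs["Dmax"].mean()),
        ltot_clade=float(obs["Ltot_clade"].mean()),
        per_pair=obs,
        p_values={"C1": float(pvals[0]), "C2": float(pvals[1]), "C3": float(pvals[2])},
        nsim=nsim,
    )
    return res
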