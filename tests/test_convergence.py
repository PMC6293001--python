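"""Ancestral states, continuous maps and Stayton convergence indices."""

import numpy as np
import pandas as pd
import pytest

from turbicomp import convergence
from turbicomp.phylo import Phylogeny, pure_birth_tree


def laplacian_anc_oracle(tree: Phylogeny, tip_values: dict) -> np.ndarray:
    """Independent BM-ML oracle: minimise sum (x_child - x_parent)^2 / len
    over internal states by an exact linear solve."""
    internal = [v for v in range(len(tree.parent)) if tree.children[v]]
    pos = {v: i for i, v in enumerate(internal)}
    A = np.zeros((len(internal), len(internal)))
    b = np.zeros(len(internal))
    for v in tree.preorder[1:]:
        p = tree.parent[v]
        w = 1.0 / tree.blen[v]
        if v in pos and p in pos:
            A[pos[v], pos[v]] += w
            A[pos[p], pos[p]] += w
            A[pos[v], pos[p]] -= w
            A[pos[p], pos[v]] -= w
        elif p in pos:  # v is a tip
            A[pos[p], pos[p]] += w
            b[pos[p]] += w * tip_values[tree.labels[v]]
    return np.linalg.solve(A, b), internal


class TestAncestralStates:
    def test_constant_trait_everywhere(self, balanced4):
        y = pd.Series([2.0] * 4, index=balanced4.tip_labels)
        anc = convergence.anc_states_ml(balanced4, y)
        assert np.allclose(anc.node_states, 2.0)

    def test_two_tip_symmetric_root(self):
        tree = Phylogeny.from_newick("(a:1,b:1);")
        anc = convergence.anc_states_ml(
            tree, pd.Series([0.0, 4.0], index=["a", "b"])
        )
        assert anc.node_states[tree.root] == pytest.approx(2.0)

    def test_matches_exact_gls_oracle(self, asym4):
        vals = {"a": 0.0, "b": 4.0, "c": 2.0, "d": 6.0}
        anc = convergence.anc_states_ml(
            asym4, pd.Series(vals)[asym4.tip_labels]
        )
        oracle, internal = laplacian_anc_oracle(asym4, vals)
        assert np.abs(anc.node_states[internal] - oracle).max() < 1e-10

    def test_oracle_agreement_on_random_trees(self):
        for seed in (2, 3, 4):
            tree = pure_birth_tree(8, seed=seed)
            rng = np.random.default_rng(seed)
            vals = dict(zip(tree.tip_labels, rng.normal(size=8)))
            anc = convergence.anc_states_ml(tree, pd.Series(vals)[tree.tip_labels])
            oracle, internal = laplacian_anc_oracle(tree, vals)
            assert np.abs(anc.node_states[internal] - oracle).max() < 1e-10

    def test_zero_branch_lengths_rejected(self):
        tree = Phylogeny.from_newick("((a:0,b:1):1,c:2);")
        with pytest.raises(ValueError, match="positive branch lengths"):
            convergence.anc_states_ml(tree, pd.Series([1.0, 2, 3], index=["a", "b", "c"]))


class TestContMap:
    def test_linear_interpolation_values(self):
        tree = Phylogeny.from_newick("(a:1,b:1);")
        y = pd.Series([1.0, 3.0], index=["a", "b"])
        anc = convergence.cont_map(tree, y, samples_per_edge=3)
        node_a = tree.tip_nodes(["a"])[0]
        vals = anc.edge_samples.query("node == @node_a")["value"].to_numpy()
        assert np.allclose(vals, [2.0, 1.5, 1.0])  # root (=2) -> tip a (=1)

    def test_constant_trait_flat_map(self, balanced4):
        y = pd.Series([5.0] * 4, index=balanced4.tip_labels)
        anc = convergence.cont_map(balanced4, y, samples_per_edge=5)
        assert np.allclose(anc.edge_samples["value"], 5.0)

    def test_midpoints_bounded_by_endpoints(self, asym4):
        y = pd.Series([0.0, 4.0, 2.0, 6.0], index=asym4.tip_labels)
        anc = convergence.cont_map(asym4, y, samples_per_edge=3)
        for node, grp in anc.edge_samples.groupby("node"):
            v = grp.sort_values("position")["value"].to_numpy()
            assert min(v[0], v[-1]) - 1e-12 <= v[1] <= max(v[0], v[-1]) + 1e-12

    def test_too_few_samples_rejected(self, balanced4):
        y = pd.Series([1.0, 2, 3, 4], index=balanced4.tip_labels)
        with pytest.raises(ValueError, match="at least 2 samples"):
            convergence.cont_map(balanced4, y, samples_per_edge=1)


def brute_force_stayton(tree: Phylogeny, states: np.ndarray, t1: int, t2: int):
    """Exhaustive enumeration oracle, written independently of the library
    path: walk the two lineages with explicit parent hops and enumerate
    every cross pair of ancestor/tip states."""
    S = np.atleast_2d(states.T).T
    up1 = [t1]
    while tree.parent[up1[-1]] >= 0:
        up1.append(int(tree.parent[up1[-1]]))
    up2 = [t2]
    while tree.parent[up2[-1]] >= 0:
        up2.append(int(tree.parent[up2[-1]]))
    common = [v for v in up1 if v in up2]
    mrca = common[0]
    lin1 = up1[: up1.index(mrca) + 1]
    lin2 = up2[: up2.index(mrca) + 1]
    dist = lambda a, b: float(np.linalg.norm(S[a] - S[b]))
    dtip = dist(t1, t2)
    dmax = max(dist(a, b) for a in lin1 for b in lin2)
    ltot = 0.0
    stack = list(tree.children[mrca])
    while stack:
        v = stack.pop()
        ltot += dist(v, int(tree.parent[v]))
        stack.extend(tree.children[v])
    return 1 - dtip / dmax, dmax - dtip, (dmax - dtip) / ltot


class TestStaytonIndices:
    def test_identical_focal_values_give_c1_of_one(self, balanced4):
        y = pd.Series([1.0, 4.0, 1.0, 6.0], index=balanced4.tip_labels)
        res = convergence.stayton_c(balanced4, y, ["a", "c"])
        assert res.dtip == 0.0
        assert res.c1 == pytest.approx(1.0)

    def test_pure_divergence_scores_zero(self, balanced4):
        # tips are the extremes: Dmax is attained at the tips themselves
        y = pd.Series([-2.0, -1.0, 1.0, 2.0], index=balanced4.tip_labels)
        res = convergence.stayton_c(balanced4, y, ["a", "d"])
        assert res.c1 == pytest.approx(0.0, abs=1e-12)
        assert res.c2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_oracle(self, asym4):
        rng = np.random.default_rng(17)
        Y = rng.normal(size=(4, 3))
        res = convergence.stayton_c(
            asym4, pd.DataFrame(Y, index=asym4.tip_labels), ["a", "c"]
        )
        states = convergence.anc_states_ml(
            asym4, pd.DataFrame(Y, index=asym4.tip_labels)
        ).node_states
        t1, t2 = asym4.tip_nodes(["a", "c"])
        c1, c2, c3 = brute_force_stayton(asym4, states, int(t1), int(t2))
        assert res.c1 == pytest.approx(c1, abs=1e-10)
        assert res.c2 == pytest.approx(c2, abs=1e-10)
        assert res.c3 == pytest.approx(c3, abs=1e-10)

    def test_scaling_behaviour(self, asym4):
        y = pd.Series([0.0, 4.0, 1.0, 6.0], index=asym4.tip_labels)
        base = convergence.stayton_c(asym4, y, ["a", "c"])
        scaled = convergence.stayton_c(asym4, y * 10.0, ["a", "c"])
        assert scaled.c1 == pytest.approx(base.c1, abs=1e-12)  # scale-free
        assert scaled.c2 == pytest.approx(10.0 * base.c2, rel=1e-12)  # linear

    def test_multivariate_reduces_to_absolute_difference(self, asym4):
        y = pd.Series([0.0, 4.0, 1.0, 6.0], index=asym4.tip_labels)
        uni = convergence.stayton_c(asym4, y, ["a", "c"])
        assert uni.dtip == pytest.approx(abs(y["a"] - y["c"]))

    def test_bounds_hold_under_fuzzing(self):
        rng = np.random.default_rng(23)
        for seed in range(25):
            tree = pure_birth_tree(10, seed=seed + 1)
            Y = pd.DataFrame(
                rng.normal(size=(10, 2)), index=tree.tip_labels
            )
            tips = list(rng.choice(tree.tip_labels, size=3, replace=False))
            res = convergence.stayton_c(tree, Y, tips)
            assert -1e-12 <= res.c1 <= 1 + 1e-12
            assert res.c2 >= -1e-12
            assert -1e-12 <= res.c3 <= 1 + 1e-12

    def test_unknown_focal_tip_errors(self, balanced4):
        y = pd.Series([1.0, 2, 3, 4], index=balanced4.tip_labels)
        with pytest.raises(ValueError, match="not in tree"):
            convergence.stayton_c(balanced4, y, ["a", "zz"])


class TestStaytonSignificance:
    def test_seeded_p_values_reproducible(self):
        tree = pure_birth_tree(12, seed=5)
        rng = np.random.default_rng(5)
        Y = pd.DataFrame(rng.normal(size=(12, 2)), index=tree.tip_labels)
        focal = tree.tip_labels[:3]
        a = convergence.stayton_significance(tree, Y, focal, nsim=150, seed=9)
        b = convergence.stayton_significance(tree, Y, focal, nsim=150, seed=9)
        assert a.p_values == b.p_values

    def test_convergent_signal_detected(self):
        # two distant tips dragged to a shared optimum far from the rest
        tree = pure_birth_tree(24, seed=11)
        rng = np.random.default_rng(11)
        from turbicomp.evomodels import simulate_bm

        y = simulate_bm(tree, 1.0, 0.0, rng)[0]
        d = tree.patristic()
        i, j = np.unravel_index(np.argmax(d), d.shape)
        focal = [tree.tip_labels[i], tree.tip_labels[j]]
        y[[i, j]] = 8.0  # strong shared optimum
        res = convergence.stayton_significance(
            tree, pd.Series(y, index=tree.tip_labels), focal, nsim=200, seed=2
        )
        assert res.p_values["C2"] < 0.05
        assert res.p_values["C1"] < 0.05

    def test_small_nsim_warns(self, balanced4):
        y = pd.Series([1.0, 2, 3, 4], index=balanced4.tip_labels)
        with pytest.warns(UserWarning, match="nsim"):
            convergence.stayton_significance(balanced4, y, ["a", "c"], nsim=50, seed=1)
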