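"""Tree growth: weight propagation, split gating, ordering, export."""
import json

import numpy as np
import pytest

from lctree import (
    CategoricalDataset,
    SimConfig,
    child_weights,
    config_profiles,
    grow_tree,
    node_profile,
    order_children,
    posterior,
    simulate_lc,
    try_split,
)
from lctree.tree import TreeNode


import dataclasses
import functools


@functools.lru_cache(maxsize=None)
def grown_tree(name, seed, root_K=2, n=1000):
    cfg = dataclasses.replace(config_profiles(name), n_cases=n)
    data = simulate_lc(cfg, seed=seed)
    return data, grow_tree(data, root_K, seed=seed, n_starts=4)


class TestChildWeights:
    def test_conservation_and_single_child(self, rng):
        w = rng.random(30)
        post = rng.dirichlet(np.ones(3), size=30)
        cw = child_weights(w, post)
        assert np.abs(np.sum(cw, axis=0) - w).max() < 1e-12
        only = child_weights(w, np.ones((30, 1)))
        assert np.array_equal(only[0], w)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            child_weights(np.ones(5), rng.dirichlet(np.ones(2), size=4))


class TestTrySplit:
    def test_single_pattern_rejected(self):
        data = CategoricalDataset.from_arrays(np.ones((200, 4), dtype=int))
        node = TreeNode("", np.ones(200), 0)
        decision = try_split(data, node, seed=0, n_starts=2)
        assert not decision.accepted

    def test_two_separated_classes_accepted(self):
        truth = np.array([[0.9] * 10, [0.1] * 10])
        for seed in range(3):
            cfg = SimConfig(1000, np.array([0.5, 0.5]), truth)
            data = simulate_lc(cfg, seed=seed)
            node = TreeNode("", np.ones(1000), 0)
            decision = try_split(data, node, seed=seed, n_starts=4)
            assert decision.accepted

    def test_coin_flip_noise_rejected(self):
        cfg = SimConfig(1000, np.array([1.0]), np.full((1, 10), 0.5))
        for seed in range(3):
            data = simulate_lc(cfg, seed=seed)
            node = TreeNode("", np.ones(1000), 0)
            decision = try_split(data, node, seed=seed, n_starts=4)
            assert not decision.accepted

    def test_tiny_node_auto_rejected(self, rng):
        data = CategoricalDataset.from_arrays(rng.integers(1, 3, size=(50, 4)))
        node = TreeNode("1", np.full(50, 0.1), 1)  # effective size 5 < 9 params
        with pytest.warns(UserWarning, match="parameters"):
            decision = try_split(data, node, seed=0)
        assert not decision.accepted
        assert "parameters" in decision.reason


class TestGrowTree:
    def test_pure_noise_gives_trivial_tree(self):
        cfg = SimConfig(800, np.array([1.0]), np.full((1, 8), 0.5))
        data = simulate_lc(cfg, seed=4)
        tree = grow_tree(data, 2, seed=4, n_starts=4)
        assert tree.root.is_leaf
        assert len(tree.leaves) == 1

    def test_configuration_a_shape(self):
        """One distinct class, one similar pair: root splits 2, one child
        splits again — three leaves — in the majority of replications."""
        hits = 0
        for seed in range(3):
            _, tree = grown_tree("A", seed)
            labels = sorted(l.label for l in tree.leaves)
            if labels == ["11", "12", "2"]:
                hits += 1
        assert hits >= 2

    def test_configuration_c_binary_root_recovers_four_leaves(self):
        """Two macro-clusters of two classes each: binary root then one
        further split per branch."""
        hits = 0
        for seed in range(3):
            _, tree = grown_tree("C", seed)
            labels = sorted(l.label for l in tree.leaves)
            if labels == ["11", "12", "21", "22"]:
                hits += 1
        assert hits >= 2

    def test_leaf_weight_conservation(self):
        data, tree = grown_tree("C", seed=0)
        total = np.zeros(data.n_cases)
        for leaf in tree.leaves:
            total += leaf.weights
        assert np.abs(total - 1.0).max() < 1e-8

    def test_depth2_weights_are_posterior_products(self):
        """A depth-2 weight must equal the product of the two stage
        posteriors, each recomputed independently from the stored models."""
        data, tree = grown_tree("A", seed=0)
        deep = [n for n in tree.nodes() if n.depth == 2]
        assert deep
        node = deep[0]
        parent = next(n for n in tree.nodes() if node in n.children)
        post_root = posterior(data, tree.root.split_model.params)
        post_parent = posterior(data, parent.split_model.params)
        expected = (post_root[:, parent.class_index]
                    * post_parent[:, node.class_index])
        assert np.abs(node.weights - expected).max() < 1e-10

    def test_same_seed_same_labels(self):
        data = simulate_lc(config_profiles("A"), seed=1)
        t1 = grow_tree(data, 2, seed=1, n_starts=2)
        t2 = grow_tree(data, 2, seed=1, n_starts=2)
        assert [n.label for n in t1.nodes()] == [n.label for n in t2.nodes()]
        assert t1.root.split_model.loglik == t2.root.split_model.loglik

    def test_children_ordered_by_size(self):
        _, tree = grown_tree("C", seed=0)
        for node in tree.nodes():
            sizes = [c.size for c in node.children]
            assert sizes == sorted(sizes, reverse=True)

    def test_leaf_profile_recovery(self):
        """Leaf conditional response probabilities should approximate the
        generating class profiles after matching."""
        data, tree = grown_tree("A", seed=0, n=4000)
        leaves = sorted(tree.leaves, key=lambda l: l.label)
        profiles = []
        for leaf in leaves:
            parent = next(n for n in tree.nodes() if leaf in n.children)
            params = parent.split_model.params
            profiles.append(
                np.array([p[leaf.class_index, 0] for p in params.response_probs])
            )
        est = np.stack(profiles)
        truth = config_profiles("A").profiles
        cost = np.abs(est[:, None, :] - truth[None]).max(axis=2)
        from scipy.optimize import linear_sum_assignment
        rows, cols = linear_sum_assignment(cost)
        assert cost[rows, cols].max() < 0.05


class TestOrderingAndProfiles:
    def _node_with_children(self, sizes):
        n = len(sizes)
        node = TreeNode("", np.ones(10), 0)
        for k, s in enumerate(sizes):
            w = np.zeros(10)
            w[:1] = s
            node.children.append(TreeNode("?", w, 1, class_index=k))
        return node

    def test_reorders_and_relabels(self):
        node = self._node_with_children([3.0, 7.0])
        order_children(node)
        assert [c.size for c in node.children] == [7.0, 3.0]
        assert [c.label for c in node.children] == ["1", "2"]

    def test_idempotent(self):
        node = self._node_with_children([7.0, 3.0])
        order_children(node)
        first = [(c.label, c.class_index) for c in node.children]
        order_children(node)
        assert [(c.label, c.class_index) for c in node.children] == first

    def test_exact_ties_broken_deterministically(self):
        node = self._node_with_children([5.0, 5.0, 5.0])
        order_children(node)
        a = [c.class_index for c in node.children]
        node2 = self._node_with_children([5.0, 5.0, 5.0])
        order_children(node2)
        assert [c.class_index for c in node2.children] == a

    def test_node_profile_requires_split(self):
        node = TreeNode("", np.ones(5), 0)
        with pytest.raises(ValueError):
            node_profile(node)

    def test_node_profile_rows_normalized(self):
        _, tree = grown_tree("A", seed=0)
        params = node_profile(tree.root)
        assert params.proportions.sum() == pytest.approx(1, abs=1e-10)
        for p in params.response_probs:
            assert ((p >= 0) & (p <= 1)).all()
            assert np.abs(p.sum(axis=1) - 1).max() < 1e-10


class TestExport:
    def test_single_node_json(self):
        cfg = SimConfig(100, np.array([1.0]), np.full((1, 5), 0.5))
        data = simulate_lc(cfg, seed=0)
        tree = grow_tree(data, 2, seed=0, n_starts=2)
        d = tree.to_dict()
        assert d["root"]["label"] == "root"
        assert d["root"]["children"] == []

    def test_json_round_trip_preserves_fields(self):
        _, tree = grown_tree("A", seed=0)
        d = tree.to_dict()
        assert json.loads(tree.to_json()) == d
        sizes = {n["label"]: n["size"] for n in _walk(d["root"])}
        for node in tree.nodes():
            assert sizes[node.display_label()] == node.size

    def test_dot_structure(self):
        _, tree = grown_tree("A", seed=0)
        dot = tree.to_dot()
        assert dot.startswith("digraph")
        assert dot.count("{") == dot.count("}")
        for node in tree.nodes():
            assert f'n_{node.label or "root"}' in dot
        n_edges = dot.count("->")
        assert n_edges == len(tree.nodes()) - 1


def _walk(node_dict):
    yield node_dict
    for child in node_dict["children"]:
        yield from _walk(child)
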