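"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately use different algorithms from the package:
exhaustive enumeration over internal state assignments for parsimony,
dense multivariate-normal linear algebra for Brownian likelihoods, and
breadth-first search on an explicitly built node graph for edge
distances.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from phyplace.treespace import Node, ReferenceTree


def random_binary_tree(rng: np.random.Generator, n_tips: int,
                       with_lengths: bool = True) -> ReferenceTree:
    """Random rooted binary tree grown by sequential random attachment."""
    labels = [f"t{i+1}" for i in range(n_tips)]
    root = Node(children=[Node(label=labels[0]), Node(label=labels[1])])
    for lbl in labels[2:]:
        nodes = [n for n in root.postorder() if n is not root]
        host = nodes[rng.integers(len(nodes))]
        parent = host.parent
        mid = Node()
        idx = parent.children.index(host)
        parent.children[idx] = mid
        mid.parent = parent
        mid.add_child(host)
        mid.add_child(Node(label=lbl))
    if with_lengths:
        for node in root.postorder():
            if node is not root:
                node.length = float(rng.uniform(0.1, 2.0))
    return ReferenceTree(root)


def brute_force_unordered(tree: ReferenceTree, tip_sets: dict[str, frozenset],
                          n_states: int) -> int:
    """Minimal unordered steps by enumerating every internal (and tip)
    state assignment."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_tip]
    tips = [n for n in nodes if n.is_tip]
    tip_choices = [sorted(tip_sets[t.label]) if tip_sets[t.label] else
                   list(range(n_states)) for t in tips]
    best = np.inf
    for internal_assign in itertools.product(range(n_states), repeat=len(internals)):
        state_of = {id(n): s for n, s in zip(internals, internal_assign)}
        for tip_assign in itertools.product(*tip_choices):
            for t, s in zip(tips, tip_assign):
                state_of[id(t)] = s
            cost = sum(
                1
                for n in nodes
                if n is not tree.root and state_of[id(n)] != state_of[id(n.parent)]
            )
            best = min(best, cost)
    return int(best)


def brute_force_interval(tree: ReferenceTree, tip_intervals: dict[str, tuple]) -> float:
    """Minimal linear (ordered) parsimony length by dynamic programming over
    the breakpoint grid (optimum of linear parsimony lies on the multiset of
    interval endpoints)."""
    grid = sorted({b for iv in tip_intervals.values() if iv is not None for b in iv})
    if not grid:
        return 0.0
    grid = np.asarray(grid, float)
    BIG = 1e18

    def cost_below(node) -> np.ndarray:
        # cost of subtree if node takes each grid value
        if node.is_tip:
            iv = tip_intervals[node.label]
            if iv is None:
                return np.zeros(len(grid))
            lo, hi = iv
            return np.where((grid >= lo) & (grid <= hi), 0.0,
                            np.minimum(np.abs(grid - lo), np.abs(grid - hi)))
        total = np.zeros(len(grid))
        for child in node.children:
            child_cost = cost_below(child)
            # min over child value of child_cost + |x - y|
            total += np.array([
                np.min(child_cost + np.abs(grid - x)) for x in grid
            ])
        return total

    return float(np.min(cost_below(tree.root)))


def dense_bm_loglik(V: np.ndarray, x: np.ndarray, reml: bool = False) -> float:
    """Profile-root Brownian log-likelihood by dense MVN linear algebra.

    With ``reml`` the root state is integrated out (restricted likelihood),
    still at unit rate.
    """
    import math

    n = len(x)
    Vi = np.linalg.inv(V)
    ones = np.ones(n)
    mu = (ones @ Vi @ x) / (ones @ Vi @ ones)
    r = x - mu
    Q = r @ Vi @ r
    sign, logdetV = np.linalg.slogdet(V)
    assert sign > 0
    if reml:
        # REML: density of any (n-1) contrasts; equivalently the profile
        # likelihood corrected by the information of the mean
        return -0.5 * ((n - 1) * math.log(2 * math.pi) + logdetV
                       + math.log(ones @ Vi @ ones) + Q)
    return -0.5 * (n * math.log(2 * math.pi) + logdetV + Q)


def covariance_from_tree(tree: ReferenceTree) -> tuple[np.ndarray, list[str]]:
    """Tip covariance (shared root-to-MRCA path length) from branch lengths."""
    tips = tree.tips()
    labels = [t.label for t in tips]
    idx = {lbl: i for i, lbl in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    # depth of each node from root
    depth = {id(tree.root): 0.0}
    for node in reversed(list(tree.root.postorder())):
        if node is tree.root:
            continue
        depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
    clades: dict[int, list[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            clades[id(node)] = [node.label]
            V[idx[node.label], idx[node.label]] = depth[id(node)]
            continue
        kids = [clades.pop(id(c)) for c in node.children]
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                for a in kids[i]:
                    for b in kids[j]:
                        V[idx[a], idx[b]] = V[idx[b], idx[a]] = depth[id(node)]
        clades[id(node)] = [l for grp in kids for l in grp]
    return V, labels


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
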