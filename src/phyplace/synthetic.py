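"""Synthetic trees and character data with the structure the analyses assume.

The generator emulates the shape of the empirical study system: a dated
binary reference tree of ~45 testudinoid-like tips; ~25 continuous
log-ratio-style characters evolving by Brownian motion with lognormal
among-branch rate multipliers and normally distributed within-species
variation observed on 1-10 specimens per species; ~60 discrete
characters (ordered and unordered, 2-5 states) with polymorphic cells
and missing data; and one or two fossil queries generated by actually
evolving extra tips from a known edge of the tree, so the true
attachment branch is known exactly.

Everything is driven by a single :class:`SyntheticConfig` plus a seed and
is bit-reproducible from the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import characters as chars
from .characters import CharacterMatrix, summarize_species
from .treespace import (
    Backbone,
    Node,
    Placement,
    ReferenceTree,
    prune_query,
)

__all__ = ["SyntheticConfig", "Fixture", "simulate_tree", "simulate_continuous",
           "simulate_discrete", "make_dataset", "make_fixture"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped defaults: 45 tips, 25 continuous + 60 discrete characters.

    Rates are per Myr on a tree whose root age is set by the pure-birth
    rate (0.04/Myr gives root ages near the deep-testudinoid scale of
    ~90 Ma for 45 tips).  ``intraspecific_sd_frac`` scales the
    within-species standard deviation relative to the expected
    among-species Brownian standard deviation at the root depth.
    """

    n_tips: int = 45
    seed: int = 0
    birth_rate: float = 0.04
    # continuous characters
    n_continuous: int = 25
    bm_rate: float = 0.01
    branch_rate_sd: float = 0.5        # lognormal sd of branch rate multipliers
    p_multi_specimen: float = 0.2      # share of species x char cells with n > 1
    max_specimens: int = 10
    intraspecific_sd_frac: float = 0.2
    # discrete characters
    n_discrete: int = 60
    state_counts: tuple[int, ...] = (2, 2, 3, 4, 5)
    ordered_fraction: float = 0.4
    mk_rate: float = 0.004
    polymorphism_prob: float = 0.15
    # shared
    missing_fraction: float = 0.1
    # queries
    n_queries: int = 1
    cherry: bool = False
    query_age_frac: float = 0.3        # tip age as fraction of attachment age
    # 'random' draws the host edge uniformly; 'longest' pins it to the
    # longest-duration edge; 'pendant' pins it to the longest pendant edge
    # (a clear-signal fixture: the attachment is sister to one extant tip
    # and not degenerate with a neighboring node)
    query_host_edge: str = "random"

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValueError("need at least 4 tips")
        for name in ("birth_rate", "bm_rate", "mk_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_multi_specimen", "intraspecific_sd_frac", "ordered_fraction",
                     "polymorphism_prob", "missing_fraction", "query_age_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class Fixture:
    """A backbone, a combined matrix with query rows, and the truth."""

    tree: ReferenceTree              # reference tree (queries absent)
    matrix: CharacterMatrix
    truth: Placement
    query_labels: tuple[str, ...]
    true_tree: ReferenceTree         # tree with queries attached (for oracles)
    config: SyntheticConfig


def simulate_tree(config: SyntheticConfig, rng: Optional[np.random.Generator] = None) -> ReferenceTree:
    """Pure-birth (Yule) dated tree; ultrametric, ages in Ma."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_tips
    root = Node()
    active = [root.add_child(Node()), root.add_child(Node())]
    births = {id(root): 0.0}
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (config.birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        births[id(node)] = t
        active.append(node.add_child(Node()))
        active.append(node.add_child(Node()))
    t += rng.exponential(1.0 / (config.birth_rate * n))
    height = t
    for i, tip in enumerate(active):
        tip.label = f"sp{i+1:02d}"
        births[id(tip)] = height
    for node in root.postorder():
        node.age = height - births[id(node)]
    tree = ReferenceTree(root)
    tree.set_lengths_from_ages()
    return tree


def _preorder(tree):
    out = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(reversed(node.children))
    return out


def _branch_rate_multipliers(tree, sd, rng):
    """Lognormal (mean 1) rate multiplier per branch; sd=0 is a strict clock."""
    out = {}
    for node in tree.postorder():
        if node is tree.root:
            continue
        out[id(node)] = (
            float(rng.lognormal(-0.5 * sd * sd, sd)) if sd > 0 else 1.0
        )
    return out


def simulate_continuous(
    tree: ReferenceTree,
    config: SyntheticConfig,
    rng: np.random.Generator,
    queries: tuple[str, ...] = (),
):
    """Brownian species means plus specimen-level observations.

    Returns (cont_mean, cont_lo, cont_hi, cont_n, true_means, specimens).
    Query tips get exactly one specimen and no missing cells, mirroring a
    fossil scored once.
    """
    C = config.n_continuous
    mult = _branch_rate_multipliers(tree, config.branch_rate_sd, rng)
    values = {id(tree.root): np.zeros(C)}
    for node in _preorder(tree):
        if node is tree.root:
            continue
        var = config.bm_rate * mult[id(node)] * max(node.length, 0.0)
        values[id(node)] = values[id(node.parent)] + rng.normal(0.0, np.sqrt(var), C)
    tips = tree.tips()
    labels = [t.label for t in tips]
    names = [f"RC{j+1}" for j in range(C)]
    true_means = pd.DataFrame(
        np.vstack([values[id(t)] for t in tips]), index=labels, columns=names
    )
    scale_sd = config.intraspecific_sd_frac * np.sqrt(config.bm_rate * tree.root.age)
    mean = true_means.copy() * np.nan
    lo, hi = mean.copy(), mean.copy()
    n_df = pd.DataFrame(0, index=labels, columns=names, dtype=int)
    spec_rows = []
    for sp in labels:
        is_query = sp in queries
        for ch in names:
            if not is_query and rng.random() < config.missing_fraction:
                continue
            if is_query or rng.random() >= config.p_multi_specimen:
                k = 1
            else:
                k = int(rng.integers(2, config.max_specimens + 1))
            obs = true_means.at[sp, ch] + rng.normal(0.0, scale_sd, k)
            m, l, h, kk = summarize_species(obs)
            mean.at[sp, ch], lo.at[sp, ch], hi.at[sp, ch] = m, l, h
            n_df.at[sp, ch] = kk
            for v in obs:
                spec_rows.append({"species": sp, "character": ch, "value": float(v)})
    specimens = pd.DataFrame(spec_rows)
    return mean, lo, hi, n_df, true_means, specimens


def _evolve_discrete(parent_state, duration, rate, n_states, ordered, rng):
    k = rng.poisson(rate * duration)
    s = parent_state
    for _ in range(k):
        if ordered:
            step = 1 if rng.random() < 0.5 else -1
            s = min(max(s + step, 0), n_states - 1)
        else:
            choices = [x for x in range(n_states) if x != s]
            s = int(choices[rng.integers(len(choices))])
    return s


def simulate_discrete(
    tree: ReferenceTree,
    config: SyntheticConfig,
    rng: np.random.Generator,
    queries: tuple[str, ...] = (),
):
    """Mk (unordered) and stepwise-walk (ordered) discrete characters.

    Polymorphic cells add one adjacent (ordered) or random other observed
    (unordered) state with the configured probability; missing cells are
    masked at the configured rate (never for query rows).  Returns
    (disc DataFrame of frozensets, ordered flags).
    """
    D = config.n_discrete
    labels = tree.tip_labels
    names = [f"D{j+1}" for j in range(D)]
    n_states = [int(config.state_counts[rng.integers(len(config.state_counts))])
                for _ in range(D)]
    is_ordered = [bool(rng.random() < config.ordered_fraction) for _ in range(D)]
    disc = pd.DataFrame(None, index=labels, columns=names, dtype=object)
    for j, ch in enumerate(names):
        root_state = int(rng.integers(n_states[j]))
        states = {id(tree.root): root_state}
        for node in _preorder(tree):
            if node is tree.root:
                continue
            states[id(node)] = _evolve_discrete(
                states[id(node.parent)], max(node.length, 0.0), config.mk_rate,
                n_states[j], is_ordered[j], rng,
            )
        for tip in tree.tips():
            sp = tip.label
            if sp not in queries and rng.random() < config.missing_fraction:
                disc.at[sp, ch] = None
                continue
            cell = {states[id(tip)]}
            if n_states[j] > 1 and rng.random() < config.polymorphism_prob:
                s = states[id(tip)]
                if is_ordered[j]:
                    extra = s + 1 if s + 1 < n_states[j] else s - 1
                else:
                    others = [x for x in range(n_states[j]) if x != s]
                    extra = int(others[rng.integers(len(others))])
                cell.add(extra)
            disc.at[sp, ch] = frozenset(cell)
    disc = disc.where(disc.notna(), None)
    return disc, pd.Series(is_ordered, index=names, dtype=bool)


def _assemble_matrix(tree, config, rng, queries=()):
    mean, lo, hi, n_df, true_means, specimens = simulate_continuous(
        tree, config, rng, queries
    )
    disc, ordered = simulate_discrete(tree, config, rng, queries)
    matrix = CharacterMatrix(
        cont_mean=mean, cont_lo=lo, cont_hi=hi, cont_n=n_df,
        disc=disc, ordered=ordered, queries=frozenset(queries),
    )
    return matrix, true_means, specimens


def make_dataset(config: SyntheticConfig):
    """(tree, matrix, true_means): a reference tree with data, no queries."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    matrix, true_means, _ = _assemble_matrix(tree, config, rng)
    return tree, matrix, true_means


def make_fixture(config: SyntheticConfig) -> Fixture:
    """Evolve 1-2 query tips from a recorded edge; return backbone + truth.

    The queries are simulated on the *placed* tree (reference tree with
    the query subtree attached at a known edge), then pruned off, so the
    character data carry exactly the signal a correct placement method
    should recover.
    """
    if not 1 <= config.n_queries <= 2:
        raise ValueError("fixtures support 1 or 2 queries")
    if config.cherry and config.n_queries != 2:
        raise ValueError("a cherry fixture needs 2 queries")
    rng = np.random.default_rng(config.seed)
    ref = simulate_tree(config, rng)
    qlabels = tuple(f"fossil{i+1}" for i in range(config.n_queries))

    # choose a host edge (not above the root) and attachment ages
    edges = [node for _, node in ref.edges(unrooted=False)]
    if config.query_host_edge in ("longest", "pendant"):
        pool = [n for n in edges if n.is_tip] if config.query_host_edge == "pendant" else edges
        host = max(pool, key=lambda n: n.parent.age - n.age)
        att_age = 0.5 * (host.age + host.parent.age)
    else:
        host = edges[rng.integers(len(edges))]
        att_age = float(rng.uniform(host.age, host.parent.age))
    parent = host.parent
    mid = Node(age=att_age)
    idx = parent.children.index(host)
    parent.children[idx] = mid
    mid.parent = parent
    mid.add_child(host)
    if config.cherry:
        stem_age = att_age * (0.5 + 0.5 * config.query_age_frac)
        cherry = Node(age=stem_age)
        mid.add_child(cherry)
        for q in qlabels:
            cherry.add_child(Node(label=q, age=stem_age * config.query_age_frac))
    elif config.n_queries == 2:
        # independent pair: attach the second query to another edge
        mid.add_child(Node(label=qlabels[0], age=att_age * config.query_age_frac))
        others = [
            n for n in ref.root.postorder()
            if n is not ref.root and (not n.is_tip or n.label not in qlabels)
        ]
        host2 = others[rng.integers(len(others))]
        att2 = float(rng.uniform(host2.age, host2.parent.age))
        mid2 = Node(age=att2)
        idx2 = host2.parent.children.index(host2)
        gp = host2.parent
        gp.children[idx2] = mid2
        mid2.parent = gp
        mid2.add_child(host2)
        mid2.add_child(Node(label=qlabels[1], age=att2 * config.query_age_frac))
    else:
        mid.add_child(Node(label=qlabels[0], age=att_age * config.query_age_frac))
    true_tree = ReferenceTree(ref.root)
    true_tree.set_lengths_from_ages()

    matrix, _, _ = _assemble_matrix(true_tree, config, rng, queries=qlabels)

    # prune queries to recover the reference tree and the true placement
    work = true_tree
    if config.n_queries == 1:
        bb = prune_query(work, qlabels[0])
        truth = Placement("single", (bb.true_edge,), qlabels)
        reference = bb.tree
    else:
        from .bayes import classify_placement, _child_side_map
        bb1 = prune_query(work, qlabels[0])
        reference = prune_query(bb1.tree, qlabels[1]).tree
        truth = classify_placement(work, qlabels, _child_side_map(reference))
    reference.set_ages_from_lengths()
    return Fixture(
        tree=reference, matrix=matrix, truth=truth, query_labels=qlabels,
        true_tree=true_tree, config=config,
    )
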