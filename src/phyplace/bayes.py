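"""Bayesian placement under Brownian motion with free branch lengths.

Branch lengths are estimated in units of expected accumulated Brownian
variance rather than time, so the diffusion rate is free to vary across
branches (no clock).  The likelihood is the restricted (REML) Brownian
likelihood -- the root state is integrated out via phylogenetically
independent contrasts -- optionally weighted per character.  Character
weights follow the reference-vs-random-trees protocol: the weight of a
character derives from the fraction of random trees against which the
reference topology attains the higher REML likelihood for that
character; the fractions can be used directly ("fractional"), or
thresholded at 0.95 ("binary"), or ignored ("equal").

The branch-length prior is a compound Dirichlet: Gamma on the tree
length (shape 1, anchored to the ML tree length) with a flat Dirichlet
over branch proportions.  The MCMC moves are a single-branch multiplier,
a whole-tree rescale, and query reattachment (prune one query and
regraft it to a uniformly chosen edge at a uniform position, keeping its
pendant length); cherry, sequential and independent-pair arrangements of
two queries are all reachable through reattachment alone, because a
query's pendant edge is itself a valid target for the other query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .treespace import (
    Backbone,
    Node,
    Placement,
    ReferenceTree,
    TreeError,
    prune_query,
)

__all__ = [
    "BranchLengthPrior",
    "CharacterWeights",
    "McmcSettings",
    "McmcRun",
    "ConvergenceReport",
    "unroot",
    "reml_loglik",
    "ml_branch_lengths",
    "random_topology",
    "reml_char_weights",
    "zscore_transform",
    "mcmc_place",
    "geweke",
    "ess",
    "burnin_protocol",
    "summarize_placements",
]

LOG2PI = math.log(2.0 * math.pi)
_MINVAR = 1e-10


# ---------------------------------------------------------------------------
# Unrooted representation and REML likelihood
# ---------------------------------------------------------------------------


def unroot(tree: ReferenceTree) -> ReferenceTree:
    """Copy of the tree re-rooted as a basal multifurcation.

    A bifurcating root is suppressed by merging its two child edges, so
    each non-root node corresponds to exactly one unrooted branch.
    """
    work = tree.copy()
    root = work.root
    if len(root.children) == 2:
        internal = next((c for c in root.children if not c.is_tip), None)
        if internal is None:
            raise TreeError("cannot unroot a two-tip tree")
        other = next(c for c in root.children if c is not internal)
        if internal.length is not None or other.length is not None:
            other.length = (other.length or 0.0) + (internal.length or 0.0)
        new_root = Node(label=internal.label)
        for child in list(internal.children):
            new_root.add_child(child)
        new_root.add_child(other)
        internal.children = []
        work = ReferenceTree(new_root, rooted=False)
    work.rooted = False
    return work


def reml_loglik(
    tree: ReferenceTree,
    X: pd.DataFrame,
    weights: Optional[np.ndarray] = None,
    per_character: bool = False,
):
    """Weighted REML Brownian log-likelihood with branch lengths as given.

    Branch lengths are in variance units (rate fixed at 1); the root state
    is integrated out, so the result is invariant to the rooting of the
    tree.  ``weights`` multiply the per-character log-likelihoods.
    """
    stats: dict[int, tuple[np.ndarray, float]] = {}
    Q = np.zeros(X.shape[1])
    logdet = 0.0
    n_contrasts = 0
    for node in tree.postorder():
        if node.is_tip:
            if node.length is None or node.length < 0:
                raise TreeError(f"tip {node.label!r} lacks a valid branch length")
            stats[id(node)] = (X.loc[node.label].to_numpy(float), float(node.length))
            continue
        x, v = stats.pop(id(node.children[0]))
        for child in node.children[1:]:
            x2, v2 = stats.pop(id(child))
            total = max(v + v2, _MINVAR)
            Q += (x - x2) ** 2 / total
            logdet += math.log(total)
            n_contrasts += 1
            x = (v2 * x + v * x2) / total
            v = v * v2 / total
        own = node.length if (node is not tree.root and node.length is not None) else 0.0
        stats[id(node)] = (x, v + own)
    per_char = -0.5 * (n_contrasts * LOG2PI + logdet + Q)
    if per_character:
        return per_char
    if weights is None:
        return float(per_char.sum())
    return float((np.asarray(weights, float) * per_char).sum())


# ---------------------------------------------------------------------------
# Branch length optimization
# ---------------------------------------------------------------------------


def _branch_nodes(tree: ReferenceTree) -> list[Node]:
    return [n for n in tree.postorder() if n is not tree.root]


def _expanding_brent(fun, x0: float, upper0: float) -> float:
    """Bounded minimization on [0, hi], expanding hi while the optimum
    presses against it."""
    hi = max(upper0, 10.0 * x0, 1e-6)
    for _ in range(8):
        res = optimize.minimize_scalar(fun, bounds=(0.0, hi), method="bounded")
        if res.x < 0.95 * hi:
            return float(res.x)
        hi *= 10.0
    return float(res.x)


def ml_branch_lengths(
    tree: ReferenceTree,
    X: pd.DataFrame,
    weights: Optional[np.ndarray] = None,
    max_sweeps: int = 10,
    tol: float = 1e-6,
    init: Optional[float] = None,
):
    """Coordinate-ascent REML estimation of branch lengths (variance units).

    Returns (tree copy with optimized lengths in the unrooted
    representation, log-likelihood).  Deterministic given the starting
    lengths; branch lengths are constrained to be non-negative.
    """
    if weights is not None and not np.any(np.asarray(weights) > 0):
        raise ValueError("all character weights are zero")
    work = unroot(tree)
    branches = _branch_nodes(work)
    if init is None:
        init = max(float(X.loc[work.tip_labels].var(ddof=1).mean()), 1e-3) / max(
            len(branches), 1
        )
    for node in branches:
        node.length = init
    last = reml_loglik(work, X, weights)
    for _ in range(max_sweeps):
        for node in branches:
            def neg(v, node=node):
                node.length = v
                return -reml_loglik(work, X, weights)

            node.length = _expanding_brent(neg, node.length, upper0=4.0 * init)
        cur = reml_loglik(work, X, weights)
        if cur - last < tol:
            break
        last = cur
    return work, reml_loglik(work, X, weights)


def random_topology(labels: Sequence[str], rng: np.random.Generator) -> ReferenceTree:
    """Uniform random unrooted binary labelled topology (random addition)."""
    labels = list(labels)
    if len(labels) < 3:
        raise TreeError("need at least 3 tips")
    order = list(rng.permutation(labels))
    root = Node()
    for lbl in order[:3]:
        root.add_child(Node(label=lbl, length=1.0))
    tree = ReferenceTree(root, rooted=False)
    for lbl in order[3:]:
        edges = [n for n in root.postorder() if n is not root]
        host = edges[rng.integers(len(edges))]
        parent = host.parent
        mid = Node(length=1.0)
        idx = parent.children.index(host)
        parent.children[idx] = mid
        mid.parent = parent
        mid.add_child(host)
        mid.add_child(Node(label=lbl, length=1.0))
    return ReferenceTree(root, rooted=False)


# ---------------------------------------------------------------------------
# Character weights
# ---------------------------------------------------------------------------


@dataclass
class CharacterWeights:
    """Reference-vs-random-trees reliability weights.

    ``fraction`` is the share of random trees against which the reference
    tree has the higher per-character REML likelihood; ``weight`` is the
    effective weight under the chosen mode (equal / binary with the 0.95
    cutoff / fractional).
    """

    table: pd.DataFrame  # index: character; columns: fraction, weight
    mode: str
    n_random: int
    cutoff: float = 0.95

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(float)

    def to_json(self, path) -> None:
        payload = {
            "mode": self.mode, "n_random": self.n_random, "cutoff": self.cutoff,
            "fraction": self.table["fraction"].to_dict(),
            "weight": self.table["weight"].to_dict(),
        }
        pd.Series(payload).to_json(path)

    @classmethod
    def from_json(cls, path) -> "CharacterWeights":
        payload = pd.read_json(path, typ="series")
        tbl = pd.DataFrame({
            "fraction": pd.Series(payload["fraction"], dtype=float),
            "weight": pd.Series(payload["weight"], dtype=float),
        })
        return cls(table=tbl, mode=payload["mode"], n_random=int(payload["n_random"]),
                   cutoff=float(payload["cutoff"]))


def reml_char_weights(
    tree: ReferenceTree,
    X: pd.DataFrame,
    n_random: int = 1000,
    mode: str = "fractional",
    seed: int = 0,
    cutoff: float = 0.95,
    max_sweeps: int = 4,
) -> CharacterWeights:
    """Character weights from reference-vs-random-tree likelihood wins.

    Random topologies are uniform over labelled unrooted topologies on the
    same tips, each with its branch lengths freshly optimized.  Exact
    likelihood ties count as non-wins.
    """
    if mode not in ("equal", "binary", "fractional"):
        raise ValueError(f"unknown weighting mode {mode!r}")
    rng = np.random.default_rng(seed)
    ref_tree, _ = ml_branch_lengths(tree, X, max_sweeps=max_sweeps)
    ref_ll = reml_loglik(ref_tree, X, per_character=True)
    wins = np.zeros(X.shape[1])
    for _ in range(n_random):
        topo = random_topology(X.index, rng)
        rand_tree, _ = ml_branch_lengths(topo, X, max_sweeps=max_sweeps)
        rand_ll = reml_loglik(rand_tree, X, per_character=True)
        wins += (ref_ll > rand_ll).astype(float)
    frac = wins / n_random
    if mode == "equal":
        weight = np.ones_like(frac)
    elif mode == "binary":
        weight = (frac >= cutoff).astype(float)
    else:
        weight = frac.copy()
    tbl = pd.DataFrame({"fraction": frac, "weight": weight}, index=X.columns)
    return CharacterWeights(table=tbl, mode=mode, n_random=n_random, cutoff=cutoff)


def zscore_transform(X: pd.DataFrame, reference_rows: Optional[Sequence[str]] = None):
    """Rescale each character to zero mean and unit variance.

    Constants come from ``reference_rows`` (default: all rows) and are
    applied to every row, so query rows are measured on the same scale.
    Returns (transformed, location, scale).
    """
    ref = X.loc[list(reference_rows)] if reference_rows is not None else X
    loc, scale = ref.mean(), ref.std(ddof=1)
    if (scale <= 0).any() or not np.isfinite(scale).all():
        bad = list(scale.index[(scale <= 0) | ~np.isfinite(scale)])
        raise ValueError(f"zero variance in characters {bad}")
    return (X - loc) / scale, loc, scale


# ---------------------------------------------------------------------------
# Prior
# ---------------------------------------------------------------------------


@dataclass
class BranchLengthPrior:
    """Compound Dirichlet prior on the branch lengths of the placed tree.

    Tree length T ~ Gamma(shape ``alpha`` = 1, anchored to the ML tree
    length), branch proportions ~ flat Dirichlet.  By default the Gamma is
    parameterized so its *mean* equals the ML tree length (rate = 1/T_ML);
    ``literal_beta=True`` instead uses the ML tree length directly as the
    rate parameter, the literal reading of "beta = sum of branch lengths".
    """

    ml_tree_length: float
    alpha: float = 1.0
    literal_beta: bool = False

    def __post_init__(self):
        if self.ml_tree_length <= 0 or self.alpha <= 0:
            raise ValueError("prior parameters must be positive")

    @property
    def rate(self) -> float:
        return self.ml_tree_length if self.literal_beta else 1.0 / self.ml_tree_length

    def log_density(self, lengths: np.ndarray) -> float:
        m = len(lengths)
        T = float(np.sum(lengths))
        if T <= 0 or np.any(lengths < 0):
            return -np.inf
        log_gamma_T = (
            self.alpha * math.log(self.rate)
            - special.gammaln(self.alpha)
            + (self.alpha - 1.0) * math.log(T)
            - self.rate * T
        )
        # flat Dirichlet over proportions: (m-1)!; Jacobian T^-(m-1)
        return log_gamma_T + special.gammaln(m) - (m - 1) * math.log(T)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


@dataclass
class McmcSettings:
    generations: int = 200_000
    sample_interval: int = 100
    multiplier_tuning: float = 1.4
    rescale_tuning: float = 0.5
    p_branch: float = 0.55
    p_rescale: float = 0.1
    p_reattach: float = 0.35
    likelihood_off: bool = False  # prior-recovery runs

    def __post_init__(self):
        total = self.p_branch + self.p_rescale + self.p_reattach
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("move probabilities must sum to 1")
        if self.generations < 1 or self.sample_interval < 1:
            raise ValueError("invalid chain settings")


@dataclass
class McmcRun:
    samples: pd.DataFrame  # generation, loglik, log_prior, tree_length, mode, edges, order
    settings: McmcSettings
    seed: int
    n_queries: int
    acceptance: dict[str, float]
    burnin_frac: float = 0.1


def _child_side_map(tree: ReferenceTree) -> dict[frozenset, frozenset]:
    """Edge key -> clade below the edge in the rooted reference tree."""
    sets = tree._clade_sets()
    all_tips = sets[id(tree.root)]
    out = {}
    for node in tree.postorder():
        if node is tree.root:
            continue
        clade = sets[id(node)]
        key = tree._key_from_clade(clade, all_tips)
        out.setdefault(key, clade)
    return out


def classify_placement(
    sampled: ReferenceTree,
    queries: Sequence[str],
    child_side: dict[frozenset, frozenset],
) -> Placement:
    """Map a sampled tree back to (mode, backbone edge(s), order)."""
    queries = tuple(queries)
    if len(queries) == 1:
        bb = prune_query(sampled, queries[0])
        return Placement("single", (bb.true_edge,), queries)
    q1, q2 = queries
    t1 = sampled.find_tip(q1)
    sibs = t1.parent.children
    if len(sibs) == 2 and all(c.is_tip for c in sibs) and {c.label for c in sibs} == {q1, q2}:
        wo1 = prune_query(sampled, q1).tree
        edge = prune_query(wo1, q2).true_edge
        return Placement("cherry", (edge,), queries)
    wo2 = prune_query(sampled, q2).tree
    e1 = prune_query(wo2, q1).true_edge
    wo1 = prune_query(sampled, q1).tree
    e2 = prune_query(wo1, q2).true_edge
    if e1 != e2:
        return Placement("pair", (e1, e2), queries)
    # sequential: decide which query sits rootward of the other
    a1, a2 = sampled.find_tip(q1).parent, sampled.find_tip(q2).parent
    anc, anc_query, other_query = None, None, None
    node = a2
    while node is not None:
        if node is a1:
            anc, anc_query, other_query = a1, q1, q2
            break
        node = node.parent
    if anc is None:
        anc, anc_query, other_query = a2, q2, q1
    below = frozenset(
        t.label for t in anc.postorder() if t.is_tip and t.label not in queries
    )
    rootward = anc_query if below == child_side.get(e1, below) else other_query
    return Placement("sequential", (e1,), queries, order=rootward)


def _prune_tip(tree: ReferenceTree, label: str) -> tuple[Node, float]:
    """Remove a tip in place; return (tip node, merged-edge length at the
    former attachment)."""
    tip = tree.find_tip(label)
    parent = tip.parent
    parent.remove_child(tip)
    merged = None
    if len(parent.children) == 1 and parent is not tree.root:
        child = parent.children[0]
        child.length = (child.length or 0.0) + (parent.length or 0.0)
        merged = child.length
        gp = parent.parent
        idx = gp.children.index(parent)
        gp.children[idx] = child
        child.parent = gp
    elif parent is tree.root and len(parent.children) == 2:
        c1, c2 = parent.children
        keep, move = (c1, c2) if not c1.is_tip else (c2, c1)
        move.length = (move.length or 0.0) + (keep.length or 0.0)
        merged = move.length
        new_root = Node()
        for child in list(keep.children):
            new_root.add_child(child)
        new_root.add_child(move)
        tree.root = new_root
    if merged is None:
        # parent keeps degree >= 3: no merge happened
        merged = sum(c.length or 0.0 for c in parent.children) / max(len(parent.children), 1)
    return tip, merged


def _attach_tip(tree: ReferenceTree, tip: Node, host: Node, split: float) -> None:
    parent = host.parent
    mid = Node()
    mid.length = (host.length or 0.0) * (1.0 - split)
    host_new = (host.length or 0.0) * split
    idx = parent.children.index(host)
    parent.children[idx] = mid
    mid.parent = parent
    mid.add_child(host)
    host.length = host_new
    mid.add_child(tip)


def mcmc_place(
    tree: ReferenceTree,
    X: pd.DataFrame,
    weights: Optional[np.ndarray],
    prior: BranchLengthPrior,
    queries: Sequence[str],
    settings: McmcSettings = McmcSettings(),
    seed: int = 0,
) -> McmcRun:
    """MCMC over query placements and branch lengths.

    ``tree`` is the reference topology (queries absent); ``X`` holds rows
    for reference species and queries alike.  The posterior is
    proportional to the weighted REML likelihood times the compound
    Dirichlet prior.  The chain is reproducible bit-for-bit from ``seed``.
    """
    queries = tuple(queries)
    if not 1 <= len(queries) <= 2:
        raise ValueError("mcmc_place supports one or two queries")
    for q in queries:
        if q not in X.index or X.loc[q].isna().all():
            raise ValueError(f"query {q!r} has no data")
    rng = np.random.default_rng(seed)
    child_side = _child_side_map(tree)

    state = unroot(tree)
    m0 = len(_branch_nodes(state))
    m = m0 + 2 * len(queries)
    init = prior.ml_tree_length / m
    for node in _branch_nodes(state):
        node.length = init
    for q in queries:
        hosts = _branch_nodes(state)
        host = hosts[rng.integers(len(hosts))]
        _attach_tip(state, Node(label=q, length=init), host, split=0.5)

    tip_x = {lbl: X.loc[lbl].to_numpy(float) for lbl in X.index}
    w_arr = None if weights is None else np.asarray(weights, float)
    cache: dict = {"post": None, "branches": None}

    def branches():
        if cache["branches"] is None:
            cache["branches"] = _branch_nodes(state)
        return cache["branches"]

    def lengths_vec():
        return np.array([n.length for n in branches()])

    def loglik():
        if settings.likelihood_off:
            return 0.0
        if cache["post"] is None:
            cache["post"] = list(state.postorder())
        stats: dict[int, tuple[np.ndarray, float]] = {}
        Q = 0.0
        logdet = 0.0
        n_contrasts = 0
        root = state.root
        for node in cache["post"]:
            if node.is_tip:
                stats[id(node)] = (tip_x[node.label], node.length)
                continue
            x, v = stats.pop(id(node.children[0]))
            for child in node.children[1:]:
                x2, v2 = stats.pop(id(child))
                total = v + v2
                if total < _MINVAR:
                    total = _MINVAR
                d = x - x2
                if w_arr is None:
                    Q += (d @ d) / total
                else:
                    Q += (w_arr @ (d * d)) / total
                logdet += math.log(total)
                n_contrasts += 1
                x = (v2 * x + v * x2) / total
                v = v * v2 / total
            own = node.length if (node is not root and node.length is not None) else 0.0
            stats[id(node)] = (x, v + own)
        w_sum = X.shape[1] if w_arr is None else float(w_arr.sum())
        return -0.5 * (w_sum * (n_contrasts * LOG2PI + logdet) + Q)

    cur_ll = loglik()
    cur_prior = prior.log_density(lengths_vec())
    proposed = {"branch": 0, "rescale": 0, "reattach": 0}
    accepted = {"branch": 0, "rescale": 0, "reattach": 0}
    records = []
    move_p = np.array([settings.p_branch, settings.p_rescale, settings.p_reattach])

    for gen in range(settings.generations + 1):
        if gen > 0:
            kind = ("branch", "rescale", "reattach")[rng.choice(3, p=move_p)]
            proposed[kind] += 1
            if kind == "branch":
                blist = branches()
                node = blist[rng.integers(len(blist))]
                old = node.length
                factor = math.exp(settings.multiplier_tuning * (rng.random() - 0.5))
                node.length = old * factor
                new_ll = loglik()
                new_prior = prior.log_density(lengths_vec())
                log_alpha = (new_ll - cur_ll) + (new_prior - cur_prior) + math.log(factor)
                if math.log(rng.random() + 1e-300) < log_alpha:
                    cur_ll, cur_prior = new_ll, new_prior
                    accepted[kind] += 1
                else:
                    node.length = old
            elif kind == "rescale":
                factor = math.exp(settings.rescale_tuning * (rng.random() - 0.5))
                blist = branches()
                for node in blist:
                    node.length *= factor
                new_ll = loglik()
                new_prior = prior.log_density(lengths_vec())
                log_alpha = (new_ll - cur_ll) + (new_prior - cur_prior) + len(blist) * math.log(factor)
                if math.log(rng.random() + 1e-300) < log_alpha:
                    cur_ll, cur_prior = new_ll, new_prior
                    accepted[kind] += 1
                else:
                    for node in blist:
                        node.length /= factor
            else:
                q = queries[rng.integers(len(queries))]
                snapshot = state.copy()
                cache["post"] = cache["branches"] = None
                tip, merged_len = _prune_tip(state, q)
                targets = _branch_nodes(state)
                host = targets[rng.integers(len(targets))]
                host_len = host.length or 0.0
                _attach_tip(state, tip, host, split=float(rng.random()))
                new_ll = loglik()
                new_prior = prior.log_density(lengths_vec())
                # forward draws position on the target edge, reverse on the
                # merged edge at the old location
                hastings = math.log(max(host_len, _MINVAR)) - math.log(max(merged_len, _MINVAR))
                log_alpha = (new_ll - cur_ll) + (new_prior - cur_prior) + hastings
                if math.log(rng.random() + 1e-300) < log_alpha:
                    cur_ll, cur_prior = new_ll, new_prior
                    accepted[kind] += 1
                else:
                    state = snapshot
                    cache["post"] = cache["branches"] = None
        if gen % settings.sample_interval == 0:
            placement = classify_placement(state, queries, child_side)
            records.append({
                "generation": gen,
                "loglik": cur_ll,
                "log_prior": cur_prior,
                "tree_length": float(lengths_vec().sum()),
                "mode": placement.mode,
                "edges": placement.edges,
                "order": placement.order,
            })
    if settings.generations >= 10_000 and all(v == 0 for v in accepted.values()):
        raise RuntimeError(f"zero acceptance across all moves: {proposed}")
    acc = {
        k: (accepted[k] / proposed[k] if proposed[k] else math.nan) for k in proposed
    }
    return McmcRun(
        samples=pd.DataFrame(records), settings=settings, seed=seed,
        n_queries=len(queries), acceptance=acc,
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


def _autocorr(x: np.ndarray) -> np.ndarray:
    n = len(x)
    x = x - x.mean()
    nfft = int(2 ** math.ceil(math.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    if acov[0] <= 0:
        return np.zeros(n)
    return acov / acov[0]


def _tau(x: np.ndarray) -> float:
    """Integrated autocorrelation time (Geyer initial positive sequence)."""
    rho = _autocorr(x)
    n = len(x)
    tau = 1.0
    for lag in range(1, n - 1, 2):
        pair = rho[lag] + rho[lag + 1] if lag + 1 < n else rho[lag]
        if pair <= 0:
            break
        tau += 2.0 * pair
    return max(tau, 1.0)


def ess(series) -> float:
    """Effective sample size from the integrated autocorrelation time."""
    x = np.asarray(series, float)
    if len(x) < 4 or np.ptp(x) == 0:
        return math.nan
    return len(x) / _tau(x)


def geweke(series, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late window means.

    Window variances are the autocorrelation-adjusted (spectral) variances
    of the two sub-series.  Returns NaN for constant series (diagnostic
    undefined, not an error).
    """
    x = np.asarray(series, float)
    if len(x) < 100:
        raise ValueError("Geweke diagnostic needs at least 100 samples")
    if np.ptp(x) == 0:
        return math.nan
    a = x[: int(first * len(x))]
    b = x[-int(last * len(x)):]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return math.nan
    var_a = a.var(ddof=1) * _tau(a) / len(a)
    var_b = b.var(ddof=1) * _tau(b) / len(b)
    return float((a.mean() - b.mean()) / math.sqrt(var_a + var_b))


@dataclass
class ConvergenceReport:
    converged: bool
    burnin_frac: float
    rerun_flag: bool
    log: list[str]


def burnin_protocol(
    run: McmcRun,
    z_crit: float = 1.96,
    min_ess: float = 500.0,
    max_burnin: float = 0.5,
    series_column: str = "loglik",
) -> ConvergenceReport:
    """Iterative burn-in escalation until the chain looks converged.

    Starting at 10% burn-in, checks the Geweke statistic and the ESS of
    the chosen series; while either fails, discards another 10%.  If the
    chain still fails at ``max_burnin``, flags it for a re-run at twice
    the length.  Every decision is logged.
    """
    series = run.samples[series_column].to_numpy(float)
    log: list[str] = []
    burn = 0.1
    while burn <= max_burnin + 1e-9:
        post = series[int(burn * len(series)):]
        z = geweke(post) if len(post) >= 100 else math.nan
        e = ess(post)
        ok_z = (not math.isnan(z)) and abs(z) < z_crit
        ok_e = (not math.isnan(e)) and e >= min_ess
        if math.isnan(z) and np.ptp(post) == 0:
            log.append(f"burn-in {burn:.0%}: constant series, treated as converged")
            run.burnin_frac = burn
            return ConvergenceReport(True, burn, False, log)
        log.append(f"burn-in {burn:.0%}: geweke z={z:.3f}, ESS={e:.0f}")
        if ok_z and ok_e:
            run.burnin_frac = burn
            return ConvergenceReport(True, burn, False, log)
        burn = round(burn + 0.1, 10)
    log.append(f"not converged at {max_burnin:.0%} burn-in: flagging for a 2x re-run")
    run.burnin_frac = max_burnin
    return ConvergenceReport(False, max_burnin, True, log)


def summarize_placements(run: McmcRun, burnin_frac: Optional[float] = None) -> pd.DataFrame:
    """Posterior probability per (edge, mode) from post-burn-in samples."""
    burn = run.burnin_frac if burnin_frac is None else burnin_frac
    samples = run.samples
    post = samples[samples["generation"] >= burn * samples["generation"].max()]
    if post.empty:
        raise ValueError("no post-burn-in samples")
    groups = post.groupby(["mode", "edges", "order"], dropna=False).size()
    out = (groups / len(post)).rename("posterior").reset_index()
    return out.sort_values("posterior", ascending=False).reset_index(drop=True)
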