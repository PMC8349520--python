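"""Strict-clock Brownian maximum-likelihood placement on a dated tree.

Characters evolve by Brownian motion whose variance accumulates in
proportion to elapsed time (one diffusion rate per character across the
whole tree -- a strict morphological clock).  A query is tried on every
branch of the dated reference tree; on each branch the attachment age and
the query tip age are optimized within the branch's age interval and the
query's temporal bounds, while all reference divergence times stay fixed.

Likelihoods are computed with Felsenstein's pruning algorithm in a form
that profiles out the root state and (optionally) the per-character rates
analytically, so the numerical optimization is only two-dimensional.

Also provides the phylogenetic PCA rotation used to orthogonalize
characters against the evolutionary covariance implied by the dated tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .treespace import Node, ReferenceTree, TreeError

__all__ = [
    "TemporalConstraints",
    "BrownianFit",
    "prune_quadratic",
    "strict_clock_loglik",
    "tree_covariance",
    "phylo_pca_rotation",
    "ml_place",
]

LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class TemporalConstraints:
    """Allowed age window (Ma) for the query tip; extant queries use (0, 0)."""

    lower: float = 0.0
    upper: float = 0.0

    def __post_init__(self):
        if not (self.upper >= self.lower >= 0.0):
            raise ValueError("temporal bounds must satisfy upper >= lower >= 0")


@dataclass
class BrownianFit:
    """Result of fitting the strict-clock model with a query on one edge."""

    edge: frozenset
    log_likelihood: float
    attachment_age: float
    tip_age: float
    pendant_length: float
    rates: np.ndarray
    root_states: np.ndarray


def _durations_from_ages(tree: ReferenceTree) -> None:
    for node in tree.postorder():
        if node is tree.root:
            continue
        if node.age is None or node.parent.age is None:
            raise TreeError("dated operations require node ages on every node")
        node.length = node.parent.age - node.age
        if node.length < 0:
            raise TreeError("negative branch duration: child older than parent")


def prune_quadratic(tree: ReferenceTree, X: pd.DataFrame, min_var: float = 1e-12):
    """Pruning pass returning the sufficient statistics of the BM likelihood.

    Returns (Q, logdet_contrasts, v_root, root_state, n_tips): per-character
    standardized contrast sums of squares Q_c (at unit rate), the summed log
    contrast variances, the effective root variance 1/(1'V^-1 1), the GLS
    root state per character, and the tip count.  Branch lengths must be on
    the nodes; polytomies are combined pairwise (exact for the MVN model).
    """
    stats: dict[int, tuple[np.ndarray, float]] = {}
    Q = np.zeros(X.shape[1])
    logdet = 0.0
    n_tips = 0
    for node in tree.postorder():
        if node.is_tip:
            if node.label not in X.index:
                raise KeyError(f"tip {node.label!r} has no character row")
            if node.length is None or node.length < 0:
                raise TreeError(f"tip {node.label!r} lacks a valid branch length")
            stats[id(node)] = (X.loc[node.label].to_numpy(float), float(node.length))
            n_tips += 1
            continue
        x, v = stats.pop(id(node.children[0]))
        for child in node.children[1:]:
            x2, v2 = stats.pop(id(child))
            total = max(v + v2, min_var)
            Q += (x - x2) ** 2 / total
            logdet += math.log(total)
            x = (v2 * x + v * x2) / total
            v = v * v2 / total
        own = node.length if (node is not tree.root and node.length is not None) else 0.0
        stats[id(node)] = (x, v + own)
    root_state, v_root = stats[id(tree.root)]
    return Q, logdet, v_root, root_state, n_tips


def strict_clock_loglik(
    tree: ReferenceTree,
    X: pd.DataFrame,
    rates: Optional[np.ndarray] = None,
    reml: bool = False,
    shared_rate: bool = False,
):
    """Brownian log-likelihood of continuous characters on a dated tree.

    With ``rates=None`` the per-character diffusion rates (trait^2/Myr) are
    profiled at their maximizing values (a single shared rate instead when
    ``shared_rate``).  Characters are independent; the total is the sum of
    per-character Brownian log-densities.  Returns (loglik, rates,
    root_states).
    """
    work = tree.copy()
    _durations_from_ages(work)
    Q, logdet, v_root, root_state, n = prune_quadratic(work, X)
    n_chars = X.shape[1]
    n_eff = n - 1 if reml else n
    ld = logdet if reml else logdet + math.log(max(v_root, 1e-300))
    if rates is None:
        if shared_rate:
            sigma2 = np.full(n_chars, max(Q.sum() / (n_eff * n_chars), 1e-300))
        else:
            sigma2 = np.maximum(Q / n_eff, 1e-300)
    else:
        sigma2 = np.asarray(rates, float)
        if (sigma2 < 0).any():
            raise ValueError("rates must be non-negative")
        sigma2 = np.maximum(sigma2, 1e-300)
    ll = -0.5 * (n_eff * (LOG2PI + np.log(sigma2)) + ld + Q / sigma2)
    return float(ll.sum()), sigma2, root_state


# ---------------------------------------------------------------------------
# Phylogenetic PCA rotation
# ---------------------------------------------------------------------------


def tree_covariance(tree: ReferenceTree) -> pd.DataFrame:
    """Shared-ancestry covariance (in Myr) implied by a dated tree."""
    tips = tree.tips()
    labels = [t.label for t in tips]
    root_age = tree.root.age
    if root_age is None:
        raise TreeError("tree covariance requires node ages")
    C = pd.DataFrame(0.0, index=labels, columns=labels)
    clades: dict[int, list[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            clades[id(node)] = [node.label]
            C.loc[node.label, node.label] = root_age - node.age
            continue
        kids = [clades.pop(id(c)) for c in node.children]
        shared = root_age - node.age
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                C.loc[kids[i], kids[j]] = shared
                C.loc[kids[j], kids[i]] = shared
        clades[id(node)] = [lbl for grp in kids for lbl in grp]
    return C


def phylo_pca_rotation(
    X: pd.DataFrame,
    tree: ReferenceTree,
    extra_rows: Optional[pd.DataFrame] = None,
):
    """Rotate characters with the loadings of a phylogenetic PCA.

    The evolutionary covariance between characters is estimated by
    generalized least squares with the tree covariance; the data (centered
    on the GLS ancestral mean) are rotated by its eigenvectors with no
    dimension truncation.  ``extra_rows`` (e.g. query/fossil rows) are
    rotated with the same center and loadings.  Missing cells are refused:
    impute or exclude them explicitly first.

    Returns (rotated, loadings, eigenvalues[, rotated_extra]).
    """
    if X.isna().any().any():
        raise ValueError(
            "phylogenetic PCA cannot handle missing cells: "
            "mean-impute or exclude them explicitly first"
        )
    C = tree_covariance(tree).loc[X.index, X.index].to_numpy()
    Cinv = np.linalg.inv(C)
    ones = np.ones(len(X))
    Xv = X.to_numpy(float)
    anc = (ones @ Cinv @ Xv) / (ones @ Cinv @ ones)
    centered = Xv - anc
    R = centered.T @ Cinv @ centered / (len(X) - 1)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    cols = [f"pPC{i+1}" for i in range(X.shape[1])]
    rotated = pd.DataFrame(centered @ eigvec, index=X.index, columns=cols)
    loadings = pd.DataFrame(eigvec, index=X.columns, columns=cols)
    if extra_rows is not None:
        extra = pd.DataFrame(
            (extra_rows.to_numpy(float) - anc) @ eigvec,
            index=extra_rows.index, columns=cols,
        )
        return rotated, loadings, eigval, extra
    return rotated, loadings, eigval


# ---------------------------------------------------------------------------
# ML placement
# ---------------------------------------------------------------------------


class _Message:
    """Gaussian elimination message: value, accumulated variance, and the
    contrast terms (Q per character, summed log variances) consumed so far."""

    __slots__ = ("x", "v", "Q", "ld")

    def __init__(self, x, v, Q, ld):
        self.x, self.v, self.Q, self.ld = x, v, Q, ld

    def shifted(self, dv: float) -> "_Message":
        return _Message(self.x, self.v + dv, self.Q, self.ld)


def _combine(m1: _Message, m2: _Message, min_var: float = 1e-12) -> _Message:
    total = max(m1.v + m2.v, min_var)
    Q = m1.Q + m2.Q + (m1.x - m2.x) ** 2 / total
    ld = m1.ld + m2.ld + math.log(total)
    x = (m2.v * m1.x + m1.v * m2.x) / total
    return _Message(x, m1.v * m2.v / total, Q, ld)


def _edge_message_table(tree: ReferenceTree, X: pd.DataFrame):
    """Downward messages and root-path recombination chains per edge.

    ``below[n]`` eliminates the subtree under n (variance accumulated at
    n).  ``chain[n]`` lists, for every ancestor of n from its parent up to
    the root, the combined downward message of that ancestor's off-path
    children and the ancestor's own edge length -- everything needed to
    finish the elimination toward the root after a query is inserted on
    the edge above n, without touching the rest of the tree.  The
    elimination terminates at the model root, which the strict-clock
    profile-root likelihood depends on.
    """
    zero = np.zeros(X.shape[1])
    below: dict[int, _Message] = {}
    for node in tree.postorder():
        if node.is_tip:
            below[id(node)] = _Message(
                X.loc[node.label].to_numpy(float), 0.0, zero.copy(), 0.0
            )
            continue
        msg = below[id(node.children[0])].shifted(node.children[0].length)
        for child in node.children[1:]:
            msg = _combine(msg, below[id(child)].shifted(child.length))
        below[id(node)] = msg
    chain: dict[int, list[tuple[Optional[_Message], float]]] = {}
    for node in tree.postorder():
        if node is tree.root:
            continue
        links = []
        cur = node
        while cur.parent is not None:
            parent = cur.parent
            sibs = [c for c in parent.children if c is not cur]
            sib_msg = None
            if sibs:
                sib_msg = below[id(sibs[0])].shifted(sibs[0].length)
                for s in sibs[1:]:
                    sib_msg = _combine(sib_msg, below[id(s)].shifted(s.length))
            own = parent.length if (parent is not tree.root and parent.length) else 0.0
            links.append((sib_msg, own))
            cur = parent
        chain[id(node)] = links
    return below, chain


def _placement_loglik(
    below: _Message,
    links: list,
    xq: np.ndarray,
    child_age: float,
    parent_age: float,
    att_age: float,
    tip_age: float,
    n_tips: int,
    shared_rate: bool,
    reml: bool = False,
) -> float:
    """Profile log-likelihood of the query attached at (att_age, tip_age)."""
    a = max(att_age - child_age, 0.0)
    b = max(parent_age - att_age, 0.0)
    s = max(att_age - tip_age, 0.0)
    msg = _combine(below.shifted(a), _Message(xq, s, np.zeros_like(xq), 0.0))
    msg = msg.shifted(b)
    for sib_msg, own in links:
        if sib_msg is not None:
            msg = _combine(msg, sib_msg)
        msg = msg.shifted(own)
    n = n_tips
    if reml:
        n_eff, ld = n - 1, msg.ld
    else:
        n_eff, ld = n, msg.ld + math.log(max(msg.v, 1e-300))
    Q = msg.Q
    if shared_rate:
        C = len(Q)
        sigma2 = max(Q.sum() / (n_eff * C), 1e-300)
        return float(
            -0.5 * (n_eff * C * (LOG2PI + math.log(sigma2)) + C * ld + Q.sum() / sigma2)
        )
    sigma2 = np.maximum(Q / n_eff, 1e-300)
    return float(np.sum(-0.5 * (n_eff * (LOG2PI + np.log(sigma2)) + ld + Q / sigma2)))


def _fit_components(
    below, links, xq, child_age, parent_age, att_age, tip_age, n, shared_rate
):
    a = max(att_age - child_age, 0.0)
    b = max(parent_age - att_age, 0.0)
    s = max(att_age - tip_age, 0.0)
    msg = _combine(below.shifted(a), _Message(xq, s, np.zeros_like(xq), 0.0))
    msg = msg.shifted(b)
    for sib_msg, own in links:
        if sib_msg is not None:
            msg = _combine(msg, sib_msg)
        msg = msg.shifted(own)
    if shared_rate:
        rates = np.full(len(msg.Q), max(msg.Q.sum() / (n * len(msg.Q)), 1e-300))
    else:
        rates = np.maximum(msg.Q / n, 1e-300)
    return rates, msg.x


def ml_place(
    tree: ReferenceTree,
    X: pd.DataFrame,
    query: str,
    constraints: TemporalConstraints = TemporalConstraints(0.0, 0.0),
    shared_rate: bool = False,
    reml: bool = False,
    tol: float = 1e-8,
) -> tuple[list[BrownianFit], BrownianFit]:
    """Maximum-likelihood placement of one query on every feasible edge.

    For each edge, the attachment age ranges over [max(child age, lower),
    parent age] and the tip age over [lower, min(upper, attachment age)];
    the profile log-likelihood is maximized by coordinate-wise bounded
    scalar optimization from three starting points.  Reference node ages
    are never altered.  Returns (per-edge fits, best fit).
    """
    if query not in X.index:
        raise KeyError(f"query {query!r} has no character row")
    q_obs = X.loc[query].notna()
    if not q_obs.any():
        raise ValueError(f"query {query!r} has no observed characters")
    X_obs = X.loc[:, q_obs.index[q_obs]]
    backbone_rows = [s for s in X_obs.index if s != query]
    if X_obs.loc[backbone_rows].isna().any().any():
        raise ValueError("reference species must have complete continuous rows")
    X_fit = X_obs.loc[backbone_rows + [query]]

    X_ref = X_fit.drop(index=query)
    xq = X_fit.loc[query].to_numpy(float)
    n_total = len(X_fit)
    work = tree.copy()
    _durations_from_ages(work)
    below, chain = _edge_message_table(work, X_ref)

    lower, upper = constraints.lower, constraints.upper
    fits: list[BrownianFit] = []
    violations = []
    for key, child in work.edges(unrooted=False):
        child_age, parent_age = child.age, child.parent.age
        att_lo = max(child_age, lower)
        att_hi = parent_age
        if att_hi < att_lo - 1e-12:
            violations.append(
                f"{sorted(key)}: branch ages [{child_age:g}, {parent_age:g}] "
                f"below the lower bound {lower:g}"
            )
            continue
        msg_b, links = below[id(child)], chain[id(child)]

        def loglik(att_age: float, tip_age: float) -> float:
            return _placement_loglik(
                msg_b, links, xq, child_age, parent_age, att_age, tip_age,
                n_total, shared_rate, reml=reml,
            )

        xatol = max(tol, 1e-7)

        def profile(att_age: float) -> tuple[float, float]:
            t_hi = min(upper, att_age)
            if t_hi <= lower + 1e-12:
                return loglik(att_age, lower), lower
            res = optimize.minimize_scalar(
                lambda t: -loglik(att_age, t),
                bounds=(lower, t_hi), method="bounded", options={"xatol": xatol},
            )
            t_best = float(res.x)
            ll = loglik(att_age, t_best)
            # the boundary (degenerate pendant) can beat the interior
            ll_lo = loglik(att_age, lower)
            return (ll, t_best) if ll >= ll_lo else (ll_lo, lower)

        span = att_hi - att_lo
        # coarse deterministic scan to pick the basin, then coordinate
        # refinement; the scan includes both interval endpoints
        best = (-np.inf, att_lo, lower)
        atts = np.linspace(att_lo, att_hi, 9) if span > 0 else [att_lo]
        tips = (np.linspace(lower, upper, 5) if upper > lower + 1e-12 else [lower])
        for att in atts:
            for tip in tips:
                if tip > att + 1e-12:
                    continue
                ll = loglik(att, min(tip, att))
                best = max(best, (ll, float(att), float(min(tip, att))))
        att = best[1]
        for _ in range(3):  # coordinate sweeps until stable
            if span > 0:
                res = optimize.minimize_scalar(
                    lambda a: -profile(a)[0],
                    bounds=(att_lo, att_hi), method="bounded",
                    options={"xatol": xatol},
                )
                att = float(res.x)
            ll, t_best = profile(att)
            if ll <= best[0] + tol:
                best = max(best, (ll, att, t_best))
                break
            best = (ll, att, t_best)
        ll, att_age, tip_age = best
        rates, roots = _fit_components(
            msg_b, links, xq, child_age, parent_age, att_age, tip_age, n_total,
            shared_rate,
        )
        fits.append(BrownianFit(
            edge=key, log_likelihood=ll, attachment_age=att_age, tip_age=tip_age,
            pendant_length=att_age - tip_age, rates=rates, root_states=roots,
        ))
    if not fits:
        raise TreeError(
            "no feasible edge under the temporal constraints: " + "; ".join(violations)
        )
    best_fit = max(fits, key=lambda f: f.log_likelihood)
    return fits, best_fit


def fits_to_frame(fits: list[BrownianFit]) -> pd.DataFrame:
    frame = pd.DataFrame([
        {
            "edge": ",".join(sorted(f.edge)),
            "loglik": f.log_likelihood,
            "attachment_age": f.attachment_age,
            "tip_age": f.tip_age,
            "pendant_length": f.pendant_length,
        }
        for f in fits
    ]).sort_values("loglik", ascending=False)
    # the two rooted child edges of the root share one unrooted branch:
    # report the better fit once
    frame = frame.drop_duplicates(subset="edge", keep="first")
    return frame.reset_index(drop=True)
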