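"""Leave-one-out placement performance and cost-scheme grid search.

Each extant species is pruned from the reference tree and re-placed from
its morphology alone.  The error of one trial is the nodal distance d
between the true and inferred attachment branches on the unrooted
backbone, scaled by its maximum possible value (the attachment node's
eccentricity minus one) to give d_s in [0, 1].  Ties among co-optimal
placements contribute the median of their scaled errors.  Across species
the errors are summarized by the cumulative error distribution curve,
its area under the curve (AUC = 1 - mean d_s, exact for the step CDF),
and the median.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import parsimony as mp
from .characters import CharacterMatrix
from .treespace import (
    Backbone,
    ReferenceTree,
    edge_distances_from,
    prune_query,
    scaled_error,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PerformanceSummary",
    "cumulative_curve",
    "auc",
    "loo_run",
    "parsimony_placer",
    "ml_placer",
    "bayes_placer",
    "scheme_grid",
    "default_scheme_grid",
]

# A placer maps (backbone, species) -> list of co-optimal edge keys.
Placer = Callable[[Backbone, str], list]


@dataclass
class PerformanceSummary:
    """Per-species placement errors and their overall summary."""

    per_species: pd.DataFrame  # species, d, d_max, d_s
    engine: str
    scheme: str = ""

    @property
    def d_s(self) -> np.ndarray:
        return self.per_species["d_s"].to_numpy(float)

    @property
    def auc(self) -> float:
        return auc(self.d_s)

    @property
    def median(self) -> float:
        return float(np.median(self.d_s))

    def to_frame(self) -> pd.DataFrame:
        return self.per_species.copy()


def cumulative_curve(d_s_values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF of the scaled errors.

    Returns (x, F(x)) at x = 0, the sorted unique errors, and 1.
    """
    v = np.asarray(d_s_values, float)
    if v.size == 0:
        raise ValueError("cumulative curve needs at least one error value")
    if ((v < 0) | (v > 1)).any():
        raise ValueError("scaled errors must lie in [0, 1]")
    xs = np.unique(np.concatenate([[0.0], np.sort(v), [1.0]]))
    F = np.array([(v <= x).mean() for x in xs])
    return xs, F


def auc(d_s_values: Sequence[float], method: str = "step") -> float:
    """Area under the cumulative error curve.

    'step' integrates the empirical step CDF exactly, which equals
    1 - mean(d_s); 'trapezoid' joins the CDF points linearly instead
    (differences are below 1/(2n)).
    """
    v = np.asarray(d_s_values, float)
    if v.size == 0:
        raise ValueError("AUC needs at least one error value")
    if method == "step":
        return float(1.0 - v.mean())
    if method == "trapezoid":
        xs, F = cumulative_curve(v)
        return float(np.trapezoid(F, xs))
    raise ValueError(f"unknown AUC method {method!r}")


def loo_run(
    tree: ReferenceTree,
    species: Sequence[str],
    placer: Placer,
    engine: str = "",
    scheme: str = "",
) -> PerformanceSummary:
    """Leave-one-out driver: prune, re-place, and score each species.

    ``placer`` returns the co-optimal attachment edges for one species on
    its backbone; species for which it returns nothing are skipped with a
    logged warning and excluded from the curve.
    """
    rows = []
    for sp in species:
        backbone = prune_query(tree, sp)
        edges = placer(backbone, sp)
        if not edges:
            logger.warning("species %s skipped: no feasible placement", sp)
            continue
        dist = edge_distances_from(backbone, backbone.true_edge)
        d_max = max(dist.values())
        tie_d = sorted(dist[e] for e in edges)
        d_s = float(np.median([scaled_error(d, d_max) for d in tie_d]))
        rows.append({
            "species": sp,
            "d": float(np.median(tie_d)),
            "d_max": d_max,
            "d_s": d_s,
            "n_ties": len(edges),
        })
    if not rows:
        raise ValueError("no species could be placed")
    return PerformanceSummary(pd.DataFrame(rows), engine=engine, scheme=scheme)


# ---------------------------------------------------------------------------
# Engine adapters
# ---------------------------------------------------------------------------


def parsimony_placer(matrix: CharacterMatrix, scheme: mp.CostScheme) -> Placer:
    """Single-query parsimony placer over all backbone edges."""

    def place(backbone: Backbone, sp: str) -> list:
        try:
            table = mp.placement_search(backbone, matrix, [sp], scheme)
        except ValueError:
            return []
        return [table.placements[i].edges[0] for i in table.co_optimal]

    return place


def ml_placer(X: pd.DataFrame, shared_rate: bool = False, tol: float = 1e-6) -> Placer:
    """Strict-clock Brownian ML placer for extant queries (tip age 0)."""
    from .brownian_ml import TemporalConstraints, ml_place

    def place(backbone: Backbone, sp: str) -> list:
        if sp not in X.index or X.loc[sp].isna().all():
            return []
        fits, best = ml_place(
            backbone.tree, X, sp, TemporalConstraints(0.0, 0.0),
            shared_rate=shared_rate,
        )
        top = [f.edge for f in fits if f.log_likelihood >= best.log_likelihood - 1e-9]
        return sorted(set(top), key=lambda k: sorted(k))

    return place


def bayes_placer(
    X: pd.DataFrame,
    weights: Optional[np.ndarray] = None,
    settings=None,
    seed: int = 0,
) -> Placer:
    """Bayesian placer: one MCMC per species, maximum-posterior edge."""
    from .bayes import (
        BranchLengthPrior, McmcSettings, mcmc_place, ml_branch_lengths,
        summarize_placements,
    )

    settings = settings or McmcSettings()

    def place(backbone: Backbone, sp: str) -> list:
        if sp not in X.index or X.loc[sp].isna().all():
            return []
        X_bb = X.loc[[t for t in backbone.tree.tip_labels] + [sp]]
        fit_tree, _ = ml_branch_lengths(backbone.tree, X_bb.drop(index=sp), max_sweeps=3)
        prior = BranchLengthPrior(ml_tree_length=max(fit_tree.total_length(), 1e-6))
        run = mcmc_place(
            backbone.tree, X_bb, weights, prior, [sp],
            settings=settings, seed=seed + zlib.crc32(sp.encode()) % 100_000,
        )
        post = summarize_placements(run)
        best = post.iloc[0]
        return [best["edges"][0]]

    return place


# ---------------------------------------------------------------------------
# Cost-scheme grid search (parsimony, cached lengths)
# ---------------------------------------------------------------------------

K_GRID = (1, 2, 3, 6, 10, 25, 50, 75, 100, 125, 250, 500, 750, 1000)
R_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)
SCALINGS = ("raw", "range", "zscore")


def default_scheme_grid(ci: bool = True) -> list[mp.CostScheme]:
    """The full factorial: per scaling, equal weights plus every (k, R)."""
    schemes = []
    for scaling in SCALINGS:
        schemes.append(mp.CostScheme("equal", scaling=scaling, ci=ci))
        for k in K_GRID:
            for R in R_GRID:
                schemes.append(
                    mp.CostScheme("extended" if R > 0 else "implied",
                                  k=float(k), R=R, scaling=scaling, ci=ci)
                )
    return schemes


@dataclass
class _LooCache:
    data: mp.ScoredData
    species: list[str]
    lengths: dict[str, np.ndarray]     # species -> (n_edges, n_chars)
    distances: dict[str, np.ndarray]   # species -> nodal distance per edge
    d_max: dict[str, int]


def _build_loo_cache(
    tree: ReferenceTree, matrix: CharacterMatrix, scaling: str, ci: bool
) -> _LooCache:
    from .treespace import apply_placement, enumerate_placements

    data = mp.ScoredData(matrix, mp.CostScheme("equal", scaling=scaling, ci=ci))
    lengths, distances, d_max = {}, {}, {}
    species = [s for s in matrix.extant if s in tree.tip_labels]
    for sp in species:
        backbone = prune_query(tree, sp)
        placements = enumerate_placements(backbone, [sp])
        L = np.empty((len(placements), data.n_characters))
        for i, placement in enumerate(placements):
            L[i] = mp.character_lengths(apply_placement(backbone, placement), data)
        dist = edge_distances_from(backbone, backbone.true_edge)
        distances[sp] = np.array([dist[p.edges[0]] for p in placements])
        d_max[sp] = max(dist.values())
        lengths[sp] = L
    return _LooCache(data, species, lengths, distances, d_max)


def _summary_from_cache(cache: _LooCache, scheme: mp.CostScheme) -> PerformanceSummary:
    data = cache.data
    kc = None
    if scheme.weighting != "equal":
        kc = (np.full(data.n_characters, float(scheme.k))
              if scheme.weighting == "implied"
              else mp.extended_k(scheme.k, scheme.R, data.missing_fraction))
    rows = []
    for sp in cache.species:
        L = cache.lengths[sp]
        if kc is None:
            scores = L @ data.weights
        else:
            h = np.maximum(L - data.min_steps, 0.0)
            scores = (data.weights * h / (h + kc)).sum(axis=1)
        best = scores.min()
        ties = np.flatnonzero(scores <= best + 1e-9)
        tie_d = np.sort(cache.distances[sp][ties])
        d_s = float(np.median(tie_d / cache.d_max[sp]))
        rows.append({
            "species": sp, "d": float(np.median(tie_d)),
            "d_max": cache.d_max[sp], "d_s": d_s, "n_ties": len(ties),
        })
    return PerformanceSummary(pd.DataFrame(rows), engine="parsimony",
                              scheme=scheme.label())


def plot_cumulative_curves(summaries: Sequence[PerformanceSummary], path) -> None:
    """Save an SVG of cumulative error curves (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for summary in summaries:
        xs, F = cumulative_curve(summary.d_s)
        label = f"{summary.engine} {summary.scheme}".strip()
        ax.step(xs, F, where="post",
                label=f"{label} (AUC={summary.auc:.3f})")
    ax.set_xlabel("scaled placement error $d_s$")
    ax.set_ylabel("fraction of species with error $\\leq d_s$")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def loo_parsimony(
    tree: ReferenceTree, matrix: CharacterMatrix, scheme: mp.CostScheme
) -> PerformanceSummary:
    """Parsimony LOO with per-scaling length caching (one matrix compile)."""
    cache = _build_loo_cache(tree, matrix, scheme.scaling, scheme.ci)
    return _summary_from_cache(cache, scheme)


def scheme_grid(
    tree: ReferenceTree,
    matrix: CharacterMatrix,
    scalings: Sequence[str] = SCALINGS,
    k_values: Sequence[float] = K_GRID,
    R_values: Sequence[float] = R_GRID,
    ci: bool = True,
) -> tuple[pd.DataFrame, list[mp.CostScheme]]:
    """LOO performance over the full scaling x weighting factorial.

    Per-character placement lengths are cached per scaling, so the 71
    weighting schemes per scaling reuse one set of tree scorings.  Returns
    (results table, list of AUC-maximal schemes -- all ties reported).
    """
    rows = []
    scored: list[tuple[mp.CostScheme, float, float]] = []
    for scaling in scalings:
        cache = _build_loo_cache(tree, matrix, scaling, ci)
        schemes = [mp.CostScheme("equal", scaling=scaling, ci=ci)]
        schemes += [
            mp.CostScheme("extended" if R > 0 else "implied",
                          k=float(k), R=R, scaling=scaling, ci=ci)
            for k in k_values for R in R_values
        ]
        for scheme in schemes:
            summary = _summary_from_cache(cache, scheme)
            scored.append((scheme, summary.auc, summary.median))
            rows.append({
                "scaling": scaling, "weighting": scheme.weighting,
                "k": scheme.k if scheme.k is not None else np.nan,
                "R": scheme.R, "ci": ci,
                "auc": summary.auc, "median": summary.median,
            })
    table = pd.DataFrame(rows)
    best_auc = table["auc"].max()
    best = [s for s, a, _ in scored if a >= best_auc - 1e-12]
    return table, best
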