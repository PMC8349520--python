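"""Parsimony scoring and exhaustive placement search.

Two scoring kernels cover the whole combined matrix:

* unordered discrete characters are scored with unit-cost Sankoff dynamic
  programming, which handles polymorphic state sets, missing cells and
  polytomies exactly (it reduces to Fitch on binary trees);
* ordered discrete and continuous characters are scored with interval
  (linear/additive) parsimony.  Each child hands its parent a flat-bottom
  V cost profile; the sum of k such profiles attains its minimum between
  the k-th and (k+1)-th order statistics of the pooled interval bounds,
  which generalizes the classic two-child interval rule to polytomies.
  Continuous 95% CI cells behave exactly like polymorphic ordered states.

Weighting regimes: equal weights, implied weights (each character
contributes h/(h+k), h = observed homoplasy), and extended implied
weights where the concavity is adjusted per character for missing data,
extrapolating the homoplasy of unseen cells as a proportion R of the
observed homoplasy per observed cell: k_c = k / (1 + R * m_c / o_c).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .characters import CharacterMatrix
from .treespace import (
    Backbone,
    Placement,
    ReferenceTree,
    apply_placement,
    enumerate_placements,
)

__all__ = [
    "CostScheme",
    "ScoredData",
    "character_lengths",
    "min_steps",
    "extended_k",
    "tree_score",
    "placement_search",
    "bootstrap_support",
    "PlacementScoreTable",
    "SupportTable",
]

_BIG = 1e12
_TIE_TOL = 1e-9


@dataclass(frozen=True)
class CostScheme:
    """Scaling + weighting settings that fix the parsimony score of a tree.

    weighting : 'equal' | 'implied' | 'extended'
    k : concavity constant (required unless weighting == 'equal')
    R : extrapolated homoplasy proportion in [0, 1] (extended only)
    scaling : 'raw' | 'range' | 'zscore' applied to continuous characters
    ci : score continuous cells as 95% CI ranges (True) or point means
    """

    weighting: str = "equal"
    k: Optional[float] = None
    R: float = 0.0
    scaling: str = "raw"
    ci: bool = True

    def __post_init__(self):
        if self.weighting not in ("equal", "implied", "extended"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.weighting != "equal" and (self.k is None or self.k <= 0):
            raise ValueError("implied weighting requires a concavity k > 0")
        if not 0.0 <= self.R <= 1.0:
            raise ValueError("R must lie in [0, 1]")

    def label(self) -> str:
        if self.weighting == "equal":
            return f"{self.scaling}/equal"
        return f"{self.scaling}/{self.weighting} k={self.k:g} R={self.R:g}"


def extended_k(k: float, R: float, missing_fraction) -> np.ndarray:
    """Per-character concavity under extended implied weighting.

    Missing cells are treated as carrying homoplasy equal to R times the
    observed homoplasy per observed cell, which folds into the concavity
    as k_c = k / (1 + R * missing/observed).  R = 0 or no missing data
    leaves k unchanged; k_c decreases monotonically with missing fraction.
    """
    if not 0.0 <= R <= 1.0:
        raise ValueError("R must lie in [0, 1]")
    mf = np.asarray(missing_fraction, float)
    if np.any((mf < 0) | (mf >= 1)):
        raise ValueError("missing fraction must lie in [0, 1)")
    return k / (1.0 + R * mf / (1.0 - mf))


class ScoredData:
    """Matrix compiled to scoring arrays for a fixed cost scheme.

    Characters are ordered interval block first (continuous, then ordered
    discrete), unordered discrete block second.  Uninformative discrete
    characters get weight zero, mirroring their exclusion from analyses.
    """

    def __init__(self, matrix: CharacterMatrix, scheme: CostScheme):
        work = matrix
        if work.scaling is None and scheme.scaling != "raw":
            work, _ = work.scale(scheme.scaling)
        self.matrix = work
        self.scheme = scheme
        self.species = work.species
        self.row_of = {sp: i for i, sp in enumerate(self.species)}

        int_names, lo, hi = work.interval_blocks(ci=scheme.ci)
        unord_names, allowed = work.unordered_blocks()
        self.interval_names = int_names
        self.unordered_names = unord_names
        self.names = int_names + unord_names
        self.lo, self.hi = lo, hi
        self.allowed = allowed

        informative = work.informative_mask()
        w_int = np.ones(len(int_names))
        for j, name in enumerate(int_names):
            if name in informative.index and not informative[name]:
                w_int[j] = 0.0
        w_un = np.array([1.0 if informative.get(n, True) else 0.0 for n in unord_names])
        self.weights = np.concatenate([w_int, w_un])

        mf = work.missing_fraction()
        self.missing_fraction = np.clip(
            np.array([mf.get(n, 0.0) for n in self.names]), 0.0, 1.0 - 1e-12
        )
        self.min_steps = min_steps(self)

    @property
    def n_characters(self) -> int:
        return len(self.names)

    def char_k(self) -> Optional[np.ndarray]:
        s = self.scheme
        if s.weighting == "equal":
            return None
        if s.weighting == "implied":
            return np.full(self.n_characters, float(s.k))
        return extended_k(s.k, s.R, self.missing_fraction)


def min_steps(data: ScoredData) -> np.ndarray:
    """Minimum conceivable length per character over any tree.

    Interval characters: max(0, max of lows - min of highs).  Unordered
    characters: (size of the smallest state set hitting every observed
    cell) - 1, i.e. the best-case polymorphism resolution.
    """
    out = np.zeros(data.n_characters)
    if data.lo.size:
        max_lo = data.lo.max(axis=0)
        min_hi = data.hi.min(axis=0)
        gap = max_lo - min_hi
        gap[~np.isfinite(gap)] = 0.0
        out[: data.lo.shape[1]] = np.maximum(0.0, gap)
    offset = data.lo.shape[1]
    n_sp, n_un, _ = data.allowed.shape
    for j in range(n_un):
        n_states_j = int(data.allowed[:, j].any(axis=0).sum())
        cells = []
        for i in range(n_sp):
            states = frozenset(np.flatnonzero(data.allowed[i, j]))
            # cells allowing every state of the character (missing, or
            # fully polymorphic) constrain nothing for the hitting set
            if 0 < len(states) < n_states_j:
                cells.append(states)
        if not cells:
            out[offset + j] = 0.0
            continue
        observed = sorted(set().union(*cells))
        best = len(observed)
        for size in range(1, len(observed) + 1):
            if any(
                all(set(combo) & c for c in cells)
                for combo in itertools.combinations(observed, size)
            ):
                best = size
                break
        out[offset + j] = best - 1
    return out


def character_lengths(tree: ReferenceTree, data: ScoredData) -> np.ndarray:
    """Per-character parsimony length of ``tree`` (one postorder pass)."""
    n_int = data.lo.shape[1]
    n_sp, n_un, smax = data.allowed.shape
    cost = np.zeros(n_int)
    states: dict[int, tuple] = {}
    for node in tree.postorder():
        if node.is_tip:
            try:
                row = data.row_of[node.label]
            except KeyError:
                raise KeyError(f"tip {node.label!r} has no data row") from None
            ival = (data.lo[row], data.hi[row])
            dp = np.where(data.allowed[row], 0.0, _BIG)
            states[id(node)] = (ival, dp)
            continue
        kids = [states.pop(id(c)) for c in node.children]
        k = len(kids)
        if k == 1:  # unary node (transiently possible): pass through
            states[id(node)] = kids[0]
            continue
        # interval block: min region of the summed flat-bottom profiles
        if n_int:
            los = np.stack([kv[0][0] for kv in kids])
            his = np.stack([kv[0][1] for kv in kids])
            pooled = np.sort(np.concatenate([los, his], axis=0), axis=0)
            a, b = pooled[k - 1], pooled[k]
            m = np.where(np.isfinite(a), a, 0.0)
            cost += np.maximum(los - m, 0.0).sum(axis=0)
            cost += np.maximum(m - his, 0.0).sum(axis=0)
            ival = (a, b)
        else:
            ival = (np.empty(0), np.empty(0))
        # unordered block: unit-cost Sankoff
        if n_un:
            dp = np.zeros((n_un, smax))
            for _, child_dp in kids:
                dp += np.minimum(child_dp, child_dp.min(axis=1, keepdims=True) + 1.0)
        else:
            dp = np.empty((0, smax))
        states[id(node)] = (ival, dp)
    (_, root_dp) = states[id(tree.root)]
    lengths = np.empty(data.n_characters)
    lengths[:n_int] = cost
    if n_un:
        lengths[n_int:] = root_dp.min(axis=1)
    return lengths


def score_from_lengths(lengths: np.ndarray, data: ScoredData) -> float:
    """Total score under the scheme from per-character lengths."""
    contrib = character_contributions(lengths, data)
    return float(contrib.sum())


def character_contributions(lengths: np.ndarray, data: ScoredData) -> np.ndarray:
    kc = data.char_k()
    if kc is None:
        return data.weights * lengths
    h = lengths - data.min_steps
    if (h < -1e-9).any():
        warnings.warn("negative homoplasy clamped to zero", stacklevel=2)
    h = np.maximum(h, 0.0)
    return data.weights * h / (h + kc)


def tree_score(tree: ReferenceTree, matrix: CharacterMatrix, scheme: CostScheme) -> float:
    """Parsimony score of a fully specified tree under a cost scheme."""
    data = ScoredData(matrix, scheme)
    return score_from_lengths(character_lengths(tree, data), data)


# ---------------------------------------------------------------------------
# Placement search and bootstrap
# ---------------------------------------------------------------------------


@dataclass
class PlacementScoreTable:
    placements: list[Placement]
    scores: np.ndarray
    lengths: np.ndarray  # (n_placements, n_characters)
    data: ScoredData

    @property
    def co_optimal(self) -> list[int]:
        best = self.scores.min()
        return [i for i, s in enumerate(self.scores) if s <= best + _TIE_TOL]

    @property
    def best_placements(self) -> list[Placement]:
        return [self.placements[i] for i in self.co_optimal]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        co = set(self.co_optimal)
        for i, (p, s) in enumerate(zip(self.placements, self.scores)):
            rows.append({
                "mode": p.mode,
                "edge": "|".join(sorted(",".join(sorted(e)) for e in p.edges)),
                "order": p.order or "",
                "score": s,
                "co_optimal": i in co,
            })
        return pd.DataFrame(rows).sort_values("score", kind="stable").reset_index(drop=True)


def _query_has_data(matrix: CharacterMatrix, query: str) -> bool:
    cont_ok = matrix.cont_mean.loc[query].notna().any() if matrix.continuous_names else False
    disc_ok = matrix.disc.loc[query].notna().any() if matrix.discrete_names else False
    return bool(cont_ok or disc_ok)


def placement_search(
    backbone: Backbone,
    matrix: CharacterMatrix,
    queries: Sequence[str],
    scheme: CostScheme,
    modes: Optional[Sequence[str]] = None,
) -> PlacementScoreTable:
    """Score every placement of the queries on the backbone exhaustively.

    For one query this is all E single placements; for two queries all E
    cherries, 2E sequentials and E(E-1) independent pairs.  Co-optimal
    placements are reported as ties, never broken silently.
    """
    for q in queries:
        if not _query_has_data(matrix, q):
            raise ValueError(f"query {q!r} has no scored data; refusing to place")
    data = ScoredData(matrix, scheme)
    placements = enumerate_placements(backbone, queries, modes=modes)
    lengths = np.empty((len(placements), data.n_characters))
    for i, placement in enumerate(placements):
        tree = apply_placement(backbone, placement)
        lengths[i] = character_lengths(tree, data)
    scores = np.array([score_from_lengths(lengths[i], data) for i in range(len(placements))])
    return PlacementScoreTable(placements, scores, lengths, data)


@dataclass
class SupportTable:
    """Bootstrap placement frequencies per (edge, mode)."""

    table: pd.DataFrame  # columns: edge (frozenset), mode, support_pct
    n_reps: int
    seed: int

    def branch_support(self, modes: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Aggregate support per branch, optionally over a subset of modes
        (e.g. the non-cherry kinds, as plotted per branch in figures)."""
        tbl = self.table
        if modes is not None:
            tbl = tbl[tbl["mode"].isin(modes)]
        out = tbl.groupby("edge", sort=False)["support_pct"].sum().reset_index()
        return out.sort_values("support_pct", ascending=False).reset_index(drop=True)


def bootstrap_support(
    backbone: Backbone,
    matrix: CharacterMatrix,
    queries: Sequence[str],
    scheme: CostScheme,
    n_reps: int = 5000,
    seed: int = 0,
    table: Optional[PlacementScoreTable] = None,
) -> SupportTable:
    """Character-resampling bootstrap of placement support.

    Characters (continuous and discrete alike) are resampled with
    replacement as exchangeable columns; per replicate, the co-optimal
    placements share one unit of mass equally.  Only characters carrying
    weight participate, mirroring the exclusion of uninformative ones.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if table is None:
        table = placement_search(backbone, matrix, queries, scheme)
    data = table.data
    active = np.flatnonzero(data.weights > 0)
    contrib = np.stack([
        character_contributions(table.lengths[i], data)
        for i in range(len(table.placements))
    ])[:, active]
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(len(active), np.full(len(active), 1.0 / len(active)), size=n_reps)
    rep_scores = contrib @ counts.T  # (placements, reps)
    mass: dict[tuple, float] = {}
    mins = rep_scores.min(axis=0)
    for r in range(n_reps):
        winners = np.flatnonzero(rep_scores[:, r] <= mins[r] + _TIE_TOL)
        share = 1.0 / len(winners)
        for i in winners:
            p = table.placements[i]
            key = (p.edges, p.mode)
            mass[key] = mass.get(key, 0.0) + share
    rows = [
        {"edge": edges[0] if len(edges) == 1 else edges, "mode": mode,
         "support_pct": 100.0 * m / n_reps}
        for (edges, mode), m in mass.items()
    ]
    tbl = pd.DataFrame(rows).sort_values("support_pct", ascending=False).reset_index(drop=True)
    return SupportTable(table=tbl, n_reps=n_reps, seed=seed)
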